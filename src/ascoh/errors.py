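"""Exception types shared across the pipeline."""


class InsufficientDataError(ValueError):
    """A series is too short, or a requested analysis window is not covered."""


class DegenerateSignalError(ValueError):
    """A signal has zero variance, so normalized autocorrelation is undefined."""


class DegenerateLabelsError(ValueError):
    """A label vector contains only one class, so ROC analysis is undefined."""


class DegenerateCohortError(RuntimeError):
    """Repeated random splits failed to place both classes in the training set."""
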