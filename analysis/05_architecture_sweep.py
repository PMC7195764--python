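"""Sweep hidden-layer width and depth across dose thresholds.

Reproduces the architecture-selection methodology: per (nodes, depth,
dose threshold) cell an ensemble of training runs yields mean error and
mean AUC surfaces; for depth > 1 the single-layer-minus-deeper
difference surfaces are printed (negative error difference means the
deeper network is worse).  Writes the long-format surface table to
<out>/architecture_sweep.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ascoh import coherence as coh
from ascoh import neural_net as nn
from ascoh import pipeline as pl
from ascoh import preprocessing as pp
from ascoh import synthetic_data as sd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20260)
    ap.add_argument("--runs", type=int, default=30)
    ap.add_argument("--nodes", type=int, nargs="+", default=[2, 4, 8, 12, 16])
    ap.add_argument("--depths", type=int, nargs="+", default=[1, 2])
    ap.add_argument("--thresholds", type=float, nargs="+", default=[400.0, 450.0])
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = sd.generate_cohort(sd.SyntheticCohortConfig(seed=args.seed))
    spectra, doses = [], []
    for p in cohort.patients:
        u = pp.resample_to_uniform(p.beats)
        spectra.append(coh.autocorrelation_spectrum(u))
        doses.append(p.dose_mcg)
    doses = np.array(doses)
    X, _ = nn.prepare_inputs(spectra, feature_len=400)
    features = {thr: (X, (doses > thr).astype(int)) for thr in args.thresholds}

    cfg = nn.MlpConfig(input_dim=X.shape[1], n_runs=args.runs, seed=args.seed)
    surface = nn.architecture_sweep(features, args.nodes, args.depths, cfg)

    rows = []
    for di, depth in enumerate(surface.depth_grid):
        for ni, nodes in enumerate(surface.node_grid):
            for ti, thr in enumerate(surface.thresholds):
                rows.append({"depth": depth, "nodes": nodes, "dose_threshold_mcg": thr,
                             "mean_error": surface.mean_error[di, ni, ti],
                             "mean_auc": surface.mean_auc[di, ni, ti]})
    table = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "architecture_sweep.csv", index=False)
    print(table.round(3).to_string(index=False))
    for depth in surface.depth_grid:
        if depth == 1:
            continue
        d_err, d_auc = surface.diff_vs_single_layer(depth)
        print(f"\nsingle-layer minus depth-{depth} mean error "
              f"(negative => deeper worse):\n{np.round(d_err, 3)}")
        print(f"single-layer minus depth-{depth} mean AUC:\n{np.round(d_auc, 3)}")


if __name__ == "__main__":
    main()
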