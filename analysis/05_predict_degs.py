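"""Predict downregulated genes from kernel-weighted peak features.

For each of 100 expression-matched control resamples, fits a lasso-logistic
model on the DAR-category features and on binding-occupancy-only features,
scores out-of-fold, and writes per-resample AUCs and the max-accuracy
operating points (TPR/FPR).

Usage: python analysis/05_predict_degs.py --seed 1 --sim results/sim \
    --features results/features --out results/prediction
"""

import argparse
from pathlib import Path

import pandas as pd

from pioneerdyn import prediction as pred


def run(seed: int, sim: Path, features: Path, out: Path, n_resample: int = 100):
    out.mkdir(parents=True, exist_ok=True)
    feats = pd.read_csv(features / "gene_features.tsv", sep="\t", index_col=0)
    truth_genes = pd.read_csv(sim / "truth_genes.tsv", sep="\t", index_col=0)
    cases = truth_genes.loc[truth_genes.deg_status == "down", "baseline_expr"]
    pool = truth_genes.loc[truth_genes.deg_status == "stable", "baseline_expr"]

    res = pred.predict_deg_pipeline(
        feats,
        {"dars": ["down_dar", "ndar", "up_dar"], "chip_only": ["chip"]},
        cases, pool, n_resample=n_resample, seed=seed,
    )
    rows = []
    for name, roc in res.items():
        ops = roc.operating_points
        ops.insert(0, "feature_set", name)
        rows.append(ops)
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
            out / f"roc_{name}.tsv", sep="\t", index=False
        )
    all_ops = pd.concat(rows, ignore_index=True)
    all_ops.to_csv(out / "resample_metrics.tsv", sep="\t", index=False)

    d = res["dars"].resample_aucs
    c = res["chip_only"].resample_aucs
    ops_d = res["dars"].operating_points
    print(
        f"DAR features: AUC {d.mean():.3f} +/- {d.std():.3f}; "
        f"binding-only: {c.mean():.3f} +/- {c.std():.3f} "
        f"(DAR better in {(d > c).sum()}/{len(d)} resamples)"
    )
    print(
        f"max-accuracy operating point (DARs): "
        f"TPR {ops_d.tpr_at_max_acc.mean():.2f}, FPR {ops_d.fpr_at_max_acc.mean():.2f}"
    )
    return res


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--features", type=Path, default=Path("results/features"))
    ap.add_argument("--out", type=Path, default=Path("results/prediction"))
    ap.add_argument("--resamples", type=int, default=100)
    args = ap.parse_args()
    run(args.seed, args.sim, args.features, args.out, args.resamples)
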