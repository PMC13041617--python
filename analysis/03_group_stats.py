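"""Group statistics on the per-subject metrics.

Mann-Whitney comparisons of the summed voxel-based SBRs (brainstem,
midbrain, pons) and the midbrain-to-pons ratio, age-adjusted ANCOVA,
Fisher's exact test on the sex split, and the ROC of the ratio with the
disease group as positive reference.  Writes results/group_stats.json and,
when matplotlib is importable, a ROC curve to results/roc_curve.svg.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import numpy as np

from sertquant.io import read_table
from sertquant.pipeline import group_statistics


def main() -> None:
    metrics = read_table(
        ROOT / "results" / "metrics.csv",
        required_columns=["subject_id", "group", "age", "sex", "excluded",
                          "midbrain_pons_ratio"],
    )
    stats = group_statistics(metrics)
    out = ROOT / "results" / "group_stats.json"
    out.write_text(json.dumps(stats, indent=2))

    for m in ("brainstem_summed_sbr", "midbrain_summed_sbr",
              "pons_summed_sbr", "midbrain_pons_ratio"):
        d = stats[m]
        direction = "lower" if d["median_positive"] < d["median_control"] else "higher"
        print(f"{m}: disease median {d['median_positive']:.2f} vs control "
              f"{d['median_control']:.2f} ({direction}), "
              f"Mann-Whitney p={d['mannwhitney_p']:.2g}, "
              f"ANCOVA p={d['ancova_group_p']:.2g}")
    roc = stats["ratio_roc"]
    print(f"ratio ROC: AUC {roc['auc']:.2f}, cutoff {roc['cutoff']:.2f} "
          f"(positive rule: ratio {roc['direction']} cutoff), "
          f"sens {roc['sensitivity']:.2f} / spec {roc['specificity']:.2f}")
    print(f"sex Fisher p={stats['sex_fisher_p']:.2f}, "
          f"age Mann-Whitney p={stats['age_mannwhitney_p']:.2g}")
    print(f"stats -> {out.relative_to(ROOT)}")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    df = metrics[~metrics["excluded"].astype(bool)]
    pos = df[df.group == "MSA-P"]["midbrain_pons_ratio"].to_numpy()
    neg = df[df.group == "HC"]["midbrain_pons_ratio"].to_numpy()
    thresholds = np.unique(np.concatenate([pos, neg]))
    tpr = [(pos <= t).mean() for t in thresholds]
    fpr = [(neg <= t).mean() for t in thresholds]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, *fpr, 1], [0, *tpr, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="gray")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"midbrain-to-pons ratio ROC (AUC {roc['auc']:.2f})")
    fig.tight_layout()
    fig.savefig(ROOT / "results" / "roc_curve.svg")
    print("ROC curve -> results/roc_curve.svg")


if __name__ == "__main__":
    main()
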