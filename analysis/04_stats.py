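#!/usr/bin/env python
"""Dyad-level statistics: conditions contrast, regressions, correlation.

Reads the ROI x condition index table written by 03_synchrony.py, rebuilds
the statistics report, prints the headline numbers, and (if matplotlib is
available) draws the satisfaction-difference vs right-cluster index
scatter under results/.
"""

from pathlib import Path

import pandas as pd

from dyadsync.stats import build_stats_report

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    roi = pd.read_csv(OUT / "pipeline" / "roi_condition_index.tsv", sep="\t")
    rep = build_stats_report(roi)

    k3, k2 = rep.kw_three_way, rep.kw_two_way
    print(f"Kruskal-Wallis positive/negative/baseline (right cluster): "
          f"H({k3.df}, n = {k3.group_sizes[0]}) = {k3.H:.2f}, p = {k3.p:.3f}")
    print(f"Kruskal-Wallis emotion vs baseline: "
          f"H({k2.df}, n = {k2.group_sizes[0]}) = {k2.H:.2f}, p = {k2.p:.3f}")
    for name, reg in (("right", rep.regression_right), ("left", rep.regression_left)):
        s = reg.terms["satisfaction_difference"]
        e = reg.terms["emotion_positive"]
        print(f"frontal {name} OLS (n = {reg.n_rows}): "
              f"delta-satisfaction {s.estimate:.4f} (t({reg.df_resid}) = {s.t:.2f}, "
              f"p = {s.p:.3f}); emotion(positive) {e.estimate:.4f} (p = {e.p:.3f})")
    p = rep.pearson
    print(f"Pearson, delta-satisfaction vs right-cluster emotion index: "
          f"r = {p.r:.2f}, p = {p.p:.3f}, n = {p.n}")
    print("(larger index = larger normalized DTW distance = LESS synchrony; a "
          "negative slope means mismatched couples synchronise more)")

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        print("matplotlib not installed; skipping the scatter plot")
        return
    right = roi[(roi.roi == "frontal_right") & (roi.condition != "baseline")]
    per_dyad = right.groupby("dyad_id").agg(
        index=("index", "mean"), ds=("satisfaction_difference", "first")
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(per_dyad.ds, per_dyad["index"], color="tab:blue")
    ax.set_xlabel("relationship-satisfaction difference")
    ax.set_ylabel("right-cluster normalized DTW distance")
    ax.set_title(f"r = {p.r:.2f}, p = {p.p:.3f} (n = {p.n} dyads)")
    fig.tight_layout()
    fig.savefig(OUT / "fig_satisfaction_vs_distance.png", dpi=150)
    print(f"scatter -> {OUT / 'fig_satisfaction_vs_distance.png'}")


if __name__ == "__main__":
    main()
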