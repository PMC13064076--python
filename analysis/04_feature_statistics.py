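#!/usr/bin/env python
"""Condition-level feature statistics over the demonstration cohort.

Builds per-condition 2-D threshold histograms and cumulative size curves
from the synthetic cohort, writes the tables to results/statistics/ and the
color-map / CDF figures to scratch/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from astroca.feature_stats import FEATURES, accumulate_histograms, cumulative_distribution
from astroca.io import write_histogram
from astroca.scenarios import cohort_tables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    tables = cohort_tables(seed=args.seed)
    conditions = sorted({t.condition for t in tables})
    out_tab = ROOT / "results" / "statistics"
    out_fig = ROOT / "scratch" / "figures"
    out_fig.mkdir(parents=True, exist_ok=True)

    hists = {}
    for cond in conditions:
        group = [t for t in tables if t.condition == cond]
        hists[cond] = accumulate_histograms(group)
        for feat in FEATURES:
            write_histogram(hists[cond][feat], out_tab, group=cond.replace(" ", ""))
        count_l2 = hists[cond]["max_size"].freq[2].sum()
        print(f"{cond}: {len(group)} recordings, "
              f"{count_l2:.1f} events/cell/600 s at threshold 2")

    # 2-D color-coded frequency maps of event size across thresholds
    fig, axes = plt.subplots(1, len(conditions), figsize=(4 * len(conditions), 3),
                             sharey=True)
    for ax, cond in zip(np.atleast_1d(axes), conditions):
        h = hists[cond]["max_size"]
        im = ax.imshow(h.freq, aspect="auto", origin="lower", cmap="inferno")
        ax.set_title(cond)
        ax.set_xlabel("max size bin (log-spaced)")
        ax.set_yticks(range(len(h.levels)), [f"{lv:g}" for lv in h.levels])
    np.atleast_1d(axes)[0].set_ylabel("Ca2+ threshold (dF/F_R)")
    fig.colorbar(im, ax=axes, label="events / cell / 600 s")
    fig.savefig(out_fig / "size_threshold_maps.png", dpi=150)

    # cumulative size curves at threshold 2
    fig2, ax = plt.subplots(figsize=(4, 3))
    for cond in conditions:
        c = cumulative_distribution(hists[cond]["max_size"], 2.0)
        ax.semilogx(c.x, c.cdf, label=cond)
    ax.set_xlabel("max event size (um^2)")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    fig2.tight_layout()
    fig2.savefig(out_fig / "cumulative_size_threshold2.png", dpi=150)
    print(f"histograms -> {out_tab}; figures -> {out_fig}")


if __name__ == "__main__":
    main()
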