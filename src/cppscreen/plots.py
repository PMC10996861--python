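"""Minimal diagnostic plots: CPP boxplots by sex/class and per-speaker means."""

from __future__ import annotations

from .dataset import Cohort


def boxplot_by_sex(cohort: Cohort, ax=None):
    """Horizontal CPP boxplots, one per (sex, class) cell."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    groups, labels = [], []
    for sex in ("female", "male"):
        for label in ("N", "SMS"):
            values = [
                v
                for r in cohort
                if r.sex == sex and r.label == label
                for v in r.cpp_values
            ]
            if values:
                groups.append(values)
                labels.append(f"{sex} {label}")
    ax.boxplot(groups, tick_labels=labels, vert=False)
    ax.set_xlabel("CPP")
    return ax


def speaker_mean_bars(cohort: Cohort, ax=None):
    """Bar chart of per-speaker mean CPP, colored by class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    summary = cohort.summary()
    colors = ["tab:orange" if lab == "SMS" else "tab:blue" for lab in summary["label"]]
    ax.bar(summary["speaker_id"], summary["mean_cpp"], color=colors)
    ax.set_ylabel("mean CPP")
    ax.tick_params(axis="x", rotation=90)
    return ax
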