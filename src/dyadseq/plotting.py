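"""Plots for graphical inspection: state distribution, entropy, transitions, MDS."""

from __future__ import annotations

import numpy as np

from .seqdata import STATE_NAMES, DescriptiveSummary

# Readable default labels for the four joint states; callers can pass their
# own (e.g. none / SC only / DC only / SC+DC).
DEFAULT_STATE_LABELS = STATE_NAMES


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_state_distribution(
    summary: DescriptiveSummary, ax=None, state_labels=DEFAULT_STATE_LABELS
):
    """Stacked area plot of the per-interval joint-state proportions."""
    ax = _get_ax(ax)
    t = np.arange(1, summary.state_distribution.shape[1] + 1)
    ax.stackplot(t, summary.state_distribution, labels=state_labels)
    ax.set_xlabel("interval")
    ax.set_ylabel("relative frequency")
    ax.set_ylim(0, 1)
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_entropy(summary: DescriptiveSummary, ax=None):
    """Normalized Shannon entropy of the state distribution per interval."""
    ax = _get_ax(ax)
    t = np.arange(1, len(summary.entropy) + 1)
    ax.plot(t, summary.entropy)
    ax.set_xlabel("interval")
    ax.set_ylabel("normalized entropy")
    ax.set_ylim(0, 1)
    return ax


def plot_transition_histogram(summary: DescriptiveSummary, ax=None):
    """Histogram of per-dyad state-transition counts (behavioral volatility)."""
    ax = _get_ax(ax)
    counts = summary.transition_counts
    ax.hist(counts, bins=np.arange(counts.max() + 2) - 0.5)
    ax.set_xlabel("number of state transitions")
    ax.set_ylabel("dyads")
    return ax


def plot_mds(coords: np.ndarray, labels=None, ax=None):
    """Scatter of 2-D classical MDS coordinates, optionally colored by cluster."""
    ax = _get_ax(ax)
    if labels is None:
        ax.scatter(coords[:, 0], coords[:, 1])
    else:
        labels = np.asarray(labels)
        for c in np.unique(labels):
            sel = labels == c
            ax.scatter(coords[sel, 0], coords[sel, 1], label=f"cluster {c + 1}")
        ax.legend(fontsize="small")
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax
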