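"""Generic diagnostic plots (embedding scatter, optimizer traces)."""

from __future__ import annotations

import numpy as np


def plot_embedding(result, dims=(0, 1), ax=None):
    """Scatter of two embedding coordinates coloured by class label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords, labels = result.coords, np.asarray(result.labels)
    for lab in dict.fromkeys(labels):
        rows = coords[labels == lab]
        ax.scatter(rows[:, dims[0]], rows[:, dims[1]], s=8, label=str(lab))
    ax.set_xlabel(f"coordinate {dims[0] + 1}")
    ax.set_ylabel(f"coordinate {dims[1] + 1}")
    ax.set_title(f"{result.method} embedding")
    ax.legend()
    return ax


def plot_trace(trace, ax=None, label=None):
    """Best-so-far objective trace of a metaheuristic run."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(len(trace)), trace, label=label)
    ax.set_xlabel("iteration")
    ax.set_ylabel("best objective")
    if label:
        ax.legend()
    return ax
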