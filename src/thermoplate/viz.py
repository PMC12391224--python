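"""Basic plotting helpers (optional; requires matplotlib)."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np


def stripchart(values: Sequence[float], groups: Sequence, letters: Mapping | None = None,
               ax=None, jitter: float = 0.08, seed: int = 0):
    """Per-group stripchart of total-heat values with 95% CI bars.

    Group labels are annotated with their compact-letter-display string
    when ``letters`` is given.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    labels = list(dict.fromkeys(groups))
    rng = np.random.default_rng(seed)
    if ax is None:
        _, ax = plt.subplots(figsize=(1.6 * len(labels) + 1, 4))
    for i, lab in enumerate(labels):
        y = values[groups == lab]
        x = i + rng.uniform(-jitter, jitter, size=y.size)
        ax.plot(x, y, "o", alpha=0.7)
        mean = y.mean()
        half = 1.96 * y.std(ddof=1) / np.sqrt(y.size)
        ax.errorbar([i], [mean], yerr=[half], fmt="_", color="black",
                    capsize=6, markersize=18, zorder=3)
    ticks = [
        f"{lab} ({letters[lab]})" if letters and lab in letters else str(lab)
        for lab in labels
    ]
    ax.set_xticks(range(len(labels)), ticks)
    ax.set_ylabel("total heat (uJ/cell)")
    return ax
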