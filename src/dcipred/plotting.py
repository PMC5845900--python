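"""Minimal visual summaries: learned kernels and classifier weights.

Matplotlib is imported lazily; the rest of the package works without it.
"""

from __future__ import annotations

import numpy as np


def plot_atoms(dictionary, ax=None, offset: float = 1.5):
    """Waterfall plot of a dictionary's kernels (one trace per atom).

    Returns the matplotlib Axes. Atoms are already sorted by activation
    energy, so the top trace is the most-used kernel.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.8 * dictionary.n_atoms + 1))
    for i, atom in enumerate(dictionary.atoms):
        ax.plot(atom - i * offset, lw=1.5)
        ax.text(dictionary.kernel_length - 0.5, -i * offset,
                f"atom {i}", va="center", fontsize=8)
    ax.set_xlabel("samples")
    ax.set_yticks([])
    title = f"{dictionary.variable} ds={dictionary.ds_minutes:g} min" \
        if dictionary.variable else "learned kernels"
    ax.set_title(f"{title}, KL={dictionary.kernel_length}")
    return ax


def plot_feature_weights(weights, tags, top: int = 20, ax=None):
    """Horizontal bar chart of the largest-|weight| features.

    ``weights`` is one coefficient per feature column (e.g. PLS regression
    coefficients); ``tags`` the matching provenance dicts. Returns the Axes.
    """
    import matplotlib.pyplot as plt

    weights = np.asarray(weights, float).ravel()
    order = np.argsort(-np.abs(weights))[:top]
    labels = []
    for j in order:
        t = tags[j]
        if t.get("kind") == "baseline":
            labels.append(t["variable"])
        else:
            labels.append(f"{t['variable']} ds{t['ds_minutes']:g} "
                          f"KL{t['kernel_length']} k{t['kernel_index']}")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(order) + 1))
    ax.barh(range(len(order)), weights[order])
    ax.set_yticks(range(len(order)), labels, fontsize=7)
    ax.invert_yaxis()
    ax.set_xlabel("weight")
    ax.set_title(f"top {len(order)} feature weights")
    return ax
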