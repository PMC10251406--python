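"""Minimal figure helpers: replacement-vs-depth profiles and the
labeled-protein pathway heatmap."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_replacement_profiles(profiles, boundary: float | None = None,
                              ax=None):
    """Percent replacement vs normalized depth, one line per profile.

    Depth increases downward (surface at the top of the axis), the
    convention of mat cross-sections.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 5))
    for rp in profiles:
        ax.plot(rp.percent, rp.depths, marker=".", lw=1,
                label=rp.profile_id)
    if boundary is not None:
        ax.axhline(boundary, color="0.4", ls="--", lw=1,
                   label="photic boundary")
    ax.set_xlabel("C replacement (%)")
    ax.set_ylabel("normalized depth")
    ax.invert_yaxis()
    ax.legend(fontsize=7)
    return ax


def plot_pathway_heatmap(matrix, ax=None):
    """Heatmap of sqrt-transformed labeled-protein relative abundance.

    ``matrix`` is the output of :func:`dielmat.proteomics.pathway_matrix`;
    zero cells (no labeled proteins) render gray.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    values = matrix.to_numpy(dtype=float)
    masked = np.ma.masked_where(values == 0, values)
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("0.8")
    im = ax.imshow(masked, aspect="auto", cmap=cmap)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    ax.set_xticks(range(matrix.shape[1]),
                  ["|".join(str(v) for v in c) for c in matrix.columns],
                  rotation=90, fontsize=6)
    plt.colorbar(im, ax=ax, label="sqrt relative abundance")
    return ax
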