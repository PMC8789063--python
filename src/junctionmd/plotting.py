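"""Optional hexagonal deviation plots (requires matplotlib).

Each analyzed step is drawn as a hexagon of six wedges, one per step
parameter, with signed deviations from the B-form reference scaled
against the inner/outer display rings (0.5/1.0 A for translations,
5/10 deg for rotations by default); wedges below the suppression
threshold are omitted.  Negative deviations are red, positive blue.
"""

from __future__ import annotations

import numpy as np

from .deformability import DeviationReport
from .geometry import PARAM_NAMES


def hexplot_deviations(report: DeviationReport, path, *, quantity: str = "mean"):
    """Render one hexagon per step for mean (or stiffness) deviations."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table
    rows = table[table["quantity"].str.startswith(f"{quantity}_")]
    labels = list(dict.fromkeys(rows["label"]))
    n = len(labels)
    fig, axes = plt.subplots(1, n, figsize=(1.6 * n, 1.9), subplot_kw={"polar": True})
    axes = np.atleast_1d(axes)
    rings = report.mean_rings if quantity == "mean" else report.stiffness_rings
    for ax, label in zip(axes, labels):
        sub = rows[rows["label"] == label].set_index("quantity")
        for i, name in enumerate(PARAM_NAMES):
            row = sub.loc[f"{quantity}_{name}"]
            if bool(row.get("suppressed", False)):
                continue
            kind = "translation" if i < 3 else "rotation"
            outer = rings[kind][1]
            radius = min(abs(row["deviation"]) / outer, 1.3)
            theta = i * np.pi / 3
            ax.bar(theta, radius, width=np.pi / 3 * 0.9,
                   color="crimson" if row["deviation"] < 0 else "royalblue",
                   alpha=0.8)
        for r, style in ((0.5, ":"), (1.0, "-")):
            ax.plot(np.linspace(0, 2 * np.pi, 120), np.full(120, r),
                    color="gray" if style == ":" else "black",
                    lw=0.6, ls=style)
        ax.set_ylim(0, 1.35)
        ax.set_xticks([i * np.pi / 3 for i in range(6)])
        ax.set_xticklabels([p[:2] for p in PARAM_NAMES], fontsize=6)
        ax.set_yticks([])
        ax.set_title(label, fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
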