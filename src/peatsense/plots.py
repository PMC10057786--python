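"""Optional figures: the I/R diagram and the pseudo-van-Krevelen plot.

Both take the per-sample tables produced by the pipeline; acceptance of an
analysis rests on the tables, these plots exist for visual inspection.
"""

from __future__ import annotations

import pandas as pd

_LAYER_MARKERS = {"litter": "^", "upper50": "o", "below_water_table": "s",
                  "deep": "D", "other": "x"}


def ir_diagram(ir_table: pd.DataFrame, ax=None):
    """Scatter I-index against R-index, markers by layer, colors by class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    classes = sorted(ir_table["class"].unique())
    cmap = plt.get_cmap("tab10")
    for i, cls in enumerate(classes):
        sub = ir_table[ir_table["class"] == cls]
        for layer, grp in sub.groupby("layer"):
            ax.scatter(grp["r_index"], grp["i_index"], s=25,
                       color=cmap(i), marker=_LAYER_MARKERS.get(layer, "o"),
                       label=f"{cls} / {layer}")
    ax.set_xlabel("R-index")
    ax.set_ylabel("I-index")
    ax.legend(fontsize=6, ncol=2)
    return ax


def pseudo_van_krevelen(hi_oi_table: pd.DataFrame, ax=None):
    """HI against OI per sample, the pseudo-van-Krevelen diagram."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    cmap = plt.get_cmap("tab10")
    for i, (cls, grp) in enumerate(hi_oi_table.groupby("class")):
        ax.scatter(grp["OI"], grp["HI"], s=25, color=cmap(i), label=cls)
    ax.set_xlabel("OI (mg O2 as CO2 / g TOC)")
    ax.set_ylabel("HI (mg HC / g TOC)")
    ax.legend(fontsize=7)
    return ax
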