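"""Ward hierarchical clustering of temporal profiles and heat-map export."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy


def ward_cluster(rows) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerate row vectors under Ward's minimum-variance criterion.

    Returns the scipy linkage matrix and the dendrogram leaf order.
    Distances are Euclidean; merges are deterministic, with ties resolved
    toward the smaller row index by scipy's stable pair scan.
    """
    x = np.asarray(rows, dtype=float)
    if x.ndim != 2:
        raise ValueError("rows must be a 2-d array of equal-length profiles")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if not np.isfinite(x).all():
        raise ValueError("profiles must be finite")
    linkage = hierarchy.linkage(x, method="ward", metric="euclidean")
    leaves = hierarchy.leaves_list(linkage)
    return linkage, leaves


def heatmap_export(
    matrix_rows: pd.DataFrame,
    leaf_order,
    column_blocks: dict[str, list[str]],
    path: str | Path,
) -> pd.DataFrame:
    """Write a clustered heat map image plus a TSV of the row order.

    ``matrix_rows`` holds per-gene log2-ratio profiles; ``column_blocks``
    maps block labels (e.g. transient / sustained) to column subsets shown
    side by side.  Rows are drawn in dendrogram order on a diverging scale
    centred at log-ratio 0.  Returns the row-order table that was written
    next to the image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    leaf_order = np.asarray(leaf_order)
    n = matrix_rows.shape[0]
    if sorted(leaf_order.tolist()) != list(range(n)):
        raise ValueError("leaf_order must be a permutation of the row indices")
    path = Path(path)

    ordered = matrix_rows.iloc[leaf_order]
    blocks = [ordered[cols] for cols in column_blocks.values()]
    vmax = max(float(np.abs(b.to_numpy()).max()) for b in blocks) or 1.0

    fig, axes = plt.subplots(
        1, len(blocks), figsize=(2.2 * len(blocks) + 1, 6), sharey=True,
        constrained_layout=True,
    )
    axes = np.atleast_1d(axes)
    for ax, (label, block) in zip(axes, zip(column_blocks, blocks)):
        im = ax.imshow(block.to_numpy(), aspect="auto", cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, interpolation="nearest")
        ax.set_title(label)
        ax.set_xticks(range(block.shape[1]))
        ax.set_xticklabels([str(c) for c in block.columns], rotation=90, fontsize=6)
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.6, label="log2 ratio")
    fig.savefig(path, dpi=150)
    plt.close(fig)

    order_table = pd.DataFrame({
        "row_rank": np.arange(n),
        "gene_id": ordered.index,
    })
    order_table.to_csv(path.with_suffix(".row_order.tsv"), sep="\t", index=False)
    return order_table
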