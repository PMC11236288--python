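"""Latent-space visualization of cells and prototypes.

Figures show the held-out cells of one fold embedded in the latent space
of a chosen gene set, with the learned prototypes overlaid as stars. When
``z_dim > 2`` a UMAP projection is fitted on the cells and the prototypes
are transformed with it (not refitted), so prototype placement is
faithful to the cell embedding. Every figure also writes a delimited
sidecar with the plotted coordinates and colors, so figure content is
testable without image comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

COLOR_KEYS = ("phenotype", "celltype", "predicted_prob")


def _project(z_cells: np.ndarray, z_proto: np.ndarray, seed: int
             ) -> Tuple[np.ndarray, np.ndarray]:
    """2-D coordinates: identity at z_dim=2, else UMAP fit on cells."""
    if z_cells.shape[1] == 2:
        return z_cells, z_proto
    import umap

    reducer = umap.UMAP(n_components=2, random_state=seed)
    xy_cells = reducer.fit_transform(z_cells)
    xy_proto = reducer.transform(z_proto)
    return np.asarray(xy_cells), np.asarray(xy_proto)


def latent_frame(results, set_name: str, *, fold: int = 0,
                 color_by: str = "phenotype",
                 target_class: Optional[int] = None,
                 seed: int = 0) -> pd.DataFrame:
    """Tabulate the 2-D embedding behind a latent-space figure.

    One row per held-out cell plus one per prototype; columns: x, y,
    kind (cell/prototype), phenotype, celltype (when known), color.
    For ``color_by='predicted_prob'`` the color is the per-set posterior
    probability of ``target_class`` (default: the last class), in [0, 1].
    """
    if color_by not in COLOR_KEYS:
        raise ValueError(f"color_by must be one of {COLOR_KEYS}")
    try:
        j = results.model.gene_sets.names.index(set_name)
    except ValueError:
        raise KeyError(f"unknown gene set {set_name!r}") from None
    fr = results.folds[fold]
    net = fr.net
    if color_by == "celltype" and fr.q_test is None:
        raise ValueError("celltype coloring requires per-cell labels q")
    z_cells = fr.sim.z[:, j, :]
    z_proto = net.centers.data[j].reshape(-1, net.spec.z_dim)  # (C*B, z)
    xy_c, xy_p = _project(z_cells, z_proto, seed)

    C, B = net.C, net.B
    if target_class is None:
        target_class = C
    if color_by == "phenotype":
        color = fr.y_test.astype(float)
    elif color_by == "celltype":
        color = fr.q_test.astype(float)
    else:
        color = fr.sim.posterior[:, j, target_class - 1]
    cells = pd.DataFrame({
        "x": xy_c[:, 0], "y": xy_c[:, 1], "kind": "cell",
        "phenotype": fr.y_test,
        "celltype": fr.q_test if fr.q_test is not None else -1,
        "color": color})
    proto_pheno = np.repeat(np.arange(1, C + 1), B)
    proto_label = np.tile(np.arange(1, B + 1), C)
    protos = pd.DataFrame({
        "x": xy_p[:, 0], "y": xy_p[:, 1], "kind": "prototype",
        "phenotype": proto_pheno, "celltype": proto_label,
        "color": proto_pheno.astype(float)})
    return pd.concat([cells, protos], ignore_index=True)


def plot_latent(results, set_name: str, out: str | Path, *,
                fold: int = 0, color_by: str = "phenotype",
                target_class: Optional[int] = None,
                celltype_panels: bool = False,
                seed: int = 0) -> Tuple[Path, pd.DataFrame]:
    """Render the latent space of one gene set; write figure + sidecar.

    ``celltype_panels`` adds one panel per biological label (cells of
    that label only, against all prototypes), exposing which
    subpopulations the phenotypes separate in.
    """
    frame = latent_frame(results, set_name, fold=fold, color_by=color_by,
                         target_class=target_class, seed=seed)
    fr = results.folds[fold]
    if celltype_panels and fr.q_test is None:
        raise ValueError("celltype panels require per-cell labels q")

    cells = frame[frame["kind"] == "cell"]
    protos = frame[frame["kind"] == "prototype"]
    if celltype_panels:
        labels = sorted(cells["celltype"].unique())
        fig, axes = plt.subplots(1, len(labels),
                                 figsize=(4 * len(labels), 3.6),
                                 squeeze=False)
        panels = [(axes[0][i], cells[cells["celltype"] == lab],
                   f"label {lab}") for i, lab in enumerate(labels)]
    else:
        fig, ax = plt.subplots(figsize=(5, 4))
        panels = [(ax, cells, set_name)]
    continuous = color_by == "predicted_prob"
    for ax, sub, title in panels:
        if continuous:
            sc = ax.scatter(sub["x"], sub["y"], c=sub["color"], s=8,
                            cmap="viridis", vmin=0.0, vmax=1.0)
        else:
            for val in sorted(sub["color"].unique()):
                pts = sub[sub["color"] == val]
                ax.scatter(pts["x"], pts["y"], s=8,
                           label=f"{color_by} {int(val)}")
        ax.scatter(protos["x"], protos["y"], marker="*", s=220, c="black",
                   edgecolors="white", linewidths=0.8, label="prototype",
                   zorder=5)
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
        if not continuous:
            ax.legend(fontsize=7, frameon=False)
    if continuous:
        fig.colorbar(sc, ax=[p[0] for p in panels], shrink=0.8)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    sidecar = out.with_suffix(".tsv")
    frame.to_csv(sidecar, sep="\t", index=False, float_format="%.6g")
    return out, frame
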