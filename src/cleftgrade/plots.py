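"""Publication-style figures: confusion heat-table, ROC curves, heatmap panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluate import ConfusionMatrix, MetricsReport, row_normalize
from .mesh_io import TriangleMesh, normalize_pose
from .render import render_all
from .surfgradcam import SCALAR_NAME_TEMPLATE
from .views import ViewSet

__all__ = ["plot_confusion", "plot_roc", "plot_heatmap_panels"]


def plot_confusion(cm: ConfusionMatrix, path: str | Path) -> None:
    """Row-normalized confusion matrix with the within-±1 band readable."""
    frac = row_normalize(cm)
    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(frac, cmap="Blues", vmin=0, vmax=1)
    for i in range(4):
        for j in range(4):
            ax.text(j, i, f"{frac[i, j]:.2f}\n({cm.counts[i, j]})",
                    ha="center", va="center",
                    color="white" if frac[i, j] > 0.5 else "black", fontsize=8)
    ax.set_xlabel("predicted severity")
    ax.set_ylabel("ground-truth severity")
    ax.set_xticks(range(4))
    ax.set_yticks(range(4))
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(report: MetricsReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4))
    for c, curve in report.roc_curves.items():
        ax.plot(curve["fpr"], curve["tpr"],
                label=f"class {c} (AUC {report.auc[c]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap_panels(
    mesh: TriangleMesh,
    viewset: ViewSet,
    path: str | Path,
    classes: list[int] | None = None,
    view_ids: list[int] | None = None,
    resolution: int = 128,
) -> None:
    """Classes-by-viewpoints grid of the surface heatmaps, blue -> red.

    Expects ``surfgradcam_class{c}`` scalar arrays on the mesh (see
    :func:`cleftgrade.surfgradcam.explain`).
    """
    classes = classes if classes is not None else [
        c for c in range(4) if SCALAR_NAME_TEMPLATE.format(c=c) in mesh.vertex_scalars
    ]
    if not classes:
        raise ValueError("mesh carries no surfgradcam_class* scalar arrays")
    view_ids = view_ids if view_ids is not None else [0, len(viewset) // 2]
    normed = normalize_pose(mesh)
    rendered = render_all(normed, viewset, resolution)
    cmap = plt.get_cmap("jet")

    fig, axes = plt.subplots(
        len(view_ids), len(classes),
        figsize=(2.2 * len(classes), 2.2 * len(view_ids)), squeeze=False,
    )
    for r, vid in enumerate(view_ids):
        rv = rendered[vid]
        for col, c in enumerate(classes):
            scal = mesh.vertex_scalars[SCALAR_NAME_TEMPLATE.format(c=c)]
            face_vals = scal[mesh.faces].mean(axis=1)
            img = np.ones(rv.face_id.shape + (3,))
            fg = rv.face_id >= 0
            img[fg] = cmap(face_vals[rv.face_id[fg]])[:, :3]
            ax = axes[r][col]
            ax.imshow(img)
            ax.set_xticks([])
            ax.set_yticks([])
            if r == 0:
                ax.set_title(f"class {c}", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
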