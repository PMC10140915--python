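"""Figure helpers for presence/absence heatmaps and repertoire PCAs.

Matplotlib is imported lazily so the core pipeline has no hard plotting
dependency; install the ``plots`` extra to use these.
"""

from __future__ import annotations

from pathlib import Path

from .conservation import PCAResult, PresenceAbsenceMatrix, cluster_heatmap_order

__all__ = ["heatmap_figure", "pca_figure"]


def heatmap_figure(M: PresenceAbsenceMatrix, path: str | Path) -> None:
    """Clustered presence/absence heatmap (orthogroups × species)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_order, col_order = cluster_heatmap_order(M)
    data = M.matrix.loc[row_order, col_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.18 * len(col_order)), max(4, 0.02 * len(row_order)))
    )
    ax.imshow(data.to_numpy(), aspect="auto", cmap="Blues", interpolation="none")
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=5)
    ax.set_yticks([])
    ax.set_xlabel("species")
    ax.set_ylabel(f"{len(row_order)} orthogroups")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_figure(
    result: PCAResult, M: PresenceAbsenceMatrix, path: str | Path
) -> None:
    """Species scatter on the first two components, colored by family."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = result.coordinates
    tax = M.taxonomy.table.set_index("species_id")
    families = sorted(tax["family"].unique())
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(6, 5))
    for i, fam in enumerate(families):
        spp = [s for s in coords.index if tax.loc[s, "family"] == fam]
        if not spp:
            continue
        ax.scatter(
            coords.loc[spp, "PC1"],
            coords.loc[spp, "PC2"] if "PC2" in coords else 0,
            label=fam,
            color=cmap(i % 20),
            s=25,
        )
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
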