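"""Orthogroup presence/absence summaries and subfamily conservation levels.

An orthogroup restricted to a focal category (CTL or CTLDcp) gives one row
of a binary orthogroup × species matrix. Each row is then assigned the
highest taxonomic rank at which the orthogroup is (nearly) universally
present, using a coverage threshold θ: a subfamily conserved in ≥θ of a
phylum's species is phylum-level, else class-level, else shared between
several families of one class (the mussel+oyster pattern), else confined to
a single family, else lineage-restricted.

θ defaults to 0.9 so that, in clades of ten or more species, a single
missing species — a real-data occurrence usually reflecting an incomplete
assembly rather than true loss — does not demote an otherwise universal
subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .io import OrthogroupTable, Taxonomy
from .repertoire import CTL, CTLDCP, ArchitectureCall

__all__ = [
    "LEVELS",
    "PresenceAbsenceMatrix",
    "ConservationCall",
    "PCAResult",
    "build_presence_matrix",
    "pca_species",
    "cluster_heatmap_order",
    "assign_conservation_level",
    "assign_all",
    "tolerant_class_call",
]

#: Conservation levels, from broadest to most restricted.
LEVELS = ("PHYLUM", "CLASS", "MULTI_FAMILY", "FAMILY", "RESTRICTED")


@dataclass(eq=False)
class PresenceAbsenceMatrix:
    """Binary orthogroup × species matrix with its taxonomy attached."""

    matrix: pd.DataFrame  # int 0/1, index orthogroups, columns species
    taxonomy: Taxonomy

    def __post_init__(self) -> None:
        unknown = sorted(set(self.matrix.columns) - set(self.taxonomy.species))
        if unknown:
            raise ValueError(f"species not in taxonomy: {unknown}")
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix must be 0/1")
        if vals.shape[0] and not vals.any(axis=1).all():
            empty = self.matrix.index[~vals.any(axis=1)]
            raise ValueError(f"all-zero rows: {list(empty[:5])}")
        self.matrix = self.matrix.astype(np.int8)

    @property
    def orthogroups(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return list(self.matrix.columns)


@dataclass(frozen=True)
class ConservationCall:
    orthogroup_id: str
    level: str
    anchor_taxon: str | None
    coverage_by_taxon: Mapping[str, float]


@dataclass(eq=False)
class PCAResult:
    coordinates: pd.DataFrame  # species × components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray


def build_presence_matrix(
    orthogroups: OrthogroupTable,
    calls: Mapping[str, ArchitectureCall],
    taxonomy: Taxonomy,
    category: str = CTL,
) -> PresenceAbsenceMatrix:
    """Presence matrix of orthogroups containing the focal category.

    Rows are restricted to orthogroups with ≥1 protein of ``category``
    anywhere; a cell is 1 iff that species contributes ≥1 such protein.
    Proteins missing from ``calls`` are treated as OTHER.
    """
    if category not in (CTL, CTLDCP):
        raise ValueError(f"category must be {CTL!r} or {CTLDCP!r}")
    unknown = sorted(set(orthogroups.species) - set(taxonomy.species))
    if unknown:
        raise ValueError(f"species in orthogroups absent from taxonomy: {unknown}")
    rows: dict[str, list[int]] = {}
    for og_id, by_species in orthogroups.members.items():
        row = []
        for sp in orthogroups.species:
            hit = any(
                (c := calls.get(p)) is not None and c.category == category
                for p in by_species[sp]
            )
            row.append(int(hit))
        if any(row):
            rows[og_id] = row
    matrix = pd.DataFrame.from_dict(
        rows, orient="index", columns=orthogroups.species, dtype=np.int8
    )
    if matrix.empty:
        matrix = pd.DataFrame(
            np.empty((0, len(orthogroups.species)), dtype=np.int8),
            columns=orthogroups.species,
        )
    return PresenceAbsenceMatrix(matrix=matrix, taxonomy=taxonomy)


def pca_species(M: PresenceAbsenceMatrix, n_components: int = 2) -> PCAResult:
    """PCA of species over their orthogroup-presence profiles.

    Species are observations, orthogroup columns are features; columns are
    centered but not scaled (scaling 0/1 columns would inflate rare
    orthogroups). Components come ordered by decreasing explained variance.
    """
    from sklearn.decomposition import PCA

    X = M.matrix.T.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 species and 2 orthogroups")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate matrix: no variance across species")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    coordinates = pd.DataFrame(
        coords, index=M.species, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCAResult(
        coordinates=coordinates,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def _leaf_order(values: np.ndarray, labels: list[str]) -> list[str]:
    # Canonical label sort first makes the result independent of input order.
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    values = values[order]
    if len(labels) <= 2:
        return labels
    d = pdist(values.astype(bool), metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # two all-zero vectors: treat as identical
    Z = linkage(d, method="average")
    return [labels[i] for i in leaves_list(Z)]


def cluster_heatmap_order(M: PresenceAbsenceMatrix) -> tuple[list[str], list[str]]:
    """Deterministic heatmap leaf orders for rows (orthogroups) and columns
    (species): average-linkage hierarchical clustering on Jaccard distances
    between binary profiles."""
    if M.matrix.empty:
        raise ValueError("empty presence matrix")
    vals = M.matrix.to_numpy()
    row_order = _leaf_order(vals, M.orthogroups)
    col_order = _leaf_order(vals.T, M.species)
    return row_order, col_order


def _coverages(
    present: frozenset[str], taxonomy: Taxonomy, rank: str
) -> dict[str, float]:
    return {
        taxon: sum(1 for s in spp if s in present) / len(spp)
        for taxon, spp in taxonomy.groups(rank).items()
    }


def assign_conservation_level(
    M: PresenceAbsenceMatrix,
    orthogroup_id: str,
    theta: float = 0.9,
) -> ConservationCall:
    """Highest rank at which the orthogroup covers ≥θ of a taxon's species.

    Evaluated top-down: PHYLUM if some phylum reaches θ; else CLASS; else
    MULTI_FAMILY if ≥2 families *within one class* reach θ (anchored on that
    class); else FAMILY if exactly one family reaches θ; else RESTRICTED.
    Families reaching θ in different classes, without class-level coverage,
    do not combine — such patterns stay RESTRICTED. Ties between taxa at
    equal rank break lexicographically.
    """
    if not 0 < theta <= 1:
        raise ValueError("theta must be in (0, 1]")
    try:
        row = M.matrix.loc[orthogroup_id]
    except KeyError:
        raise ValueError(f"orthogroup {orthogroup_id!r} not in matrix") from None
    present = frozenset(row.index[row.to_numpy() == 1])
    tax = M.taxonomy

    cov_all: dict[str, float] = {}
    for rank in ("phylum", "class", "family"):
        cov_all.update(_coverages(present, tax, rank))
    reported = {
        taxon: cov
        for taxon, cov in cov_all.items()
        if any(s in present for s in tax.species_in(taxon))
    }

    def qualifying(rank: str) -> list[str]:
        return sorted(
            t for t, c in _coverages(present, tax, rank).items() if c >= theta
        )

    phyla = qualifying("phylum")
    if phyla:
        return ConservationCall(orthogroup_id, "PHYLUM", phyla[0], reported)
    classes = qualifying("class")
    if classes:
        return ConservationCall(orthogroup_id, "CLASS", classes[0], reported)
    families = qualifying("family")
    by_class: dict[str, list[str]] = {}
    for fam in families:
        by_class.setdefault(tax.class_of_family(fam), []).append(fam)
    multi = sorted(cls for cls, fams in by_class.items() if len(fams) >= 2)
    if multi:
        return ConservationCall(orthogroup_id, "MULTI_FAMILY", multi[0], reported)
    if len(families) == 1:
        return ConservationCall(orthogroup_id, "FAMILY", families[0], reported)
    return ConservationCall(orthogroup_id, "RESTRICTED", None, reported)


def assign_all(
    M: PresenceAbsenceMatrix, theta: float = 0.9
) -> dict[str, ConservationCall]:
    return {g: assign_conservation_level(M, g, theta) for g in M.orthogroups}


def tolerant_class_call(
    M: PresenceAbsenceMatrix,
    orthogroup_id: str,
    taxon: str,
    max_exceptions: int = 1,
) -> bool:
    """Is the orthogroup present in all of a taxon's species, tolerating up
    to ``max_exceptions`` absences? Equivalent to a coverage threshold of
    (n − max_exceptions)/n for a taxon of n species."""
    try:
        row = M.matrix.loc[orthogroup_id]
    except KeyError:
        raise ValueError(f"orthogroup {orthogroup_id!r} not in matrix") from None
    species = M.taxonomy.species_in(taxon)
    absent = sum(1 for s in species if row.get(s, 0) == 0)
    return absent <= max_exceptions
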