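"""Proteome screening: longest-isoform filtering and the CTL / CTLDcp split.

A protein is a **CTL** if its domain annotation consists only of C-type
lectin-like domains (Pfam PF00059), a **CTLDcp** if it carries PF00059 plus
at least one other domain family, and **OTHER** if it has no PF00059 hit.
Counting is done per gene after keeping only the longest isoform, matching
how repertoire sizes are reported in comparative surveys of this family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import DomainHit, Taxonomy

__all__ = [
    "CTL_ACCESSION",
    "CTL",
    "CTLDCP",
    "OTHER",
    "ArchitectureCall",
    "filter_longest_isoform",
    "classify_architecture",
    "classify_proteins",
    "census",
]

#: Unversioned Pfam accession of the C-type lectin-like domain.
CTL_ACCESSION = "PF00059"

CTL = "CTL"
CTLDCP = "CTLDcp"
OTHER = "OTHER"


@dataclass(frozen=True)
class ArchitectureCall:
    """Domain-architecture category of one protein.

    ``other_domain_accessions`` is deduplicated (by unversioned accession)
    and sorted: architectures are described by domain composition, not copy
    number.
    """

    protein_id: str
    category: str
    n_ctl_domains: int
    other_domain_accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        ok = (
            (self.category == CTL and self.n_ctl_domains >= 1
             and not self.other_domain_accessions)
            or (self.category == CTLDCP and self.n_ctl_domains >= 1
                and self.other_domain_accessions)
            or (self.category == OTHER and self.n_ctl_domains == 0)
        )
        if not ok:
            raise ValueError(
                f"inconsistent architecture call for {self.protein_id!r}: "
                f"{self.category}, {self.n_ctl_domains} CTL domains, "
                f"others={self.other_domain_accessions}"
            )


def filter_longest_isoform(isoform_map: pd.DataFrame) -> dict[str, str]:
    """Retain one protein per gene: the longest isoform.

    Length ties break to the lexicographically smallest protein_id so the
    result is independent of input row order. Idempotent: filtering an
    already-filtered map returns it unchanged.
    """
    if isoform_map.empty:
        return {}
    ordered = isoform_map.sort_values(
        ["gene_id", "length", "protein_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).drop_duplicates("gene_id", keep="first")
    return dict(zip(ordered["gene_id"], ordered["protein_id"]))


def classify_architecture(
    hits: Sequence[DomainHit],
    protein_id: str | None = None,
    lectin_accessions: Iterable[str] = (CTL_ACCESSION,),
) -> ArchitectureCall:
    """Classify one protein's domain hits into CTL / CTLDcp / OTHER.

    ``lectin_accessions`` lists the unversioned accessions counted as the
    lectin domain (normally just PF00059; alternate lectin folds can be
    added for retention analyses). A protein with zero hits is OTHER.
    """
    lectins = frozenset(lectin_accessions)
    ids = {h.protein_id for h in hits}
    if len(ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(ids)}")
    if ids:
        (hit_pid,) = ids
        if protein_id is not None and protein_id != hit_pid:
            raise ValueError(
                f"hits belong to {hit_pid!r}, not {protein_id!r}"
            )
        protein_id = hit_pid
    if protein_id is None:
        raise ValueError("protein_id required when the hit list is empty")
    n_ctl = sum(1 for h in hits if h.accession in lectins)
    others = tuple(sorted({h.accession for h in hits if h.accession not in lectins}))
    if n_ctl == 0:
        category = OTHER
    elif others:
        category = CTLDCP
    else:
        category = CTL
    return ArchitectureCall(
        protein_id=protein_id,
        category=category,
        n_ctl_domains=n_ctl,
        other_domain_accessions=others,
    )


def classify_proteins(
    hits: Iterable[DomainHit],
    protein_ids: Iterable[str] | None = None,
    lectin_accessions: Iterable[str] = (CTL_ACCESSION,),
) -> dict[str, ArchitectureCall]:
    """Group hits by protein and classify each one.

    ``protein_ids`` optionally supplies the full protein universe so that
    proteins without any hit are classified OTHER rather than dropped.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    if protein_ids is not None:
        for pid in protein_ids:
            by_protein.setdefault(pid, [])
    return {
        pid: classify_architecture(phits, protein_id=pid,
                                   lectin_accessions=lectin_accessions)
        for pid, phits in by_protein.items()
    }


def census(
    calls: Mapping[str, ArchitectureCall] | Iterable[ArchitectureCall],
    gene_to_protein: Mapping[str, str],
    protein_to_species: Mapping[str, str],
    species: Iterable[str] | Taxonomy | None = None,
) -> pd.DataFrame:
    """Per-species counts of CTL and CTLDcp genes.

    Counts genes (post isoform filter): every gene in ``gene_to_protein``
    contributes via its retained protein's call. Proteins absent from
    ``calls`` count as OTHER. Species with zero lectin genes keep their row
    when a species universe (list or :class:`~ctlkit.io.Taxonomy`) is given.
    """
    if not isinstance(calls, Mapping):
        calls = {c.protein_id: c for c in calls}
    if isinstance(species, Taxonomy):
        universe = list(species.species)
    elif species is not None:
        universe = list(species)
    else:
        universe = []
    counts: dict[str, dict[str, int]] = {
        sp: {"n_ctl_genes": 0, "n_ctldcp_genes": 0} for sp in universe
    }
    for gene, protein in gene_to_protein.items():
        try:
            sp = protein_to_species[protein]
        except KeyError:
            raise ValueError(
                f"protein {protein!r} (gene {gene!r}) has no species assignment"
            ) from None
        row = counts.setdefault(sp, {"n_ctl_genes": 0, "n_ctldcp_genes": 0})
        call = calls.get(protein)
        if call is None:
            continue
        if call.category == CTL:
            row["n_ctl_genes"] += 1
        elif call.category == CTLDCP:
            row["n_ctldcp_genes"] += 1
    out = pd.DataFrame.from_dict(counts, orient="index").astype(int)
    out.index.name = "species_id"
    return out.sort_index()
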