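"""Categorize CTLDcp families by lectin-domain retention across clades.

For each orthogroup containing at least one multi-domain lectin protein,
each species is scored ABSENT, PRESENT_WITH_CTL or PRESENT_WITHOUT_CTL
depending on whether any of its member proteins still carries the C-type
lectin-like domain (PF00059). Families are then sorted into three classes:

* **A** — the lectin domain is retained broadly, including in chordate
  orthologs (same-architecture families across metazoans);
* **B** — bivalve orthologs retain the lectin domain while every present
  chordate ortholog has lost it (chordate-specific domain loss);
* **C** — the family has no orthologs outside bivalves at all
  (bivalve-restricted architectures).

The clades default to Bivalvia and Chordata but are configurable, as is an
optional list of alternate lectin accessions (e.g. a Gal-lectin fold) to
count as retention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io import DomainHit, Taxonomy
from .repertoire import CTL_ACCESSION

__all__ = [
    "ABSENT",
    "PRESENT_WITH_CTL",
    "PRESENT_WITHOUT_CTL",
    "RetentionProfile",
    "CategoryCall",
    "ArchitectureComparison",
    "retention_profile",
    "categorize",
    "compare_architectures",
]

ABSENT = "ABSENT"
PRESENT_WITH_CTL = "PRESENT_WITH_CTL"
PRESENT_WITHOUT_CTL = "PRESENT_WITHOUT_CTL"

STATUSES = (ABSENT, PRESENT_WITH_CTL, PRESENT_WITHOUT_CTL)


@dataclass(frozen=True)
class RetentionProfile:
    """Per-species lectin-domain retention status for one orthogroup."""

    orthogroup_id: str
    status: Mapping[str, str]  # species → status

    def __post_init__(self) -> None:
        bad = {s for s in self.status.values() if s not in STATUSES}
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")


@dataclass(frozen=True)
class CategoryCall:
    orthogroup_id: str
    category: str  # A, B, C or UNCLASSIFIED
    bivalve_retention: float
    chordate_retention: float
    outside_bivalvia_presence: float
    no_chordates_warning: bool = False


@dataclass(frozen=True)
class ArchitectureComparison:
    """Ordered domain lists of one representative protein per clade."""

    orthogroup_id: str
    architectures: Mapping[str, tuple[str, ...]]  # species → accessions
    missing_representatives: tuple[str, ...] = ()  # clades without members


def retention_profile(
    orthogroup_id: str,
    members_by_species: Mapping[str, Sequence[str]],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    lectin_accessions: Iterable[str] = (CTL_ACCESSION,),
) -> RetentionProfile:
    """Score every species of an orthogroup for lectin-domain retention.

    A species is PRESENT_WITH_CTL iff at least one of its member proteins
    carries a hit whose unversioned accession is in ``lectin_accessions``.
    """
    lectins = frozenset(lectin_accessions)
    status: dict[str, str] = {}
    for sp, proteins in members_by_species.items():
        if not proteins:
            status[sp] = ABSENT
            continue
        with_ctl = any(
            h.accession in lectins
            for p in proteins
            for h in hits_by_protein.get(p, ())
        )
        status[sp] = PRESENT_WITH_CTL if with_ctl else PRESENT_WITHOUT_CTL
    return RetentionProfile(orthogroup_id=orthogroup_id, status=status)


def categorize(
    profile: RetentionProfile,
    taxonomy: Taxonomy,
    rho: float = 0.5,
    epsilon: float = 0.0,
    bivalve_clade: str = "Bivalvia",
    chordate_clade: str = "Chordata",
) -> CategoryCall:
    """Assign a retention profile to category A, B, C or UNCLASSIFIED.

    Retention fractions are computed over *present* species of each clade.
    Rule: **C** if the fraction of non-bivalve species that are present at
    all is ≤ ε; else **B** if every present chordate has lost the lectin
    domain and bivalve retention is ≥ ρ; else **A** if chordate retention
    is ≥ ρ; else UNCLASSIFIED. If no chordate is present (yet the family
    does occur outside bivalves) the call is UNCLASSIFIED with a warning
    flag rather than an error.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must be in [0, 1]")
    if not 0 <= epsilon <= 1:
        raise ValueError("epsilon must be in [0, 1]")
    bivalves = set(taxonomy.species_in(bivalve_clade))
    chordates = set(taxonomy.species_in(chordate_clade))

    def _retention(clade: set[str]) -> tuple[float, int]:
        present = [
            sp for sp, st in profile.status.items()
            if sp in clade and st != ABSENT
        ]
        if not present:
            return 0.0, 0
        with_ctl = sum(
            1 for sp in present if profile.status[sp] == PRESENT_WITH_CTL
        )
        return with_ctl / len(present), len(present)

    outside = [sp for sp in profile.status if sp not in bivalves]
    if outside:
        outside_presence = sum(
            1 for sp in outside if profile.status[sp] != ABSENT
        ) / len(outside)
    else:
        outside_presence = 0.0

    bivalve_retention, _ = _retention(bivalves)
    chordate_retention, n_chordates_present = _retention(chordates)

    if outside_presence <= epsilon:
        category, warn = "C", False
    elif n_chordates_present == 0:
        category, warn = "UNCLASSIFIED", True
    elif chordate_retention == 0.0 and bivalve_retention >= rho:
        category, warn = "B", False
    elif chordate_retention >= rho:
        category, warn = "A", False
    else:
        category, warn = "UNCLASSIFIED", False

    return CategoryCall(
        orthogroup_id=profile.orthogroup_id,
        category=category,
        bivalve_retention=bivalve_retention,
        chordate_retention=chordate_retention,
        outside_bivalvia_presence=outside_presence,
        no_chordates_warning=warn,
    )


def compare_architectures(
    orthogroup_id: str,
    members_by_species: Mapping[str, Sequence[str]],
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    representatives: Mapping[str, str],
    protein_lengths: Mapping[str, int],
) -> ArchitectureComparison:
    """Side-by-side domain architectures for one representative species per
    clade (e.g. a mussel versus human).

    Per representative species, the member protein with the greatest length
    is chosen (ties break to the lexicographically smallest protein_id) and
    its domain accessions are listed in envelope-start order; overlapping
    hits are both kept, in coordinate order. Representatives without
    members in the orthogroup are flagged, not errors.
    """
    architectures: dict[str, tuple[str, ...]] = {}
    missing: list[str] = []
    for clade, sp in representatives.items():
        proteins = list(members_by_species.get(sp, ()))
        if not proteins:
            missing.append(clade)
            continue
        chosen = max(
            sorted(proteins), key=lambda p: protein_lengths.get(p, 0)
        )
        hits = sorted(
            hits_by_protein.get(chosen, ()),
            key=lambda h: (h.env_start, h.env_end, h.accession),
        )
        architectures[sp] = tuple(h.accession for h in hits)
    return ArchitectureComparison(
        orthogroup_id=orthogroup_id,
        architectures=architectures,
        missing_representatives=tuple(missing),
    )
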