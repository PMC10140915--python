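"""End-to-end pipeline helpers: from raw input files (or an in-memory
synthetic bundle) to repertoire censuses, conservation calls and CTLDcp
category calls, plus recovery scoring against a planted truth record."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import categories, conservation, repertoire
from .io import (
    DomainHit,
    OrthogroupTable,
    Taxonomy,
    read_expression,
    read_isoform_map,
    read_orthogroups_tsv,
    read_pfamscan,
    read_structure_annotations,
    read_taxonomy,
)
from .simulate import ScenarioBundle

__all__ = [
    "PipelineInputs",
    "load_inputs",
    "inputs_from_bundle",
    "classify_and_census",
    "conservation_calls",
    "category_calls",
    "recovery_rate",
]


@dataclass(eq=False)
class PipelineInputs:
    """Parsed inputs shared by all downstream analyses."""

    taxonomy: Taxonomy
    isoform_map: pd.DataFrame
    hits_by_species: dict[str, list[DomainHit]]
    orthogroups: OrthogroupTable

    @property
    def hits_by_protein(self) -> dict[str, list[DomainHit]]:
        out: dict[str, list[DomainHit]] = {}
        for sp_hits in self.hits_by_species.values():
            for h in sp_hits:
                out.setdefault(h.protein_id, []).append(h)
        return out

    @property
    def protein_species(self) -> dict[str, str]:
        return {
            h.protein_id: sp
            for sp, sp_hits in self.hits_by_species.items()
            for h in sp_hits
        }


def load_inputs(directory: str | Path) -> PipelineInputs:
    """Read a standard input layout: taxonomy.tsv, isoform_map.tsv,
    Orthogroups.tsv and one pfamscan/<species>.tsv per species."""
    d = Path(directory)
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    hits = {
        sp: read_pfamscan(d / "pfamscan" / f"{sp}.tsv")
        for sp in taxonomy.species
        if (d / "pfamscan" / f"{sp}.tsv").exists()
    }
    return PipelineInputs(
        taxonomy=taxonomy,
        isoform_map=read_isoform_map(d / "isoform_map.tsv"),
        hits_by_species=hits,
        orthogroups=read_orthogroups_tsv(d / "Orthogroups.tsv"),
    )


def inputs_from_bundle(bundle: ScenarioBundle) -> PipelineInputs:
    return PipelineInputs(
        taxonomy=bundle.taxonomy,
        isoform_map=bundle.isoform_map,
        hits_by_species=bundle.hits_by_species,
        orthogroups=bundle.orthogroups,
    )


def classify_and_census(
    inputs: PipelineInputs,
    lectin_accessions: Iterable[str] = (repertoire.CTL_ACCESSION,),
) -> tuple[dict[str, repertoire.ArchitectureCall], dict[str, str], pd.DataFrame]:
    """Longest-isoform filter → architecture calls → per-species census.

    Returns (calls for retained proteins, gene→retained protein map, census
    table). Proteins of non-retained isoforms are not classified.
    """
    retained = repertoire.filter_longest_isoform(inputs.isoform_map)
    retained_set = set(retained.values())
    hits_by_protein = inputs.hits_by_protein
    calls = repertoire.classify_proteins(
        (h for hs in hits_by_protein.values() for h in hs if h.protein_id in retained_set),
        protein_ids=retained_set,
        lectin_accessions=lectin_accessions,
    )
    # species assignment: from the isoform map gene prefix is unreliable in
    # general, so derive it from the per-species hit files, falling back to
    # orthogroup membership for hit-less proteins.
    protein_species = inputs.protein_species
    for og_id, by_species in inputs.orthogroups.members.items():
        for sp, prots in by_species.items():
            for p in prots:
                protein_species.setdefault(p, sp)
    retained_species: dict[str, str] = {}
    gene_of = dict(zip(inputs.isoform_map["protein_id"], inputs.isoform_map["gene_id"]))
    sibling_species = {
        gene_of[p]: sp for p, sp in protein_species.items() if p in gene_of
    }
    for gene, protein in retained.items():
        sp = protein_species.get(protein)
        if sp is None:
            # hit-less, unassigned protein: attribute via a sibling isoform
            sp = sibling_species.get(gene)
        if sp is not None:
            retained_species[protein] = sp
    # genes with no domain hit anywhere have no species evidence in the
    # inputs; they are OTHER by construction and cannot change the census
    countable = {
        gene: protein
        for gene, protein in retained.items()
        if protein in retained_species
        or calls[protein].category != repertoire.OTHER
    }
    census = repertoire.census(
        calls,
        gene_to_protein=countable,
        protein_to_species=retained_species,
        species=inputs.taxonomy,
    )
    return calls, retained, census


def conservation_calls(
    inputs: PipelineInputs,
    calls: Mapping[str, repertoire.ArchitectureCall],
    category: str = repertoire.CTL,
    theta: float = 0.9,
) -> tuple[conservation.PresenceAbsenceMatrix, dict[str, conservation.ConservationCall]]:
    M = conservation.build_presence_matrix(
        inputs.orthogroups, calls, inputs.taxonomy, category=category
    )
    return M, conservation.assign_all(M, theta=theta)


def category_calls(
    inputs: PipelineInputs,
    calls: Mapping[str, repertoire.ArchitectureCall],
    rho: float = 0.5,
    epsilon: float = 0.0,
    bivalve_clade: str = "Bivalvia",
    chordate_clade: str = "Chordata",
) -> tuple[dict[str, categories.RetentionProfile], dict[str, categories.CategoryCall]]:
    """Retention profiles and A/B/C calls for every orthogroup containing at
    least one CTLDcp protein."""
    hits_by_protein = inputs.hits_by_protein
    profiles: dict[str, categories.RetentionProfile] = {}
    cat: dict[str, categories.CategoryCall] = {}
    for og_id, by_species in inputs.orthogroups.members.items():
        has_ctldcp = any(
            (c := calls.get(p)) is not None and c.category == repertoire.CTLDCP
            for prots in by_species.values()
            for p in prots
        )
        if not has_ctldcp:
            continue
        prof = categories.retention_profile(og_id, by_species, hits_by_protein)
        profiles[og_id] = prof
        cat[og_id] = categories.categorize(
            prof,
            inputs.taxonomy,
            rho=rho,
            epsilon=epsilon,
            bivalve_clade=bivalve_clade,
            chordate_clade=chordate_clade,
        )
    return profiles, cat


def recovery_rate(
    truth_labels: Mapping[str, str], observed: Mapping[str, str]
) -> float:
    """Fraction of truth-labelled items whose observed label matches.

    Items missing from ``observed`` (e.g. an orthogroup that lost all its
    lectin members to noise) count as misses.
    """
    if not truth_labels:
        return 1.0
    hits = sum(
        1 for key, label in truth_labels.items() if observed.get(key) == label
    )
    return hits / len(truth_labels)
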