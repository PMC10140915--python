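"""Truth-tagged synthetic inputs emulating a multi-species lectin survey.

The generator plants known structure at every level the pipeline measures:

* a four-rank taxonomy (default: a mollusc-like focal phylum with two
  classes of three ten-species families each, plus a small chordate
  outgroup);
* single-domain lectin (CTL) orthogroups conserved at chosen taxonomic
  levels — phylum, class, two-families-within-a-class, single family, or
  lineage-restricted — with geometric within-species paralog expansion;
* multi-domain lectin (CTLDcp) orthogroups planted in retention categories
  A (lectin domain kept everywhere), B (kept in bivalve-like species, lost
  in chordate orthologs) and C (bivalve-restricted);
* per-protein domain tables in the pfam_scan.pl dialect, a gene↔isoform map
  with extra shorter isoforms to exercise the longest-isoform filter,
  structure annotations (class-conserved lectins are emitted as small
  secreted single-domain proteins), and an OrthoFinder-style table;
* negative-binomial expression counts for one focal species with planted
  tissue programs (a mucosal set expressed only in digestive gland + gill)
  and per-experiment stimulus responders with a known log2 fold change.

Ten species per family is the default so that a 0.9 coverage threshold
tolerates exactly one absent species per family — the single-species
exception regime real assemblies show. A single seed feeds named
sub-streams (architecture, orthology, structure, isoforms, expression,
noise), so identical configs produce byte-identical file bundles.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    DomainHit,
    ExpressionDataset,
    OrthogroupTable,
    Taxonomy,
    write_expression,
    write_isoform_map,
    write_orthogroups_tsv,
    write_pfamscan,
    write_structure_annotations,
    write_taxonomy,
)

__all__ = [
    "ExperimentSpec",
    "ExpressionSpec",
    "ScenarioConfig",
    "ScenarioBundle",
    "generate_scenario",
    "inject_noise",
]

#: Versioned accession written to pfam_scan files for the lectin domain.
CTL_VERSIONED = "PF00059.21"

#: Pfam ids for the accessions the simulator uses.
_PFAM_IDS = {
    "PF00059": "Lectin_C",
    "PF00008": "EGF",
    "PF00084": "Sushi",
    "PF00431": "CUB",
    "PF00530": "SRCR",
    "PF01822": "WSC",
    "PF01826": "TIL",
    "PF07686": "V-set",
    "PF00047": "ig",
    "PF00057": "Ldl_recept_a",
    "PF00090": "TSP_1",
}

_BACKGROUND_POOL = ("PF00047", "PF00057", "PF00090")


def _default_taxonomy() -> dict[str, dict[str, dict[str, int]]]:
    return {
        "Mollusca": {
            "Bivalvia": {"Mytilidae": 10, "Ostreidae": 10, "Pectinidae": 10},
            "Cephalopoda": {
                "Architeuthidae": 10,
                "Octopodidae": 10,
                "Sepiidae": 10,
            },
        },
        "Chordata": {"Mammalia": {"Hominidae": 6}},
    }


def _default_pools() -> dict[str, list[str]]:
    return {
        "A": ["PF00008", "PF00084"],
        "B": ["PF00431", "PF01822"],
        "C": ["PF00530", "PF07686", "PF01826"],
    }


@dataclass
class ExperimentSpec:
    """One stimulation experiment: control vs stimulated samples in one
    tissue, with a named responder gene program and a planted effect."""

    experiment_id: str
    tissue: str
    responders: str  # name of a planted tissue program ("mucosal", ...)
    log2fc: float = 2.0
    n_control: int = 5
    n_stimulated: int = 5
    dispersion: float = 0.1


@dataclass
class ExpressionSpec:
    sample_types: tuple[str, ...] = (
        "digestive_gland",
        "gill",
        "hemocytes",
        "larvae",
        "mantle",
    )
    n_baseline_per_type: int = 5
    dispersion: float = 0.1
    mean_grid: tuple[float, ...] = (20.0, 50.0, 100.0, 200.0, 500.0)
    program_mean: float = 200.0
    low_mean: float = 5.0
    n_hemocyte_program: int = 20
    experiments: list[ExperimentSpec] = field(
        default_factory=lambda: [
            ExperimentSpec("toxin_digestive_gland", "digestive_gland", "mucosal"),
            ExperimentSpec("bacteria_hemocytes", "hemocytes", "hemocyte"),
        ]
    )


@dataclass
class ScenarioConfig:
    """Full description of one synthetic scenario; see the module docstring
    for what the defaults emulate."""

    taxonomy: dict[str, dict[str, dict[str, int]]] = field(
        default_factory=_default_taxonomy
    )
    focal_phylum: str = "Mollusca"
    conserved_class: str = "Bivalvia"  # also the "bivalve" clade for categories
    chordate_clade: str = "Chordata"
    n_phylum_conserved: int = 10
    n_class_conserved: int = 10
    n_multi_family: int = 10
    n_family_specific: int = 20
    n_restricted: int = 50
    n_ctldcp_a: int = 15
    n_ctldcp_b: int = 15
    n_ctldcp_c: int = 15
    ctldcp_domain_pools: dict[str, list[str]] = field(default_factory=_default_pools)
    paralog_mean: float = 2.0
    multi_isoform_rate: float = 0.2
    n_background_genes: int = 40
    presence_flip_rate: float = 0.0
    domain_loss_rate: float = 0.0
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    write_fasta: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_phylum_conserved", "n_class_conserved", "n_multi_family",
            "n_family_specific", "n_restricted", "n_ctldcp_a", "n_ctldcp_b",
            "n_ctldcp_c", "n_background_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("presence_flip_rate", "domain_loss_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.paralog_mean < 1:
            raise ValueError("paralog_mean must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        data = dict(data)
        if "expression" in data and isinstance(data["expression"], Mapping):
            expr = dict(data["expression"])
            if "experiments" in expr:
                expr["experiments"] = [
                    ExperimentSpec(**e) if isinstance(e, Mapping) else e
                    for e in expr["experiments"]
                ]
            if "sample_types" in expr:
                expr["sample_types"] = tuple(expr["sample_types"])
            if "mean_grid" in expr:
                expr["mean_grid"] = tuple(expr["mean_grid"])
            data["expression"] = ExpressionSpec(**expr)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(eq=False)
class ScenarioBundle:
    """In-memory synthetic dataset plus its planted truth."""

    taxonomy: Taxonomy
    isoform_map: pd.DataFrame
    hits_by_species: dict[str, list[DomainHit]]
    orthogroups: OrthogroupTable
    structure: pd.DataFrame
    expression: ExpressionDataset
    truth: dict
    config: ScenarioConfig

    def write(self, out_dir: str | Path) -> None:
        """Emit the bundle as the file formats the pipeline reads.

        Identical bundles produce byte-identical files.
        """
        out = Path(out_dir)
        (out / "pfamscan").mkdir(parents=True, exist_ok=True)
        write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        write_isoform_map(self.isoform_map, out / "isoform_map.tsv")
        for sp in self.taxonomy.species:
            write_pfamscan(
                self.hits_by_species.get(sp, []), out / "pfamscan" / f"{sp}.tsv"
            )
        write_orthogroups_tsv(self.orthogroups, out / "Orthogroups.tsv")
        write_structure_annotations(self.structure, out / "structure.tsv")
        write_expression(
            self.expression,
            out / "counts.tsv",
            out / "abundance.tsv",
            out / "sample_meta.tsv",
        )
        with open(out / "truth.json", "wt", encoding="utf-8") as fh:
            json.dump(self.truth, fh, sort_keys=True, indent=1)
            fh.write("\n")
        if self.config.write_fasta:
            self._write_fasta(out / "proteins.fasta")

    def _write_fasta(self, path: Path) -> None:
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        with open(path, "wt", encoding="utf-8") as fh:
            for _, row in self.isoform_map.iterrows():
                n = int(row["length"])
                seq = "M" + "".join(
                    alphabet[i % len(alphabet)] for i in range(n - 1)
                )
                fh.write(f">{row['protein_id']} gene={row['gene_id']}\n")
                for i in range(0, n, 60):
                    fh.write(seq[i : i + 60] + "\n")

    def file_hashes(self, out_dir: str | Path) -> dict[str, str]:
        """SHA-256 of every emitted file (bundle must be written first)."""
        out = Path(out_dir)
        hashes = {}
        for p in sorted(out.rglob("*")):
            if p.is_file():
                hashes[str(p.relative_to(out))] = hashlib.sha256(
                    p.read_bytes()
                ).hexdigest()
        return hashes


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------


def _domain_length(accession: str) -> int:
    if accession == "PF00059":
        return 110
    return 40 + int(accession[2:]) % 120


def _hits_for(protein_id: str, accessions: Sequence[str]) -> list[DomainHit]:
    """Place domains sequentially with 10-residue gaps, starting at 25."""
    hits = []
    pos = 25
    for acc in accessions:
        length = _domain_length(acc)
        versioned = CTL_VERSIONED if acc == "PF00059" else acc
        hits.append(
            DomainHit(
                protein_id=protein_id,
                pfam_accession=versioned,
                pfam_id=_PFAM_IDS.get(acc, acc),
                env_start=pos,
                env_end=pos + length - 1,
                bitscore=float(40 + length % 50),
                evalue=10.0 ** -(5 + length % 10),
            )
        )
        pos += length + 10
    return hits


class _Proteome:
    """Accumulates genes, isoforms and domain hits per species."""

    def __init__(self, species: Sequence[str]):
        self.counter = {sp: 0 for sp in species}
        self.isoforms: list[tuple[str, str, int]] = []  # gene, protein, length
        self.hits: dict[str, list[DomainHit]] = {sp: [] for sp in species}
        self.arch: dict[str, list[str]] = {}  # protein → accessions in order
        self.gene_species: dict[str, str] = {}
        self.gene_protein: dict[str, str] = {}  # gene → primary protein

    def add_gene(
        self,
        species: str,
        accessions: Sequence[str],
        rng_iso: np.random.Generator | None,
        multi_isoform_rate: float,
        prefix: str = "g",
    ) -> str:
        self.counter[species] += 1
        gene = f"{species}_{prefix}{self.counter[species]:04d}"
        protein = f"{gene}.p1"
        hits = _hits_for(protein, accessions)
        length = (hits[-1].env_end + 30) if hits else 180
        self.isoforms.append((gene, protein, length))
        self.hits[species].extend(hits)
        self.arch[protein] = list(accessions)
        self.gene_species[gene] = species
        self.gene_protein[gene] = protein
        if rng_iso is not None and rng_iso.random() < multi_isoform_rate:
            alt = f"{gene}.p2"
            alt_len = max(30, length - int(rng_iso.integers(10, 60)))
            self.isoforms.append((gene, alt, alt_len))
            if accessions:
                alt_hits = _hits_for(alt, accessions[:1])
                self.hits[species].extend(alt_hits)
                self.arch[alt] = list(accessions[:1])
            else:
                self.arch[alt] = []
        return gene


def _plant_presence(cfg: ScenarioConfig, tax: Taxonomy, rng: np.random.Generator):
    """Choose present-species sets for every planted CTL orthogroup.

    Returns a list of (level, present_species) in planting order. Raises on
    structurally impossible configs (a planted level that would alias to a
    broader one for any high coverage threshold).
    """
    phylum_species = tax.species_in(cfg.focal_phylum)
    classes = {
        cls: spp
        for cls, spp in tax.groups("class").items()
        if set(spp) <= set(phylum_species)
    }
    fam_by_class = {
        cls: sorted(
            f for f, spp in tax.groups("family").items()
            if set(spp) <= set(classes[cls])
        )
        for cls in classes
    }
    plans: list[tuple[str, list[str]]] = []

    if cfg.n_class_conserved and cfg.conserved_class not in classes:
        raise ValueError(
            f"conserved_class {cfg.conserved_class!r} not a class of "
            f"{cfg.focal_phylum!r}"
        )
    if cfg.n_class_conserved and len(classes) < 2:
        raise ValueError(
            "class-level planting needs >=2 classes in the focal phylum"
        )
    for _ in range(cfg.n_phylum_conserved):
        plans.append(("PHYLUM", list(phylum_species)))
    for _ in range(cfg.n_class_conserved):
        plans.append(("CLASS", list(classes[cfg.conserved_class])))

    pair_pool = [
        (cls, pair)
        for cls in sorted(classes)
        if len(fam_by_class[cls]) >= 3
        for pair in combinations(fam_by_class[cls], 2)
    ]
    if cfg.n_multi_family and not pair_pool:
        raise ValueError(
            "multi-family planting needs a class with >=3 families"
        )
    for i in range(cfg.n_multi_family):
        _, pair = pair_pool[i % len(pair_pool)]
        spp = sorted(
            tax.species_in(pair[0]) + tax.species_in(pair[1])
        )
        plans.append(("MULTI_FAMILY", spp))

    single_pool = [
        f
        for cls in sorted(classes)
        if len(fam_by_class[cls]) >= 2
        for f in fam_by_class[cls]
    ]
    if cfg.n_family_specific and not single_pool:
        raise ValueError(
            "family-level planting needs a class with >=2 families"
        )
    for i in range(cfg.n_family_specific):
        fam = single_pool[i % len(single_pool)]
        plans.append(("FAMILY", list(tax.species_in(fam))))

    all_families = sorted(
        f for fams in fam_by_class.values() for f in fams
    )
    if cfg.n_restricted and not all_families:
        raise ValueError("restricted planting needs at least one family")
    for i in range(cfg.n_restricted):
        fam = all_families[i % len(all_families)]
        spp = tax.species_in(fam)
        k = 1 + int(rng.integers(0, max(1, len(spp) // 2)))
        chosen = sorted(rng.choice(spp, size=min(k, len(spp)), replace=False))
        plans.append(("RESTRICTED", [str(s) for s in chosen]))
    return plans


def _build_taxonomy(cfg: ScenarioConfig) -> Taxonomy:
    rows = []
    for phylum, by_class in cfg.taxonomy.items():
        for cls, by_family in by_class.items():
            for family, n in by_family.items():
                for i in range(1, n + 1):
                    rows.append(
                        {
                            "species_id": f"{family}_sp{i:02d}",
                            "family": family,
                            "class": cls,
                            "phylum": phylum,
                        }
                    )
    return Taxonomy(pd.DataFrame(rows))


def generate_scenario(
    cfg: ScenarioConfig, out_dir: str | Path | None = None
) -> ScenarioBundle:
    """Generate a full synthetic input bundle with its truth record.

    With ``out_dir`` the bundle is also written to disk. Identical configs
    (including the seed) give byte-identical output files. Configs whose
    planted conservation levels would alias to broader levels raise
    ``ValueError``.
    """
    tax = _build_taxonomy(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng_arch, rng_orth, rng_struct, rng_iso, rng_expr, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    proteome = _Proteome(tax.species)
    og_members: dict[str, dict[str, list[str]]] = {}
    truth_conservation: dict[str, str] = {}
    truth_category: dict[str, str] = {}
    og_arch: dict[str, dict] = {}
    og_counter = 0

    def new_og() -> str:
        nonlocal og_counter
        og_counter += 1
        return f"OG{og_counter:07d}"

    # --- CTL orthogroups with planted conservation levels ----------------
    plans = _plant_presence(cfg, tax, rng_orth)
    class_conserved_ogs: list[str] = []
    for level, present in plans:
        og = new_og()
        truth_conservation[og] = level
        n_ctl = int(rng_arch.integers(1, 4))
        arch = ["PF00059"] * n_ctl
        og_arch[og] = {"with_ctl": arch, "without_ctl": None, "n_ctl_domains": n_ctl}
        if level == "CLASS":
            class_conserved_ogs.append(og)
        members: dict[str, list[str]] = {sp: [] for sp in tax.species}
        for sp in present:
            n_paralogs = int(rng_orth.geometric(1.0 / cfg.paralog_mean))
            for _ in range(n_paralogs):
                gene = proteome.add_gene(
                    sp, arch, rng_iso, cfg.multi_isoform_rate
                )
                members[sp].append(proteome.gene_protein[gene])
        og_members[og] = members

    # --- CTLDcp orthogroups with planted retention categories ------------
    bivalves = set(tax.species_in(cfg.conserved_class))
    try:
        chordates = set(tax.species_in(cfg.chordate_clade))
    except KeyError:
        chordates = set()
    if (cfg.n_ctldcp_a or cfg.n_ctldcp_b) and not chordates:
        raise ValueError(
            f"categories A/B need the chordate clade {cfg.chordate_clade!r} "
            f"in the taxonomy"
        )
    if (cfg.n_ctldcp_b or cfg.n_ctldcp_c) and not bivalves:
        raise ValueError("categories B/C need the bivalve clade")

    def plant_ctldcp(category: str, with_ctl_species: set, present: set) -> None:
        og = new_og()
        truth_category[og] = category
        pool = sorted(cfg.ctldcp_domain_pools[category])
        k = int(rng_arch.integers(1, min(2, len(pool)) + 1))
        others = [str(a) for a in rng_arch.choice(pool, size=k, replace=False)]
        og_arch[og] = {
            "with_ctl": ["PF00059"] + others,
            "without_ctl": others,
            "n_ctl_domains": 1,
        }
        members: dict[str, list[str]] = {sp: [] for sp in tax.species}
        for sp in tax.species:
            if sp not in present:
                continue
            arch = og_arch[og]["with_ctl" if sp in with_ctl_species else "without_ctl"]
            if (
                sp in with_ctl_species
                and cfg.domain_loss_rate
                and rng_arch.random() < cfg.domain_loss_rate
            ):
                arch = og_arch[og]["without_ctl"]
            gene = proteome.add_gene(sp, arch, rng_iso, cfg.multi_isoform_rate)
            members[sp].append(proteome.gene_protein[gene])
        og_members[og] = members

    all_species = set(tax.species)
    for _ in range(cfg.n_ctldcp_a):
        plant_ctldcp("A", with_ctl_species=all_species, present=all_species)
    for _ in range(cfg.n_ctldcp_b):
        plant_ctldcp(
            "B", with_ctl_species=bivalves, present=bivalves | chordates
        )
    for _ in range(cfg.n_ctldcp_c):
        plant_ctldcp("C", with_ctl_species=bivalves, present=bivalves)

    # --- background (non-lectin) genes, outside any orthogroup -----------
    for sp in tax.species:
        for _ in range(cfg.n_background_genes):
            k = int(rng_arch.integers(0, 3))
            accs = [
                str(a)
                for a in rng_arch.choice(_BACKGROUND_POOL, size=k, replace=False)
            ]
            proteome.add_gene(sp, accs, rng_iso, cfg.multi_isoform_rate)

    orthogroups = OrthogroupTable(species=list(tax.species), members=og_members)
    isoform_map = pd.DataFrame(
        proteome.isoforms, columns=["gene_id", "protein_id", "length"]
    )

    # --- structure annotations -------------------------------------------
    mucosal_genes = {
        g
        for og in class_conserved_ogs
        for sp, prots in og_members[og].items()
        for p in prots
        for g in [p.rsplit(".", 1)[0]]
    }
    struct_rows = []
    for gene, protein, _length in proteome.isoforms:
        if gene in mucosal_genes:
            signal, tm = True, 0
        else:
            signal = bool(rng_struct.random() < 0.3)
            tm = int(rng_struct.poisson(0.2))
        struct_rows.append(
            {
                "protein_id": protein,
                "has_signal_peptide": signal,
                "n_transmembrane": tm,
            }
        )
    structure = pd.DataFrame(struct_rows)

    # --- expression for the focal species ---------------------------------
    focal = sorted(bivalves)[0] if bivalves else tax.species[0]
    focal_genes = [
        g for g in proteome.gene_species if proteome.gene_species[g] == focal
    ]
    focal_mucosal = [g for g in focal_genes if g in mucosal_genes]
    # hemocyte program drawn from focal genes outside any orthogroup
    assigned = {
        p for by in og_members.values() for ps in by.values() for p in ps
    }
    unassigned_focal = [
        g for g in focal_genes if proteome.gene_protein[g] not in assigned
    ]
    espec = cfg.expression
    hemocyte_set = unassigned_focal[: espec.n_hemocyte_program]
    program: dict[str, str] = {}
    for g in focal_genes:
        if g in focal_mucosal:
            program[g] = "mucosal"
        elif g in hemocyte_set:
            program[g] = "hemocyte"
        else:
            program[g] = "broad"

    types = list(espec.sample_types)
    means = np.zeros((len(focal_genes), len(types)))
    broad_means = rng_expr.choice(espec.mean_grid, size=len(focal_genes))
    for i, g in enumerate(focal_genes):
        prog = program[g]
        for j, st in enumerate(types):
            if prog == "mucosal":
                means[i, j] = (
                    espec.program_mean
                    if st in ("digestive_gland", "gill")
                    else 0.0
                )
            elif prog == "hemocyte":
                means[i, j] = (
                    espec.program_mean if st == "hemocytes" else espec.low_mean
                )
            else:
                means[i, j] = broad_means[i]

    def nb_draw(mu: np.ndarray, dispersion: float) -> np.ndarray:
        r = 1.0 / dispersion
        p = r / (r + mu)
        draw = rng_expr.negative_binomial(r, p)
        return np.where(mu > 0, draw, 0)

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_cols: list[np.ndarray] = []
    for st in types:
        j = types.index(st)
        for i in range(1, espec.n_baseline_per_type + 1):
            sid = f"baseline_{st}_{i}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "sample_type": st,
                    "experiment_id": "baseline",
                    "condition": "control",
                }
            )
            count_cols.append(nb_draw(means[:, j], espec.dispersion))
    responders: dict[str, list[str]] = {}
    for exp in espec.experiments:
        j = types.index(exp.tissue)
        resp = [g for g in focal_genes if program[g] == exp.responders]
        responders[exp.experiment_id] = resp
        resp_mask = np.array([program[g] == exp.responders for g in focal_genes])
        base_mu = means[:, j]
        stim_mu = np.where(resp_mask, base_mu * 2.0**exp.log2fc, base_mu)
        for cond, n_samp, mu in (
            ("control", exp.n_control, base_mu),
            ("stimulated", exp.n_stimulated, stim_mu),
        ):
            for i in range(1, n_samp + 1):
                sid = f"{exp.experiment_id}_{cond}_{i}"
                sample_ids.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "sample_type": exp.tissue,
                        "experiment_id": exp.experiment_id,
                        "condition": cond,
                    }
                )
                count_cols.append(nb_draw(mu, exp.dispersion))

    counts = pd.DataFrame(
        np.column_stack(count_cols), index=focal_genes, columns=sample_ids
    )
    counts.index.name = "gene_id"
    libsize = counts.sum(axis=0).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(libsize > 0, counts.to_numpy() / libsize * 1e6, 0.0)
    abundance = pd.DataFrame(
        np.round(tpm, 4), index=counts.index, columns=counts.columns
    )
    expression = ExpressionDataset(
        counts=counts, abundance=abundance, sample_meta=pd.DataFrame(meta_rows)
    )

    # --- truth -------------------------------------------------------------
    census_truth: dict[str, dict[str, int]] = {
        sp: {"n_ctl_genes": 0, "n_ctldcp_genes": 0} for sp in tax.species
    }
    from .repertoire import filter_longest_isoform

    retained = filter_longest_isoform(isoform_map)
    for gene, protein in retained.items():
        arch = proteome.arch[protein]
        n_ctl = sum(1 for a in arch if a == "PF00059")
        if n_ctl == 0:
            continue
        sp = proteome.gene_species[gene]
        if all(a == "PF00059" for a in arch):
            census_truth[sp]["n_ctl_genes"] += 1
        else:
            census_truth[sp]["n_ctldcp_genes"] += 1

    presence = {
        og: sorted(sp for sp, prots in by.items() if prots)
        for og, by in og_members.items()
    }
    truth = {
        "seed": cfg.seed,
        "focal_species": focal,
        "conservation": truth_conservation,
        "ctldcp_category": truth_category,
        "orthogroup_architecture": og_arch,
        "architecture": dict(sorted(proteome.arch.items())),
        "census": census_truth,
        "tissue_program": program,
        "responders": responders,
        "presence": {"pre_noise": presence, "post_noise": presence},
        "noise": {"presence_flip_rate": 0.0, "n_flips": 0},
    }

    bundle = ScenarioBundle(
        taxonomy=tax,
        isoform_map=isoform_map,
        hits_by_species=proteome.hits,
        orthogroups=orthogroups,
        structure=structure,
        expression=expression,
        truth=truth,
        config=cfg,
    )
    if cfg.presence_flip_rate > 0:
        bundle = inject_noise(
            bundle,
            cfg.presence_flip_rate,
            seed=int(rng_noise.integers(0, 2**31 - 1)),
        )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def inject_noise(
    bundle: ScenarioBundle, flip_rate: float, seed: int
) -> ScenarioBundle:
    """Flip orthogroup×species presence cells independently with probability
    ``flip_rate``, emulating assembly/annotation artifacts.

    A 1→0 flip removes the species' members from the orthogroup (the
    proteins stay in the proteome, as orthology failures leave singletons);
    a 0→1 flip plants a fresh gene with the orthogroup's canonical
    lectin-bearing architecture. Truth labels stay frozen; the pre- and
    post-noise presence states are both recorded.
    """
    if not 0 <= flip_rate < 1:
        raise ValueError("flip_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    new_members = {
        og: {sp: list(prots) for sp, prots in by.items()}
        for og, by in bundle.orthogroups.members.items()
    }
    iso_rows = list(
        bundle.isoform_map.itertuples(index=False, name=None)
    )
    hits = {sp: list(h) for sp, h in bundle.hits_by_species.items()}
    struct_rows: list[dict] = []
    counter = 0
    n_flips = 0
    species = bundle.orthogroups.species
    for og in bundle.orthogroups.orthogroup_ids:
        arch_info = bundle.truth["orthogroup_architecture"][og]
        for sp in species:
            if rng.random() >= flip_rate:
                continue
            n_flips += 1
            if new_members[og][sp]:
                new_members[og][sp] = []
            else:
                counter += 1
                gene = f"{sp}_gN{counter:04d}"
                protein = f"{gene}.p1"
                accs = arch_info["with_ctl"]
                new_hits = _hits_for(protein, accs)
                length = (new_hits[-1].env_end + 30) if new_hits else 180
                iso_rows.append((gene, protein, length))
                hits[sp].extend(new_hits)
                struct_rows.append(
                    {
                        "protein_id": protein,
                        "has_signal_peptide": False,
                        "n_transmembrane": 0,
                    }
                )
                new_members[og][sp] = [protein]
    orthogroups = OrthogroupTable(species=list(species), members=new_members)
    isoform_map = pd.DataFrame(
        iso_rows, columns=["gene_id", "protein_id", "length"]
    )
    structure = pd.concat(
        [bundle.structure, pd.DataFrame(struct_rows)], ignore_index=True
    ) if struct_rows else bundle.structure.copy()
    truth = copy.deepcopy(bundle.truth)
    truth["presence"]["post_noise"] = {
        og: sorted(sp for sp, prots in by.items() if prots)
        for og, by in new_members.items()
    }
    truth["noise"] = {"presence_flip_rate": flip_rate, "n_flips": n_flips}
    return ScenarioBundle(
        taxonomy=bundle.taxonomy,
        isoform_map=isoform_map,
        hits_by_species=hits,
        orthogroups=orthogroups,
        structure=structure,
        expression=bundle.expression,
        truth=truth,
        config=bundle.config,
    )
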