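"""Readers and writers for the tabular formats exchanged with upstream tools.

The pipeline consumes outputs of standard comparative-genomics tools —
``pfam_scan.pl`` domain tables, OrthoFinder ``Orthogroups.tsv`` — plus plain
TSV tables for the taxonomy, gene↔isoform map, structure annotations and the
expression matrices, and writes the same dialects back out so every reader
has a matching writer.

Coordinate convention: Pfam *envelope* coordinates, 1-based and inclusive at
both ends, preserved exactly as emitted by ``pfam_scan.pl``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ParseError",
    "DomainHit",
    "OrthogroupTable",
    "Taxonomy",
    "ExpressionDataset",
    "SAMPLE_TYPES",
    "CONDITIONS",
    "read_pfamscan",
    "write_pfamscan",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
    "read_taxonomy",
    "write_taxonomy",
    "read_isoform_map",
    "write_isoform_map",
    "read_structure_annotations",
    "write_structure_annotations",
    "read_expression",
    "write_expression",
]

PFAM_ACCESSION_RE = re.compile(r"^PF\d{5}(\.\d+)?$")

#: Sample types recognised in expression metadata (five assayed sample types
#: plus a catch-all for anything else in a heterogeneous SRA-style compendium).
SAMPLE_TYPES = (
    "digestive_gland",
    "gill",
    "hemocytes",
    "larvae",
    "mantle",
    "other",
)

CONDITIONS = ("control", "stimulated")


class ParseError(ValueError):
    """Raised when an input file violates its expected dialect."""


# ---------------------------------------------------------------------------
# pfam_scan.pl tabular dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain hit on one protein, in envelope coordinates.

    ``pfam_accession`` keeps the version suffix verbatim (``PF00059.21``);
    use :attr:`accession` for version-insensitive comparisons.
    """

    protein_id: str
    pfam_accession: str
    pfam_id: str
    env_start: int
    env_end: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not PFAM_ACCESSION_RE.match(self.pfam_accession):
            raise ValueError(
                f"invalid Pfam accession {self.pfam_accession!r} "
                f"on protein {self.protein_id!r}"
            )
        if self.env_start < 1 or self.env_end < self.env_start:
            raise ValueError(
                f"invalid envelope coordinates {self.env_start}-{self.env_end} "
                f"on protein {self.protein_id!r}"
            )
        if self.evalue < 0:
            raise ValueError(f"negative E-value on protein {self.protein_id!r}")

    @property
    def accession(self) -> str:
        """Unversioned Pfam accession (``PF00059.21`` → ``PF00059``)."""
        return self.pfam_accession.split(".", 1)[0]


# pfam_scan.pl column order:
# seq id, aln start, aln end, env start, env end, hmm acc, hmm name, type,
# hmm start, hmm end, hmm length, bit score, E-value, significance, clan
_PFAMSCAN_NCOL = 15


def read_pfamscan(path: str | Path) -> list[DomainHit]:
    """Parse a ``pfam_scan.pl`` output file into :class:`DomainHit` records.

    Lines starting with ``#`` and blank lines are comments. One hit per
    remaining line; envelope columns provide the coordinates. Malformed
    lines raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != _PFAMSCAN_NCOL:
                raise ParseError(
                    f"{path}:{lineno}: expected {_PFAMSCAN_NCOL} columns, "
                    f"got {len(parts)}"
                )
            try:
                hit = DomainHit(
                    protein_id=parts[0],
                    pfam_accession=parts[5],
                    pfam_id=parts[6],
                    env_start=int(parts[3]),
                    env_end=int(parts[4]),
                    bitscore=float(parts[11]),
                    evalue=float(parts[12]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


_PFAMSCAN_HEADER = (
    "# <seq id> <alignment start> <alignment end> <envelope start> "
    "<envelope end> <hmm acc> <hmm name> <type> <hmm start> <hmm end> "
    "<hmm length> <bit score> <E-value> <significance> <clan>"
)


def write_pfamscan(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the ``pfam_scan.pl`` tabular dialect.

    Columns the :class:`DomainHit` type does not track (alignment
    coordinates, HMM coordinates, clan) are filled with self-consistent
    placeholders; the typed fields round-trip exactly through
    :func:`read_pfamscan`.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(_PFAMSCAN_HEADER + "\n#\n")
        for h in hits:
            hmm_len = h.env_end - h.env_start + 1
            fh.write(
                f"{h.protein_id} {h.env_start} {h.env_end} "
                f"{h.env_start} {h.env_end} {h.pfam_accession} {h.pfam_id} "
                f"Domain 1 {hmm_len} {hmm_len} {h.bitscore!r} {h.evalue!r} "
                f"1 No_clan\n"
            )


# ---------------------------------------------------------------------------
# OrthoFinder Orthogroups.tsv
# ---------------------------------------------------------------------------


@dataclass
class OrthogroupTable:
    """Orthogroup membership: orthogroup → species → member proteins.

    Every orthogroup carries the same species columns; a protein may belong
    to at most one orthogroup (OrthoFinder guarantees this; we re-check).
    """

    species: list[str]
    members: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        species_set = set(self.species)
        if len(species_set) != len(self.species):
            raise ValueError("duplicate species column")
        seen: dict[str, str] = {}
        for og_id, by_species in self.members.items():
            if set(by_species) != species_set:
                raise ValueError(
                    f"orthogroup {og_id!r} does not cover the species columns"
                )
            for sp, prots in by_species.items():
                for p in prots:
                    if p in seen:
                        raise ValueError(
                            f"protein {p!r} appears in orthogroups "
                            f"{seen[p]!r} and {og_id!r}"
                        )
                    seen[p] = og_id

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.members)

    def members_of(self, orthogroup_id: str) -> dict[str, list[str]]:
        return self.members[orthogroup_id]

    def all_proteins(self) -> list[str]:
        return [
            p
            for by_species in self.members.values()
            for prots in by_species.values()
            for p in prots
        ]


def read_orthogroups_tsv(path: str | Path) -> OrthogroupTable:
    """Parse an OrthoFinder-style ``Orthogroups.tsv``.

    First column ``Orthogroup``; one column per species; cells hold
    comma+space-separated protein IDs or are empty.
    """
    path = Path(path)
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "Orthogroup":
            raise ParseError(
                f"{path}: first column must be 'Orthogroup', got {cols[0]!r}"
            )
        species = cols[1:]
        members: dict[str, dict[str, list[str]]] = {}
        for lineno, raw in enumerate(fh, start=2):
            row = raw.rstrip("\n").split("\t")
            if len(row) != len(cols):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols)} columns, "
                    f"got {len(row)}"
                )
            og_id = row[0]
            if og_id in members:
                raise ParseError(f"{path}:{lineno}: duplicate orthogroup {og_id!r}")
            members[og_id] = {
                sp: (cell.split(", ") if cell else [])
                for sp, cell in zip(species, row[1:])
            }
    try:
        return OrthogroupTable(species=species, members=members)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_orthogroups_tsv(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.species) + "\n")
        for og_id, by_species in table.members.items():
            cells = [", ".join(by_species[sp]) for sp in table.species]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class Taxonomy:
    """Species → family → class → phylum rank table.

    Rank values are assumed unique across ranks (a name identifies a taxon
    unambiguously), which holds for Linnaean names.
    """

    table: pd.DataFrame

    RANKS = ("family", "class", "phylum")

    def __post_init__(self) -> None:
        required = ("species_id",) + self.RANKS
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"taxonomy missing columns: {missing}")
        self.table = self.table.loc[:, list(required)].astype(str)
        if self.table["species_id"].duplicated().any():
            dup = self.table.loc[self.table["species_id"].duplicated(), "species_id"]
            raise ValueError(f"duplicate species_id: {sorted(set(dup))}")
        if (self.table[list(required)] == "").any().any():
            raise ValueError("empty rank value in taxonomy")
        self._by_rank: dict[str, dict[str, list[str]]] = {}
        for rank in self.RANKS:
            groups: dict[str, list[str]] = {}
            for taxon, sub in self.table.groupby(rank, sort=True):
                groups[str(taxon)] = sorted(sub["species_id"])
            self._by_rank[rank] = groups

    @property
    def species(self) -> list[str]:
        return list(self.table["species_id"])

    def groups(self, rank: str) -> dict[str, list[str]]:
        """Taxon → sorted member species, for one rank."""
        return self._by_rank[rank]

    def rank_of(self, taxon: str) -> str | None:
        for rank in self.RANKS:
            if taxon in self._by_rank[rank]:
                return rank
        return None

    def species_in(self, taxon: str) -> list[str]:
        """Species of a named taxon, searched across family/class/phylum."""
        rank = self.rank_of(taxon)
        if rank is None:
            raise KeyError(f"taxon {taxon!r} not found at any rank")
        return self._by_rank[rank][taxon]

    def class_of_family(self, family: str) -> str:
        sub = self.table.loc[self.table["family"] == family, "class"]
        if sub.empty:
            raise KeyError(f"family {family!r} not found")
        return str(sub.iloc[0])


def read_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    try:
        return Taxonomy(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_taxonomy(taxonomy: Taxonomy, path: str | Path) -> None:
    taxonomy.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Isoform map, structure annotations
# ---------------------------------------------------------------------------


def _validate_isoform_map(df: pd.DataFrame) -> pd.DataFrame:
    required = ["gene_id", "protein_id", "length"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"isoform map missing columns: {missing}")
    df = df.loc[:, required].copy()
    df["length"] = pd.to_numeric(df["length"], errors="raise").astype(int)
    if df["protein_id"].duplicated().any():
        dup = df.loc[df["protein_id"].duplicated(), "protein_id"]
        raise ValueError(f"protein_id listed twice: {sorted(set(dup))}")
    if (df["length"] < 1).any():
        raise ValueError("isoform length must be >= 1")
    return df


def read_isoform_map(path: str | Path) -> pd.DataFrame:
    """Gene↔isoform table with columns gene_id, protein_id, length."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "protein_id": str})
    try:
        return _validate_isoform_map(df)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_isoform_map(df: pd.DataFrame, path: str | Path) -> None:
    _validate_isoform_map(df).to_csv(path, sep="\t", index=False)


def read_structure_annotations(path: str | Path) -> pd.DataFrame:
    """Per-protein signal peptide / transmembrane calls from an external
    predictor, columns protein_id, has_signal_peptide (0/1), n_transmembrane.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = ["protein_id", "has_signal_peptide", "n_transmembrane"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df.loc[:, required].copy()
    df["has_signal_peptide"] = df["has_signal_peptide"].astype(int).astype(bool)
    df["n_transmembrane"] = df["n_transmembrane"].astype(int)
    if (df["n_transmembrane"] < 0).any():
        raise ParseError(f"{path}: negative n_transmembrane")
    return df


def write_structure_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.loc[:, ["protein_id", "has_signal_peptide", "n_transmembrane"]].copy()
    out["has_signal_peptide"] = out["has_signal_peptide"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class ExpressionDataset:
    """Counts + TPM-scale abundance (genes × samples) with sample metadata.

    ``sample_meta`` columns: sample_id, sample_type, experiment_id,
    condition. Both matrices share the same gene rows and the metadata
    covers every sample column exactly once.
    """

    counts: pd.DataFrame
    abundance: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta
        required = ["sample_id", "sample_type", "experiment_id", "condition"]
        missing = [c for c in required if c not in meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        meta = meta.loc[:, required].astype(str)
        if meta["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        bad_type = set(meta["sample_type"]) - set(SAMPLE_TYPES)
        if bad_type:
            raise ValueError(f"unknown sample_type values: {sorted(bad_type)}")
        bad_cond = set(meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown condition values: {sorted(bad_cond)}")
        meta_samples = set(meta["sample_id"])
        for name, mat in (("counts", self.counts), ("abundance", self.abundance)):
            extra = sorted(set(mat.columns) - meta_samples)
            if extra:
                raise ValueError(
                    f"{name} sample {extra[0]!r} missing from metadata"
                )
            absent = sorted(meta_samples - set(mat.columns))
            if absent:
                raise ValueError(f"{name} matrix lacks sample {absent[0]!r}")
        if set(self.counts.index) != set(self.abundance.index):
            raise ValueError("counts and abundance gene sets differ")
        counts = self.counts
        vals = counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative count")
        if not (vals == vals.astype(int)).all():
            raise ValueError("non-integer count")
        self.counts = counts.astype(int)
        self.abundance = self.abundance.loc[self.counts.index, self.counts.columns]
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundance")
        self.sample_meta = meta.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_where(self, **criteria: str) -> list[str]:
        """Sample IDs whose metadata matches every keyword (e.g.
        ``sample_type="gill"``, ``condition="control"``)."""
        mask = pd.Series(True, index=self.sample_meta.index)
        for key, value in criteria.items():
            mask &= self.sample_meta[key] == value
        return list(self.sample_meta.loc[mask, "sample_id"])


def read_expression(
    counts_path: str | Path,
    abundance_path: str | Path,
    meta_path: str | Path,
) -> ExpressionDataset:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    try:
        return ExpressionDataset(counts=counts, abundance=abundance, sample_meta=meta)
    except ValueError as exc:
        raise ParseError(f"{counts_path}: {exc}") from exc


def write_expression(
    ds: ExpressionDataset,
    counts_path: str | Path,
    abundance_path: str | Path,
    meta_path: str | Path,
) -> None:
    ds.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    # shortest-repr floats: exact round-trip through read_expression
    ds.abundance.to_csv(abundance_path, sep="\t", index_label="gene_id")
    ds.sample_meta.to_csv(meta_path, sep="\t", index=False)
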