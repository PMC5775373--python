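"""Read, validate, and subset peptide-elution tables.

The central container is :class:`RepertoirePair`: one cell line's set of
unique eluted peptides, each carrying its measured abundance before and
after infection. Peptide identity is the exact amino-acid sequence, so a
peptide detected in both conditions is a single record with two abundances —
this pairing is what lets downstream analyses compare the same ligand across
conditions.

HLA alleles are mapped to the four classical inhibitory-KIR epitope groups
(A3/11, Bw4, C1, C2) via an :class:`EpitopeMap`; a curated default map of
common alleles ships with the package and can be overridden from a TSV.
"""

from __future__ import annotations

import copy
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .exceptions import ConflictError, SchemaError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

ORIGIN_SELF = "self"
ORIGIN_VIRAL = "viral"
ORIGINS = (ORIGIN_SELF, ORIGIN_VIRAL)

#: Sentinel for peptides that could not be assigned to any HLA-I molecule.
UNASSIGNED = "NA"

#: The four mutually exclusive KIR epitope groups on HLA-I alleles.
KIR_EPITOPES = ("A3/11", "Bw4", "C1", "C2")
NO_EPITOPE = "none"

#: Canonical column names of the peptide-table TSV dialect.
REQUIRED_COLUMNS = (
    "sequence",
    "length",
    "abundance_uninfected",
    "abundance_infected",
    "origin",
    "hla_allele",
)


@dataclass(frozen=True)
class PeptideRecord:
    """One unique eluted peptide with per-condition abundances.

    Abundances are in arbitrary mass-spectrometry response units; the
    uninfected abundance contributes to T_H, the infected abundance to
    T_HI (self) or T_MV (viral). Viral peptides cannot be presented before
    the infection, so their uninfected abundance must be zero.
    """

    sequence: str
    abundance_uninfected: float
    abundance_infected: float
    origin: str = ORIGIN_SELF
    hla_allele: str = UNASSIGNED

    def __post_init__(self) -> None:
        if not self.sequence or not _AA_SET.issuperset(self.sequence):
            bad = sorted(set(self.sequence) - _AA_SET) or ["<empty>"]
            raise ValidationError(
                f"sequence {self.sequence!r} contains characters outside the "
                f"20-letter amino-acid alphabet: {bad}"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(f"origin must be one of {ORIGINS}, got {self.origin!r}")
        for name in ("abundance_uninfected", "abundance_infected"):
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ValidationError(f"{name} must be a nonnegative real, got {value!r}")
        if self.abundance_uninfected == 0.0 and self.abundance_infected == 0.0:
            raise ValidationError(
                f"peptide {self.sequence!r} has zero abundance in both conditions"
            )
        if self.origin == ORIGIN_VIRAL and self.abundance_uninfected != 0.0:
            raise ValidationError(
                f"viral peptide {self.sequence!r} has nonzero pre-infection abundance"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class RepertoirePair:
    """A cell line's paired pre/post-infection peptide repertoire.

    Exposes the unique-peptide counts (n_H, n_HI, n_MV) and total abundances
    (T_H, T_HI, T_MV) used throughout the analysis; all six are recomputed
    from the records on access, so any filtering stays consistent.
    """

    cell_line_id: str
    records: dict[str, PeptideRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, cell_line_id: str, records: Iterable[PeptideRecord]) -> "RepertoirePair":
        out: dict[str, PeptideRecord] = {}
        for rec in records:
            if rec.sequence in out:
                raise ConflictError(f"duplicate peptide sequence {rec.sequence!r}")
            out[rec.sequence] = rec
        return cls(cell_line_id=cell_line_id, records=out)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def self_records(self) -> list[PeptideRecord]:
        return [r for r in self.records.values() if r.origin == ORIGIN_SELF]

    def viral_records(self) -> list[PeptideRecord]:
        return [r for r in self.records.values() if r.origin == ORIGIN_VIRAL]

    # ---- derived counts and totals -------------------------------------
    @property
    def n_H(self) -> int:
        """Unique self peptides presented before infection."""
        return sum(1 for r in self.self_records() if r.abundance_uninfected > 0)

    @property
    def n_HI(self) -> int:
        """Unique self peptides presented after infection."""
        return sum(1 for r in self.self_records() if r.abundance_infected > 0)

    @property
    def n_MV(self) -> int:
        """Unique virus-derived peptides (post-infection only)."""
        return len(self.viral_records())

    @property
    def T_H(self) -> float:
        return math.fsum(r.abundance_uninfected for r in self.self_records())

    @property
    def T_HI(self) -> float:
        return math.fsum(r.abundance_infected for r in self.self_records())

    @property
    def T_MV(self) -> float:
        return math.fsum(r.abundance_infected for r in self.viral_records())

    def subset(self, sequences: Iterable[str]) -> "RepertoirePair":
        keep = set(sequences)
        missing = keep - self.records.keys()
        if missing:
            raise ValidationError(f"sequences not in repertoire: {sorted(missing)[:5]}")
        return RepertoirePair(
            cell_line_id=self.cell_line_id,
            records={s: r for s, r in self.records.items() if s in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sequence": r.sequence,
                "length": r.length,
                "abundance_uninfected": r.abundance_uninfected,
                "abundance_infected": r.abundance_infected,
                "origin": r.origin,
                "hla_allele": r.hla_allele,
            }
            for r in sorted(self.records.values(), key=lambda r: r.sequence)
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


class EpitopeMap(Mapping):
    """Total mapping from HLA allele name to a KIR epitope group.

    Alleles absent from the underlying table — including the ``"NA"``
    unassigned sentinel — map to ``"none"``.
    """

    def __init__(self, mapping: Mapping[str, str]):
        bad = {a: e for a, e in mapping.items() if e not in KIR_EPITOPES + (NO_EPITOPE,)}
        if bad:
            raise ValidationError(f"unknown epitope labels in map: {bad}")
        self._map = dict(mapping)

    def __getitem__(self, allele: str) -> str:
        return self._map[allele]

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def epitope(self, allele: str) -> str:
        """Epitope group for *allele*; unknown alleles and "NA" give "none"."""
        return self._map.get(allele, NO_EPITOPE)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EpitopeMap":
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        for col in ("allele", "epitope"):
            if col not in df.columns:
                raise SchemaError(f"epitope map is missing required column {col!r}")
        return cls(dict(zip(df["allele"], df["epitope"])))

    @classmethod
    def default(cls) -> "EpitopeMap":
        """The curated allele table shipped with the package."""
        ref = resources.files("alteredself").joinpath("data/epitope_map.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def assign_epitope(allele: str, epitope_map: EpitopeMap) -> str:
    """Map an HLA allele name to its KIR epitope group (total function)."""
    return epitope_map.epitope(allele)


def load_peptide_table(
    path: str | Path,
    dialect: Optional[Mapping[str, str]] = None,
    cell_line_id: Optional[str] = None,
) -> RepertoirePair:
    """Load and validate a peptide-elution TSV into a :class:`RepertoirePair`.

    Parameters
    ----------
    path
        Tab-separated file with header; required columns are
        ``sequence, length, abundance_uninfected, abundance_infected,
        origin, hla_allele`` (lines starting with ``#`` are ignored).
    dialect
        Optional mapping from canonical column name to the name actually
        used in the file.
    cell_line_id
        Identifier for the cell line; defaults to the file stem.

    Rows sharing a sequence are merged (abundances summed) only when their
    origin, allele, and length agree; otherwise a :class:`ConflictError` is
    raised. Viral rows have any pre-infection abundance forced to zero.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if dialect:
        rename = {src: canon for canon, src in dialect.items()}
        df = df.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"peptide table {path.name} is missing required column {col!r}")

    records: dict[str, PeptideRecord] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # 1-based file line, counting the header
        seq = str(row.sequence).strip().upper()
        if not seq or not _AA_SET.issuperset(seq):
            raise ValidationError(
                f"row {line}: sequence {row.sequence!r} contains non-amino-acid characters"
            )
        try:
            length = int(row.length)
            ab_u = float(row.abundance_uninfected)
            ab_i = float(row.abundance_infected)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {line}: non-numeric field ({exc})") from None
        if ab_u < 0 or ab_i < 0:
            raise ValidationError(f"row {line}: negative abundance")
        if length != len(seq):
            raise ValidationError(
                f"row {line}: length column ({length}) does not match sequence length ({len(seq)})"
            )
        origin = str(row.origin).strip().lower()
        if origin not in ORIGINS:
            raise ValidationError(f"row {line}: origin must be one of {ORIGINS}, got {origin!r}")
        allele = str(row.hla_allele).strip() or UNASSIGNED
        if origin == ORIGIN_VIRAL:
            ab_u = 0.0  # viral peptides cannot be presented pre-infection
        if seq in records:
            prev = records[seq]
            if prev.origin != origin or prev.hla_allele != allele:
                raise ConflictError(
                    f"row {line}: duplicate sequence {seq!r} with conflicting annotations"
                )
            ab_u += prev.abundance_uninfected
            ab_i += prev.abundance_infected
        try:
            records[seq] = PeptideRecord(
                sequence=seq,
                abundance_uninfected=ab_u,
                abundance_infected=ab_i,
                origin=origin,
                hla_allele=allele,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line}: {exc}") from None

    return RepertoirePair(
        cell_line_id=cell_line_id or path.stem,
        records=records,
    )


def write_peptide_table(pair: RepertoirePair, path: str | Path) -> None:
    """Write a repertoire back to the TSV dialect :func:`load_peptide_table` reads."""
    pair.to_frame().to_csv(path, sep="\t", index=False)


def restrict_repertoire(
    pair: RepertoirePair,
    epitope_map: Optional[EpitopeMap] = None,
    mode: str = "kir_epitopes",
) -> RepertoirePair:
    """Restrict a repertoire to peptides presented by KIR-epitope-bearing alleles.

    ``mode="kir_epitopes"`` keeps records whose allele maps to A3/11, Bw4,
    C1, or C2 (unassigned "NA" peptides are dropped); ``mode="all"`` is the
    identity. Counts and totals are recomputed implicitly.
    """
    if mode == "all":
        return RepertoirePair(pair.cell_line_id, dict(pair.records))
    if mode != "kir_epitopes":
        raise ValidationError(f"mode must be 'kir_epitopes' or 'all', got {mode!r}")
    emap = epitope_map if epitope_map is not None else EpitopeMap.default()
    kept = {
        s: r
        for s, r in pair.records.items()
        if assign_epitope(r.hla_allele, emap) in KIR_EPITOPES
    }
    return RepertoirePair(pair.cell_line_id, kept)


def filter_ninemers(pair: RepertoirePair) -> RepertoirePair:
    """Keep only 9-mer peptides (the length analysed for P7/P8 motifs)."""
    kept = {s: r for s, r in pair.records.items() if r.length == 9}
    return RepertoirePair(pair.cell_line_id, kept)


def copy_pair(pair: RepertoirePair) -> RepertoirePair:
    return copy.deepcopy(pair)
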