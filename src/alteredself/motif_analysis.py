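"""Sequence-based iKIR-ligand analysis over P7/P8 "KIR motifs".

Crystal structures of inhibitory KIRs bound to HLA-C place positions 7 and 8
of the presented 9-mer in direct contact with the receptor. A hypothetical
iKIR of a given specificity therefore recognises all peptides sharing a
"KIR motif": the ordered pair of residue classes at P7 and P8 under a
:class:`SpecificityScheme`. Two schemes are provided:

* ``exact_pair`` — each amino acid is its own class (20 x 20 = 400 motifs,
  maximal specificity);
* ``physchem_group`` — four physico-chemical classes (non-polar, polar,
  basic, acidic; 4 x 4 = 16 motifs, degenerate specificity).

For each motif the *ligand density* is the summed abundance of all peptides
carrying it, before (L_pre) and after (L_post) infection; the change is
categorised as increase / equal / decrease with nested novel,
decrease-by-at-least-half, and disappeared flags.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import EmptyInputError, UndefinedCategoryError, ValidationError
from .repertoire_io import AMINO_ACIDS, ORIGIN_VIRAL, RepertoirePair

#: Physico-chemical residue classes used by the degenerate scheme.
PHYSCHEM_CLASSES: dict[str, str] = {
    "non-polar": "GAVLIMFWP",
    "polar": "STCYNQ",
    "basic": "KRH",
    "acidic": "DE",
}

#: 1-based peptide positions contacting the inhibitory KIR.
CONTACT_POSITIONS = (7, 8)


@dataclass(frozen=True)
class SpecificityScheme:
    """A reduced amino-acid alphabet defining motif classes at P7/P8."""

    name: str
    alphabet: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.alphabet)
        if missing:
            raise ValidationError(f"scheme {self.name!r} misses residues {sorted(missing)}")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.alphabet.values())))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def motif_space_size(self) -> int:
        """Number of distinct ordered (P7, P8) class pairs."""
        return self.n_classes ** 2

    def classify(self, residue: str) -> str:
        try:
            return self.alphabet[residue]
        except KeyError:
            raise ValidationError(f"unknown residue {residue!r}") from None

    @classmethod
    def exact_pair(cls) -> "SpecificityScheme":
        return cls(name="exact_pair", alphabet={aa: aa for aa in AMINO_ACIDS})

    @classmethod
    def physchem_group(cls) -> "SpecificityScheme":
        alphabet = {
            aa: group for group, members in PHYSCHEM_CLASSES.items() for aa in members
        }
        return cls(name="physchem_group", alphabet=alphabet)

    @classmethod
    def by_name(cls, name: str) -> "SpecificityScheme":
        if name == "exact_pair":
            return cls.exact_pair()
        if name == "physchem_group":
            return cls.physchem_group()
        raise ValidationError(f"unknown specificity scheme {name!r}")


MotifKey = tuple[str, str]


def extract_motif(sequence: str, scheme: SpecificityScheme) -> MotifKey:
    """Ordered (P7, P8) class pair of a 9-mer under *scheme* (1-based positions)."""
    if len(sequence) != 9:
        raise ValidationError(
            f"motif extraction requires a 9-mer, got length {len(sequence)} ({sequence!r})"
        )
    p7, p8 = (sequence[pos - 1] for pos in CONTACT_POSITIONS)
    return (scheme.classify(p7), scheme.classify(p8))


@dataclass
class MotifDensity:
    """Summed abundances of one motif's peptides per condition."""

    l_pre: float = 0.0
    l_post: float = 0.0
    is_viral_derived: bool = False


@dataclass
class MotifDensityTable:
    """Per-motif ligand densities for one repertoire under one scheme."""

    scheme_name: str
    cell_line_id: str
    densities: dict[MotifKey, MotifDensity] = field(default_factory=dict)

    @property
    def n_motifs(self) -> int:
        """N_P7P8: number of distinct motifs present."""
        return len(self.densities)

    @property
    def n_viral_motifs(self) -> int:
        """N_P7P8,MV: motifs with at least one viral contributor."""
        return sum(1 for d in self.densities.values() if d.is_viral_derived)

    def to_frame(self, tol: float = 1e-9) -> pd.DataFrame:
        rows = []
        for key in sorted(self.densities):
            d = self.densities[key]
            cat = categorize_change(d.l_pre, d.l_post, tol=tol)
            rows.append(
                {
                    "motif_p7": key[0],
                    "motif_p8": key[1],
                    "scheme": self.scheme_name,
                    "L_pre": d.l_pre,
                    "L_post": d.l_post,
                    "fold_change": percentual_change(d.l_pre, d.l_post),
                    "category": cat.top,
                    "novel": cat.novel,
                    "at_least_half": cat.at_least_half,
                    "disappeared": cat.disappeared,
                    "viral_derived": d.is_viral_derived,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "motif_p7", "motif_p8", "scheme", "L_pre", "L_post", "fold_change",
                "category", "novel", "at_least_half", "disappeared", "viral_derived",
            ],
        )


def motif_density_table(pair: RepertoirePair, scheme: SpecificityScheme) -> MotifDensityTable:
    """Group a 9-mer repertoire by KIR motif and sum per-condition abundances.

    L_pre sums pre-infection abundances (= T_H of the input), L_post sums
    post-infection abundances of self and viral peptides (= T_HI + T_MV).
    """
    table = MotifDensityTable(scheme_name=scheme.name, cell_line_id=pair.cell_line_id)
    for rec in pair:
        key = extract_motif(rec.sequence, scheme)
        density = table.densities.setdefault(key, MotifDensity())
        density.l_pre += rec.abundance_uninfected
        density.l_post += rec.abundance_infected
        if rec.origin == ORIGIN_VIRAL:
            density.is_viral_derived = True
    return table


@dataclass(frozen=True)
class ChangeCategory:
    """Increase/equal/decrease taxonomy with nested flags.

    Invariants: disappeared => at_least_half => decrease; novel => increase.
    """

    top: str
    novel: bool = False
    at_least_half: bool = False
    disappeared: bool = False

    def __post_init__(self) -> None:
        if self.top not in ("increase", "equal", "decrease"):
            raise ValidationError(f"unknown top-level category {self.top!r}")
        if self.novel and self.top != "increase":
            raise ValidationError("novel implies increase")
        if self.at_least_half and self.top != "decrease":
            raise ValidationError("at_least_half implies decrease")
        if self.disappeared and not self.at_least_half:
            raise ValidationError("disappeared implies at_least_half")


def categorize_change(l_pre: float, l_post: float, tol: float = 1e-9) -> ChangeCategory:
    """Categorise the change in ligand density between conditions.

    ``equal`` holds when |L_post - L_pre| <= tol * max(L_pre, L_post) (a
    relative tolerance, since densities are sums of measured reals).
    Decreases are flagged ``at_least_half`` when the drop is >= 50% of
    L_pre, and ``disappeared`` when L_post is exactly zero. Increases from
    L_pre == 0 are ``novel``. A (0, 0) pair has no defined category.
    """
    if l_pre == 0.0 and l_post == 0.0:
        raise UndefinedCategoryError("both ligand densities are zero; category undefined")
    if abs(l_post - l_pre) <= tol * max(l_pre, l_post):
        return ChangeCategory(top="equal")
    if l_post < l_pre:
        at_least_half = (l_pre - l_post) / l_pre >= 0.5
        return ChangeCategory(
            top="decrease",
            at_least_half=at_least_half,
            disappeared=at_least_half and l_post == 0.0,
        )
    return ChangeCategory(top="increase", novel=l_pre == 0.0)


def percentual_change(l_pre: float, l_post: float) -> float:
    """Fold change (L_post - L_pre) / L_pre; +inf sentinel for novel motifs."""
    if l_pre == 0.0 and l_post == 0.0:
        raise UndefinedCategoryError("both ligand densities are zero; change undefined")
    if l_pre == 0.0:
        return math.inf
    return (l_post - l_pre) / l_pre


#: Reporting order for category counts/frequencies.
CATEGORY_KEYS = ("increase", "equal", "decrease", "novel", "decrease_ge50", "disappeared")


def tally_categories(categories: list[ChangeCategory]) -> dict[str, int]:
    counts = dict.fromkeys(CATEGORY_KEYS, 0)
    for cat in categories:
        counts[cat.top] += 1
        if cat.novel:
            counts["novel"] += 1
        if cat.at_least_half:
            counts["decrease_ge50"] += 1
        if cat.disappeared:
            counts["disappeared"] += 1
    return counts


@dataclass
class MotifChangeSummary:
    """Per-category motif counts and frequencies for one repertoire/scheme."""

    cell_line_id: str
    scheme_name: str
    n_motifs: int
    n_viral_motifs: int
    counts: dict[str, int]
    frequencies: dict[str, float]

    def to_row(self) -> dict:
        row = {
            "cell_line_id": self.cell_line_id,
            "scheme": self.scheme_name,
            "N_P7P8": self.n_motifs,
            "N_P7P8_MV": self.n_viral_motifs,
        }
        for key in CATEGORY_KEYS:
            row[f"n_{key}"] = self.counts[key]
            row[f"frac_{key}"] = self.frequencies[key]
        return row


def motif_change_summary(table: MotifDensityTable, tol: float = 1e-9) -> MotifChangeSummary:
    """Categorise every motif's density change and tabulate counts/frequencies."""
    if not table.densities:
        raise EmptyInputError("motif density table is empty")
    categories = [
        categorize_change(d.l_pre, d.l_post, tol=tol) for d in table.densities.values()
    ]
    counts = tally_categories(categories)
    n = len(categories)
    return MotifChangeSummary(
        cell_line_id=table.cell_line_id,
        scheme_name=table.scheme_name,
        n_motifs=n,
        n_viral_motifs=table.n_viral_motifs,
        counts=counts,
        frequencies={k: v / n for k, v in counts.items()},
    )
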