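"""Descriptive layer: abundance totals, per-allele fractions, disappearing peptides.

Three quantities summarise how a cell line's presented repertoire changes
after infection:

* total abundances T_H (self, uninfected), T_HI (self, infected) and
  T_MV (viral);
* the abundance-weighted fraction of each condition's total presented by
  each HLA allele, f_i = nHLA_i / T_* (with "NA" kept as its own category);
* the disappearing fraction |n_H \\ n_HI| / n_H — the proportion of unique
  pre-infection self peptides that are absent after infection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .exceptions import UndefinedFractionError
from .repertoire_io import ORIGIN_SELF, ORIGIN_VIRAL, RepertoirePair

#: Conditions over which totals and fractions are defined.
CONDITIONS = ("uninfected_self", "infected_self", "viral")


def _condition_terms(pair: RepertoirePair, condition: str) -> list[tuple[str, float]]:
    """(allele, abundance) contributions for one condition."""
    if condition == "uninfected_self":
        return [
            (r.hla_allele, r.abundance_uninfected)
            for r in pair.self_records()
        ]
    if condition == "infected_self":
        return [(r.hla_allele, r.abundance_infected) for r in pair.self_records()]
    if condition == "viral":
        return [(r.hla_allele, r.abundance_infected) for r in pair.viral_records()]
    raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")


def total_abundance(pair: RepertoirePair, condition: str) -> float:
    """Total abundance T_H, T_HI, or T_MV for the chosen condition."""
    return math.fsum(a for _, a in _condition_terms(pair, condition))


@dataclass
class HlaFractionTable:
    """Per-allele presentation fractions for one condition.

    ``fractions`` maps allele name (including the "NA" unassigned category)
    to f_i = summed abundance of that allele's peptides / total; fractions
    sum to 1.
    """

    condition: str
    total: float
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": self.condition, "hla_allele": a, "fraction": f}
            for a, f in sorted(self.fractions.items())
        ]
        return pd.DataFrame(rows, columns=["condition", "hla_allele", "fraction"])


def hla_fractions(pair: RepertoirePair, condition: str) -> HlaFractionTable:
    """Abundance-weighted per-allele fractions f_i = nHLA_i / T_*.

    Raises :class:`UndefinedFractionError` when the condition total is zero.
    """
    terms = _condition_terms(pair, condition)
    total = math.fsum(a for _, a in terms)
    if total <= 0:
        raise UndefinedFractionError(
            f"total abundance for condition {condition!r} is zero; fractions undefined"
        )
    sums: dict[str, float] = {}
    for allele, abundance in terms:
        if abundance > 0:
            sums[allele] = sums.get(allele, 0.0) + abundance
    return HlaFractionTable(
        condition=condition,
        total=total,
        fractions={a: s / total for a, s in sums.items()},
    )


def disappearing_fraction(pair: RepertoirePair) -> float:
    """Fraction of unique pre-infection self peptides absent after infection.

    "Absent" means infected-condition abundance exactly zero; the statistic
    depends only on presence/absence, never on abundance scale.
    """
    pre = [r for r in pair.self_records() if r.abundance_uninfected > 0]
    if not pre:
        raise UndefinedFractionError("no pre-infection self peptides; fraction undefined")
    gone = sum(1 for r in pre if r.abundance_infected == 0)
    return gone / len(pre)


def summary(pair: RepertoirePair) -> dict:
    """One-row summary of counts, totals, and the disappearing fraction."""
    n_H = pair.n_H
    return {
        "cell_line_id": pair.cell_line_id,
        "n_H": n_H,
        "n_HI": pair.n_HI,
        "n_MV": pair.n_MV,
        "T_H": pair.T_H,
        "T_HI": pair.T_HI,
        "T_MV": pair.T_MV,
        "disappearing_fraction": disappearing_fraction(pair) if n_H else float("nan"),
    }


def summary_frame(pair: RepertoirePair) -> pd.DataFrame:
    return pd.DataFrame([summary(pair)])


def fractions_frame(pair: RepertoirePair) -> pd.DataFrame:
    """Tidy (condition, allele, fraction) table over all nonempty conditions."""
    frames = []
    for condition in CONDITIONS:
        try:
            frames.append(hla_fractions(pair, condition).to_frame())
        except UndefinedFractionError:
            continue
    if not frames:
        return pd.DataFrame(columns=["condition", "hla_allele", "fraction"])
    return pd.concat(frames, ignore_index=True)


__all__ = [
    "CONDITIONS",
    "HlaFractionTable",
    "total_abundance",
    "hla_fractions",
    "disappearing_fraction",
    "summary",
    "summary_frame",
    "fractions_frame",
    "ORIGIN_SELF",
    "ORIGIN_VIRAL",
]
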