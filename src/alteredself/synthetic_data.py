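"""Synthetic paired pre/post-infection peptide repertoires.

The generator emulates the structure of HLA-I elution data from infected
B-cell lines: mostly self-derived 9-mers with a handful of viral peptides,
a large fraction (>50% in the defaults) of pre-infection peptides vanishing
after infection, some novel post-only self peptides, heavy-tailed
(log-normal) per-peptide abundances, and a persistence multiplier that lets
the cell-line-level total abundance rise or fall after infection.

Counts are exact by construction: round(frac_disappear * n_self_pre)
peptides disappear, round(frac_novel_self * n_self_pre) are post-only, and
n_viral viral records are emitted — so parameter-recovery tests can assert
equality, not approximation. With ``force_unique_motifs`` every peptide gets
a distinct P7/P8 pair (sampled without replacement from the 400 possible),
which makes the motif analysis recover frac_disappear exactly as the
disappeared-motif frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .descriptive_stats import disappearing_fraction
from .exceptions import CapacityError, ParameterError
from .repertoire_io import (
    AMINO_ACIDS,
    ORIGIN_SELF,
    ORIGIN_VIRAL,
    PeptideRecord,
    RepertoirePair,
)

#: Default allele pool (allele, sampling weight): dominated by alleles
#: carrying one of the four KIR epitopes, with small unrestricted and
#: unassigned components, mirroring real per-cell-line assignments.
DEFAULT_ALLELE_POOL: tuple[tuple[str, float], ...] = (
    ("A*03:01", 0.18),   # A3/11
    ("B*57:01", 0.16),   # Bw4
    ("B*27:05", 0.10),   # Bw4
    ("C*07:02", 0.18),   # C1
    ("C*04:01", 0.16),   # C2
    ("A*02:01", 0.12),   # no KIR epitope
    ("NA", 0.10),        # unassigned
)


@dataclass
class GeneratorParams:
    """Parameters of the synthetic repertoire generator.

    Abundances are log-normal (location/scale on the log scale, arbitrary
    MS-response units); persisting peptides' infected abundance is their
    uninfected abundance times an independent log-normal multiplier, whose
    location controls whether total abundance rises or falls.
    """

    n_self_pre: int = 800
    frac_disappear: float = 0.65
    frac_novel_self: float = 0.15
    n_viral: int = 8
    abundance_loc: float = math.log(1000.0)
    abundance_scale: float = 1.5
    persist_loc: float = 0.0
    persist_scale: float = 0.8
    allele_pool: tuple[tuple[str, float], ...] = DEFAULT_ALLELE_POOL
    length_distribution: dict[int, float] = field(default_factory=lambda: {9: 1.0})
    residue_weights: Optional[dict[str, float]] = None
    force_unique_motifs: bool = False
    seed: int = 0
    cell_line_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_self_pre < 0 or self.n_viral < 0:
            raise ParameterError("peptide counts must be nonnegative")
        for name in ("frac_disappear", "frac_novel_self"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.abundance_scale < 0 or self.persist_scale < 0:
            raise ParameterError("scale parameters must be nonnegative")
        if not self.length_distribution or any(
            l < 1 or w < 0 for l, w in self.length_distribution.items()
        ):
            raise ParameterError("length_distribution must map positive lengths to weights >= 0")

    @property
    def n_novel_self(self) -> int:
        return round(self.frac_novel_self * self.n_self_pre)

    @property
    def n_total(self) -> int:
        return self.n_self_pre + self.n_novel_self + self.n_viral


def _residue_distribution(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray]:
    aas = np.array(list(AMINO_ACIDS))
    if params.residue_weights is None:
        return aas, np.full(len(aas), 1.0 / len(aas))
    w = np.array([params.residue_weights.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if w.sum() <= 0:
        raise ParameterError("residue_weights must have positive total weight")
    return aas, w / w.sum()


def _draw_sequences(params: GeneratorParams, rng: np.random.Generator) -> list[str]:
    """Unique peptide sequences, with distinct P7/P8 pairs if forced."""
    total = params.n_total
    aas, aa_probs = _residue_distribution(params)
    lengths_pool = np.array(sorted(params.length_distribution), dtype=int)
    length_probs = np.array(
        [params.length_distribution[l] for l in lengths_pool], dtype=float
    )
    length_probs = length_probs / length_probs.sum()

    if params.force_unique_motifs:
        if total > 400:
            raise CapacityError(
                f"force_unique_motifs needs <= 400 peptides (20x20 P7/P8 pairs), got {total}"
            )
        if set(lengths_pool.tolist()) != {9}:
            raise ParameterError("force_unique_motifs requires all-9-mer length_distribution")
        pair_idx = rng.choice(400, size=total, replace=False)
        sequences = []
        for idx in pair_idx:
            chars = rng.choice(aas, size=9, p=aa_probs)
            chars[6] = AMINO_ACIDS[idx // 20]
            chars[7] = AMINO_ACIDS[idx % 20]
            sequences.append("".join(chars))
        return sequences  # distinct P7/P8 pairs imply distinct sequences

    seen: set[str] = set()
    sequences = []
    while len(sequences) < total:
        length = int(rng.choice(lengths_pool, p=length_probs))
        seq = "".join(rng.choice(aas, size=length, p=aa_probs))
        if seq not in seen:
            seen.add(seq)
            sequences.append(seq)
    return sequences


def generate_repertoire_pair(params: GeneratorParams) -> RepertoirePair:
    """Generate one cell line's paired repertoire; deterministic given the seed."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    sequences = _draw_sequences(params, rng)
    n_pre, n_novel, n_viral = params.n_self_pre, params.n_novel_self, params.n_viral

    alleles = [a for a, _ in params.allele_pool]
    weights = np.array([w for _, w in params.allele_pool], dtype=float)
    if weights.sum() <= 0:
        raise ParameterError("allele_pool must have positive total weight")
    assigned = rng.choice(alleles, size=params.n_total, p=weights / weights.sum())

    n_disappear = round(params.frac_disappear * n_pre)
    disappear_idx = set(rng.choice(n_pre, size=n_disappear, replace=False).tolist()) if n_pre else set()

    records: list[PeptideRecord] = []
    for i in range(n_pre):
        ab_u = float(rng.lognormal(params.abundance_loc, params.abundance_scale))
        if i in disappear_idx:
            ab_i = 0.0
        else:
            ab_i = ab_u * float(rng.lognormal(params.persist_loc, params.persist_scale))
        records.append(
            PeptideRecord(
                sequence=sequences[i],
                abundance_uninfected=ab_u,
                abundance_infected=ab_i,
                origin=ORIGIN_SELF,
                hla_allele=str(assigned[i]),
            )
        )
    for i in range(n_pre, n_pre + n_novel):
        records.append(
            PeptideRecord(
                sequence=sequences[i],
                abundance_uninfected=0.0,
                abundance_infected=float(rng.lognormal(params.abundance_loc, params.abundance_scale)),
                origin=ORIGIN_SELF,
                hla_allele=str(assigned[i]),
            )
        )
    for i in range(n_pre + n_novel, n_pre + n_novel + n_viral):
        records.append(
            PeptideRecord(
                sequence=sequences[i],
                abundance_uninfected=0.0,
                abundance_infected=float(rng.lognormal(params.abundance_loc, params.abundance_scale)),
                origin=ORIGIN_VIRAL,
                hla_allele=str(assigned[i]),
            )
        )
    return RepertoirePair.from_records(params.cell_line_id, records)


def generate_worst_best_fixtures(seed: int = 0) -> tuple[RepertoirePair, RepertoirePair]:
    """Two contrasting cell-line-like fixtures.

    *worst-case-like*: total abundance rises after infection while >= 50% of
    unique peptides disappear — the regime where only specific receptors see
    the loss. *best-case-like*: total abundance falls and >= 70% of peptides
    disappear, so even degenerate receptors detect a decrease. Both
    properties are asserted after generation (retrying over derived
    sub-seeds keeps the function total and deterministic).
    """
    worst = _generate_with_property(
        GeneratorParams(
            n_self_pre=500,
            frac_disappear=0.55,
            frac_novel_self=0.20,
            n_viral=10,
            persist_loc=math.log(4.0),
            persist_scale=0.5,
            cell_line_id="worst-case-like",
        ),
        seed,
        lambda pair: disappearing_fraction(pair) >= 0.5 and pair.T_HI + pair.T_MV > pair.T_H,
    )
    best = _generate_with_property(
        GeneratorParams(
            n_self_pre=500,
            frac_disappear=0.74,
            frac_novel_self=0.05,
            n_viral=5,
            persist_loc=math.log(0.5),
            persist_scale=0.4,
            cell_line_id="best-case-like",
        ),
        seed,
        lambda pair: disappearing_fraction(pair) >= 0.7 and pair.T_HI + pair.T_MV < pair.T_H,
    )
    return worst, best


def _generate_with_property(params: GeneratorParams, seed: int, check) -> RepertoirePair:
    for attempt in range(50):
        child = int(np.random.SeedSequence(seed, spawn_key=(attempt,)).generate_state(1)[0])
        params.seed = child
        pair = generate_repertoire_pair(params)
        if check(pair):
            return pair
    raise CapacityError(
        f"could not generate a repertoire with the requested properties for {params.cell_line_id}"
    )
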