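"""Probabilistic iKIR ligand-sampling model.

Instead of assuming a particular contact geometry, the sampling model treats
an inhibitory KIR as recognising each unique peptide independently with a
fixed probability p (its *specificity*; p = 1/400 is maximally specific,
p = 1 completely degenerate). One simulated receptor is a Bernoulli(p)
subset of the pool of n unique peptides; its ligand densities are

    L_U = sum of pre-infection abundances of the sampled peptides,
    L_I = sum of post-infection abundances (self + viral),

and the per-receptor signal is the fold change (L_I - L_U) / L_U. Repeating
the draw many times yields the distribution of changes a random iKIR of that
specificity would see, categorised with the same increase/equal/decrease
taxonomy as the motif analysis. Sweeping p maps specificity to the
probability of detecting a decrease, a halving, or a complete loss of
ligands.

The same Bernoulli coin is used for a peptide in both conditions, so L_U and
L_I are paired — each replicate is one receptor looking at the same cell
before and after infection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ParameterError
from .motif_analysis import (
    CATEGORY_KEYS,
    ChangeCategory,
    categorize_change,
    percentual_change,
    tally_categories,
)
from .repertoire_io import EpitopeMap, RepertoirePair, restrict_repertoire

#: Specificity grid used for the sweep (from maximal specificity 1/400 to
#: complete degeneracy), including 1/16 and the empirical ~0.2 estimate range.
DEFAULT_P_GRID = (0.0025, 0.01, 0.04, 0.0625, 0.125, 0.25, 0.5, 0.75, 1.0)


def fold_change(l_u: float, l_i: float) -> float:
    """Fold change (L_I - L_U)/L_U; +inf ("novel") when L_U == 0."""
    return percentual_change(l_u, l_i)


@dataclass
class SamplingConfig:
    """Parameters of one sampling run.

    ``pool_mode`` selects the peptide pool: ``"kir_epitopes"`` restricts to
    peptides presented by A3/11-, Bw4-, C1-, or C2-bearing alleles before
    sampling, ``"all"`` uses every peptide. ``empty_policy`` controls
    zero-ligand draws: ``"redraw"`` rejects and redraws them (a receptor
    with no ligands in either condition carries no signal), ``"skip"``
    drops them from the frequencies.
    """

    p: float
    replicates: int = 10_000
    seed: int = 0
    pool_mode: str = "all"
    empty_policy: str = "redraw"
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ParameterError(f"p must be in (0, 1], got {self.p}")
        if self.replicates < 1:
            raise ParameterError(f"replicates must be >= 1, got {self.replicates}")
        if self.pool_mode not in ("kir_epitopes", "all"):
            raise ParameterError(f"pool_mode must be 'kir_epitopes' or 'all', got {self.pool_mode!r}")
        if self.empty_policy not in ("redraw", "skip"):
            raise ParameterError(f"empty_policy must be 'redraw' or 'skip', got {self.empty_policy!r}")


def _pool_arrays(pair: RepertoirePair) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Deterministically ordered pool with per-condition abundance vectors."""
    records = sorted(pair.records.values(), key=lambda r: r.sequence)
    seqs = [r.sequence for r in records]
    a_u = np.array([r.abundance_uninfected for r in records], dtype=float)
    a_i = np.array([r.abundance_infected for r in records], dtype=float)
    return seqs, a_u, a_i


def sample_ligand_set(
    pair: RepertoirePair,
    p: float,
    rng: np.random.Generator,
    empty_policy: str = "redraw",
) -> tuple[str, ...]:
    """Draw one receptor's ligand set: each unique peptide kept with probability p.

    Under ``empty_policy="redraw"`` an empty draw is rejected and redrawn;
    under ``"skip"`` the empty tuple is returned as-is.
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"p must be in (0, 1], got {p}")
    if len(pair) == 0:
        raise EmptyInputError("cannot sample from an empty peptide pool")
    seqs, _, _ = _pool_arrays(pair)
    n = len(seqs)
    while True:
        mask = rng.random(n) < p
        if mask.any() or empty_policy == "skip":
            return tuple(s for s, keep in zip(seqs, mask) if keep)


def ligand_density(subset, pair: RepertoirePair, condition: str) -> float:
    """Summed abundance of a ligand subset in one condition.

    ``condition="uninfected"`` gives L_U, ``"infected"`` gives L_I (self
    post-infection plus viral contributions).
    """
    sub = pair.subset(subset)
    if condition == "uninfected":
        return math.fsum(r.abundance_uninfected for r in sub)
    if condition == "infected":
        return math.fsum(r.abundance_infected for r in sub)
    raise ParameterError(f"condition must be 'uninfected' or 'infected', got {condition!r}")


@dataclass
class SamplingResult:
    """Replicate-level densities, fold changes, and category frequencies."""

    p: float
    n_pool: int
    expected_ligands: float
    l_u: np.ndarray
    l_i: np.ndarray
    fold_changes: np.ndarray
    categories: list[ChangeCategory]
    counts: dict[str, int]
    frequencies: dict[str, float]
    n_redraws: int = 0
    n_skipped: int = 0
    seed: int = 0
    empty_policy: str = "redraw"
    cell_line_id: str = ""

    def summary_row(self) -> dict:
        row = {
            "cell_line_id": self.cell_line_id,
            "p": self.p,
            "n_pool": self.n_pool,
            "expected_ligands": self.expected_ligands,
            "replicates": len(self.categories),
            "n_redraws": self.n_redraws,
            "n_skipped": self.n_skipped,
        }
        for key in CATEGORY_KEYS:
            row[f"frac_{key}"] = self.frequencies[key]
        return row

    def replicates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.l_u)),
                "L_U": self.l_u,
                "L_I": self.l_i,
                "fold_change": self.fold_changes,
                "category": [c.top for c in self.categories],
                "novel": [c.novel for c in self.categories],
                "at_least_half": [c.at_least_half for c in self.categories],
                "disappeared": [c.disappeared for c in self.categories],
            }
        )


def _draw_masks(
    rng: np.random.Generator, replicates: int, n: int, p: float, empty_policy: str
) -> tuple[np.ndarray, int, np.ndarray]:
    """Bernoulli inclusion masks, redrawing or marking empty rows per policy."""
    mask = rng.random((replicates, n)) < p
    n_redraws = 0
    skipped = np.zeros(replicates, dtype=bool)
    empty_rows = np.flatnonzero(~mask.any(axis=1))
    if empty_policy == "skip":
        skipped[empty_rows] = True
        return mask, 0, skipped
    while empty_rows.size:
        n_redraws += empty_rows.size
        mask[empty_rows] = rng.random((empty_rows.size, n)) < p
        empty_rows = empty_rows[~mask[empty_rows].any(axis=1)]
    return mask, n_redraws, skipped


def run_sampling(
    pair: RepertoirePair,
    config: SamplingConfig,
    epitope_map: Optional[EpitopeMap] = None,
) -> SamplingResult:
    """Monte-Carlo estimate of a random iKIR's change-detection probabilities.

    Deterministic given (input, config.seed): replicate masks are drawn from
    ``numpy.random.default_rng(SeedSequence(seed))`` in a fixed order.
    """
    pool = restrict_repertoire(pair, epitope_map, mode=config.pool_mode)
    if len(pool) == 0:
        raise EmptyInputError("peptide pool is empty after pool_mode restriction")
    _, a_u, a_i = _pool_arrays(pool)
    n = len(a_u)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    mask, n_redraws, skipped = _draw_masks(rng, config.replicates, n, config.p, config.empty_policy)

    # correctly rounded (order-independent) sums so that e.g. the full pool
    # at p=1 reproduces the repertoire totals exactly
    l_u = np.array([math.fsum(a_u[row]) for row in mask])
    l_i = np.array([math.fsum(a_i[row]) for row in mask])
    keep = ~skipped
    fold = np.full(config.replicates, np.nan)
    nonzero = keep & (l_u > 0)
    fold[nonzero] = (l_i[nonzero] - l_u[nonzero]) / l_u[nonzero]
    fold[keep & (l_u == 0)] = np.inf  # novel: ligands only after infection

    categories = [
        categorize_change(float(u), float(i), tol=config.tol)
        for u, i, k in zip(l_u, l_i, keep)
        if k
    ]
    if not categories:
        raise EmptyInputError("all replicates were empty draws under policy='skip'")
    counts = tally_categories(categories)
    n_eff = len(categories)
    return SamplingResult(
        p=config.p,
        n_pool=n,
        expected_ligands=config.p * n,
        l_u=l_u[keep],
        l_i=l_i[keep],
        fold_changes=fold[keep],
        categories=categories,
        counts=counts,
        frequencies={k: v / n_eff for k, v in counts.items()},
        n_redraws=n_redraws,
        n_skipped=int(skipped.sum()),
        seed=config.seed,
        empty_policy=config.empty_policy,
        cell_line_id=pair.cell_line_id,
    )


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based child seed so sweep entries are order-independent."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(index,)).generate_state(1)[0])


def specificity_sweep(
    pair: RepertoirePair,
    p_values=DEFAULT_P_GRID,
    replicates: int = 10_000,
    seed: int = 0,
    pool_mode: str = "all",
    empty_policy: str = "redraw",
    tol: float = 1e-9,
    epitope_map: Optional[EpitopeMap] = None,
) -> pd.DataFrame:
    """Run the sampling model across a specificity grid.

    Each p gets an independent substream derived from the master seed by
    grid index, so adding or reordering grid values never perturbs another
    value's draws.
    """
    rows = []
    for i, p in enumerate(p_values):
        config = SamplingConfig(
            p=float(p),
            replicates=replicates,
            seed=derive_seed(seed, i),
            pool_mode=pool_mode,
            empty_policy=empty_policy,
            tol=tol,
        )
        rows.append(run_sampling(pair, config, epitope_map=epitope_map).summary_row())
    return pd.DataFrame(rows)


def enumerate_category_frequencies(
    pair: RepertoirePair,
    p: float,
    tol: float = 1e-9,
    pool_mode: str = "all",
    epitope_map: Optional[EpitopeMap] = None,
    max_pool: int = 20,
) -> dict[str, float]:
    """Exact category probabilities by exhaustive 2^n subset enumeration.

    Each subset S gets Bernoulli weight p^|S| (1-p)^(n-|S|); probabilities
    are conditioned on the draw being nonempty (the redraw policy's
    stationary distribution, and the skip policy's conditional one). Only
    feasible for small pools; guarded at ``max_pool`` peptides.
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError(f"p must be in (0, 1], got {p}")
    pool = restrict_repertoire(pair, epitope_map, mode=pool_mode)
    _, a_u, a_i = _pool_arrays(pool)
    n = len(a_u)
    if n == 0:
        raise EmptyInputError("peptide pool is empty")
    if n > max_pool:
        raise ParameterError(f"exhaustive enumeration limited to {max_pool} peptides, got {n}")
    weights = dict.fromkeys(CATEGORY_KEYS, 0.0)
    total = 0.0
    for bits in range(1, 2 ** n):
        members = [(bits >> j) & 1 for j in range(n)]
        k = sum(members)
        w = p ** k * (1.0 - p) ** (n - k)
        if w == 0.0:
            continue
        l_u = math.fsum(a for a, m in zip(a_u, members) if m)
        l_i = math.fsum(a for a, m in zip(a_i, members) if m)
        cat = categorize_change(l_u, l_i, tol=tol)
        weights[cat.top] += w
        if cat.novel:
            weights["novel"] += w
        if cat.at_least_half:
            weights["decrease_ge50"] += w
        if cat.disappeared:
            weights["disappeared"] += w
        total += w
    return {key: w / total for key, w in weights.items()}
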