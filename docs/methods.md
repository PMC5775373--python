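# Methods

## Data model

The unit of analysis is one cell line's paired peptide repertoire: the set
of unique peptides eluted from its HLA class I molecules before and after a
viral infection. Peptide identity is the exact amino-acid sequence over the
20-letter alphabet; a peptide detected in both conditions is a single record
carrying both abundances. This pairing is load-bearing: both the motif
analysis and the sampling model compare *the same* ligand set across
conditions, so the pre/post densities must refer to identical peptide sets.

Abundances are mass-spectrometry response estimates in arbitrary units;
only ratios and presence/absence are interpreted. Virus-derived peptides
cannot be presented before infection, so their pre-infection abundance is
forced to zero at load time. From the records the package derives the
unique-peptide counts n_H (self, pre), n_HI (self, post), n_MV (viral) and
the totals T_H, T_HI, T_MV. Totals and ligand densities are computed with
correctly rounded summation (`math.fsum`), which makes conservation
identities (e.g. the full pool at p = 1 reproducing the repertoire totals)
hold exactly rather than to within reduction-order noise.

HLA alleles map to the four mutually exclusive KIR epitope groups (A3/11,
Bw4, C1, C2) through a lookup table. The package ships a curated default of
common assignments from the KIR-ligand literature; it is a user-overridable
TSV, not an attempt at sequence-based epitope inference, because epitope
assignment is a property of allele identity that users may wish to pin to
their own typing. Unknown alleles and the "NA" (unassigned) sentinel map to
"none": they are excluded by the `kir_epitopes` restriction and included by
`mode="all"`.

## Descriptive statistics

Per-allele presentation fractions are abundance-weighted,
f_i = nHLA_i / T_*, where nHLA_i is the summed abundance of peptides
assigned to allele i in the chosen condition and T_* the condition total;
"NA" is kept as its own category so fractions sum to 1. The disappearing
fraction is (n_H \ n_HI)/n_H over unique self peptides, where "disappeared"
means post-infection abundance exactly zero — the elution table reports
presence/absence, so no detection threshold is imposed.

## Motif analysis

Only 9-mers enter the motif analysis; P7 and P8 (1-based) are the receptor
contact positions. A specificity scheme maps each residue to a class:
identity (400 ordered P7/P8 pairs, maximal specificity) or four
physico-chemical groups — non-polar {G,A,V,L,I,M,F,W,P}, polar
{S,T,C,Y,N,Q}, basic {K,R,H}, acidic {D,E} — giving 16 ordered pairs.
Motifs are *ordered* pairs: position matters at the contact interface, and
20×20 = 400 is only consistent with ordering.

Per motif, L_pre sums pre-infection abundances and L_post sums
post-infection abundances (self plus viral); summing over motifs conserves
T_H and T_HI + T_MV exactly, and the 16-class table is an exact coarsening
of the 400-class table. A motif with any viral contributor counts in
N_P7P8,MV (the permissive overlap reading; a mixed self+viral motif counts
once in each).

Density changes are categorised as:

* **equal** when |L_post − L_pre| ≤ tol · max(L_pre, L_post); tol defaults
  to 1e-9 (relative, because densities are sums of measured reals —
  bitwise float equality would make "equal" unreachable in practice);
* **decrease** when L_post < L_pre beyond tol, flagged *at_least_half* when
  the drop is ≥ 50% of L_pre (inclusive boundary: a drop of exactly half
  counts) and *disappeared* when L_post = 0;
* **increase** otherwise, flagged *novel* when L_pre = 0.

The per-motif "percentual change" is (L_post − L_pre)/L_pre, identical in
form to the sampling model's fold change; novel motifs carry a +inf
sentinel and are excluded from numeric histograms.

## Sampling model

The sampling model drops the contact-geometry assumption: a receptor
recognises each of the n unique pool peptides independently with
probability p, so a simulated receptor is a Bernoulli(p) subset with
expected size N = p·n (subset size is random; a fixed-size variant is
deliberately not the default, since "probability of a peptide being a
ligand" and N = p·n both describe independent Bernoulli sampling). One coin
per peptide covers both conditions, pairing L_U and L_I. The per-replicate
fold change (L_I − L_U)/L_U is categorised with the same taxonomy as the
motif analysis; frequencies over replicates (default 10,000) estimate the
probability that a random receptor of specificity p detects each kind of
change.

Empty draws (no ligands in either condition) carry no signal. The default
policy rejects and redraws them, logging the redraw count; a `skip` policy
(drop from frequencies) is available for sensitivity analysis. Both yield
the same conditional category distribution — conditioning on a nonempty
draw — which is also what the exhaustive-enumeration oracle computes.

Determinism: each run seeds `numpy.random.default_rng` from a
`SeedSequence`; sweep entries derive child seeds from the master seed by
grid index (`SeedSequence(seed, spawn_key=(i,))`), so sweeps are
order-independent and adding a grid value never perturbs another's draws.
Identical (input, config, seed) gives byte-identical outputs.

Validation: for pools of up to ~20 peptides, category probabilities are
computed exactly by enumerating all 2^n subsets with Bernoulli weights
p^|S|(1−p)^(n−|S|), conditioned on nonemptiness. The test suite checks
Monte-Carlo estimates against this oracle within three binomial standard
errors, including a three-peptide pool whose seven equally weighted
nonempty subsets give decrease 4/7, increase 2/7, equal 1/7 by hand. At
p = 1 every replicate is the full pool and the fold change equals
(T_HI + T_MV − T_H)/T_H exactly.

The default specificity grid is 0.0025 (=1/400), 0.01, 0.04, 0.0625
(=1/16), 0.125, 0.25, 0.5, 0.75, 1 — spanning maximal specificity to
complete degeneracy, with the 1/16 physico-chemical scale and the empirical
~0.2 estimate (13 KIR2DL2 binders among 59 peptides with unique P7/P8
pairs) inside the range.

## Receptor-diversity estimate

Given the fraction f of receptors detecting the event of interest (any
decrease, a halving, or a loss), the default estimate of the required
number of distinct iKIRs is ⌈1/f⌉ — the expected-count reading under which
a host carrying that many receptors expects at least one detector. It
reproduces the natural worked values (f = 0.15 → 7, f = 0.4 → 3,
f = 0.5 → 2). The explicit alternative returns the smallest k with
1 − (1−f)^k ≥ γ (default γ = 0.95), which dominates ⌈1/f⌉ as γ → 1; both
are reported side by side in the pipeline's diversity table because the
informal estimate and the confidence statement answer slightly different
questions.

## Synthetic data generator

The generator emulates the statistical structure of infected-cell-line
elution data, not its biochemistry:

* **Counts are exact by construction**: round(frac_disappear · n_self_pre)
  pre-infection self peptides get post abundance 0;
  round(frac_novel_self · n_self_pre) self peptides are post-only; n_viral
  viral records are emitted. Parameter-recovery tests can therefore assert
  equality.
* **Abundances** are log-normal (heavy-tailed, strictly positive,
  MS-response-like; default location log 1000, scale 1.5 — the units are
  arbitrary, only the tail behaviour matters). Persisting peptides' post
  abundance is the pre abundance times an independent log-normal
  multiplier; its location steers whether the cell-line total rises or
  falls after infection.
* **Defaults** mirror the empirical regime the package targets: 800 unique
  self 9-mers pre-infection, 65% disappearance (observed values run
  ~0.59–0.74), 15% novel self peptides, 8 viral peptides (~1%, "very few"),
  a persistence multiplier with median 1, and an allele pool dominated by
  epitope-bearing alleles with small unrestricted and "NA" components.
* **Sequences** are drawn i.i.d. per position from one categorical residue
  distribution (uniform by default; a single distribution shared across
  positions, since only the P7/P8 classes affect any downstream statistic).
  Uniqueness is enforced by rejection. Under `force_unique_motifs`, P7/P8
  pairs are sampled *without replacement* from the 400 possible (capacity
  error above 400 peptides), guaranteeing one motif per peptide so the
  motif analysis recovers frac_disappear exactly as the disappeared-motif
  frequency.
* **Fixtures**: `generate_worst_best_fixtures` builds a "worst-case-like"
  line (total abundance up, ≥ 50% of peptides gone — only specific
  receptors see the loss) and a "best-case-like" line (total abundance
  down, ≥ 70% gone); both properties are asserted after generation, with
  deterministic retry over derived sub-seeds.

What the generator does *not* emulate: MS detection noise and missed
identifications, HLA binding-motif constraints on sequence composition
(anchor residues), correlations between a peptide's abundance and its
probability of disappearing, and allele-specific abundance distributions.
Passing tests therefore demonstrate correctness of the computations and the
model's internal consistency, not biological conclusions about any real
cell line; analyses of real elution tables go through the same loader and
pipeline unchanged.

## Pipeline and problem sizes

The pipeline runs describe → motifs → sample → sweep → diversity from one
config with a single master seed (stage substreams derived by fixed
indices), writes every stage output as TSV with a self-describing comment
header carrying the config hash, and records per-output SHA-256 checksums
in `manifest.json`; reruns with identical configs are byte-identical. Any
stage error aborts with the stage name, and a partial manifest flags what
was written.

Default problem sizes — 10,000 replicates, the nine-value p grid, and
synthetic repertoires of a few hundred to a thousand peptides — keep a full
pipeline run and the acceptance script in the seconds range; enumeration
oracles are used at n ≤ 12 where 2^n is trivial.

## Known limitations

* The epitope map is a static allele lookup; alleles absent from it
  silently fall into "none" under restriction (by design, but worth
  checking when loading new genotypes).
* "Disappeared" is exact zero; data with imputed noise floors need
  thresholding upstream.
* The sampling model ignores receptor–ligand affinity and HLA-level
  specificity (a real iKIR binds its epitope group first, then the
  peptide), so its p conflates both layers; estimates of required receptor
  counts are therefore lower bounds in that respect.
* No statistical testing across cell lines is performed — the descriptive
  layer reports per-line quantities only.
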