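# Methods

## Array design

Universal PBM probe sets are defined by one property: the probe variable
regions jointly contain every DNA word of length *k* (k = 10 by default,
the "all 10-mer" design). We construct our own design rather than model
any vendor layout: a cyclic de Bruijn sequence of order *k* is generated
by an Eulerian traversal of the order-(k−1) de Bruijn graph (the `seed`
argument randomises the per-node edge order, selecting among valid
traversals), linearised by appending its first k−1 bases, and tiled into
probes of length 36 with consecutive probes overlapping by k−1 bases so
no word is lost at a junction. The final probe is padded by wraparound.
For k = 10 this yields 38,837 probes — the scale of an 8×60K array.
Primer/linker sequence present on physical arrays is not modelled; all
scoring is defined on variable regions only. Coordinates are 0-based,
half-open.

## Intensity model (synthetic data)

Probe intensity is simulated as

    I_i = (B + S · occ_i) · exp(ε_i),   ε_i ~ N(0, σ²)

where occ_i sums, over every window of both strands of probe *i*, the
product of ground-truth PWM probabilities (a Bernoulli-chain occupancy
surrogate). Multiplicative log-normal noise keeps intensities positive
and heteroskedastic, as fluorescence data are; with σ = 0 intensity is
strictly increasing in occupancy. Defaults: B = 200, S = 50,000
(dimensionless fluorescence units; chosen so that a single strong site
dominates background by ~2 orders of magnitude, comparable to the
dynamic range of scanned arrays), σ = 0.2, duplicate experiments per
protein at a nominal 300 nM. Ground-truth PWMs place probability 0.85 on
each consensus base (~1.2 bits/column, a realistic homeodomain
specificity); the reference-allele consensus is GGGTATCA and the variant
allele uses TGTGTCAT — a stand-in carrying the variant's GTGT core, not
a claim about the real variant motif. Random streams are keyed by
(seed, allele, replicate) so adding replicates never perturbs existing
ones.

What the generator does *not* emulate: spatial array artefacts, scanner
saturation, position-within-probe effects, sequence-composition bias,
and protein-concentration dependence. Passing tests therefore establish
the correctness of the statistics and the identifiability of motifs
under the stated noise model, not robustness to array-specific
systematics.

## E-scores

For word class *w* (a k-mer and its reverse complement), foreground =
probes containing either orientation (a probe counts once regardless of
match multiplicity), background = all other probes. The statistic keeps
the brightest ⌈n/2⌉ probes of each group, ranks them jointly with
average ranks for ties, and maps the Mann–Whitney U onto [−0.5, 0.5].
The ⌈n/2⌉ convention and average-rank ties are fixed here (and shared by
the brute-force oracle in the test suite) for determinism. Classes with
fewer than `min_foreground` = 20 foreground probes are reported as
undefined rather than given unstable extreme scores; on the all-10-mer
design a typical 8-mer class has ~34 foreground probes.

A consequence of the top-half convention worth knowing: when the
foreground size is odd, ⌈n/2⌉ retains slightly more than half of the
foreground, which pulls the null expectation slightly negative (about
−0.02 at n = 35, about −0.008 at n = 34 against a ~39k background). The
mean E-score over all classes of a signal-free experiment is therefore
≈ −0.013, not exactly 0; tests assert the honest bound.

Pattern E-scores are computed by the identical statistic with the
foreground defined by IUPAC-pattern matching on either strand; a literal
k-mer pattern reproduces the table value exactly. Both-strand matching
is applied to asymmetric patterns as well, for consistency with k-mer
handling. Computation uses packed integer k-mer codes and a sorted-rank
shortcut valid when intensities are pairwise distinct (always true under
the log-normal model); with ties it falls back to exact average-rank
scoring per class. The full 32,896-class table on 39k probes takes a few
seconds.

## Seed-and-Wobble

The seed is the defined class with maximal E-score (ties: higher median
foreground intensity, then lexicographic representative). For each
position of the seed ± `flank` (default 3) window and each base, the
foreground is the set of probes matching the seed with that one position
substituted/constrained (other non-seed positions free, full window
required to fit the probe); the weight is the median foreground
intensity minus the overall median, floored at 1e−3 of the overall
median so no column degenerates; columns are normalised to probabilities.
Weighting uses medians of raw intensities rather than E-scores because
medians are stable at the ~30-probe foreground sizes involved. The PWM
is reported in the canonical orientation whose argmax consensus string
is lexicographically smaller (ties: forward) so repeated runs and
replicate comparisons are orientation-stable.

Flank columns of the wobble window are near-uniform by construction
(the array sequence context around seed matches is essentially random),
so derived PWMs are trimmed to columns with ≥ 0.3 bits before
replicate-to-replicate comparison, as is standard when rendering logos;
untrimmed matrices are preserved in the results and in MEME output.

A single secondary motif is derived by removing every probe matching
the primary motif's trimmed IUPAC consensus and re-running seeding and
wobbling on the remainder (skipped when too few probes remain).

## Motif comparison

Two PWMs are aligned over all offsets and both orientations with at
least 4 overlapping columns; the reported alignment maximises the mean
per-column Pearson correlation of the probability 4-vectors. Two
constant (uniform) columns correlate 1 if equal; a constant column
against a varying one contributes 0. An exhaustive nested-loop oracle
cross-checks the implementation in the tests. Information content per
column is 2 + Σ p·log₂p bits; IUPAC consensus takes, per column, the
smallest degenerate code covering all bases with probability ≥ 0.25
(the argmax base if none reach it).

## EMSA quantification and affinity

Percent bound per lane is 100·bound/(bound+unbound). Titrations on the
standard ladder (1, 2, 4, 10, 20, 40, 100, 150, 200, 300 nM) are fitted
by bounded least squares to `f_max·P/(Kd+P)` with Kd ∈ [1e−3, 1e5] nM,
f_max ∈ (0, 100]; initialisation is deterministic (Kd₀ = concentration
nearest half of the maximum observed signal, f_max₀ = that maximum) and
the gradient tolerance is 1e−8. f_max is fitted rather than fixed at
100 because transfer losses make full saturation unobservable. A Hill
slope is available as an option; the default is the single-site
isotherm, the simplest model consistent with 1:1 binding. Standard
errors come from the Jacobian at the optimum. Affinity differences are
reported as Kd ratios of converged fits; simulated EMSA noise is
Gaussian on the percent scale, truncated to [0, 100], matching how
densitometry percentages behave.

## Problem sizes and determinism

Unit tests run on scaled-down designs (all-6-mer and all-8-mer arrays,
~140 and ~2,260 probes) chosen so each statistic still has redundant
foregrounds; full-scale checks (39k probes, 32,896 classes, 10 seeded
recovery runs) live in the acceptance suite and in
`scripts/acceptance.py`, which derives every random stream from a single
`--seed`. The whole pipeline is a pure function of its configuration:
identical configs produce bit-identical outputs, and every output file
is listed in the report manifest with a SHA-256 hash.

## Known limitations

- The occupancy surrogate ignores binding cooperativity, flanking-
  sequence effects and protein concentration; it is a test harness, not
  a biophysical claim.
- Gapped patterns are supported in pattern E-scores but gapped words are
  not enumerated in the all-k-mer table.
- Replicate-combined scores (median-of-medians intensities, Z-scores,
  cross-array normalisation) are out of scope; each experiment is scored
  independently.
- The variant-allele consensus used in simulations is a constructed
  GTGT-core stand-in; conclusions about the real proteins require real
  array data read through `read_probe_table`.
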