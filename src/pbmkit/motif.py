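"""Seed-and-Wobble motif derivation and PWM comparison.

Seed-and-Wobble derives a position weight matrix from a PBM in two steps:

* **Seed** — pick the 8-mer reverse-complement class with the highest
  E-score (ties broken by higher median foreground intensity, then by
  lexicographic representative).
* **Wobble** — for every position in a window extending ``flank`` bases on
  each side of the seed, and every base b, substitute b at that position
  (leaving all other non-seed positions unconstrained), collect the probes
  matching the perturbed word on either strand, and weight the base by the
  background-subtracted median intensity of that foreground. Each column is
  floored at a small epsilon and normalised to sum to 1.

A secondary motif is derived by masking every probe that matches the
primary motif's consensus and re-running seed selection and wobbling on
the remainder (one iteration).

``SeedAndWobble`` wraps the procedure as a model object: build it from a
``PbmExperiment``, call ``fit()`` and receive a ``MotifFitResults`` holding
the E-score table, primary and secondary PWMs, and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer import KmerClass, SequencePattern, all_escores, match_probes
from .sequences import BASES, IUPAC_CODES, SET_TO_IUPAC, decode, encode
from .simulate import PbmExperiment

__all__ = [
    "Pwm",
    "MotifComparison",
    "select_seed",
    "wobble_pwm",
    "information_content",
    "consensus",
    "compare_pwms",
    "SeedAndWobble",
    "MotifFitResults",
]

logger = logging.getLogger(__name__)


@dataclass
class Pwm:
    """Position weight matrix: (width, 4) base probabilities in A,C,G,T order."""

    matrix: np.ndarray
    source_seed_kmer: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.matrix.shape[0] < 1:
            raise ValueError("pwm matrix must be (width, 4) with width >= 1")
        if (self.matrix < 0).any():
            raise ValueError("pwm entries must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm columns must each sum to 1 within 1e-9")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.matrix[::-1, ::-1], source_seed_kmer=self.source_seed_kmer)

    def argmax_consensus(self) -> str:
        return decode(np.argmax(self.matrix, axis=1).astype(np.uint8))

    def canonical(self) -> "Pwm":
        """Orientation whose consensus string is lexicographically smaller."""
        rc = self.reverse_complement()
        return rc if rc.argmax_consensus() < self.argmax_consensus() else self

    def trim_low_ic(self, min_ic: float = 0.3) -> "Pwm":
        """Drop flanking columns with information content below ``min_ic`` bits."""
        ic = information_content(self)
        keep = np.flatnonzero(ic >= min_ic)
        if keep.size == 0:
            return self
        return Pwm(self.matrix[keep[0]:keep[-1] + 1], source_seed_kmer=self.source_seed_kmer)


@dataclass
class MotifComparison:
    """Best-scoring alignment of one PWM against another."""

    offset: int
    orientation: str  # "forward" | "reverse-complement"
    per_column_correlation: np.ndarray
    mean_correlation: float


def select_seed(table: pd.DataFrame) -> KmerClass:
    """Highest-E-score k-mer class of an E-score table.

    Ties go to the class with the higher median foreground intensity, then
    to the lexicographically smaller representative.
    """
    defined = table.dropna(subset=["escore"])
    if defined.empty:
        raise ValueError("no defined E-scores to seed from")
    best = defined.sort_values(
        by=["escore", "median_fg_intensity", "kmer"],
        ascending=[False, False, True],
        kind="stable",
    ).iloc[0]
    return KmerClass(best["kmer"])


class _WobbleMatcher:
    """Foregrounds for seed perturbations, via packed core-word codes.

    The seed core is contiguous, so "seed with one position substituted"
    (or "seed plus one constrained flank base") reduces to an equality test
    on precomputed w-mer codes plus at most one extra column comparison,
    OR-ed over every placement where the full seed±flank span fits.
    """

    def __init__(self, enc: np.ndarray, seed_codes: np.ndarray, flank: int):
        from .sequences import kmer_codes

        self.w = len(seed_codes)
        self.flank = flank
        self.span = self.w + 2 * flank
        self.L = enc.shape[1]
        enc_rc = (3 - enc)[:, ::-1]
        self.strands = [(enc, kmer_codes(enc, self.w)),
                        (enc_rc, kmer_codes(enc_rc, self.w))]
        self.weights_pow = 4 ** np.arange(self.w - 1, -1, -1, dtype=np.int64)
        self.seed_code = int(self.weights_pow @ seed_codes.astype(np.int64))
        self.seed_codes = seed_codes
        # core start positions t such that the whole span fits: s = t - flank
        self.core_starts = range(flank, self.L - self.span + flank + 1)

    def core_substituted(self, j: int, b: int) -> np.ndarray:
        """Probes containing the seed with core position j replaced by base b."""
        target = self.seed_code + (b - int(self.seed_codes[j])) * int(self.weights_pow[j])
        n = self.strands[0][0].shape[0]
        hit = np.zeros(n, dtype=bool)
        for _, codes in self.strands:
            for t in self.core_starts:
                hit |= codes[:, t] == target
        return hit

    def flank_constrained(self, p: int, b: int) -> np.ndarray:
        """Probes containing the intact seed with span position p equal to b.

        p is a span coordinate outside the core ([0, flank) or
        [flank + w, span)).
        """
        n = self.strands[0][0].shape[0]
        hit = np.zeros(n, dtype=bool)
        for enc, codes in self.strands:
            for t in self.core_starts:
                pos = t - self.flank + p
                hit |= (codes[:, t] == self.seed_code) & (enc[:, pos] == b)
        return hit


def wobble_pwm(
    experiment: PbmExperiment,
    seed: KmerClass | str,
    flank: int = 3,
    pseudo: float = 1e-3,
    probe_subset: np.ndarray | None = None,
) -> Pwm:
    """Derive a PWM around a seed k-mer by single-position substitution.

    For each window position p in [-flank, seed_length + flank) and base b,
    the foreground is the probes matching the seed with position p set to b
    (non-seed positions otherwise unconstrained); the weight is the median
    foreground intensity minus the overall median intensity, floored at
    pseudo * overall median. Columns are normalised and the PWM is returned
    in canonical orientation.

    ``probe_subset`` restricts the calculation to a boolean mask over
    probes (used for secondary-motif derivation).
    """
    rep = seed.representative if isinstance(seed, KmerClass) else str(seed)
    w = len(rep)
    span = w + 2 * flank
    L = len(experiment.sequences[0]) if len(experiment) else 0
    if span > L:
        raise ValueError(f"seed width {w} + 2*flank {flank} exceeds probe length {L}")

    enc = experiment.encoded()
    intensity = experiment.intensities
    if probe_subset is not None:
        enc = enc[probe_subset]
        intensity = intensity[probe_subset]
    baseline = float(np.median(intensity))
    eps = pseudo * baseline
    seed_codes = encode(rep)
    matcher = _WobbleMatcher(enc, seed_codes, flank)

    weights = np.zeros((span, 4))
    for p in range(span):
        in_core = flank <= p < flank + w
        for b in range(4):
            if in_core:
                fg = matcher.core_substituted(p - flank, b)
            else:
                fg = matcher.flank_constrained(p, b)
            if not fg.any():
                logger.warning(
                    "wobble: empty foreground at position %d base %s; using floor",
                    p - flank, BASES[b],
                )
                weights[p, b] = eps
            else:
                weights[p, b] = max(float(np.median(intensity[fg])) - baseline, eps)
    pwm = Pwm(weights / weights.sum(axis=1, keepdims=True), source_seed_kmer=rep)
    return pwm.canonical()


def information_content(pwm: Pwm | np.ndarray) -> np.ndarray:
    """Per-column information content in bits: 2 + sum_b p_b log2 p_b."""
    mat = pwm.matrix if isinstance(pwm, Pwm) else np.asarray(pwm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(mat > 0, mat * np.log2(mat), 0.0)
    return 2.0 + term.sum(axis=1)


def consensus(pwm: Pwm, iupac_threshold: float = 0.25) -> str:
    """IUPAC consensus: per column, the smallest code covering all bases with
    probability >= iupac_threshold (the most probable base if none reach it)."""
    mat = pwm.matrix if isinstance(pwm, Pwm) else np.asarray(pwm, dtype=float)
    out = []
    for col in mat:
        bases = frozenset(BASES[i] for i in range(4) if col[i] >= iupac_threshold)
        if not bases:
            bases = frozenset({BASES[int(np.argmax(col))]})
        out.append(SET_TO_IUPAC[bases])
    return "".join(out)


def _column_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of paired probability columns.

    Two identical constant columns correlate 1; a constant against a
    varying column correlates 0 (no preference to agree with).
    """
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac ** 2).sum(axis=1))
    nb = np.sqrt((bc ** 2).sum(axis=1))
    out = np.zeros(a.shape[0])
    both = (na > 1e-12) & (nb > 1e-12)
    out[both] = (ac[both] * bc[both]).sum(axis=1) / (na[both] * nb[both])
    const = (na <= 1e-12) & (nb <= 1e-12)
    if const.any():
        equal = np.all(np.abs(a[const] - b[const]) < 1e-9, axis=1)
        out[const] = np.where(equal, 1.0, 0.0)
    return out


def compare_pwms(a: Pwm, b: Pwm, min_overlap: int = 4) -> MotifComparison:
    """Best alignment of b against a over all offsets and both orientations.

    The alignment maximising the mean per-column Pearson correlation of the
    probability vectors, requiring at least ``min_overlap`` overlapping
    columns. Offset is the position of b's first column relative to a's.
    """
    wa, wb = a.width, b.width
    if min(wa, wb) < min_overlap:
        raise ValueError(
            f"PWMs of widths {wa} and {wb} cannot overlap by {min_overlap} columns"
        )
    best: MotifComparison | None = None
    for orientation, bmat in (("forward", b.matrix),
                              ("reverse-complement", b.matrix[::-1, ::-1])):
        for offset in range(-(wb - min_overlap), wa - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(wa, offset + wb)
            if hi_a - lo_a < min_overlap:
                continue
            cols_a = a.matrix[lo_a:hi_a]
            cols_b = bmat[lo_a - offset:hi_a - offset]
            corr = _column_correlations(cols_a, cols_b)
            mean = float(corr.mean())
            if best is None or mean > best.mean_correlation + 1e-12:
                best = MotifComparison(offset, orientation, corr, mean)
    assert best is not None
    return best


@dataclass
class MotifFitResults:
    """Seed-and-Wobble output: E-score table, motifs, and diagnostics."""

    experiment: PbmExperiment
    escore_table: pd.DataFrame
    primary_seed: KmerClass
    primary: Pwm
    secondary_seed: KmerClass | None = None
    secondary: Pwm | None = None

    @property
    def primary_trimmed(self) -> Pwm:
        return self.primary.trim_low_ic()

    def motifs(self) -> dict[str, Pwm]:
        out = {"primary": self.primary}
        if self.secondary is not None:
            out["secondary"] = self.secondary
        return out

    def summary(self) -> str:
        lines = [
            f"Seed-and-Wobble fit: {self.experiment.protein_label} "
            f"(replicate {self.experiment.replicate_id})",
            f"  probes: {len(self.experiment)}",
            f"  defined 8-mer classes: {int(self.escore_table['escore'].notna().sum())}"
            f" / {len(self.escore_table)}",
            f"  max E-score: {self.escore_table['escore'].max():.4f}",
        ]
        for name, seed, pwm in (
            ("primary", self.primary_seed, self.primary),
            ("secondary", self.secondary_seed, self.secondary),
        ):
            if pwm is None:
                continue
            ic = information_content(pwm)
            lines += [
                f"  {name} seed 8-mer: {seed}",
                f"  {name} consensus: {consensus(pwm)} "
                f"({pwm.width} columns, {ic.sum():.2f} bits total)",
            ]
        return "\n".join(lines)

    def plot_logo(self, which: str = "primary", ax=None):
        """Information-content profile with per-column consensus labels.

        Requires matplotlib (optional dependency).
        """
        import matplotlib.pyplot as plt

        pwm = self.motifs()[which]
        ic = information_content(pwm)
        if ax is None:
            _, ax = plt.subplots(figsize=(0.5 * pwm.width + 1, 2.5))
        ax.bar(np.arange(pwm.width), ic, color="steelblue")
        for i, ch in enumerate(consensus(pwm)):
            ax.text(i, ic[i] + 0.05, ch, ha="center", fontsize=9)
        ax.set_ylim(0, 2.1)
        ax.set_ylabel("bits")
        ax.set_xlabel("position")
        ax.set_title(f"{self.experiment.protein_label} {which} motif")
        return ax


class SeedAndWobble:
    """Seed-and-Wobble motif model for one PBM experiment.

    Parameters
    ----------
    experiment : PbmExperiment
    k : int
        Word length for the E-score table (8 for universal arrays).
    flank : int
        Bases added on each side of the seed in the wobble step.
    min_foreground : int
        Classes with fewer foreground probes are left undefined.
    pseudo : float
        Weight floor as a fraction of the overall median intensity.
    """

    def __init__(self, experiment: PbmExperiment, k: int = 8, flank: int = 3,
                 min_foreground: int = 20, pseudo: float = 1e-3):
        self.experiment = experiment
        self.k = k
        self.flank = flank
        self.min_foreground = min_foreground
        self.pseudo = pseudo

    def fit(self, secondary: bool = True,
            escore_table: pd.DataFrame | None = None) -> MotifFitResults:
        """Derive primary (and optionally secondary) motifs.

        A precomputed E-score table for this experiment may be passed to
        avoid recomputation.
        """
        exp = self.experiment
        table = escore_table if escore_table is not None else all_escores(
            exp, k=self.k, min_foreground=self.min_foreground
        )
        seed1 = select_seed(table)
        primary = wobble_pwm(exp, seed1, flank=self.flank, pseudo=self.pseudo)
        sec_seed = sec_pwm = None
        if secondary:
            mask_pat = SequencePattern(consensus(primary.trim_low_ic()))
            matched = match_probes(exp, mask_pat)
            keep = np.ones(len(exp), dtype=bool)
            keep[matched] = False
            if keep.sum() >= self.min_foreground * 2:
                sub = PbmExperiment(
                    [exp.probes[i] for i in np.flatnonzero(keep)],
                    protein_label=exp.protein_label,
                    replicate_id=exp.replicate_id,
                    concentration_nM=exp.concentration_nM,
                )
                sub_table = all_escores(sub, k=self.k,
                                        min_foreground=self.min_foreground)
                try:
                    sec_seed = select_seed(sub_table)
                    sec_pwm = wobble_pwm(sub, sec_seed, flank=self.flank,
                                         pseudo=self.pseudo)
                except ValueError:
                    sec_seed = sec_pwm = None
        return MotifFitResults(exp, table, seed1, primary, sec_seed, sec_pwm)
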