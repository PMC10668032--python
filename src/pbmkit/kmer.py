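"""8-mer and pattern E-scores.

The E-score is a rank-based enrichment statistic in [-0.5, 0.5] comparing
intensities of probes containing a word (foreground) against all other
probes (background). It is a modified Wilcoxon-Mann-Whitney statistic
restricted to the most informative half of each group: with F½ the
ceil(|F|/2) brightest foreground probes and B½ the ceil(|B|/2) brightest
background probes, rank F½ ∪ B½ jointly (ties share average ranks) and
return U / (|F½| |B½|) - 0.5, where U counts foreground-over-background
wins with ties counting one half. Being a rank statistic, it is invariant
under any strictly increasing transform of the intensities and so robust
to array-to-array scale differences.

A "pattern E-score" is the same statistic with the foreground defined as
the probes matching an arbitrary (possibly degenerate IUPAC) sequence
pattern on either strand, instead of the probes containing a given 8-mer.

k-mers are collapsed into reverse-complement classes (double-stranded
words); a probe is in a class's foreground if its variable region contains
the word or its reverse complement, counted once regardless of match
multiplicity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .sequences import (
    code_to_kmer,
    iupac_to_regex,
    kmer_codes,
    kmer_to_code,
    reverse_complement,
    revcomp_code_table,
)
from .simulate import PbmExperiment

__all__ = [
    "KmerClass",
    "SequencePattern",
    "UndefinedScoreError",
    "enumerate_kmer_classes",
    "match_probes",
    "escore",
    "all_escores",
    "pattern_escore",
]


class UndefinedScoreError(ValueError):
    """E-score undefined: empty foreground or empty background."""


@dataclass(frozen=True)
class KmerClass:
    """A k-mer and its reverse complement treated as one double-stranded word.

    The representative is the lexicographically smaller of the pair.
    """

    representative: str

    def __post_init__(self) -> None:
        rc = reverse_complement(self.representative)
        if rc < self.representative:
            object.__setattr__(self, "representative", rc)

    @property
    def is_palindromic(self) -> bool:
        return self.representative == reverse_complement(self.representative)

    @property
    def k(self) -> int:
        return len(self.representative)

    def __str__(self) -> str:
        return self.representative


@dataclass(frozen=True)
class SequencePattern:
    """A degenerate sequence pattern over the 15 IUPAC nucleotide codes."""

    iupac: str

    def __post_init__(self) -> None:
        iupac_to_regex(self.iupac)  # validates
        if not self.iupac:
            raise ValueError("pattern must be non-empty")

    def __len__(self) -> int:
        return len(self.iupac)

    def regex(self) -> re.Pattern:
        return re.compile(iupac_to_regex(self.iupac))


def enumerate_kmer_classes(k: int) -> list[KmerClass]:
    """All reverse-complement k-mer classes, in representative order.

    Cardinality is (4**k + 4**(k/2)) / 2 for even k and 4**k / 2 for odd k
    (odd-length DNA words cannot be palindromic).
    """
    if not 1 <= k <= 10:
        raise ValueError(f"k must be in [1, 10], got {k}")
    codes = np.arange(4 ** k, dtype=np.int64)
    rc = revcomp_code_table(k)
    reps = np.unique(np.minimum(codes, rc))
    return [KmerClass(code_to_kmer(int(c), k)) for c in reps]


def match_probes(experiment: PbmExperiment, pattern: SequencePattern | str) -> np.ndarray:
    """Indices of probes matching the pattern on either strand.

    A probe matches if its variable region contains >= 1 match to the
    pattern on the forward strand, or its reverse complement does.
    """
    if isinstance(pattern, str):
        pattern = SequencePattern(pattern)
    seqs = experiment.sequences
    if seqs and len(pattern) > len(seqs[0]):
        raise ValueError(
            f"pattern length {len(pattern)} exceeds probe length {len(seqs[0])}"
        )
    fwd = pattern.regex()
    rev = re.compile(iupac_to_regex(reverse_complement(pattern.iupac)))
    hits = [
        i for i, s in enumerate(seqs)
        if fwd.search(s) is not None or rev.search(s) is not None
    ]
    return np.asarray(hits, dtype=np.int64)


def escore(fg_intensities, bg_intensities) -> float:
    """E-score from foreground and background intensity vectors.

    Ranks the brightest half of each group jointly (average ranks for ties)
    and rescales the Mann-Whitney U statistic to [-0.5, 0.5]: +0.5 means
    every retained foreground probe outranks every retained background
    probe, 0 means no enrichment.
    """
    fg = np.asarray(fg_intensities, dtype=float)
    bg = np.asarray(bg_intensities, dtype=float)
    if fg.size == 0 or bg.size == 0:
        raise UndefinedScoreError("foreground and background must both be non-empty")
    nfh = math.ceil(fg.size / 2)
    nbh = math.ceil(bg.size / 2)
    fgh = np.sort(fg)[::-1][:nfh]
    bgh = np.sort(bg)[::-1][:nbh]
    ranks = rankdata(np.concatenate([fgh, bgh]))
    u = ranks[:nfh].sum() - nfh * (nfh + 1) / 2.0
    return float(u / (nfh * nbh) - 0.5)


def _escores_fast(positions_by_class, n: int):
    """E-scores from per-class foreground positions in the global intensity order.

    ``positions_by_class`` yields, per class, the sorted 0-based positions of
    its foreground probes in the descending-intensity order of all n probes.
    Valid only when intensities are pairwise distinct (no ties): then the
    foreground-over-background win count needs no explicit background scan —
    a foreground probe at global position p with i brighter foreground
    probes has exactly p - i brighter background probes.
    """
    for pos in positions_by_class:
        nf = pos.size
        nb = n - nf
        if nf == 0 or nb == 0:
            yield float("nan")
            continue
        nfh = (nf + 1) // 2
        nbh = (nb + 1) // 2
        i = np.arange(nfh)
        bg_before = pos[:nfh] - i  # brighter background probes, per fg½ member
        wins = np.clip(nbh - bg_before, 0, nbh)
        yield float(wins.sum() / (nfh * nbh) - 0.5)


def _class_index(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert the probe matrix into (class codes, per-class probe lists).

    Returns (reps, starts, probe_ids) where probe_ids[starts[c]:starts[c+1]]
    are the distinct probes containing class reps[c] on either strand.
    """
    n = enc.shape[0]
    codes = kmer_codes(enc, k)
    rc = revcomp_code_table(k)
    canon = np.minimum(codes, rc[codes])
    probe = np.repeat(np.arange(n, dtype=np.int64), canon.shape[1])
    pair = canon.ravel() * n + probe  # unique (class, probe) pairs, sorted
    pair = np.unique(pair)
    cls = pair // n
    probe_ids = pair % n
    reps, starts = np.unique(cls, return_index=True)
    starts = np.append(starts, cls.size)
    return reps, starts, probe_ids


def all_escores(
    experiment: PbmExperiment,
    k: int = 8,
    min_foreground: int = 20,
) -> pd.DataFrame:
    """E-score table over every reverse-complement k-mer class.

    Returns a DataFrame with one row per class: ``kmer`` (representative),
    ``escore``, ``n_foreground``, ``median_fg_intensity``. Classes whose
    foreground is smaller than ``min_foreground`` (or empty/background-empty)
    get escore NaN — undefined rather than unstable.
    """
    if not 1 <= k <= 10:
        raise ValueError(f"k must be in [1, 10], got {k}")
    enc = experiment.encoded()
    n = len(experiment)
    intensity = experiment.intensities
    order = np.argsort(-intensity, kind="stable")
    pos_of = np.empty(n, dtype=np.int64)
    pos_of[order] = np.arange(n)

    reps_present, starts, probe_ids = _class_index(enc, k)
    present = {int(c): i for i, c in enumerate(reps_present)}
    distinct = np.unique(intensity).size == n

    classes = enumerate_kmer_classes(k)
    rows_kmer, rows_nf, rows_med, fg_lists = [], [], [], []
    for cls in classes:
        code = kmer_to_code(cls.representative)
        idx = present.get(code)
        if idx is None:
            fg = np.empty(0, dtype=np.int64)
        else:
            fg = probe_ids[starts[idx]:starts[idx + 1]]
        rows_kmer.append(cls.representative)
        rows_nf.append(fg.size)
        rows_med.append(float(np.median(intensity[fg])) if fg.size else float("nan"))
        fg_lists.append(fg)

    scores = np.full(len(classes), np.nan)
    if distinct:
        gen = _escores_fast((np.sort(pos_of[fg]) for fg in fg_lists), n)
        for i, s in enumerate(gen):
            scores[i] = s
    else:
        mask = np.ones(n, dtype=bool)
        for i, fg in enumerate(fg_lists):
            if fg.size == 0 or fg.size == n:
                continue
            mask[fg] = False
            scores[i] = escore(intensity[fg], intensity[mask])
            mask[fg] = True
    scores[np.asarray(rows_nf) < min_foreground] = np.nan

    return pd.DataFrame(
        {
            "kmer": rows_kmer,
            "escore": scores,
            "n_foreground": rows_nf,
            "median_fg_intensity": rows_med,
        }
    )


def pattern_escore(experiment: PbmExperiment, pattern: SequencePattern | str) -> float:
    """E-score with foreground = probes matching an IUPAC pattern (either strand).

    Identical to the 8-mer E-score when the pattern is a literal 8-mer: same
    statistic, same inputs, only the foreground definition generalises.
    """
    if isinstance(pattern, str):
        pattern = SequencePattern(pattern)
    fg_idx = match_probes(experiment, pattern)
    n = len(experiment)
    if fg_idx.size == 0 or fg_idx.size == n:
        raise UndefinedScoreError(
            f"pattern {pattern.iupac!r} matches {fg_idx.size} of {n} probes; "
            "foreground and background must both be non-empty"
        )
    mask = np.zeros(n, dtype=bool)
    mask[fg_idx] = True
    intensity = experiment.intensities
    return escore(intensity[mask], intensity[~mask])
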