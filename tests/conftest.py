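"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive each statistic from its definition by
direct enumeration, sharing no code with the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from pbmkit import ArrayDesign, Probe, design_array


def brute_escore(fg, bg) -> float:
    """E-score by exhaustive pair enumeration over the two top halves."""
    fg = sorted(fg, reverse=True)
    bg = sorted(bg, reverse=True)
    fgh = fg[: math.ceil(len(fg) / 2)]
    bgh = bg[: math.ceil(len(bg) / 2)]
    u = 0.0
    for f in fgh:
        for b in bgh:
            if f > b:
                u += 1.0
            elif f == b:
                u += 0.5
    return u / (len(fgh) * len(bgh)) - 0.5


def brute_occupancy(seq: str, pwm: np.ndarray) -> float:
    """Occupancy by direct window enumeration on both strands."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    rc = "".join(comp[c] for c in reversed(seq))
    w = pwm.shape[0]
    total = 0.0
    for strand in (seq, rc):
        for s in range(len(strand) - w + 1):
            p = 1.0
            for j in range(w):
                p *= pwm[j, idx[strand[s + j]]]
            total += p
    return total


def brute_pwm_alignment(a: np.ndarray, b: np.ndarray, min_overlap: int = 4):
    """Best mean per-column Pearson alignment by direct nested-loop search."""

    def col_corr(x, y):
        xs, ys = x - x.mean(), y - y.mean()
        nx, ny = np.sqrt((xs ** 2).sum()), np.sqrt((ys ** 2).sum())
        if nx < 1e-12 and ny < 1e-12:
            return 1.0 if np.allclose(x, y, atol=1e-9) else 0.0
        if nx < 1e-12 or ny < 1e-12:
            return 0.0
        return float((xs * ys).sum() / (nx * ny))

    best = -np.inf
    wa, wb = a.shape[0], b.shape[0]
    for bmat in (b, b[::-1, ::-1]):
        for offset in range(-wb + 1, wa):
            cols = [
                (a[i], bmat[i - offset])
                for i in range(max(0, offset), min(wa, offset + wb))
            ]
            if len(cols) < min_overlap:
                continue
            mean = float(np.mean([col_corr(x, y) for x, y in cols]))
            best = max(best, mean)
    return best


def random_experiment(rng: np.random.Generator, n_probes: int, length: int = 12,
                      integer_intensities: bool = False):
    """A random PbmExperiment, optionally with tie-prone integer intensities."""
    from pbmkit import PbmExperiment

    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, size=length)) for _ in range(n_probes)]
    if integer_intensities:
        inten = rng.integers(1, 8, size=n_probes).astype(float)
    else:
        inten = rng.lognormal(5.0, 1.0, size=n_probes)
    probes = [Probe(f"p{i:03d}", s, float(x)) for i, (s, x) in enumerate(zip(seqs, inten))]
    return PbmExperiment(probes, protein_label="rand", replicate_id=1)


@pytest.fixture(scope="session")
def full_design() -> ArrayDesign:
    """The all-10-mer design at production scale (~39k probes of 36 nt)."""
    return design_array(k=10, probe_length=36, seed=0)


@pytest.fixture(scope="session")
def small_design() -> ArrayDesign:
    """All-8-mer design (~2.4k probes of 36 nt): full pipeline at test scale."""
    return design_array(k=8, probe_length=36, seed=0)


@pytest.fixture(scope="session")
def tiny_design() -> ArrayDesign:
    """All-6-mer design (~140 probes): cheap enough for exhaustive checks."""
    return design_array(k=6, probe_length=36, seed=0)
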