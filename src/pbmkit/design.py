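"""Universal all-k-mer array design.

Universal protein-binding microarrays tile a de Bruijn sequence — a cyclic
string over {A,C,G,T} containing every length-k word exactly once — across
probes so that the probe set jointly covers all 4**k k-mers. The default
design (k=10, 36-nt variable regions, consecutive probes overlapping by
k-1 = 9 bases) yields ~39,000 probes, the scale of an 8x60K universal
array. Only the variable region is modelled; primer/linker sequence is out
of scope because all scoring is defined on variable regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sequences import BASES, encode, kmer_codes, revcomp_code_table

__all__ = ["Probe", "ArrayDesign", "debruijn_sequence", "design_array"]


@dataclass
class Probe:
    """One array spot: identifier, variable-region sequence, optional intensity."""

    probe_id: str
    sequence: str
    intensity: float | None = None

    def __post_init__(self) -> None:
        if set(self.sequence) - set(BASES):
            raise ValueError(f"probe {self.probe_id}: non-ACGT sequence")
        if self.intensity is not None and not (self.intensity >= 0):
            raise ValueError(f"probe {self.probe_id}: negative intensity")


@dataclass
class ArrayDesign:
    """An ordered probe set with complete k-mer coverage on the forward strand."""

    probes: list[Probe]
    coverage_k: int = 10
    probe_length: int = 36
    overlap: int | None = None

    def __post_init__(self) -> None:
        if self.overlap is None:
            self.overlap = self.coverage_k - 1
        for p in self.probes:
            if len(p.sequence) != self.probe_length:
                raise ValueError(
                    f"probe {p.probe_id} length {len(p.sequence)} != {self.probe_length}"
                )

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    def covered_kmers(self, k: int | None = None) -> set[int]:
        """Packed codes of all k-mers present on the forward strand of any probe."""
        k = self.coverage_k if k is None else k
        from .sequences import encode_matrix

        codes = kmer_codes(encode_matrix(self.sequences), k)
        return set(np.unique(codes).tolist())


def debruijn_sequence(k: int, seed: int = 0) -> str:
    """Linearized de Bruijn sequence of order k over {A,C,G,T}.

    Returns a string of length 4**k + (k-1) in which every k-mer occurs
    exactly once (the cyclic sequence with its first k-1 bases appended).
    The seed selects among valid Eulerian traversals of the order-(k-1)
    de Bruijn graph; every seed yields a valid sequence, and the output is
    a pure function of (k, seed).
    """
    if not 1 <= k <= 12:
        raise ValueError(f"k must be in [1, 12], got {k}")
    m = 4 ** (k - 1)  # nodes = (k-1)-mers
    rng = np.random.default_rng(seed)
    # random edge (outgoing base) order per node makes the traversal seed-dependent
    perms = rng.permuted(np.tile(np.arange(4, dtype=np.int8), (m, 1)), axis=1)
    used = np.zeros(m, dtype=np.int8)
    mask = m - 1 if k > 1 else 0

    # iterative Hierholzer: stack of (node, label of edge that led here)
    stack: list[tuple[int, int]] = [(0, -1)]
    labels: list[int] = []
    while stack:
        v, lab = stack[-1]
        if used[v] < 4:
            b = int(perms[v, used[v]])
            used[v] += 1
            nxt = ((v << 2) | b) & mask if k > 1 else 0
            stack.append((nxt, b))
        else:
            stack.pop()
            if lab >= 0:
                labels.append(lab)
    labels.reverse()  # Eulerian circuit edge labels = cyclic sequence, length 4**k
    cyc = "".join(BASES[b] for b in labels)
    return cyc + cyc[: k - 1]


def min_probe_count(k: int, probe_length: int, overlap: int | None = None) -> int:
    """Lower bound on probes needed to tile the linearized sequence."""
    if overlap is None:
        overlap = k - 1
    return math.ceil((4 ** k + k - 1 - probe_length) / (probe_length - overlap)) + 1


def design_array(k: int = 10, probe_length: int = 36, seed: int = 0) -> ArrayDesign:
    """Chop a de Bruijn sequence into overlapping probes covering all k-mers.

    Consecutive probes overlap by exactly k-1 bases so no k-mer is lost at a
    junction; the final probe is padded by wraparound of the cyclic sequence
    to the full probe length. Probe ids are "p000001", ... in genomic order.
    """
    if probe_length <= k:
        raise ValueError(f"probe_length ({probe_length}) must exceed k ({k})")
    if probe_length > 100:
        raise ValueError("probe_length must be <= 100")
    lin = debruijn_sequence(k, seed)
    step = probe_length - (k - 1)
    n = max(math.ceil((len(lin) - probe_length) / step) + 1, 1)
    # wraparound pad so the last probe reaches full length
    padded = lin + lin[k - 1: k - 1 + probe_length]
    probes = [
        Probe(f"p{i + 1:06d}", padded[i * step: i * step + probe_length])
        for i in range(n)
    ]
    return ArrayDesign(probes, coverage_k=k, probe_length=probe_length)
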