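"""Synthetic PBM intensities and EMSA titrations with known ground truth.

The PBM simulator replaces the wet assay: probe intensity follows a PWM
occupancy model, intensity_i = (B + S * occ_i) * exp(eps_i) with
eps_i ~ Normal(0, sigma^2), where occ_i sums Bernoulli-chain match
probabilities of the ground-truth PWM over every window of both strands of
the probe's variable region. Multiplicative log-normal noise keeps
intensities positive and heteroskedastic, like fluorescence data.
Experiments are produced in duplicate per protein at a nominal 300 nM,
mirroring standard universal-PBM practice.

Random streams are keyed by (rng_seed, allele, replicate_id) so adding a
replicate never perturbs an existing one.

EMSA titrations are simulated from a 1:1 Langmuir isotherm,
percent bound = 100*P/(Kd+P), with Gaussian noise on the percent scale
truncated to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import ArrayDesign, Probe
from .sequences import encode, encode_matrix

__all__ = [
    "GroundTruth",
    "PbmExperiment",
    "occupancy",
    "simulate_pbm",
    "simulate_two_allele",
    "simulate_emsa_curve",
    "consensus_pwm",
]

#: protein concentration ladder of a standard chemiluminescent EMSA titration (nM)
DEFAULT_EMSA_LADDER = (1.0, 2.0, 4.0, 10.0, 20.0, 40.0, 100.0, 150.0, 200.0, 300.0)


def _check_pwm(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != 4 or matrix.shape[0] < 1:
        raise ValueError("pwm must be a (width, 4) matrix")
    if (matrix < 0).any():
        raise ValueError("pwm entries must be non-negative")
    if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("pwm columns must sum to 1 within 1e-9")
    return matrix


@dataclass
class GroundTruth:
    """Generative model for one protein: PWM plus intensity-model parameters.

    Parameters
    ----------
    pwm : (w, 4) array
        Per-position base probabilities (A, C, G, T order).
    background : float
        Baseline intensity B (arbitrary fluorescence units), > 0.
    scale : float
        Occupancy-to-intensity gain S, >= 0.
    noise_sigma : float
        Standard deviation of Gaussian noise on log intensity, >= 0.
    rng_seed : int
        Base seed for the experiment's random stream.
    """

    pwm: np.ndarray
    background: float = 200.0
    scale: float = 50000.0
    noise_sigma: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.pwm = _check_pwm(self.pwm)
        if not self.background > 0:
            raise ValueError("background must be > 0")
        if self.scale < 0 or self.noise_sigma < 0:
            raise ValueError("scale and noise_sigma must be >= 0")


@dataclass
class PbmExperiment:
    """A probe set with measured intensities plus protein/replicate metadata."""

    probes: list[Probe]
    protein_label: str = ""
    replicate_id: int = 1
    concentration_nM: float = 300.0

    def __post_init__(self) -> None:
        lengths = {len(p.sequence) for p in self.probes}
        if len(lengths) > 1:
            raise ValueError("all probe sequences must share one length")
        for p in self.probes:
            if p.intensity is None or not np.isfinite(p.intensity) or p.intensity <= 0:
                raise ValueError(f"probe {p.probe_id}: intensity must be positive and finite")
        if not self.concentration_nM > 0:
            raise ValueError("concentration_nM must be positive")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.probes]

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.probes], dtype=float)

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 encoding of all probe sequences."""
        return encode_matrix(self.sequences)


def _occupancy_matrix(enc: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Vectorised occupancy for an (n, L) encoded sequence matrix."""
    pwm = _check_pwm(pwm)
    w = pwm.shape[0]
    n, L = enc.shape
    if L < w:
        raise ValueError(f"sequence length {L} shorter than pwm width {w}")
    nwin = L - w + 1
    # reverse-complement PWM scores the reverse strand on forward coordinates
    pwm_rc = pwm[::-1, ::-1]
    occ = np.zeros(n)
    for mat in (pwm, pwm_rc):
        scores = np.ones((n, nwin))
        for j in range(w):
            scores *= mat[j, enc[:, j:j + nwin]]
        occ += scores.sum(axis=1)
    return occ


def occupancy(sequence: str, pwm: np.ndarray) -> float:
    """PWM occupancy of a sequence: sum of window match probabilities, both strands.

    Equals sum over every width-w window on the forward strand and on the
    reverse complement of prod_j pwm[j, base_j]; symmetric under reverse
    complementation of the sequence.
    """
    enc = encode(sequence)[None, :]
    return float(_occupancy_matrix(enc, np.asarray(pwm, dtype=float))[0])


def simulate_pbm(
    design: ArrayDesign,
    truth: GroundTruth,
    protein_label: str = "protein",
    replicate_id: int = 1,
    concentration_nM: float = 300.0,
    _stream_key: tuple[int, ...] | None = None,
) -> PbmExperiment:
    """Simulate one PBM experiment from a ground-truth occupancy model.

    intensity_i = (B + S * occupancy_i) * exp(eps_i), eps_i ~ N(0, sigma^2),
    with the noise stream a pure function of (truth.rng_seed, replicate_id).
    """
    enc = encode_matrix(design.sequences)
    occ = _occupancy_matrix(enc, truth.pwm)
    mean = truth.background + truth.scale * occ
    key = _stream_key if _stream_key is not None else (truth.rng_seed, replicate_id)
    rng = np.random.default_rng(key)
    eps = rng.normal(0.0, truth.noise_sigma, size=len(occ)) if truth.noise_sigma > 0 else 0.0
    intensities = mean * np.exp(np.broadcast_to(eps, mean.shape))
    probes = [
        Probe(p.probe_id, p.sequence, float(x))
        for p, x in zip(design.probes, intensities)
    ]
    return PbmExperiment(
        probes,
        protein_label=protein_label,
        replicate_id=replicate_id,
        concentration_nM=concentration_nM,
    )


def simulate_two_allele(
    design: ArrayDesign,
    pwm_ref: np.ndarray,
    pwm_var: np.ndarray,
    background: float = 200.0,
    scale: float = 50000.0,
    noise_sigma: float = 0.2,
    rng_seed: int = 0,
    n_replicates: int = 2,
    labels: tuple[str, str] = ("SIX1-ref", "SIX1-Q177R"),
) -> list[PbmExperiment]:
    """Duplicate PBM experiments for a reference and a variant allele.

    Returns 2 * n_replicates experiments (reference replicates first), each
    with a distinct random substream keyed by (rng_seed, allele, replicate).
    """
    out = []
    for allele_idx, (label, pwm) in enumerate(zip(labels, (pwm_ref, pwm_var))):
        truth = GroundTruth(
            pwm=pwm, background=background, scale=scale,
            noise_sigma=noise_sigma, rng_seed=rng_seed,
        )
        for rep in range(1, n_replicates + 1):
            out.append(
                simulate_pbm(
                    design, truth, protein_label=label, replicate_id=rep,
                    _stream_key=(rng_seed, allele_idx, rep),
                )
            )
    return out


@dataclass
class BindingCurve:
    """EMSA titration: percent of probe bound at each protein concentration."""

    concentrations_nM: np.ndarray
    percent_bound: np.ndarray
    probe_label: str = ""
    protein_label: str = ""

    def __post_init__(self) -> None:
        self.concentrations_nM = np.asarray(self.concentrations_nM, dtype=float)
        self.percent_bound = np.asarray(self.percent_bound, dtype=float)
        if self.concentrations_nM.shape != self.percent_bound.shape:
            raise ValueError("concentration and percent-bound vectors differ in length")
        if (self.concentrations_nM <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(self.concentrations_nM) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if ((self.percent_bound < 0) | (self.percent_bound > 100)).any():
            raise ValueError("percent bound must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.concentrations_nM)


def simulate_emsa_curve(
    kd_nM: float,
    concentrations_nM=DEFAULT_EMSA_LADDER,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    probe_label: str = "",
    protein_label: str = "",
) -> BindingCurve:
    """Simulate a titration from a 1:1 isotherm with truncated Gaussian noise."""
    conc = np.asarray(concentrations_nM, dtype=float)
    if not kd_nM > 0:
        raise ValueError("kd_nM must be positive")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    frac = 100.0 * conc / (kd_nM + conc)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        frac = frac + rng.normal(0.0, noise_sd, size=conc.shape)
    frac = np.clip(frac, 0.0, 100.0)
    return BindingCurve(conc, frac, probe_label=probe_label, protein_label=protein_label)


def consensus_pwm(consensus: str, dominance: float = 0.85) -> np.ndarray:
    """PWM placing probability `dominance` on each consensus base, rest uniform.

    dominance=0.85 gives ~1.2 bits/column, a realistic specificity for a
    homeodomain; dominance=1.0 gives a point-mass PWM.
    """
    if not 0.25 <= dominance <= 1.0:
        raise ValueError("dominance must be in [0.25, 1]")
    enc = encode(consensus)
    w = len(consensus)
    pwm = np.full((w, 4), (1.0 - dominance) / 3.0)
    pwm[np.arange(w), enc] = dominance
    return pwm
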