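"""EMSA binding-curve quantification and affinity estimation.

Gel densitometry gives, per lane, the intensities of the protein-bound and
unbound probe bands; the percent of probe bound is
100 * bound / (bound + unbound). Across a protein titration this traces a
binding curve, modelled here by a 1:1 Langmuir isotherm

    percent(P) = f_max * P / (Kd + P)

with the saturating fraction f_max fitted rather than fixed at 100 (gel
transfer losses make full saturation unobservable) and the dissociation
constant Kd the concentration at half-maximal binding. A Hill-slope
variant, percent(P) = f_max * P^h / (Kd^h + P^h), is available via
``hill=True`` for cooperative binding.

``LangmuirModel(curve).fit()`` returns a ``LangmuirResults`` carrying the
estimates, their standard errors from the Jacobian at the optimum, the
residual sum of squares and a ``summary()``. Affinities of two proteins
for the same probe are compared as a Kd ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulate import BindingCurve

__all__ = [
    "BindingCurve",
    "fraction_bound",
    "LangmuirModel",
    "LangmuirResults",
    "AffinityFit",
    "fit_kd",
    "affinity_ratio",
]

KD_BOUNDS = (1e-3, 1e5)  # nM


def fraction_bound(bound_intensity: float, unbound_intensity: float) -> float:
    """Percent of probe bound: 100 * bound / (bound + unbound)."""
    if bound_intensity < 0 or unbound_intensity < 0:
        raise ValueError("band intensities must be non-negative")
    total = bound_intensity + unbound_intensity
    if total <= 0:
        raise ValueError("bound + unbound intensity must be positive")
    return 100.0 * bound_intensity / total


@dataclass
class LangmuirResults:
    """Fitted isotherm: estimates, uncertainties and diagnostics."""

    model: "LangmuirModel"
    kd_nM: float
    f_max: float
    hill: float
    rss: float
    converged: bool
    bse: dict[str, float]

    def predict(self, concentrations_nM=None) -> np.ndarray:
        conc = np.asarray(
            self.model.curve.concentrations_nM if concentrations_nM is None
            else concentrations_nM, dtype=float)
        h = self.hill
        return self.f_max * conc ** h / (self.kd_nM ** h + conc ** h)

    def summary(self) -> str:
        c = self.model.curve
        lines = [
            "Langmuir isotherm fit",
            f"  probe: {c.probe_label or '-'}   protein: {c.protein_label or '-'}",
            f"  lanes: {len(c)}  (concentrations {c.concentrations_nM[0]:g}"
            f"-{c.concentrations_nM[-1]:g} nM)",
            f"  Kd    = {self.kd_nM:10.4g} nM  (SE {self.bse.get('kd_nM', float('nan')):.3g})",
            f"  f_max = {self.f_max:10.4g} %   (SE {self.bse.get('f_max', float('nan')):.3g})",
        ]
        if self.hill != 1.0 or "hill" in self.bse:
            lines.append(f"  hill  = {self.hill:10.4g}")
        lines += [
            f"  RSS   = {self.rss:10.4g}",
            f"  converged: {self.converged}",
        ]
        return "\n".join(lines)


#: alias: the fitted-affinity record under its domain name
AffinityFit = LangmuirResults


class LangmuirModel:
    """1:1 (optionally Hill) binding isotherm for one EMSA titration.

    Parameters
    ----------
    curve : BindingCurve
        At least 3 titration points with strictly increasing concentrations.
    hill : bool
        Fit a Hill coefficient as a third parameter.
    """

    def __init__(self, curve: BindingCurve, hill: bool = False):
        if len(curve) < 3:
            raise ValueError("need >= 3 titration points to fit an isotherm")
        self.curve = curve
        self.hill = hill

    def fit(self) -> LangmuirResults:
        """Least-squares fit with a deterministic initialisation.

        kd0 is the concentration whose observed percent bound is nearest
        half of the maximum observed; f_max0 is the maximum observed.
        """
        conc = self.curve.concentrations_nM
        y = self.curve.percent_bound
        fmax0 = max(float(y.max()), 1.0)
        kd0 = float(conc[np.argmin(np.abs(y - fmax0 / 2.0))])
        kd0 = float(np.clip(kd0, *KD_BOUNDS))

        if self.hill:
            x0 = [kd0, fmax0, 1.0]
            lo, hi = [KD_BOUNDS[0], 1e-6, 0.1], [KD_BOUNDS[1], 100.0, 10.0]

            def resid(p):
                kd, fm, h = p
                return fm * conc ** h / (kd ** h + conc ** h) - y
        else:
            x0 = [kd0, fmax0]
            lo, hi = [KD_BOUNDS[0], 1e-6], [KD_BOUNDS[1], 100.0]

            def resid(p):
                kd, fm = p
                return fm * conc / (kd + conc) - y

        res = least_squares(resid, x0, bounds=(lo, hi),
                            gtol=1e-8, xtol=1e-12, ftol=1e-12)
        names = ["kd_nM", "f_max"] + (["hill"] if self.hill else [])
        bse = dict.fromkeys(names, float("nan"))
        dof = len(conc) - len(names)
        if dof > 0:
            jtj = res.jac.T @ res.jac
            try:
                cov = np.linalg.inv(jtj) * (2 * res.cost) / dof
                bse = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
            except np.linalg.LinAlgError:
                pass
        return LangmuirResults(
            model=self,
            kd_nM=float(res.x[0]),
            f_max=float(res.x[1]),
            hill=float(res.x[2]) if self.hill else 1.0,
            rss=float(2 * res.cost),
            converged=bool(res.success),
            bse=bse,
        )


def fit_kd(curve: BindingCurve, hill: bool = False) -> LangmuirResults:
    """Fit a binding curve; functional shorthand for LangmuirModel(curve).fit()."""
    return LangmuirModel(curve, hill=hill).fit()


def affinity_ratio(fit_a: LangmuirResults, fit_b: LangmuirResults) -> float:
    """Kd_a / Kd_b: a ratio > 1 means protein b binds more tightly."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("affinity_ratio requires converged fits")
    return fit_a.kd_nM / fit_b.kd_nM
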