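"""Activator-titration enzyme kinetics: rate computation and Hill fitting.

Phosphodiesterase rates against the chromogenic substrate PNPP are obtained
from A405 via the p-nitrophenol extinction coefficient (18,000 M⁻¹ cm⁻¹),
and activity versus activator concentration is fitted to the allosteric
sigmoidal (Hill) model

    v(A) = Vmax · Aʰ / (K_halfʰ + Aʰ).

Fitting is unit-agnostic: Vmax carries whatever units the dataset's rates
are in. A fixed-h = 1 (hyperbolic) fit is run alongside and compared by an
extra-sum-of-squares F test, the standard operationalization of "the
sigmoidal model fits better".
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy import stats

from .binding import DomainError

__all__ = [
    "PNP_EXTINCTION_M_CM",
    "ActivityDataset",
    "HillFitResult",
    "pnp_from_absorbance",
    "hill_model",
    "fit_hill",
]

#: Molar extinction coefficient of p-nitrophenol at 405 nm (M⁻¹ cm⁻¹).
PNP_EXTINCTION_M_CM = 18_000.0


@dataclass(frozen=True)
class ActivityDataset:
    """Replicate enzyme rates over an activator titration.

    ``conc_uM`` and ``rate`` are parallel arrays with one row per replicate
    measurement; the substrate (PNPP) is fixed, 5 mM by default.
    """

    activator: str
    conc_uM: tuple[float, ...]
    rate: tuple[float, ...]
    substrate_mM: float = 5.0

    def __post_init__(self) -> None:
        if len(self.conc_uM) != len(self.rate):
            raise DomainError("conc_uM and rate must have equal length")
        if any(c < 0 for c in self.conc_uM):
            raise DomainError("activator concentrations must be non-negative")
        if len(set(self.conc_uM)) < 5:
            raise DomainError("need at least 5 distinct activator concentrations")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        order = np.argsort(self.conc_uM, kind="stable")
        return np.asarray(self.conc_uM)[order], np.asarray(self.rate)[order]


@dataclass(frozen=True)
class HillFitResult:
    """Hill-fit estimates with standard errors and the vs-h=1 comparison."""

    Vmax: float
    Khalf: float
    h: float
    stderr: dict[str, float]
    rss: float
    rss_h1: float
    f_stat: float
    p_value: float
    converged: bool

    def predict(self, A) -> np.ndarray:
        return hill_model(A, self.Vmax, self.Khalf, self.h)


def pnp_from_absorbance(a405: float, path_cm: float = 1.0, dilution_factor: float = 1.0) -> float:
    """p-nitrophenol concentration (M) from A405.

    ``dilution_factor`` is the factor by which the assay was diluted before
    reading (e.g. 11 after quenching with 10 volumes of stop solution).
    """
    if a405 < 0:
        raise DomainError(f"absorbance must be non-negative, got {a405}")
    if path_cm <= 0 or dilution_factor <= 0:
        raise DomainError("path length and dilution factor must be positive")
    return a405 * dilution_factor / (PNP_EXTINCTION_M_CM * path_cm)


def hill_model(A, Vmax: float, Khalf: float, h: float):
    """Allosteric sigmoidal rate v = Vmax·Aʰ/(K_halfʰ + Aʰ).

    v(0) = 0, v(K_half) = Vmax/2 for any h, v → Vmax as A → ∞.
    """
    if Khalf <= 0 or h <= 0:
        raise DomainError("Khalf and h must be positive")
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise DomainError("activator concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        x = (A / Khalf) ** h
    return Vmax * x / (1.0 + x)


def _ls_fit(conc, rate, pars, model):
    def residuals(p):
        return model(conc, p) - rate

    return lmfit.minimize(
        residuals, pars, method="least_squares", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )


def fit_hill(ds: ActivityDataset, init: dict | None = None) -> HillFitResult:
    """Least-squares Hill fit of an activity dataset.

    Standard errors come from the Jacobian-based covariance. The h = 1
    (rectangular hyperbola) model is fitted to the same data and compared
    by an extra-sum-of-squares F test; small ``p_value`` means the
    sigmoidal model fits significantly better.
    """
    conc, rate = ds.arrays()
    if np.allclose(rate, 0.0):
        raise DomainError("all rates are zero; nothing to fit")

    vmax0 = float(np.max(rate))
    half = 0.5 * vmax0
    above = conc[rate >= half]
    k0 = float(above[0]) if above.size else float(np.median(conc[conc > 0]))
    defaults = {"Vmax": vmax0, "Khalf": max(k0, 1e-6), "h": 1.5}
    if init:
        defaults.update(init)

    pars = lmfit.Parameters()
    pars.add("Vmax", value=defaults["Vmax"], min=1e-12)
    pars.add("logKhalf", value=np.log10(defaults["Khalf"]), min=-6, max=9)
    pars.add("h", value=defaults["h"], min=0.05, max=10.0)

    def model(A, p):
        return hill_model(A, p["Vmax"].value, 10.0 ** p["logKhalf"].value, p["h"].value)

    res = _ls_fit(conc, rate, pars, model)
    rss = float(np.sum(res.residual**2))

    pars1 = lmfit.Parameters()
    pars1.add("Vmax", value=defaults["Vmax"], min=1e-12)
    pars1.add("logKhalf", value=np.log10(defaults["Khalf"]), min=-6, max=9)
    pars1.add("h", value=1.0, vary=False)
    res1 = _ls_fit(conc, rate, pars1, model)
    rss_h1 = float(np.sum(res1.residual**2))

    n = conc.size
    df_full = n - 3
    denom = rss / df_full if df_full > 0 else np.nan
    if denom > 0:
        f_stat = max(rss_h1 - rss, 0.0) / denom
        p_value = float(stats.f.sf(f_stat, 1, df_full))
    else:  # a perfect (noiseless) sigmoidal fit: F is unbounded
        f_stat = float("inf") if rss_h1 > rss else 0.0
        p_value = 0.0 if rss_h1 > rss else 1.0

    khalf = 10.0 ** res.params["logKhalf"].value

    def _err(name):
        e = res.params[name].stderr
        return float(e) if e is not None else float("nan")

    stderr = {
        "Vmax": _err("Vmax"),
        "Khalf": _err("logKhalf") * np.log(10.0) * khalf,
        "h": _err("h"),
    }
    return HillFitResult(
        Vmax=float(res.params["Vmax"].value),
        Khalf=float(khalf),
        h=float(res.params["h"].value),
        stderr=stderr,
        rss=rss,
        rss_h1=rss_h1,
        f_stat=float(f_stat),
        p_value=p_value,
        converged=bool(res.success),
    )
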