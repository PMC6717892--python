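"""Forward simulation and fitting of isothermal titration calorimetry data.

The forward model is the independent two-sets-of-sites binding model for a
constant-volume ("perfusion") injection cell: each injection of volume dV
into a cell of volume V0 dilutes the existing contents by (1 − dV/V0) and
adds injectant at syr_conc·dV/V0. The cumulative heat content of the cell
after injection i is

    Q(i) = V0 · Ptot(i) · [n1·θ1(L_i)·ΔH1 + n2·θ2(L_i)·ΔH2]

with free ligand L_i from the mass balance, and the measured heat of
injection i is

    δq(i) = Q(i) − Q(i−1)·(1 − dV_i/V0),

the second term accounting for bound complex displaced from the active
volume. Simulator and fitter share this single forward model, so noiseless
round trips are exact up to optimizer tolerance and independent of the
dilution convention chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import lmfit
import numpy as np
import pandas as pd

from .binding import ConvergenceError, DomainError, TwoSetsParams, free_ligand_many

__all__ = [
    "TitrationProtocol",
    "Thermogram",
    "ItcFitResult",
    "simulate_titration",
    "fit_two_sets",
    "read_thermogram",
    "write_thermogram",
]

#: Default injection schedule: a small 2 μl pre-injection followed by
#: 6 μl injections, the design used for the sensor-domain titrations.
DEFAULT_INJECTIONS_UL = (2.0,) + (6.0,) * 24


@dataclass(frozen=True)
class TitrationProtocol:
    """Cell volume, concentrations and injection schedule of one titration.

    ``cell_conc`` is the macromolecule concentration per monomer (M),
    ``syr_conc`` the injectant concentration (M), ``V0_ml`` the active cell
    volume in ml and ``injection_volumes_ul`` the ordered injection volumes
    in μl (the first may differ from the rest).
    """

    cell_conc: float
    syr_conc: float
    V0_ml: float = 1.4
    injection_volumes_ul: tuple[float, ...] = DEFAULT_INJECTIONS_UL

    def __post_init__(self) -> None:
        if not self.V0_ml > 0:
            raise DomainError("cell volume must be positive")
        if not (self.cell_conc > 0 and self.syr_conc > 0):
            raise DomainError("concentrations must be positive")
        if len(self.injection_volumes_ul) == 0 or any(
            v <= 0 for v in self.injection_volumes_ul
        ):
            raise DomainError("injection volumes must be positive and non-empty")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def concentration_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        """(Ptot, Ltot) in the cell after each injection, perfusion convention."""
        dil = 1.0 - np.asarray(self.injection_volumes_ul) / (self.V0_ml * 1e3)
        n = self.n_injections
        Ptot = np.empty(n)
        Ltot = np.empty(n)
        P, L = self.cell_conc, 0.0
        for i, d in enumerate(dil):
            P *= d
            L = L * d + self.syr_conc * (1.0 - d)
            Ptot[i], Ltot[i] = P, L
        return Ptot, Ltot


@dataclass(frozen=True)
class Thermogram:
    """Per-injection heats (μcal) plus the protocol that produced them."""

    protocol: TitrationProtocol
    heats_ucal: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.heats_ucal) != self.protocol.n_injections:
            raise DomainError(
                f"{len(self.heats_ucal)} heats for "
                f"{self.protocol.n_injections} injections"
            )

    @property
    def molar_ratio(self) -> np.ndarray:
        """Cumulative injectant : macromolecule molar ratio after each injection."""
        Ptot, Ltot = self.protocol.concentration_schedule()
        return Ltot / Ptot

    @property
    def normalized_heats(self) -> np.ndarray:
        """Heats in cal per mol of injectant for each injection."""
        dv_l = np.asarray(self.protocol.injection_volumes_ul) * 1e-6
        moles = self.protocol.syr_conc * dv_l
        return np.asarray(self.heats_ucal) * 1e-6 / moles


@dataclass(frozen=True)
class ItcFitResult:
    """Best-fit two-sets parameters with per-parameter standard errors."""

    params: TwoSetsParams
    stderr: dict[str, float]
    rss: float
    converged: bool
    identifiable: bool
    excluded: tuple[int, ...]
    message: str = ""


def _model_heats_ucal(p: TwoSetsParams, proto: TitrationProtocol) -> np.ndarray:
    Ptot, Ltot = proto.concentration_schedule()
    L = free_ligand_many(p, Ptot, Ltot)
    theta1 = p.K1 * L / (1.0 + p.K1 * L)
    theta2 = p.K2 * L / (1.0 + p.K2 * L)
    V0_l = proto.V0_ml * 1e-3
    Q = V0_l * Ptot * (p.n1 * theta1 * p.dH1 + p.n2 * theta2 * p.dH2)  # cal
    dil = 1.0 - np.asarray(proto.injection_volumes_ul) / (proto.V0_ml * 1e3)
    Qprev = np.concatenate(([0.0], Q[:-1]))
    return (Q - Qprev * dil) * 1e6


def simulate_titration(
    p: TwoSetsParams,
    proto: TitrationProtocol,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Thermogram:
    """Simulate per-injection heats for one titration.

    ``noise_sd`` is the standard deviation (μcal) of additive Gaussian
    baseline noise; the draw is deterministic given ``seed``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be non-negative")
    heats = _model_heats_ucal(p, proto)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.size)
    return Thermogram(protocol=proto, heats_ucal=tuple(float(h) for h in heats))


_LOGK_BOUNDS = (2.0, 10.0)  # log10 of K in M⁻¹


def _make_lmfit_params(init: TwoSetsParams) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    pars.add("n1", value=init.n1, min=1e-3, max=10.0)
    pars.add("n2", value=init.n2, min=1e-3, max=10.0)
    pars.add("logK1", value=np.log10(init.K1), min=_LOGK_BOUNDS[0], max=_LOGK_BOUNDS[1])
    pars.add("logK2", value=np.log10(init.K2), min=_LOGK_BOUNDS[0], max=_LOGK_BOUNDS[1])
    pars.add("dH1", value=init.dH1, min=-1e6, max=1e6)
    pars.add("dH2", value=init.dH2, min=-1e6, max=1e6)
    return pars


def _params_from_lmfit(pars) -> TwoSetsParams:
    return TwoSetsParams(
        n1=pars["n1"].value,
        n2=pars["n2"].value,
        K1=10.0 ** pars["logK1"].value,
        K2=10.0 ** pars["logK2"].value,
        dH1=pars["dH1"].value,
        dH2=pars["dH2"].value,
    )


def _swap_classes(p: TwoSetsParams) -> TwoSetsParams:
    return TwoSetsParams(n1=p.n2, n2=p.n1, K1=p.K2, K2=p.K1, dH1=p.dH2, dH2=p.dH1)


def _class_distance(a: TwoSetsParams, b: TwoSetsParams) -> float:
    return (
        (np.log10(a.K1) - np.log10(b.K1)) ** 2
        + (np.log10(a.K2) - np.log10(b.K2)) ** 2
        + ((a.dH1 - b.dH1) / 1e4) ** 2
        + ((a.dH2 - b.dH2) / 1e4) ** 2
    )


def _canonical_order(p: TwoSetsParams, stderr: dict[str, float], anchor: TwoSetsParams | None):
    """Resolve the label-swap ambiguity of the two site classes.

    With an ``anchor`` (normally the initial guess), the permutation closest
    to it in (log K, ΔH) space is kept — the caller's labels are pinned.
    Without one, class 1 is the class with the larger |ΔH|·K product.
    """
    swapped = _swap_classes(p)
    if anchor is not None:
        keep = _class_distance(p, anchor) <= _class_distance(swapped, anchor)
    else:
        keep = abs(p.dH1) * p.K1 >= abs(p.dH2) * p.K2
    if keep:
        return p, stderr
    swapped_err = {
        "n1": stderr["n2"], "n2": stderr["n1"],
        "K1": stderr["K2"], "K2": stderr["K1"],
        "dH1": stderr["dH2"], "dH2": stderr["dH1"],
    }
    return swapped, swapped_err


def fit_two_sets(
    tg: Thermogram,
    init: TwoSetsParams,
    exclude_first: bool = True,
    n_starts: int = 5,
    seed: int = 0,
) -> ItcFitResult:
    """Fit the two-sets-of-sites model to a thermogram.

    Minimizes the sum of squared residuals between observed and model
    normalized heats over (n1, n2, log K1, log K2, ΔH1, ΔH2), from
    ``n_starts`` starts (the given ``init`` plus seeded perturbations of
    it), keeping the lowest-RSS solution. The first injection is excluded
    by default, standard practice for the small pre-injection. Label-swap
    ambiguity between the two classes is resolved by anchoring to ``init``.

    Non-convergence or non-identifiability (e.g. all-zero heats) is
    reported through the ``converged``/``identifiable`` flags, never as an
    exception.
    """
    excluded = (0,) if exclude_first else ()
    mask = np.ones(tg.protocol.n_injections, dtype=bool)
    mask[list(excluded)] = False
    if mask.sum() < 10:
        raise DomainError(f"need at least 10 usable injections, have {int(mask.sum())}")

    obs = tg.normalized_heats[mask]
    proto = tg.protocol
    dv_l = np.asarray(proto.injection_volumes_ul) * 1e-6
    moles = proto.syr_conc * dv_l

    def residuals(pars):
        try:
            model = _model_heats_ucal(_params_from_lmfit(pars), proto) * 1e-6 / moles
        except ConvergenceError:
            return np.full(obs.size, 1e6)
        return model[mask] - obs

    rng = np.random.default_rng(seed)
    starts = [init]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            TwoSetsParams(
                n1=init.n1 * rng.uniform(0.7, 1.3),
                n2=init.n2 * rng.uniform(0.7, 1.3),
                K1=init.K1 * 10.0 ** rng.uniform(-0.3, 0.3),
                K2=init.K2 * 10.0 ** rng.uniform(-0.3, 0.3),
                dH1=init.dH1 * rng.uniform(0.7, 1.3) or rng.uniform(-1e3, 1e3),
                dH2=init.dH2 * rng.uniform(0.7, 1.3) or rng.uniform(-1e3, 1e3),
            )
        )

    best = None
    for start in starts:
        try:
            res = lmfit.minimize(
                residuals,
                _make_lmfit_params(start),
                method="least_squares",
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
        except Exception:  # a bad start must not kill the multi-start sweep
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[1]:
            best = (res, rss)

    if best is None:
        return ItcFitResult(
            params=init,
            stderr={k: float("nan") for k in ("n1", "n2", "K1", "K2", "dH1", "dH2")},
            rss=float("nan"),
            converged=False,
            identifiable=False,
            excluded=excluded,
            message="no start converged",
        )

    res, rss = best
    fitted = _params_from_lmfit(res.params)

    def _err(name: str) -> float:
        e = res.params[name].stderr
        return float(e) if e is not None else float("nan")

    ln10 = np.log(10.0)
    stderr = {
        "n1": _err("n1"),
        "n2": _err("n2"),
        "K1": _err("logK1") * ln10 * fitted.K1,
        "K2": _err("logK2") * ln10 * fitted.K2,
        "dH1": _err("dH1"),
        "dH2": _err("dH2"),
    }
    fitted, stderr = _canonical_order(fitted, stderr, anchor=init)

    # K is unidentifiable when the signal is flat: judge by heat amplitude
    heat_scale = float(np.max(np.abs(obs))) if obs.size else 0.0
    identifiable = heat_scale > 1e-6 and not any(
        np.isnan(v) for v in (stderr["K1"], stderr["K2"])
    )
    return ItcFitResult(
        params=fitted,
        stderr=stderr,
        rss=rss,
        converged=bool(res.success),
        identifiable=identifiable,
        excluded=excluded,
        message=str(res.message),
    )


_CSV_COLUMNS = ["injection_index", "dV_ul", "heat_ucal"]


def write_thermogram(tg: Thermogram, path) -> None:
    """Write a thermogram as CSV (injection_index, dV_ul, heat_ucal)."""
    df = pd.DataFrame(
        {
            "injection_index": np.arange(1, tg.protocol.n_injections + 1),
            "dV_ul": tg.protocol.injection_volumes_ul,
            "heat_ucal": tg.heats_ucal,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_thermogram(path, proto: TitrationProtocol) -> Thermogram:
    """Read a thermogram CSV; injection volumes in the file take precedence.

    ``proto`` supplies the cell volume and concentrations, which the CSV
    does not carry. Malformed rows raise a parse error naming the line.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"cannot parse thermogram CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"thermogram CSV {path} lacks columns {missing}")
    for i, row in df.iterrows():
        if row[_CSV_COLUMNS].isna().any():
            raise ValueError(f"thermogram CSV {path}: malformed row at line {i + 2}")
    proto = replace(proto, injection_volumes_ul=tuple(float(v) for v in df["dV_ul"]))
    return Thermogram(protocol=proto, heats_ucal=tuple(float(h) for h in df["heat_ucal"]))
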