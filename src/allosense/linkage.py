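"""Occupancy → activity linkage: does activation need one bound site or two?

Given macroscopic stepwise binding constants for the sensor dimer, this
module predicts normalized activity curves under three competing
activation hypotheses,

* ``single_site_sufficient`` — activity ∝ f1 + f2 (any occupancy activates),
* ``double_required``        — activity ∝ f2 (both sites must be occupied),
* ``proportional_occupancy`` — activity ∝ ν/2 (activity scales with mean
  occupancy),

and formalizes the three-point consistency argument that links the
calorimetric constants to the observed activation kinetics: (1) the
ordering of the observed K_half values versus the ordering a single-site
mechanism would predict from the first-site affinities; (2) whether
K_half is roughly twice the low-affinity dissociation constant, as
expected when occupying the weak site is rate-limiting; (3) whether an
observed Hill coefficient > 1 coexists with negative binding
cooperativity, which a single-site mechanism cannot produce.

Activity predictions treat the activator's free concentration as equal to
its total concentration (enzyme-as-trace). At assay-like enzyme loads this
is not strictly true at sub-μM activator; predictions carry a warning and
a depletion-corrected mode is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from enum import Enum

import numpy as np
from scipy.optimize import brentq

from .binding import (
    DomainError,
    SequentialParams,
    TwoSetsParams,
    cooperativity_index,
    occupancy_sequential,
)
from .kinetics import ActivityDataset, HillFitResult, fit_hill

__all__ = [
    "ActivationHypothesis",
    "LinkagePrediction",
    "InferenceReport",
    "predict_activity",
    "run_inference",
]

#: The "approximately twofold" acceptance band for K_half / K_diss,low.
TWOFOLD_BAND = (1.5, 3.0)

#: Hill coefficients above this are treated as apparent positive
#: cooperativity of the response (margin over h = 1 for fit uncertainty).
HILL_POSITIVE_THRESHOLD = 1.1


class ActivationHypothesis(str, Enum):
    single_site_sufficient = "single_site_sufficient"
    double_required = "double_required"
    proportional_occupancy = "proportional_occupancy"


def _normalized_activity(sp: SequentialParams, hyp: ActivationHypothesis, L: float) -> float:
    occ = occupancy_sequential(sp, L)
    if hyp is ActivationHypothesis.double_required:
        return occ.f2
    if hyp is ActivationHypothesis.single_site_sufficient:
        return occ.f1 + occ.f2
    return occ.nu / 2.0


@dataclass(frozen=True)
class LinkagePrediction:
    """Predicted normalized activity curve and its apparent Hill parameters.

    ``half_point_uM`` is the exact concentration at which the curve crosses
    0.5 (bisection); ``khalf_app_uM``/``h_app`` come from a noiseless Hill
    refit of the curve and are what an activation assay would report.
    """

    hypothesis: ActivationHypothesis
    grid_uM: tuple[float, ...]
    activity: tuple[float, ...]
    khalf_app_uM: float
    h_app: float
    half_point_uM: float
    ratio_khalf_to_kdlow: float
    warning: str = ""


def predict_activity(
    sp: SequentialParams,
    hyp: ActivationHypothesis,
    grid_uM,
    enzyme_dimer_uM: float | None = None,
) -> LinkagePrediction:
    """Predict the normalized activity curve on a concentration grid (μM).

    The grid must span at least three decades and bracket the curve's
    half-maximum. If ``enzyme_dimer_uM`` is given, free activator is
    depletion-corrected by the dimer mass balance instead of the default
    free ≈ total assumption.
    """
    grid = np.sort(np.asarray(grid_uM, dtype=float))
    if grid.size < 5 or grid[0] <= 0:
        raise DomainError("grid must contain >= 5 positive concentrations")
    if np.log10(grid[-1] / grid[0]) < 3.0:
        raise DomainError("grid must span at least three decades")

    # work in μM: rescale the stepwise constants accordingly
    sp_uM = SequentialParams(beta1=sp.beta1 * 1e-6, beta2=sp.beta2 * 1e-12)

    def free_conc(total: float) -> float:
        if enzyme_dimer_uM is None:
            return total
        # total = L + E·ν(L), monotone in L
        g = lambda L: L + enzyme_dimer_uM * occupancy_sequential(sp_uM, L).nu - total
        return brentq(g, 0.0, total, xtol=1e-15, rtol=1e-14)

    act = np.array([_normalized_activity(sp_uM, hyp, free_conc(t)) for t in grid])
    if act[0] > 0.5 or act[-1] < 0.5:
        raise DomainError(
            "grid does not bracket the half-maximum of the predicted curve; "
            f"activity spans [{act[0]:.3g}, {act[-1]:.3g}]"
        )

    half = brentq(
        lambda t: _normalized_activity(sp_uM, hyp, free_conc(t)) - 0.5,
        grid[0],
        grid[-1],
        xtol=1e-12,
        rtol=1e-14,
    )

    ds = ActivityDataset(activator="predicted", conc_uM=tuple(grid), rate=tuple(act))
    fit = fit_hill(ds)
    kd_low_uM = sp_uM.kd_low_affinity
    warning = (
        "" if enzyme_dimer_uM is not None
        else "free ligand approximated by total ligand (enzyme treated as trace)"
    )
    return LinkagePrediction(
        hypothesis=hyp,
        grid_uM=tuple(float(g) for g in grid),
        activity=tuple(float(a) for a in act),
        khalf_app_uM=fit.Khalf,
        h_app=fit.h,
        half_point_uM=float(half),
        ratio_khalf_to_kdlow=fit.Khalf / kd_low_uM,
        warning=warning,
    )


@dataclass(frozen=True)
class Criterion:
    name: str
    favors: str  # hypothesis name or "inconclusive"
    detail: str


@dataclass(frozen=True)
class LigandBlock:
    ligand: str
    kd_first_uM: float
    kd_second_uM: float
    cooperativity_c: float
    cooperativity_label: str
    observed_khalf_uM: float
    observed_h: float
    predicted_khalf_double_uM: float
    predicted_khalf_single_uM: float
    ratio_khalf_to_kdlow: float


@dataclass(frozen=True)
class InferenceReport:
    """Three-criterion consistency report; a pure function of its inputs."""

    ligands: tuple[LigandBlock, ...]
    criteria: tuple[Criterion, ...]
    verdict: str
    notes: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Occupancy-activation linkage report", ""]
        for b in self.ligands:
            lines += [
                f"[{b.ligand}] Kd(first/second) = {b.kd_first_uM:.3g}/{b.kd_second_uM:.3g} uM, "
                f"cooperativity {b.cooperativity_label} (c = {b.cooperativity_c:.3g})",
                f"  observed K_half = {b.observed_khalf_uM:.4g} uM, h = {b.observed_h:.3g}",
                f"  predicted K_half: double-required {b.predicted_khalf_double_uM:.3g} uM, "
                f"single-site {b.predicted_khalf_single_uM:.3g} uM",
                f"  K_half / Kd(low-affinity) = {b.ratio_khalf_to_kdlow:.3g}",
            ]
        lines.append("")
        lines.append(f"{'criterion':<28}{'favors':<26}detail")
        for c in self.criteria:
            lines.append(f"{c.name:<28}{c.favors:<26}{c.detail}")
        lines += ["", f"verdict: {self.verdict}"]
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


def _half_points(sp: SequentialParams) -> tuple[float, float]:
    """Exact half-activation points (μM) under double / single hypotheses."""
    sp_uM = SequentialParams(beta1=sp.beta1 * 1e-6, beta2=sp.beta2 * 1e-12)
    out = []
    for hyp in (ActivationHypothesis.double_required, ActivationHypothesis.single_site_sufficient):
        f = lambda L: _normalized_activity(sp_uM, hyp, L) - 0.5
        hi = 1.0
        while f(hi) < 0 and hi < 1e12:
            hi *= 10.0
        out.append(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))
    return out[0], out[1]


def run_inference(
    itc_cAMP: TwoSetsParams,
    itc_cGMP: TwoSetsParams,
    fit_cAMP: HillFitResult,
    fit_cGMP: HillFitResult,
) -> InferenceReport:
    """Run the three-point double-occupancy consistency test.

    ``itc_*`` are fitted two-sets parameters with class 1 the first and
    class 2 the second binding event in titration order; ``fit_*`` are the
    Hill fits of the corresponding activation assays.
    """
    blocks = []
    for ligand, itc, kin in (("cAMP", itc_cAMP, fit_cAMP), ("cGMP", itc_cGMP, fit_cGMP)):
        kd1 = 1.0 / itc.K1 * 1e6  # μM, first event
        kd2 = 1.0 / itc.K2 * 1e6
        c, label = cooperativity_index(kd1 * 1e-6, kd2 * 1e-6)
        sp = SequentialParams.from_stepwise_kds(kd1 * 1e-6, kd2 * 1e-6)
        half_double, half_single = _half_points(sp)
        kd_low = max(kd1, kd2)
        blocks.append(
            LigandBlock(
                ligand=ligand,
                kd_first_uM=kd1,
                kd_second_uM=kd2,
                cooperativity_c=c,
                cooperativity_label=label,
                observed_khalf_uM=kin.Khalf,
                observed_h=kin.h,
                predicted_khalf_double_uM=half_double,
                predicted_khalf_single_uM=half_single,
                ratio_khalf_to_kdlow=kin.Khalf / kd_low,
            )
        )
    camp, cgmp = blocks

    # Criterion 1: ordering of activation. Single-site activation would track
    # the first-site affinities; double occupancy tracks the f2 half-points.
    obs_camp_higher = camp.observed_khalf_uM > cgmp.observed_khalf_uM
    single_camp_higher = camp.predicted_khalf_single_uM > cgmp.predicted_khalf_single_uM
    double_camp_higher = camp.predicted_khalf_double_uM > cgmp.predicted_khalf_double_uM
    if obs_camp_higher == double_camp_higher and obs_camp_higher != single_camp_higher:
        fav1 = ActivationHypothesis.double_required.value
        det1 = (
            "observed K_half ordering matches the double-occupancy prediction, "
            "not the single-site (first-affinity) prediction"
        )
    elif obs_camp_higher == single_camp_higher and obs_camp_higher != double_camp_higher:
        fav1 = ActivationHypothesis.single_site_sufficient.value
        det1 = "observed K_half ordering matches the single-site prediction"
    else:
        fav1 = "inconclusive"
        det1 = "both hypotheses predict the same K_half ordering"
    crit1 = Criterion("khalf_ordering", fav1, det1)

    # Criterion 2: K_half ≈ 2 × Kd of the low-affinity site for both ligands.
    in_band = [
        TWOFOLD_BAND[0] <= b.ratio_khalf_to_kdlow <= TWOFOLD_BAND[1] for b in blocks
    ]
    ratios = ", ".join(f"{b.ligand} {b.ratio_khalf_to_kdlow:.3g}" for b in blocks)
    if all(in_band):
        crit2 = Criterion(
            "khalf_vs_kd_low",
            ActivationHypothesis.double_required.value,
            f"K_half/Kd_low in the ~twofold band {TWOFOLD_BAND} for both ligands ({ratios}); "
            "occupying the low-affinity site looks rate-limiting",
        )
    else:
        crit2 = Criterion(
            "khalf_vs_kd_low",
            "inconclusive",
            f"K_half/Kd_low outside the ~twofold band {TWOFOLD_BAND} ({ratios})",
        )

    # Criterion 3: h > 1 despite negative binding cooperativity.
    neg = [b for b in blocks if b.cooperativity_label == "negative"]
    if not neg:
        crit3 = Criterion(
            "hill_vs_cooperativity",
            "inconclusive",
            "no negatively cooperative ligand to discriminate with",
        )
    elif all(b.observed_h > HILL_POSITIVE_THRESHOLD for b in neg):
        crit3 = Criterion(
            "hill_vs_cooperativity",
            ActivationHypothesis.double_required.value,
            "h > 1 for the negatively cooperative ligand is incompatible with "
            "single-site activation, which would give h < 1",
        )
    else:
        crit3 = Criterion(
            "hill_vs_cooperativity",
            ActivationHypothesis.single_site_sufficient.value,
            "h <= 1 for the negatively cooperative ligand, as single-site "
            "activation predicts",
        )

    criteria = (crit1, crit2, crit3)
    double = ActivationHypothesis.double_required.value
    verdict = double if all(c.favors == double for c in criteria) else "undetermined"
    notes = (
        "stepwise constants mapped from fitted class constants by titration order "
        "(class 1 = first binding event); this identification is interpretive",
        "activity predictions assume free ligand ~ total ligand (enzyme as trace)",
    )
    return InferenceReport(
        ligands=tuple(blocks), criteria=criteria, verdict=verdict, notes=notes
    )
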