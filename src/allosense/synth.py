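"""Synthetic data with known ground truth for every pipeline input.

The generator defaults ARE the study conditions: the calorimetric truth
parameters are the published best-fit values for cAMP and cGMP binding to
the sensor dimer, the titration protocol is the 1.4 ml cell / 2 μl-then-
6 μl schedule with concentrations inside the stated 0.5–1.6 mM syringe and
50–150 μM cell ranges, and the kinetic truths are the published K_half and
Hill coefficients with the cGMP maximal activity 22% above cAMP
(normalized Vmax 1.0 vs 1.22). Noise models — additive Gaussian heats
(0.2 μcal, the order of a VP-type instrument baseline) and relative
Gaussian rate noise (3%, typical triplicate scatter) — are documented
constants, not fitted quantities.

Coordinate fixtures are rigid two-chain Cα scaffolds in which the C-helix
stator is held fixed and one cNMP body is rotated by a known angle about a
hinge axis through the residue 81–86 centroid, giving an exact ground
truth for the swing-metric chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import SequentialParams, TwoSetsParams
from .itc import Thermogram, TitrationProtocol, simulate_titration
from .kinetics import ActivityDataset, hill_model
from .structure import BODY_RANGE, HINGE_RANGE, StructureModel

__all__ = [
    "PUBLISHED_ITC_PARAMS",
    "KINETIC_TRUTH",
    "GeneratorConfig",
    "ItcBlock",
    "KineticsBlock",
    "StructureBlock",
    "make_itc_dataset",
    "make_kinetics_dataset",
    "make_structure_pair",
    "default_grid_uM",
]

#: Published two-sets-of-sites best-fit parameters per ligand
#: (sites per monomer, association constants M⁻¹, enthalpies cal/mol).
PUBLISHED_ITC_PARAMS: dict[str, TwoSetsParams] = {
    "cAMP": TwoSetsParams(n1=0.432, n2=0.456, K1=1.29e6, K2=4.46e4, dH1=-12070.0, dH2=-7139.0),
    "cGMP": TwoSetsParams(n1=0.508, n2=0.480, K1=8.79e4, K2=1.30e6, dH1=-5203.0, dH2=-9023.0),
}

#: Published activation-kinetics parameters per ligand (normalized Vmax,
#: K_half in μM, Hill coefficient). Vmax is normalized to the cAMP maximum;
#: the cGMP maximum is 22% higher.
KINETIC_TRUTH: dict[str, dict[str, float]] = {
    "cAMP": {"Vmax": 1.0, "Khalf": 54.22, "h": 1.85},
    "cGMP": {"Vmax": 1.22, "Khalf": 26.17, "h": 1.94},
}


def default_grid_uM(n_points: int = 12) -> np.ndarray:
    """Log-spaced activator grid spanning the assayed 0.2–1000 μM range."""
    return np.geomspace(0.2, 1000.0, n_points)


@dataclass(frozen=True)
class ItcBlock:
    truth: TwoSetsParams = PUBLISHED_ITC_PARAMS["cAMP"]
    cell_conc: float = 100e-6
    syr_conc: float = 1.0e-3
    noise_sd_ucal: float = 0.2


@dataclass(frozen=True)
class KineticsBlock:
    activator: str = "cAMP"
    Vmax: float = 1.0
    Khalf_uM: float = 54.22
    h: float = 1.85
    n_points: int = 12
    replicates: int = 3
    noise_frac: float = 0.03


@dataclass(frozen=True)
class StructureBlock:
    angle_deg: float = 50.0
    translation_A: float = 0.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus per-stage truth blocks; the seed is mandatory."""

    seed: int
    itc: ItcBlock = field(default_factory=ItcBlock)
    kinetics: KineticsBlock = field(default_factory=KineticsBlock)
    structure: StructureBlock = field(default_factory=StructureBlock)

    @classmethod
    def for_ligand(cls, ligand: str, seed: int) -> "GeneratorConfig":
        kt = KINETIC_TRUTH[ligand]
        return cls(
            seed=seed,
            itc=ItcBlock(truth=PUBLISHED_ITC_PARAMS[ligand]),
            kinetics=KineticsBlock(
                activator=ligand, Vmax=kt["Vmax"], Khalf_uM=kt["Khalf"], h=kt["h"]
            ),
        )


def make_itc_dataset(cfg: GeneratorConfig) -> tuple[Thermogram, TwoSetsParams]:
    """Simulate one titration under the configured protocol; returns truth too."""
    proto = TitrationProtocol(cell_conc=cfg.itc.cell_conc, syr_conc=cfg.itc.syr_conc)
    tg = simulate_titration(
        cfg.itc.truth, proto, noise_sd=cfg.itc.noise_sd_ucal, seed=cfg.seed
    )
    return tg, cfg.itc.truth


def make_kinetics_dataset(cfg: GeneratorConfig) -> tuple[ActivityDataset, dict[str, float]]:
    """Replicate Hill-model rates on the log grid; returns the truth block."""
    k = cfg.kinetics
    grid = default_grid_uM(k.n_points)
    conc = np.repeat(grid, k.replicates)
    rate = hill_model(conc, k.Vmax, k.Khalf_uM, k.h)
    if k.noise_frac > 0:
        rng = np.random.default_rng(cfg.seed)
        rate = rate * (1.0 + rng.normal(0.0, k.noise_frac, size=rate.size))
    ds = ActivityDataset(
        activator=k.activator,
        conc_uM=tuple(float(c) for c in conc),
        rate=tuple(float(r) for r in rate),
    )
    truth = {"Vmax": k.Vmax, "Khalf": k.Khalf_uM, "h": k.h}
    return ds, truth


def _ca_scaffold() -> StructureModel:
    """Deterministic two-chain Cα trace, residues 1–120 per chain.

    A coarse helical curve: non-collinear, non-planar, so every rigid-body
    superposition in the metric chain is well conditioned.
    """
    n_res = 120
    i = np.arange(1, n_res + 1, dtype=float)
    theta = np.radians(100.0) * i
    xyz_a = np.column_stack([8.0 * np.cos(theta), 8.0 * np.sin(theta), 1.5 * i])
    # chain B: the twofold partner, rotated 180 deg about z and offset in x
    flip = np.diag([-1.0, -1.0, 1.0])
    xyz_b = xyz_a @ flip.T + np.array([28.0, 0.0, 0.0])
    coords = np.vstack([xyz_a, xyz_b])
    return StructureModel(
        chain=tuple(["A"] * n_res + ["B"] * n_res),
        resnum=tuple(list(range(1, n_res + 1)) * 2),
        resname=tuple(["ALA"] * 2 * n_res),
        atom_name=tuple(["CA"] * 2 * n_res),
        coords=coords,
        label="scaffold",
        source_id="synthetic",
    )


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1.0 - np.cos(a)) * (K @ K)


def make_structure_pair(cfg: GeneratorConfig) -> tuple[StructureModel, StructureModel, float]:
    """Reference/moved Cα models related by a known body rotation.

    The chain A body (residues 6–83) of the moved state is rotated by the
    configured angle about a fixed axis through the chain A residue 81–86
    centroid (optionally translated along that axis); the stator and chain
    B are untouched. Returns (reference, moved, true angle in degrees).
    """
    angle = cfg.structure.angle_deg
    if not 0.0 <= angle < 180.0:
        raise ValueError(f"body rotation angle must be in [0, 180), got {angle}")
    ref = _ca_scaffold()
    ref = StructureModel(
        chain=ref.chain,
        resnum=ref.resnum,
        resname=ref.resname,
        atom_name=ref.atom_name,
        coords=ref.coords,
        label="apo",
        source_id="synthetic",
    )
    hinge_idx = [
        i
        for i in range(ref.n_atoms)
        if ref.chain[i] == "A" and HINGE_RANGE[0] - 3 <= ref.resnum[i] <= HINGE_RANGE[0] + 2
    ]
    # axis through the residue 81-86 centroid; fixed oblique direction
    pivot = ref.coords[hinge_idx].mean(axis=0)
    axis = np.array([1.0, 1.0, 1.0])
    R = _axis_angle_matrix(axis, angle)
    shift = cfg.structure.translation_A * axis / np.linalg.norm(axis)
    coords = ref.coords.copy()
    if angle != 0.0 or cfg.structure.translation_A != 0.0:
        body = [
            i
            for i in range(ref.n_atoms)
            if ref.chain[i] == "A" and BODY_RANGE[0] <= ref.resnum[i] <= BODY_RANGE[1]
        ]
        coords[body] = (coords[body] - pivot) @ R.T + pivot + shift
    mov = StructureModel(
        chain=ref.chain,
        resnum=ref.resnum,
        resname=ref.resname,
        atom_name=ref.atom_name,
        coords=coords,
        label="bound",
        source_id="synthetic",
    )
    return ref, mov, angle
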