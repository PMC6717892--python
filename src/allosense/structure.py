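"""Rigid-body conformational metrics for the sensor-domain swing.

The sensor dimer's ligand-driven motion is quantified without any hinge
decomposition: the C-helix dimer interface (residues 97–110 of both
chains) acts as a stator, the two states are aligned on it, and the cNMP
body (residues 6–83) of one chain is then superposed body-on-body. The
rotation angle of that second superposition is the swing angle; the
largest Cα displacement within the body after stator alignment is the
β-hairpin-type shift. Complementary probe distances — the Asp95–Ile62 Cα
distance tracking P-loop migration, and the residue 111→117 Cα distances
that discriminate domain-swapped from non-swapped chain topology — are
measured directly.

Structures are read with gemmi from mmCIF or PDB, keeping author chain and
residue numbering; alternate conformers are reduced to the
highest-occupancy one (ties keep the first encountered).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "StructureModel",
    "Selection",
    "SuperpositionResult",
    "SwingMetrics",
    "MissingAtomError",
    "PairingError",
    "FormatError",
    "read_structure",
    "write_structure",
    "superpose",
    "superpose_arrays",
    "rotation_angle",
    "ploop_distance",
    "swing_metrics",
    "swap_distances",
]

#: Default stator / body / hinge residue ranges (author numbering).
STATOR_RANGE = (97, 110)
BODY_RANGE = (6, 83)
HINGE_RANGE = (84, 95)
PLOOP_PROBE = (95, 62)  # hinge Asp95 -> small-helix Ile62, Cα
SWAP_PROBE = (111, 117)  # C-helix end -> β-extension start, Cα


class FormatError(ValueError):
    """Input file could not be parsed as a structure."""


class MissingAtomError(KeyError):
    """A selected residue lacks the requested atom."""


class PairingError(ValueError):
    """Two selections could not be resolved to paired atom lists."""


@dataclass(frozen=True)
class StructureModel:
    """A flat atom table: chain, residue number/name, atom name, xyz (Å)."""

    chain: tuple[str, ...]
    resnum: tuple[int, ...]
    resname: tuple[str, ...]
    atom_name: tuple[str, ...]
    coords: np.ndarray  # (n, 3) float
    label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.chain)
        if not (len(self.resnum) == len(self.resname) == len(self.atom_name) == n):
            raise ValueError("atom table columns must have equal length")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        keys = list(zip(self.chain, self.resnum, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom) keys")

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return tuple(seen)

    def _index(self) -> dict[tuple[str, int, str], int]:
        return {
            (c, r, a): i
            for i, (c, r, a) in enumerate(zip(self.chain, self.resnum, self.atom_name))
        }

    def ca(self, chain: str, resnum: int) -> np.ndarray:
        """Cα coordinates of one residue."""
        idx = self._index().get((chain, resnum, "CA"))
        if idx is None:
            raise MissingAtomError(
                f"no CA for residue {chain}:{resnum} in structure "
                f"'{self.label or self.source_id or 'unnamed'}'"
            )
        return self.coords[idx]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "StructureModel":
        """Apply the rigid motion x ↦ R·x + t to every atom."""
        return replace(self, coords=self.coords @ np.asarray(R).T + np.asarray(t))


@dataclass(frozen=True)
class Selection:
    """Chains, inclusive residue ranges (author numbering) and atom names."""

    chains: tuple[str, ...]
    residue_ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] = ("CA",)

    def resolve(
        self, model: StructureModel, strict: bool = False
    ) -> tuple[list[tuple[str, int, str]], np.ndarray]:
        """Ordered (key, coords) lists of the selected atoms present in ``model``.

        With ``strict=True``, any requested residue whose atom is missing
        raises :class:`MissingAtomError` listing the offenders.
        """
        index = model._index()
        keys, rows, missing = [], [], []
        for c in self.chains:
            for lo, hi in self.residue_ranges:
                for r in range(lo, hi + 1):
                    for a in self.atom_names:
                        i = index.get((c, r, a))
                        if i is None:
                            missing.append(f"{c}:{r}:{a}")
                        else:
                            keys.append((c, r, a))
                            rows.append(i)
        if strict and missing:
            raise MissingAtomError(
                f"missing atoms in '{model.label or model.source_id}': {missing}"
            )
        if not keys:
            raise MissingAtomError(
                f"selection {self} resolves to no atoms in "
                f"'{model.label or model.source_id}'"
            )
        return keys, model.coords[rows]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid motion x_mov ↦ R·x_mov + t onto the reference frame."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int


def read_structure(path, label: str = "") -> StructureModel:
    """Read an mmCIF or PDB file into a flat atom table.

    Author chain names and residue numbers are preserved; for alternate
    conformers the highest-occupancy atom wins (first on ties).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"structure file {path} contains no models")
    best: dict[tuple[str, int, str], tuple[float, int, str, np.ndarray]] = {}
    order = 0
    for chain in st[0]:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, atom.name)
                occ = float(atom.occ)
                prev = best.get(key)
                if prev is None or occ > prev[0]:
                    best[key] = (
                        occ,
                        prev[1] if prev is not None else order,
                        res.name,
                        np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    )
                order += 1
    if not best:
        raise FormatError(f"structure file {path} contains no atoms")
    items = sorted(best.items(), key=lambda kv: kv[1][1])
    return StructureModel(
        chain=tuple(k[0] for k, _ in items),
        resnum=tuple(k[1] for k, _ in items),
        resname=tuple(v[2] for _, v in items),
        atom_name=tuple(k[2] for k, _ in items),
        coords=np.array([v[3] for _, v in items]),
        label=label,
        source_id=path.stem,
    )


def write_structure(model: StructureModel, path) -> None:
    """Write the atom table as a minimal PDB file."""
    lines = []
    for i in range(model.n_atoms):
        x, y, z = model.coords[i]
        name = model.atom_name[i]
        element = name[0]
        lines.append(
            f"ATOM  {i + 1:>5} {name:^4} {model.resname[i]:>3} "
            f"{model.chain[i]:1}{model.resnum[i]:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def superpose_arrays(ref: np.ndarray, mov: np.ndarray) -> SuperpositionResult:
    """Kabsch least-squares superposition of paired coordinate sets.

    Returns the proper rotation R and translation t minimizing
    ||R·mov + t − ref|| over rigid motions.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise PairingError(f"coordinate sets {ref.shape} and {mov.shape} are not paired")
    if ref.shape[0] < 3:
        raise PairingError("need at least 3 paired atoms for superposition")
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    H = (mov - cm).T @ (ref - cr)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cr - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((mov @ R.T + t - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, n_atoms=ref.shape[0])


def superpose(
    ref: StructureModel,
    mov: StructureModel,
    ref_sel: Selection,
    mov_sel: Selection | None = None,
) -> SuperpositionResult:
    """Superpose ``mov`` onto ``ref`` using atoms common to both selections."""
    mov_sel = mov_sel or ref_sel
    ref_keys, ref_xyz = ref_sel.resolve(ref)
    mov_keys, mov_xyz = mov_sel.resolve(mov)
    if len(ref_keys) == len(mov_keys) and ref_keys == mov_keys:
        return superpose_arrays(ref_xyz, mov_xyz)
    # pair on positional correspondence when the key lists differ only by
    # chain naming; otherwise intersect on shared keys
    common = [k for k in ref_keys if k in set(mov_keys)]
    if len(common) >= 3:
        ri = {k: i for i, k in enumerate(ref_keys)}
        mi = {k: i for i, k in enumerate(mov_keys)}
        return superpose_arrays(
            ref_xyz[[ri[k] for k in common]], mov_xyz[[mi[k] for k in common]]
        )
    if len(ref_keys) == len(mov_keys):
        return superpose_arrays(ref_xyz, mov_xyz)
    raise PairingError(
        f"selections resolve to {len(ref_keys)} vs {len(mov_keys)} atoms "
        "with no usable common subset"
    )


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle in degrees, θ ∈ [0, 180].

    Computed as atan2(|sin θ|, cos θ) with cos θ = (trace R − 1)/2 and
    |sin θ| from the skew part of R, which keeps full precision near 0°
    where the plain arccos form loses half the significant digits.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not math.isclose(
        float(np.linalg.det(R)), 1.0, abs_tol=1e-8
    ):
        raise ValueError("input is not a proper orthonormal rotation")
    cos_theta = (np.trace(R) - 1.0) / 2.0
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_theta = 0.5 * np.linalg.norm(skew)
    return float(np.degrees(np.arctan2(sin_theta, cos_theta)))


def ploop_distance(s: StructureModel, chain: str) -> float:
    """Asp95–Ile62 Cα distance (Å), the P-loop migration probe."""
    a = s.ca(chain, PLOOP_PROBE[0])
    b = s.ca(chain, PLOOP_PROBE[1])
    return float(np.linalg.norm(a - b))


def swap_distances(
    s: StructureModel, chain_pair: tuple[str, str] | None = None
) -> tuple[float, float]:
    """Residue 111→117 Cα distances (same-chain, cross-chain), in Å.

    The same-chain distance corresponds to a non-swapped topology, the
    cross-chain distance to the domain swap.
    """
    if chain_pair is None:
        cs = s.chains
        if len(cs) < 2:
            raise MissingAtomError("need two chains to measure swap distances")
        chain_pair = (cs[0], cs[1])
    x, y = chain_pair
    r111, r117 = SWAP_PROBE
    same = float(np.linalg.norm(s.ca(x, r111) - s.ca(x, r117)))
    cross = float(np.linalg.norm(s.ca(x, r111) - s.ca(y, r117)))
    return same, cross


@dataclass(frozen=True)
class SwingMetrics:
    """Swing-out metrics for a pair of conformational states."""

    swing_angle_deg: float
    max_body_shift_A: float
    stator_rmsd_A: float
    body_rmsd_A: float
    ploop_A: dict = field(default_factory=dict)  # state label -> chain -> Å
    swap_A: dict = field(default_factory=dict)  # state label -> (same, cross) or None


def _probe_metrics(model: StructureModel, chains) -> tuple[dict, tuple | None]:
    ploop = {}
    for c in chains:
        try:
            ploop[c] = ploop_distance(model, c)
        except MissingAtomError:
            pass
    try:
        swap = swap_distances(model)
    except MissingAtomError:
        swap = None
    return ploop, swap


def swing_metrics(
    state_a: StructureModel,
    state_b: StructureModel,
    stator: Selection | None = None,
    body: Selection | None = None,
) -> SwingMetrics:
    """Stator-aligned swing angle and translation between two states.

    ``state_b`` is first aligned onto ``state_a`` using the stator
    selection (by default the C-helix interface, residues 97–110 of the
    first two chains); the body selection (by default residues 6–83 of the
    first chain) is then superposed body-on-body, and the rotation angle of
    that transform is the swing angle. The maximum body Cα displacement
    after stator alignment is reported as the shift.
    """
    chains_a = state_a.chains
    if stator is None:
        stator = Selection(chains=chains_a[:2], residue_ranges=(STATOR_RANGE,))
    if body is None:
        body = Selection(chains=chains_a[:1], residue_ranges=(BODY_RANGE,))

    align = superpose(state_a, state_b, stator)
    b_aligned = state_b.transformed(align.rotation, align.translation)

    body_fit = superpose(state_a, b_aligned, body)
    angle = rotation_angle(body_fit.rotation)

    keys_a, xyz_a = body.resolve(state_a)
    keys_b, xyz_b = body.resolve(b_aligned)
    if keys_a == keys_b:
        shifts = np.linalg.norm(xyz_b - xyz_a, axis=1)
    else:
        common = [k for k in keys_a if k in set(keys_b)]
        ia = {k: i for i, k in enumerate(keys_a)}
        ib = {k: i for i, k in enumerate(keys_b)}
        shifts = np.linalg.norm(
            xyz_b[[ib[k] for k in common]] - xyz_a[[ia[k] for k in common]], axis=1
        )

    label_a = state_a.label or "state_a"
    label_b = state_b.label or "state_b"
    ploop_a, swap_a = _probe_metrics(state_a, chains_a)
    ploop_b, swap_b = _probe_metrics(state_b, state_b.chains)
    return SwingMetrics(
        swing_angle_deg=angle,
        max_body_shift_A=float(np.max(shifts)),
        stator_rmsd_A=align.rmsd,
        body_rmsd_A=body_fit.rmsd,
        ploop_A={label_a: ploop_a, label_b: ploop_b},
        swap_A={label_a: swap_a, label_b: swap_b},
    )
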