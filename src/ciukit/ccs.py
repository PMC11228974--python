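"""Projection-approximation collision cross sections and trajectory metrics.

The PA CCS is the orientation-averaged area of the projection of the union
of atom disks (van der Waals radius + probe radius) onto a plane.
Orientations are sampled as uniform random rotations; each projected area is
estimated by Monte Carlo within the disks' bounding box.  The instrument-
comparable value applies a fixed empirical scale:

    CCS_CALC = 1.14 * CCS_PA        (probe radius 1.4 angstrom)

Also provided: Kabsch superposition RMSD and mass-weighted center-of-mass
distances for multi-model trajectory analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ciukit.structures import StructureModel

DEFAULT_PROBE_RADIUS = 1.4  # angstrom, gas collision radius
PA_CORRECTION = 1.14  # empirical CCS_PA -> CCS_CALC scale


class CCSError(ValueError):
    pass


@dataclass
class PACCSResult:
    ccs_pa: float  # nm^2
    ccs_calc: float  # nm^2 (= PA_CORRECTION * ccs_pa)
    n_orientations: int
    n_mc_points: int
    stderr: float  # nm^2, standard error over orientations
    probe_radius: float  # angstrom


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform rotation matrices via normalized random quaternions."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    mats = np.empty((n, 3, 3))
    mats[:, 0, 0] = 1 - 2 * (y * y + z * z)
    mats[:, 0, 1] = 2 * (x * y - z * w)
    mats[:, 0, 2] = 2 * (x * z + y * w)
    mats[:, 1, 0] = 2 * (x * y + z * w)
    mats[:, 1, 1] = 1 - 2 * (x * x + z * z)
    mats[:, 1, 2] = 2 * (y * z - x * w)
    mats[:, 2, 0] = 2 * (x * z - y * w)
    mats[:, 2, 1] = 2 * (y * z + x * w)
    mats[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return mats


def _projected_area(
    centers: np.ndarray, radii: np.ndarray, n_points: int, rng: np.random.Generator
) -> float:
    """MC estimate of the area (angstrom^2) of a union of disks in 2-D."""
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box_area = float(np.prod(hi - lo))
    pts = lo + (hi - lo) * rng.random((n_points, 2))
    inside = np.zeros(n_points, dtype=bool)
    # chunk over atoms to bound memory on large structures
    chunk = max(1, int(2e6) // max(n_points, 1))
    for start in range(0, centers.shape[0], chunk):
        c = centers[start : start + chunk]
        r = radii[start : start + chunk]
        todo = ~inside
        if not np.any(todo):
            break
        d2 = ((pts[todo, None, :] - c[None, :, :]) ** 2).sum(axis=-1)
        inside[todo] = np.any(d2 <= (r**2)[None, :], axis=1)
    return box_area * inside.mean()


def pa_ccs(
    structure: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_orientations: int = 64,
    n_mc_points: int = 4000,
    seed: int = 0,
) -> PACCSResult:
    """Projection-approximation CCS of a structure (nm^2).

    Mean over ``n_orientations`` uniformly random orientations of the MC
    projected area of the union of disks with radii atom_radius +
    ``probe_radius``.  Deterministic given ``seed``.
    """
    if structure.n_atoms < 1:
        raise CCSError("structure has no atoms")
    if n_orientations < 1 or n_mc_points < 1:
        raise CCSError("n_orientations and n_mc_points must be >= 1")
    if probe_radius < 0:
        raise CCSError("probe_radius must be non-negative")
    rng = np.random.default_rng(seed)
    radii = structure.radii + probe_radius
    coords = structure.coords - structure.coords.mean(axis=0)
    rotations = _random_rotations(n_orientations, rng)
    areas = np.empty(n_orientations)
    for i, rot in enumerate(rotations):
        projected = (coords @ rot.T)[:, :2]
        areas[i] = _projected_area(projected, radii, n_mc_points, rng)
    mean_a2 = float(areas.mean())
    stderr_a2 = (
        float(areas.std(ddof=1) / math.sqrt(n_orientations))
        if n_orientations > 1
        else 0.0
    )
    ccs_pa = mean_a2 / 100.0  # angstrom^2 -> nm^2
    return PACCSResult(
        ccs_pa=ccs_pa,
        ccs_calc=corrected_ccs_calc(ccs_pa),
        n_orientations=n_orientations,
        n_mc_points=n_mc_points,
        stderr=stderr_a2 / 100.0,
        probe_radius=probe_radius,
    )


def corrected_ccs_calc(ccs_pa: float) -> float:
    """Instrument-comparable CCS: 1.14 * CCS_PA."""
    if ccs_pa <= 0:
        raise CCSError("ccs_pa must be positive")
    return PA_CORRECTION * ccs_pa


def kabsch_rmsd(
    frame: StructureModel | np.ndarray,
    reference: StructureModel | np.ndarray,
) -> float:
    """RMSD after optimal rigid superposition (Kabsch algorithm)."""
    p = frame.coords if isinstance(frame, StructureModel) else np.asarray(frame, float)
    q = (
        reference.coords
        if isinstance(reference, StructureModel)
        else np.asarray(reference, float)
    )
    if p.shape != q.shape:
        raise CCSError("atom count mismatch between frame and reference")
    if p.shape[0] < 3:
        raise CCSError("need at least 3 atoms for superposition")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    if np.linalg.matrix_rank(np.vstack([pc, qc])) < 2:
        raise CCSError("degenerate (collinear) coordinates")
    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rot = vt.T @ correction @ u.T
    diff = (rot @ pc.T).T - qc
    return float(np.sqrt((diff**2).sum() / p.shape[0]))


def com_distance(
    structure: StructureModel,
    selection_a: str | np.ndarray,
    selection_b: str | np.ndarray,
) -> float:
    """Distance (angstrom) between mass-weighted centroids of two selections.

    Selections are label strings (matched against ``structure.labels``) or
    boolean/index masks.
    """

    def pick(sel):
        if isinstance(sel, str):
            return structure.select_label(sel)
        return structure.subset(np.asarray(sel))

    a, b = pick(selection_a), pick(selection_b)
    if a.n_atoms == 0 or b.n_atoms == 0:
        raise CCSError("empty selection")
    return float(np.linalg.norm(a.center_of_mass() - b.center_of_mass()))


def trajectory_profile(
    frames: list[StructureModel],
    reference: StructureModel,
    rmsd_selection: str | np.ndarray | None = None,
    com_selections: tuple | None = None,
    stride: int = 1,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_orientations: int = 32,
    n_mc_points: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-frame RMSD, optional ligand-protein COM distance, and CCS_CALC.

    ``stride`` subsamples frames (every stride-th frame, starting at 0).
    All frames must share the reference's atom count and ordering.
    """
    if stride < 1:
        raise CCSError("stride must be >= 1")

    def pick(st, sel):
        if sel is None:
            return st
        if isinstance(sel, str):
            return st.select_label(sel)
        return st.subset(np.asarray(sel))

    ref_sel = pick(reference, rmsd_selection)
    rows = []
    for frame_index in range(0, len(frames), stride):
        frame = frames[frame_index]
        if frame.n_atoms != reference.n_atoms:
            raise CCSError(f"frame {frame_index}: atom count mismatch with reference")
        row = {
            "frame": frame_index,
            "rmsd": kabsch_rmsd(pick(frame, rmsd_selection), ref_sel),
        }
        if com_selections is not None:
            row["com_distance"] = com_distance(frame, *com_selections)
        result = pa_ccs(
            frame,
            probe_radius=probe_radius,
            n_orientations=n_orientations,
            n_mc_points=n_mc_points,
            seed=seed + frame_index,
        )
        row["ccs_calc"] = result.ccs_calc
        row["ccs_pa"] = result.ccs_pa
        rows.append(row)
    return pd.DataFrame(rows)
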