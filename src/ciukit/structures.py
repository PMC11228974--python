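"""Atomic structure container shared by the charge-placement and CCS modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Bondi-style van der Waals radii (angstrom); fallback used for rare elements.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 1.80,
    "MG": 1.73,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}
DEFAULT_VDW_RADIUS = 1.70

# Standard atomic masses (Da), enough for protein/ligand work.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "FE": 55.845,
    "MG": 24.305,
    "ZN": 65.38,
    "NA": 22.990,
    "K": 39.098,
    "CA": 40.078,
}
DEFAULT_ATOMIC_MASS = 12.011


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_ATOMIC_MASS)


@dataclass
class StructureModel:
    """Atoms with coordinates plus optional residue/chain/selection annotations.

    Coordinates are in angstrom, masses in Da, radii in angstrom.  Annotation
    arrays are either ``None`` or aligned with ``coords`` along axis 0.
    """

    elements: np.ndarray  # (n,) str
    coords: np.ndarray  # (n, 3) float
    radii: np.ndarray | None = None  # (n,) float
    masses: np.ndarray | None = None  # (n,) float
    atom_names: np.ndarray | None = None
    res_names: np.ndarray | None = None
    res_ids: np.ndarray | None = None
    chain_ids: np.ndarray | None = None
    labels: np.ndarray | None = None  # free-form selection labels

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if self.coords.shape[0] != self.elements.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.radii is None:
            self.radii = np.array([vdw_radius(e) for e in self.elements])
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if self.masses is None:
            self.masses = np.array([atomic_mass(e) for e in self.elements])
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        for name in ("atom_names", "res_names", "res_ids", "chain_ids", "labels"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=object)
                if arr.shape[0] != self.n_atoms:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def subset(self, mask: np.ndarray) -> "StructureModel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_atoms, dtype=bool)
            idx[mask] = True
            mask = idx

        def take(arr):
            return None if arr is None else arr[mask]

        return StructureModel(
            elements=self.elements[mask],
            coords=self.coords[mask],
            radii=self.radii[mask],
            masses=self.masses[mask],
            atom_names=take(self.atom_names),
            res_names=take(self.res_names),
            res_ids=take(self.res_ids),
            chain_ids=take(self.chain_ids),
            labels=take(self.labels),
        )

    def select_label(self, label: str) -> "StructureModel":
        """Atoms whose ``labels`` entry equals *label*."""
        if self.labels is None:
            raise ValueError("structure carries no selection labels")
        return self.subset(self.labels == label)

    def center_of_mass(self) -> np.ndarray:
        total = float(self.masses.sum())
        if total <= 0:
            raise ValueError("total mass is zero")
        return (self.coords * self.masses[:, None]).sum(axis=0) / total
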