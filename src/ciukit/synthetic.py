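"""Synthetic CIU datasets with known ground truth.

Generates arrival-time-distribution (ATD) matrices over a collision-voltage
ramp for several co-isolated species, calibrant tables, and toy 3-D
structures.  Every generator is a pure function of its parameters and a seed,
so downstream stages (calibration, fingerprints, 4PL fits, chi profiles,
ejection curves) can be validated against closed-form truth.

The unfolding transition is modeled as a two-state population exchange: the
ATD at voltage v is a mixture of a compact and an extended Gaussian with
weights (1 - f) and f, where f is a logistic in v.  A species with a
ligand-ejection channel has its effective unfolding midpoint shifted by
``coupling * S(v)`` where S is the ligand survival fraction, so the extra
stabilization fades as the ligand is lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from ciukit import calibration as cal
from ciukit.structures import StructureModel


class SyntheticError(ValueError):
    pass


def make_voltage_grid(
    start: float,
    stop: float,
    step: float,
    refine_start: float | None = None,
    refine_stop: float | None = None,
    refine_step: float | None = None,
) -> np.ndarray:
    """Coarse voltage ramp with an optional refined sub-interval.

    Returns the sorted union of the coarse grid ``start..stop`` (inclusive,
    spacing ``step``) and, if given, the refined grid over
    ``refine_start..refine_stop`` with spacing ``refine_step``.
    """
    if start >= stop:
        raise SyntheticError("start must be < stop")
    if step <= 0:
        raise SyntheticError("step must be positive")
    n = int(round((stop - start) / step))
    grid = start + step * np.arange(n + 1)
    if refine_start is not None:
        if refine_step is None or refine_stop is None:
            raise SyntheticError("refinement requires start, stop and step")
        if refine_step <= 0:
            raise SyntheticError("refine_step must be positive")
        if refine_start < start or refine_stop > stop or refine_start > refine_stop:
            raise SyntheticError("refinement interval outside the coarse ramp")
        m = int(round((refine_stop - refine_start) / refine_step))
        fine = refine_start + refine_step * np.arange(m + 1)
        grid = np.union1d(np.round(grid, 9), np.round(fine, 9))
    return np.asarray(grid, dtype=float)


def unfolded_fraction(v: float, v50: float, slope: float):
    """Logistic unfolded fraction f = 1 / (1 + exp(-slope * (v - v50)))."""
    if np.any(np.asarray(slope) <= 0):
        raise SyntheticError("slope must be positive")
    return expit(slope * (np.asarray(v, dtype=float) - v50))


def survival_fraction(v: float, v50_eject: float, slope_eject: float):
    """Ligand survival S = 1 - logistic(v; v50_eject, slope_eject)."""
    return 1.0 - unfolded_fraction(v, v50_eject, slope_eject)


@dataclass
class EjectionParams:
    """Voltage-dependent ligand-loss channel and its unfolding coupling."""

    v50_eject: float  # V, 50% ejection point
    slope_eject: float  # 1/V
    coupling: float = 0.0  # V shift added to v50_unfold while ligand survives

    def __post_init__(self) -> None:
        if self.slope_eject <= 0:
            raise SyntheticError("slope_eject must be positive")


@dataclass
class SpeciesParams:
    """Generative description of one co-isolated species."""

    name: str
    ccs_compact: float  # nm^2
    ccs_extended: float  # nm^2
    v50_unfold: float  # V
    slope_unfold: float  # 1/V
    atd_width: float = 0.15  # ms, Gaussian sigma of each conformer peak
    mass: float = 43313.0  # Da (mid-size protein default)
    charge: int = 12
    ejection: EjectionParams | None = None
    replicate_v50_sd: float = 0.0  # V, between-replicate midpoint jitter

    def __post_init__(self) -> None:
        if not (self.ccs_extended > self.ccs_compact > 0):
            raise SyntheticError("require ccs_extended > ccs_compact > 0")
        if self.slope_unfold <= 0:
            raise SyntheticError("slope_unfold must be positive")
        if self.atd_width <= 0:
            raise SyntheticError("atd_width must be positive")
        if self.replicate_v50_sd < 0:
            raise SyntheticError("replicate_v50_sd must be >= 0")

    @property
    def mz(self) -> float:
        return (self.mass + self.charge * cal.PROTON_MASS) / self.charge

    def effective_v50(self, v: float) -> float:
        """Unfolding midpoint at voltage v, shifted while ligand survives."""
        if self.ejection is None:
            return self.v50_unfold
        s = survival_fraction(v, self.ejection.v50_eject, self.ejection.slope_eject)
        return self.v50_unfold + self.ejection.coupling * float(s)

    def unfolded_fraction_at(self, v: float) -> float:
        return float(unfolded_fraction(v, self.effective_v50(v), self.slope_unfold))


@dataclass
class InstrumentParams:
    """Emulated instrument settings: ramp, calibration truth, noise."""

    voltage_grid: np.ndarray = field(
        default_factory=lambda: make_voltage_grid(20, 60, 1, 42, 44, 0.5)
    )
    cal_A: float = 1.2
    cal_X: float = 1.41
    edc_coefficient: float = cal.DEFAULT_EDC_COEFFICIENT
    drift_gas_mass: float = cal.N2_MASS
    time_window: float = 14.0  # ms, ATD support [0, time_window)
    bin_width: float = 0.1  # ms
    noise_sd: float = 0.0  # relative multiplicative intensity noise
    n_replicates: int = 5

    def __post_init__(self) -> None:
        self.voltage_grid = np.asarray(self.voltage_grid, dtype=float)
        if self.voltage_grid.size < 2 or np.any(np.diff(self.voltage_grid) <= 0):
            raise SyntheticError("voltage_grid must be strictly increasing")
        if self.n_replicates < 1:
            raise SyntheticError("n_replicates must be >= 1")
        if self.bin_width <= 0 or self.time_window <= 0:
            raise SyntheticError("bin_width and time_window must be positive")
        if self.cal_A <= 0 or self.cal_X <= 0:
            raise SyntheticError("calibration truth must be positive")

    @property
    def time_bins(self) -> np.ndarray:
        """ATD bin centers in ms."""
        n = int(round(self.time_window / self.bin_width))
        return (np.arange(n) + 0.5) * self.bin_width

    def calibration_model(self) -> cal.CalibrationModel:
        return cal.CalibrationModel(
            A=self.cal_A,
            X=self.cal_X,
            edc_coefficient=self.edc_coefficient,
            drift_gas_mass=self.drift_gas_mass,
        )


@dataclass
class ArrivalTimeDistribution:
    """Intensity over arrival-time bins for one species at one voltage."""

    voltage: float
    times: np.ndarray  # ms, bin centers
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise SyntheticError("times/intensities shape mismatch")


@dataclass
class SyntheticDataset:
    species: list[SpeciesParams]
    instrument: InstrumentParams
    atds: dict[tuple[str, int, float], ArrivalTimeDistribution]
    seed: int

    @property
    def truth(self) -> dict:
        return {"species": self.species, "instrument": self.instrument}

    def atd(self, species: str, replicate: int, voltage: float) -> ArrivalTimeDistribution:
        return self.atds[(species, replicate, float(voltage))]


def _sub_rng(base_seed: int, *key: int) -> np.random.Generator:
    """Deterministic independent stream for a (species, replicate, voltage) cell."""
    seq = np.random.SeedSequence(entropy=base_seed, spawn_key=tuple(key))
    return np.random.default_rng(seq)


def simulate_atd(
    species: SpeciesParams,
    inst: InstrumentParams,
    v: float,
    seed: int,
    v50_offset: float = 0.0,
) -> ArrivalTimeDistribution:
    """One noisy bimodal ATD at collision voltage *v*.

    The compact/extended peak centers are the drift times obtained by
    inverting the instrument's calibration truth at the species' two CCS
    values; component weights are (1 - f) and f with f the effective
    unfolded fraction.  ``v50_offset`` implements between-replicate jitter.
    """
    model = inst.calibration_model()
    td_compact = cal.invert_calibration(
        model, species.ccs_compact, species.mz, species.charge, species.mass
    )
    td_extended = cal.invert_calibration(
        model, species.ccs_extended, species.mz, species.charge, species.mass
    )
    if not (0 < td_compact < inst.time_window and 0 < td_extended < inst.time_window):
        raise SyntheticError(
            "calibration truth places conformer drift times outside the ATD window"
        )
    f = float(
        unfolded_fraction(v, species.effective_v50(v) + v50_offset, species.slope_unfold)
    )
    t = inst.time_bins
    sig = species.atd_width
    intensity = (1.0 - f) * np.exp(-0.5 * ((t - td_compact) / sig) ** 2) + f * np.exp(
        -0.5 * ((t - td_extended) / sig) ** 2
    )
    if inst.noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + inst.noise_sd * rng.standard_normal(t.size))
        intensity = np.clip(intensity, 0.0, None)
    return ArrivalTimeDistribution(voltage=float(v), times=t, intensities=intensity)


def simulate_dataset(
    species_list: list[SpeciesParams],
    inst: InstrumentParams,
    seed: int,
) -> SyntheticDataset:
    """Full factorial species x replicates x voltages with derived sub-seeds."""
    if not species_list:
        raise SyntheticError("species_list must be non-empty")
    atds: dict[tuple[str, int, float], ArrivalTimeDistribution] = {}
    for i, sp in enumerate(species_list):
        for j in range(inst.n_replicates):
            if sp.replicate_v50_sd > 0:
                jitter_rng = _sub_rng(seed, i, j)
                offset = float(sp.replicate_v50_sd * jitter_rng.standard_normal())
            else:
                offset = 0.0
            for k, v in enumerate(inst.voltage_grid):
                cell_seed = int(
                    np.random.SeedSequence(entropy=seed, spawn_key=(i, j, k + 1000))
                    .generate_state(1)[0]
                )
                atds[(sp.name, j, float(v))] = simulate_atd(
                    sp, inst, float(v), cell_seed, v50_offset=offset
                )
    return SyntheticDataset(
        species=list(species_list), instrument=inst, atds=atds, seed=seed
    )


def simulate_calibrants(
    true_A: float,
    true_X: float,
    calibrant_specs: list[dict] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    edc_coefficient: float = cal.DEFAULT_EDC_COEFFICIENT,
    drift_gas_mass: float = cal.N2_MASS,
) -> list[cal.CalibrantPoint]:
    """Calibrant table whose drift times are exact inversions of a power-law
    truth, optionally perturbed by multiplicative noise."""
    if true_A <= 0:
        raise SyntheticError("true_A must be positive")
    specs = calibrant_specs if calibrant_specs is not None else cal.DEFAULT_CALIBRANTS
    model = cal.CalibrationModel(
        A=true_A,
        X=true_X,
        edc_coefficient=edc_coefficient,
        drift_gas_mass=drift_gas_mass,
    )
    rng = np.random.default_rng(seed)
    points = []
    for spec in specs:
        mz = (spec["mass"] + spec["charge"] * cal.PROTON_MASS) / spec["charge"]
        td = cal.invert_calibration(model, spec["ccs_lit"], mz, spec["charge"], spec["mass"])
        if noise_sd > 0:
            td = td * (1.0 + noise_sd * rng.standard_normal())
        points.append(
            cal.CalibrantPoint(
                name=spec["name"],
                mass=spec["mass"],
                charge=spec["charge"],
                mz=mz,
                ccs_lit=spec["ccs_lit"],
                td=float(td),
            )
        )
    return points


def simulate_structure(
    n_atoms: int,
    bond_length: float = 1.5,
    seed: int = 0,
    clash_distance: float = 1.0,
    max_retries: int = 200,
    element: str = "C",
) -> StructureModel:
    """Self-avoiding random-walk chain with fixed step length.

    Consecutive atoms are exactly ``bond_length`` apart and no two atoms come
    closer than ``clash_distance``.  Raises after ``max_retries`` failed
    placement attempts per atom.
    """
    if n_atoms < 1:
        raise SyntheticError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_atoms, 3))
    for i in range(1, n_atoms):
        for attempt in range(max_retries):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + bond_length * direction
            dists = np.linalg.norm(coords[:i] - candidate, axis=1)
            if np.all(dists[: i - 1] >= clash_distance) if i > 1 else True:
                coords[i] = candidate
                break
        else:
            raise SyntheticError(f"failed to place atom {i} after {max_retries} tries")
    return StructureModel(
        elements=np.array([element] * n_atoms, dtype=object), coords=coords
    )
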