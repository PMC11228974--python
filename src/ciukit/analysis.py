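"""CIU fingerprints, unfolding curves, 4PL fits and replicate statistics.

The central quantity is the centroid CCS of a per-voltage CCS distribution.
Plotted against collision voltage it forms an unfolding curve; a
four-parameter logistic (4PL)

    CCS(V) = L + (U - L) / (1 + exp(-h * (V - v50)))

is fitted per replicate, and the voltage required to induce chi percent of
the maximal unfolding is read off the fit in closed form:

    V_chi = v50 - (1/h) * ln(100/chi - 1)

so V_50 is exactly the fitted midpoint.  Replicate V_chi values are
aggregated as mean +/- sd and compared across species by one-way ANOVA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from ciukit import calibration as cal
from ciukit.synthetic import ArrivalTimeDistribution


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# distributions and fingerprints
# ---------------------------------------------------------------------------

@dataclass
class CCSDistribution:
    """Calibrated intensity-vs-CCS profile at one collision voltage."""

    voltage: float
    ccs_bins: np.ndarray  # nm^2, strictly increasing
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.ccs_bins = np.asarray(self.ccs_bins, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ccs_bins.shape != self.intensities.shape:
            raise AnalysisError("bins/intensities shape mismatch")
        if np.any(np.diff(self.ccs_bins) <= 0):
            raise AnalysisError("ccs_bins must be strictly increasing")
        if np.any(self.intensities < 0):
            raise AnalysisError("negative intensity")


def atd_to_ccs_distribution(
    atd: ArrivalTimeDistribution,
    model: cal.CalibrationModel,
    mz: float,
    charge: int,
    mass: float,
) -> CCSDistribution:
    """Map each arrival-time bin through the calibration; bins whose corrected
    drift time is non-positive (pre-mobility flight time) are dropped."""
    min_td = model.edc_coefficient * math.sqrt(mz) / 1000.0
    keep = atd.times > min_td
    if not np.any(keep):
        raise AnalysisError("no arrival-time bin survives the EDC correction")
    td_prime = atd.times[keep] - min_td
    mu = cal.reduced_mass(mass, model.drift_gas_mass)
    ccs = model.A * td_prime**model.X * charge / math.sqrt(mu)
    return CCSDistribution(
        voltage=atd.voltage, ccs_bins=ccs, intensities=atd.intensities[keep]
    )


def centroid_ccs(dist: CCSDistribution) -> float:
    """Intensity-weighted mean CCS (nm^2)."""
    total = dist.intensities.sum()
    if total <= 0:
        raise AnalysisError("all-zero intensities")
    return float(np.dot(dist.ccs_bins, dist.intensities) / total)


@dataclass
class FingerprintMatrix:
    voltages: np.ndarray
    ccs_bins: np.ndarray
    matrix: np.ndarray  # (n_voltages, n_bins), column (per-voltage) max = 1


def build_fingerprint(
    dists: list[CCSDistribution],
    ccs_bins: np.ndarray | None = None,
) -> FingerprintMatrix:
    """Per-voltage max-normalized CCS fingerprint on a common bin axis.

    Distributions are sorted by voltage and interpolated onto ``ccs_bins``
    (default 25-45 nm^2 at 0.1 nm^2).  Duplicate voltages are an error.
    """
    if not dists:
        raise AnalysisError("no distributions")
    voltages = np.array([d.voltage for d in dists])
    if len(np.unique(voltages)) != len(voltages):
        raise AnalysisError("duplicate voltages in fingerprint input")
    if ccs_bins is None:
        ccs_bins = np.arange(25.0, 45.0 + 1e-9, 0.1)
    ccs_bins = np.asarray(ccs_bins, dtype=float)
    order = np.argsort(voltages)
    rows = []
    for idx in order:
        d = dists[idx]
        row = np.interp(ccs_bins, d.ccs_bins, d.intensities, left=0.0, right=0.0)
        peak = row.max()
        if peak > 0:
            row = row / peak
        rows.append(row)
    return FingerprintMatrix(
        voltages=voltages[order], ccs_bins=ccs_bins, matrix=np.vstack(rows)
    )


# ---------------------------------------------------------------------------
# unfolding curves and 4PL fits
# ---------------------------------------------------------------------------

@dataclass
class UnfoldingCurve:
    """Centroid CCS vs collision voltage for one species replicate."""

    species: str
    replicate: int
    voltages: np.ndarray
    ccs: np.ndarray  # nm^2
    reference_voltage: float = 30.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.ccs = np.asarray(self.ccs, dtype=float)
        if self.voltages.shape != self.ccs.shape:
            raise AnalysisError("voltages/ccs shape mismatch")
        if len(np.unique(self.voltages)) != self.voltages.size:
            raise AnalysisError("duplicate voltages in curve")


def curve_from_distributions(
    dists: list[CCSDistribution],
    species: str = "",
    replicate: int = 0,
    reference_voltage: float = 30.0,
) -> UnfoldingCurve:
    ordered = sorted(dists, key=lambda d: d.voltage)
    return UnfoldingCurve(
        species=species,
        replicate=replicate,
        voltages=np.array([d.voltage for d in ordered]),
        ccs=np.array([centroid_ccs(d) for d in ordered]),
        reference_voltage=reference_voltage,
    )


def delta_ccs(curve: UnfoldingCurve) -> UnfoldingCurve:
    """Curve re-expressed relative to its most compact (reference) point."""
    match = np.isclose(curve.voltages, curve.reference_voltage)
    if not np.any(match):
        raise AnalysisError(
            f"reference voltage {curve.reference_voltage} V not among curve points"
        )
    ref = curve.ccs[match][0]
    return UnfoldingCurve(
        species=curve.species,
        replicate=curve.replicate,
        voltages=curve.voltages.copy(),
        ccs=curve.ccs - ref,
        reference_voltage=curve.reference_voltage,
    )


@dataclass
class FourPLFit:
    """Four-parameter logistic fit: lower/upper asymptote, midpoint, slope."""

    lower: float
    upper: float
    v50: float
    hill: float
    rss: float
    converged: bool
    message: str = ""

    def predict(self, v):
        v = np.asarray(v, dtype=float)
        return self.lower + (self.upper - self.lower) * expit(self.hill * (v - self.v50))


def _4pl(v, lower, upper, v50, hill):
    return lower + (upper - lower) * expit(hill * (v - v50))


def fit_4pl(curve: UnfoldingCurve) -> FourPLFit:
    """Least-squares 4PL fit of an unfolding curve.

    Non-convergence and degenerate (flat) inputs are reported through the
    ``converged`` flag rather than raised.
    """
    v, y = curve.voltages, curve.ccs
    if v.size < 6:
        raise AnalysisError("need at least 6 points spanning the transition")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-9 * max(1.0, abs(float(y.mean()))):
        return FourPLFit(
            lower=float(y.mean()),
            upper=float(y.mean()),
            v50=float("nan"),
            hill=float("nan"),
            rss=float(np.sum((y - y.mean()) ** 2)),
            converged=False,
            message="degenerate: no transition in data",
        )
    # initialization: half-range crossing for v50, middle 20-80% span for h
    half = y.min() + 0.5 * span
    v50_0 = float(v[np.argmin(np.abs(y - half))])
    lo_v = v[y <= y.min() + 0.2 * span]
    hi_v = v[y >= y.min() + 0.8 * span]
    width = (hi_v.min() - lo_v.max()) if (lo_v.size and hi_v.size) else np.ptp(v) / 4
    h0 = 4.0 / max(float(width), 1e-6)
    p0 = [float(y.min()), float(y.max()), v50_0, h0]
    bounds = (
        [-np.inf, -np.inf, v.min() - np.ptp(v), 1e-9],
        [np.inf, np.inf, v.max() + np.ptp(v), np.inf],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _4pl, v, y, p0=p0, bounds=bounds, maxfev=20000
            )
    except (RuntimeError, ValueError) as exc:
        return FourPLFit(
            lower=float("nan"),
            upper=float("nan"),
            v50=float("nan"),
            hill=float("nan"),
            rss=float("inf"),
            converged=False,
            message=f"fit failed: {exc}",
        )
    lower, upper, v50, hill = (float(x) for x in popt)
    if upper < lower:  # canonicalize: rising logistic with positive hill
        lower, upper, hill = upper, lower, -hill
    rss = float(np.sum((_4pl(v, lower, upper, v50, hill) - y) ** 2))
    ok = upper > lower and hill > 0 and v.min() - np.ptp(v) <= v50 <= v.max() + np.ptp(v)
    return FourPLFit(
        lower=lower,
        upper=upper,
        v50=v50,
        hill=hill,
        rss=rss,
        converged=bool(ok),
        message="" if ok else "degenerate parameter estimates",
    )


def ciu_chi(fit: FourPLFit, chi: float) -> float:
    """Voltage inducing *chi* percent of maximal unfolding (closed form)."""
    if not (0 < chi < 100):
        raise AnalysisError("chi must be in (0, 100)")
    if not fit.converged:
        raise AnalysisError("fit did not converge")
    return fit.v50 - math.log(100.0 / chi - 1.0) / fit.hill


@dataclass
class ChiProfile:
    chi_grid: np.ndarray  # percentages
    mean_v: np.ndarray  # V, mean over replicates
    sd_v: np.ndarray  # V, sd over replicates (ddof=1)
    n_replicates: int


DEFAULT_CHI_GRID = np.arange(10.0, 91.0, 10.0)


def chi_profile(
    fits: list[FourPLFit], chi_grid: np.ndarray | None = None
) -> ChiProfile:
    """Per-chi mean and sd of CIU_chi across replicate fits.

    Non-converged replicates are excluded with a warning; if all replicates
    are excluded this is an error.
    """
    if len(fits) < 2:
        raise AnalysisError("need at least 2 replicate fits")
    grid = np.asarray(chi_grid if chi_grid is not None else DEFAULT_CHI_GRID, float)
    usable = [f for f in fits if f.converged]
    if len(usable) < len(fits):
        warnings.warn(
            f"excluding {len(fits) - len(usable)} non-converged replicate(s)",
            stacklevel=2,
        )
    if not usable:
        raise AnalysisError("no converged replicate fits")
    values = np.array([[ciu_chi(f, c) for c in grid] for f in usable])
    return ChiProfile(
        chi_grid=grid,
        mean_v=values.mean(axis=0),
        sd_v=values.std(axis=0, ddof=1) if len(usable) > 1 else np.zeros(grid.size),
        n_replicates=len(usable),
    )


# ---------------------------------------------------------------------------
# species comparison
# ---------------------------------------------------------------------------

@dataclass
class SpeciesComparison:
    chi: float
    group_means: dict[str, float]
    f_stat: float
    p_value: float
    degenerate: bool = False


def anova_compare(groups: dict[str, list[float]], chi: float = 50.0) -> SpeciesComparison:
    """One-way fixed-effects ANOVA across species' replicate CIU_chi values."""
    if len(groups) < 2:
        raise AnalysisError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise AnalysisError(f"group {name!r} needs at least 2 values")
    means = {k: float(v.mean()) for k, v in arrays.items()}
    within_var = sum(float(np.var(v, ddof=1)) for v in arrays.values())
    mean_spread = float(np.ptp(list(means.values())))
    if within_var == 0.0 and mean_spread == 0.0:
        return SpeciesComparison(
            chi=chi, group_means=means, f_stat=0.0, p_value=1.0, degenerate=True
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_value = stats.f_oneway(*arrays.values())
    return SpeciesComparison(
        chi=chi,
        group_means=means,
        f_stat=float(f_stat),
        p_value=float(p_value),
        degenerate=not np.isfinite(f_stat),
    )


# ---------------------------------------------------------------------------
# ligand ejection
# ---------------------------------------------------------------------------

def ejection_fraction(bound: float, ejected: float) -> float:
    """Fraction of ions that have lost the ligand."""
    if bound < 0 or ejected < 0:
        raise AnalysisError("intensities must be non-negative")
    total = bound + ejected
    if total <= 0:
        raise AnalysisError("bound + ejected must be positive")
    return ejected / total


@dataclass
class EjectionCurve:
    voltages: np.ndarray
    fractions: np.ndarray
    v50_eject: float
    slope_eject: float
    converged: bool
    message: str = ""


def fit_ejection(voltages: np.ndarray, fractions: np.ndarray) -> EjectionCurve:
    """Rising-logistic fit of ejected fraction vs voltage."""
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(fractions, dtype=float)
    if v.size < 5:
        raise AnalysisError("need at least 5 points spanning the transition")
    if np.any((y < 0) | (y > 1)):
        raise AnalysisError("fractions must lie in [0, 1]")
    if np.ptp(y) < 1e-9:
        return EjectionCurve(
            voltages=v,
            fractions=y,
            v50_eject=float("nan"),
            slope_eject=float("nan"),
            converged=False,
            message="degenerate: constant fraction",
        )

    def logistic(x, v50, k):
        return expit(k * (x - v50))

    half_idx = int(np.argmin(np.abs(y - 0.5)))
    try:
        popt, _ = optimize.curve_fit(
            logistic, v, y, p0=[float(v[half_idx]), 1.0], maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        return EjectionCurve(
            voltages=v,
            fractions=y,
            v50_eject=float("nan"),
            slope_eject=float("nan"),
            converged=False,
            message=f"fit failed: {exc}",
        )
    v50, k = (float(x) for x in popt)
    return EjectionCurve(
        voltages=v,
        fractions=y,
        v50_eject=v50,
        slope_eject=k,
        converged=k > 0,
        message="" if k > 0 else "non-positive fitted slope",
    )


# ---------------------------------------------------------------------------
# energy conversion
# ---------------------------------------------------------------------------

def elab(voltage: float, charge: int) -> float:
    """Laboratory-frame collision energy: E_lab = z * V (eV)."""
    if charge < 1:
        raise AnalysisError("charge must be >= 1")
    return float(charge) * float(voltage)
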