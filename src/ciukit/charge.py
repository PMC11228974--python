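"""Stochastic proton placement on chargeable sites by Coulomb minimization.

A protein structure exposes a set of chargeable sites: acidic groups
(Asp, Glu side chains and the C-terminus; charge -1 when deprotonated,
0 when protonated) and basic groups (Lys, Arg, His side chains and the
N-terminus; +1 when protonated, 0 when deprotonated).  Given a target net
charge, the search randomly redistributes protons with charge-conserving
moves, greedily keeping energy-lowering configurations and restarting each
round from the incumbent best, until a full round brings no improvement.

Energies are unscreened Coulomb sums in relative units of e^2/angstrom; only
the ordering of configurations matters for placement.

An exhaustive enumeration oracle is provided for small instances.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from ciukit.structures import StructureModel

ACIDIC_RESIDUES = {"ASP", "GLU"}
BASIC_RESIDUES = {"LYS", "ARG", "HIS"}

# representative charged-group atom per residue class (configurable)
SITE_ATOMS = {
    "ASP": "CG",
    "GLU": "CD",
    "LYS": "NZ",
    "ARG": "CZ",
    "HIS": "NE2",
}


class ChargeError(ValueError):
    pass


class InfeasibleChargeError(ChargeError):
    pass


@dataclass
class ChargeSite:
    index: int
    residue_name: str
    site_class: str  # "acidic" | "basic"
    position: np.ndarray  # (3,) angstrom
    protonated: bool = False

    def __post_init__(self) -> None:
        if self.site_class not in ("acidic", "basic"):
            raise ChargeError(f"unknown site class {self.site_class!r}")
        self.position = np.asarray(self.position, dtype=float)

    def charge(self, protonated: bool | None = None) -> int:
        p = self.protonated if protonated is None else protonated
        if self.site_class == "basic":
            return 1 if p else 0
        return 0 if p else -1


@dataclass
class ProtonConfig:
    states: tuple[bool, ...]
    net_charge: int
    energy: float  # e^2 / angstrom


def site_charges(sites: list[ChargeSite], states) -> np.ndarray:
    return np.array(
        [s.charge(protonated=bool(p)) for s, p in zip(sites, states, strict=True)],
        dtype=float,
    )


def net_charge(sites: list[ChargeSite], states) -> int:
    return int(site_charges(sites, states).sum())


def find_sites(structure: StructureModel) -> list[ChargeSite]:
    """Chargeable sites of an annotated structure.

    One site per Asp/Glu/Lys/Arg/His side chain (located at the residue's
    representative charged-group atom, falling back to the residue centroid
    when that atom is absent), plus one N-terminal and one C-terminal site
    per chain.  Unknown residue codes are skipped with a warning.
    """
    import warnings

    if structure.n_atoms == 0:
        raise ChargeError("empty structure")
    if structure.res_names is None or structure.res_ids is None:
        raise ChargeError("structure lacks residue annotations")
    chains = (
        structure.chain_ids
        if structure.chain_ids is not None
        else np.array(["A"] * structure.n_atoms, dtype=object)
    )
    names = (
        structure.atom_names
        if structure.atom_names is not None
        else np.array([""] * structure.n_atoms, dtype=object)
    )

    sites: list[ChargeSite] = []
    idx = 0
    # group atoms into residues preserving file order
    seen: dict[tuple, dict] = {}
    order: list[tuple] = []
    for a in range(structure.n_atoms):
        key = (chains[a], structure.res_ids[a])
        if key not in seen:
            seen[key] = {"res": str(structure.res_names[a]), "atoms": []}
            order.append(key)
        seen[key]["atoms"].append(a)

    standard = {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }

    per_chain: dict = {}
    for key in order:
        per_chain.setdefault(key[0], []).append(key)

    for chain, keys in per_chain.items():
        known = []
        for key in keys:
            if seen[key]["res"] in standard:
                known.append(key)
            else:
                warnings.warn(
                    f"skipping unknown residue code {seen[key]['res']!r}", stacklevel=2
                )
        for pos_in_chain, key in enumerate(known):
            res = seen[key]["res"]
            atoms = seen[key]["atoms"]

            def rep_position(atom_name: str | None) -> np.ndarray:
                if atom_name is not None:
                    for a in atoms:
                        if str(names[a]) == atom_name:
                            return structure.coords[a]
                return structure.coords[atoms].mean(axis=0)

            if res in ACIDIC_RESIDUES or res in BASIC_RESIDUES:
                cls = "acidic" if res in ACIDIC_RESIDUES else "basic"
                sites.append(
                    ChargeSite(
                        index=idx,
                        residue_name=res,
                        site_class=cls,
                        position=rep_position(SITE_ATOMS.get(res)),
                    )
                )
                idx += 1
            if pos_in_chain == 0:  # N-terminus
                sites.append(
                    ChargeSite(
                        index=idx,
                        residue_name=f"{res}-Nterm",
                        site_class="basic",
                        position=rep_position("N"),
                    )
                )
                idx += 1
            if pos_in_chain == len(known) - 1:  # C-terminus
                sites.append(
                    ChargeSite(
                        index=idx,
                        residue_name=f"{res}-Cterm",
                        site_class="acidic",
                        position=rep_position("C"),
                    )
                )
                idx += 1
    if not sites:
        raise ChargeError("no chargeable sites found")
    return sites


def config_energy(sites: list[ChargeSite], states) -> float:
    """Pairwise Coulomb energy E = sum_{i<j} q_i q_j / r_ij (e^2/angstrom)."""
    q = site_charges(sites, states)
    charged = np.nonzero(q)[0]
    if charged.size < 2:
        return 0.0
    pos = np.array([sites[i].position for i in charged])
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    if np.any(dist[np.triu_indices(charged.size, k=1)] == 0):
        raise ChargeError("coincident charged sites (zero separation)")
    np.fill_diagonal(dist, np.inf)
    qc = q[charged]
    return float(0.5 * qc @ (1.0 / dist) @ qc)


@dataclass
class ChargeFeasibility:
    feasible: bool
    target: int
    n_acidic: int
    n_basic: int
    proton_counts: list[tuple[int, int]]  # (protonated basic, protonated acidic)


def solve_net_charge(sites: list[ChargeSite], target_charge: int) -> ChargeFeasibility:
    """Feasibility of a target net charge and the proton-count combinations
    (b basic protons, a acidic protons) with b - (n_acidic - a) = target."""
    n_basic = sum(1 for s in sites if s.site_class == "basic")
    n_acidic = sum(1 for s in sites if s.site_class == "acidic")
    feasible = -n_acidic <= target_charge <= n_basic
    combos = []
    if feasible:
        for b in range(n_basic + 1):
            a = target_charge - b + n_acidic
            if 0 <= a <= n_acidic:
                combos.append((b, a))
    return ChargeFeasibility(
        feasible=feasible,
        target=target_charge,
        n_acidic=n_acidic,
        n_basic=n_basic,
        proton_counts=combos,
    )


def _energy_matrix(sites: list[ChargeSite]) -> np.ndarray:
    pos = np.array([s.position for s in sites])
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, np.inf)
    off = dist[np.isfinite(dist)]
    if off.size and np.any(off == 0):
        raise ChargeError("coincident sites (zero separation)")
    return 1.0 / dist


def _total_energy(inv: np.ndarray, q: np.ndarray) -> float:
    return float(0.5 * q @ inv @ q)


def minimize_protons(
    sites: list[ChargeSite],
    target_charge: int,
    seed: int = 0,
    max_rounds: int = 50,
    moves_per_round: int | None = None,
    validate: bool = False,
) -> ProtonConfig:
    """Best-found proton placement at fixed net charge.

    Moves are charge-conserving: a proton hop between two same-class sites,
    or a paired acid/base toggle.  Energy-lowering moves are accepted
    greedily; each round restarts from the incumbent best and the search
    stops when a full round yields no improvement (or ``max_rounds``).
    Deterministic given ``seed``.  With ``validate=True`` net-charge
    conservation is asserted after every move.
    """
    feas = solve_net_charge(sites, target_charge)
    if not feas.feasible:
        raise InfeasibleChargeError(
            f"target {target_charge:+d} outside [-{feas.n_acidic}, +{feas.n_basic}]"
        )
    rng = np.random.default_rng(seed)
    n = len(sites)
    basic_idx = np.array([i for i, s in enumerate(sites) if s.site_class == "basic"])
    acidic_idx = np.array([i for i, s in enumerate(sites) if s.site_class == "acidic"])
    inv = _energy_matrix(sites)
    base_q = np.array(
        [0.0 if s.site_class == "basic" else -1.0 for s in sites]
    )  # all-deprotonated charges; protonation adds +1

    def charges(states: np.ndarray) -> np.ndarray:
        return base_q + states

    # random feasible start
    b, a = feas.proton_counts[rng.integers(len(feas.proton_counts))]
    states = np.zeros(n)
    if b:
        states[rng.choice(basic_idx, size=b, replace=False)] = 1.0
    if a:
        states[rng.choice(acidic_idx, size=a, replace=False)] = 1.0

    energy = _total_energy(inv, charges(states))
    best_states, best_energy = states.copy(), energy
    if moves_per_round is None:
        moves_per_round = max(100, 20 * n)
    patience = 3  # rounds without improvement before declaring a stable minimum

    stall = 0
    for round_no in range(max_rounds):
        states, energy = best_states.copy(), best_energy  # reseed from incumbent
        if round_no > 0:
            # kick a few random moves to escape the incumbent's basin
            for _ in range(1 + int(rng.integers(3))):
                move = _propose_move(rng, states, basic_idx, acidic_idx)
                if move is not None:
                    for i, val in move:
                        states[i] = val
            energy = _total_energy(inv, charges(states))
        improved = False
        for _ in range(moves_per_round):
            move = _propose_move(rng, states, basic_idx, acidic_idx)
            if move is None:
                continue
            trial = states.copy()
            for i, val in move:
                trial[i] = val
            trial_energy = _total_energy(inv, charges(trial))
            if validate and net_charge(sites, trial.astype(bool)) != target_charge:
                raise AssertionError("move violated net-charge conservation")
            if trial_energy < energy - 1e-15:
                states, energy = trial, trial_energy
                if energy < best_energy - 1e-15:
                    best_states, best_energy = states.copy(), energy
                    improved = True
        stall = 0 if improved else stall + 1
        if stall >= patience:
            break

    states_bool = tuple(bool(x) for x in best_states)
    return ProtonConfig(
        states=states_bool,
        net_charge=net_charge(sites, states_bool),
        energy=best_energy,
    )


def _propose_move(rng, states, basic_idx, acidic_idx):
    """One random charge-conserving move as a list of (index, new_value)."""
    kinds = []
    b_on = basic_idx[states[basic_idx] == 1] if basic_idx.size else np.array([], int)
    b_off = basic_idx[states[basic_idx] == 0] if basic_idx.size else np.array([], int)
    a_on = acidic_idx[states[acidic_idx] == 1] if acidic_idx.size else np.array([], int)
    a_off = acidic_idx[states[acidic_idx] == 0] if acidic_idx.size else np.array([], int)
    if b_on.size and b_off.size:
        kinds.append("basic_hop")
    if a_on.size and a_off.size:
        kinds.append("acidic_hop")
    if b_on.size and a_off.size:
        kinds.append("base_to_acid")
    if b_off.size and a_on.size:
        kinds.append("acid_to_base")
    if not kinds:
        return None
    kind = kinds[rng.integers(len(kinds))]
    if kind == "basic_hop":
        return [(int(rng.choice(b_on)), 0.0), (int(rng.choice(b_off)), 1.0)]
    if kind == "acidic_hop":
        return [(int(rng.choice(a_on)), 0.0), (int(rng.choice(a_off)), 1.0)]
    if kind == "base_to_acid":  # deprotonate base (-1) + protonate acid (+1)
        return [(int(rng.choice(b_on)), 0.0), (int(rng.choice(a_off)), 1.0)]
    return [(int(rng.choice(a_on)), 0.0), (int(rng.choice(b_off)), 1.0)]


def brute_force_minimum(
    sites: list[ChargeSite],
    target_charge: int,
    max_configurations: int = 2**20,
) -> ProtonConfig:
    """Exact global minimum by enumeration; ties broken by the
    lexicographically smallest state vector."""
    feas = solve_net_charge(sites, target_charge)
    if not feas.feasible:
        raise InfeasibleChargeError(
            f"target {target_charge:+d} outside [-{feas.n_acidic}, +{feas.n_basic}]"
        )
    basic_idx = [i for i, s in enumerate(sites) if s.site_class == "basic"]
    acidic_idx = [i for i, s in enumerate(sites) if s.site_class == "acidic"]
    total = sum(
        math.comb(len(basic_idx), b) * math.comb(len(acidic_idx), a)
        for b, a in feas.proton_counts
    )
    if total > max_configurations:
        raise ChargeError(
            f"{total} configurations exceed enumeration cap {max_configurations}"
        )
    inv = _energy_matrix(sites)
    base_q = np.array([0.0 if s.site_class == "basic" else -1.0 for s in sites])
    n = len(sites)
    best: tuple[float, tuple[bool, ...]] | None = None
    for b, a in feas.proton_counts:
        for b_set in itertools.combinations(basic_idx, b):
            for a_set in itertools.combinations(acidic_idx, a):
                states = np.zeros(n)
                states[list(b_set)] = 1.0
                states[list(a_set)] = 1.0
                e = _total_energy(inv, base_q + states)
                key = tuple(bool(x) for x in states)
                if (
                    best is None
                    or e < best[0] - 1e-12
                    or (abs(e - best[0]) <= 1e-12 and key < best[1])
                ):
                    best = (e, key)
    assert best is not None
    return ProtonConfig(
        states=best[1], net_charge=net_charge(sites, best[1]), energy=best[0]
    )


@dataclass
class ConvergenceBenchmark:
    energies: list[float]
    modal_states: tuple[bool, ...]
    modal_frequency: float
    frequency_table: dict[tuple[bool, ...], int]


def benchmark_convergence(
    sites: list[ChargeSite],
    target_charge: int,
    n_seeds: int,
    master_seed: int = 0,
    **kwargs,
) -> ConvergenceBenchmark:
    """Repeat the stochastic search over *n_seeds* seeds and tabulate the
    most-observed minimized configuration."""
    if n_seeds < 2:
        raise ChargeError("n_seeds must be >= 2")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds)
    energies = []
    counter: Counter = Counter()
    for s in seeds:
        cfg = minimize_protons(sites, target_charge, seed=int(s), **kwargs)
        energies.append(cfg.energy)
        counter[cfg.states] += 1
    modal_states, modal_count = counter.most_common(1)[0]
    return ConvergenceBenchmark(
        energies=energies,
        modal_states=modal_states,
        modal_frequency=modal_count / n_seeds,
        frequency_table=dict(counter),
    )
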