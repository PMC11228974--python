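"""Readers and writers for the pipeline's plain-text formats.

ATD matrices use the raw-CSV dialect common to CIU tooling: the first column
holds arrival-time bins (ms), the header row holds collision voltages, and
each remaining column is the ATD at one voltage.  Structures are standard
PDB; configuration and model serialization are YAML.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.PDB import PDBParser

from ciukit import calibration as cal
from ciukit.structures import StructureModel
from ciukit.synthetic import ArrivalTimeDistribution


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ATD matrices (raw CSV dialect)
# ---------------------------------------------------------------------------

def write_atd_matrix(path, atds: list[ArrivalTimeDistribution]) -> None:
    """One CSV per species/replicate: first column arrival time, one column
    per collision voltage."""
    if not atds:
        raise FormatError("nothing to write")
    ordered = sorted(atds, key=lambda a: a.voltage)
    times = ordered[0].times
    for a in ordered[1:]:
        if not np.array_equal(a.times, times):
            raise FormatError("ATDs do not share a bin axis")
    data = {"arrival_time_ms": times}
    for a in ordered:
        data[f"{a.voltage:g}"] = a.intensities
    pd.DataFrame(data).to_csv(path, index=False)


def read_atd_matrix(path) -> list[ArrivalTimeDistribution]:
    """Parse a raw-CSV ATD matrix; errors carry 1-based line numbers."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise FormatError(f"{path}: empty file")
    lines = text.splitlines()
    header = lines[0].split(",")
    if len(header) < 2:
        raise FormatError(f"{path}:1: need an arrival-time column plus voltages")
    try:
        voltages = [float(v) for v in header[1:]]
    except ValueError as exc:
        raise FormatError(f"{path}:1: non-numeric voltage in header ({exc})") from None
    if len(set(voltages)) != len(voltages):
        raise FormatError(f"{path}:1: duplicate voltages in header")
    n_cols = len(header)
    times, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(",")
        if len(cells) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: expected {n_cols} columns, found {len(cells)}"
            )
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        times.append(values[0])
        rows.append(values[1:])
    matrix = np.asarray(rows)
    times = np.asarray(times)
    order = np.argsort(voltages)
    if not np.array_equal(order, np.arange(len(voltages))):
        warnings.warn(f"{path}: voltages unsorted in header; sorting", stacklevel=2)
    return [
        ArrivalTimeDistribution(
            voltage=voltages[j], times=times, intensities=matrix[:, j]
        )
        for j in order
    ]


# ---------------------------------------------------------------------------
# calibrant tables
# ---------------------------------------------------------------------------

CALIBRANT_COLUMNS = ["name", "mass_da", "charge", "mz", "ccs_lit_nm2", "td_ms"]


def write_calibrant_table(path, points: list[cal.CalibrantPoint]) -> None:
    pd.DataFrame(
        [
            {
                "name": p.name,
                "mass_da": p.mass,
                "charge": p.charge,
                "mz": p.mz,
                "ccs_lit_nm2": p.ccs_lit,
                "td_ms": p.td,
            }
            for p in points
        ]
    ).to_csv(path, index=False)


def read_calibrant_table(path) -> list[cal.CalibrantPoint]:
    df = pd.read_csv(path)
    missing = [c for c in CALIBRANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        cal.CalibrantPoint(
            name=str(r["name"]),
            mass=float(r["mass_da"]),
            charge=int(r["charge"]),
            mz=float(r["mz"]),
            ccs_lit=float(r["ccs_lit_nm2"]),
            td=float(r["td_ms"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# calibration model / config (YAML)
# ---------------------------------------------------------------------------

def write_calibration_model(path, model: cal.CalibrationModel) -> None:
    payload = {
        "A": float(model.A),
        "X": float(model.X),
        "edc_coefficient": float(model.edc_coefficient),
        "drift_gas_mass": float(model.drift_gas_mass),
        "fit_r2": float(model.fit_r2),
        "residuals": [float(r) for r in np.atleast_1d(model.residuals)],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_calibration_model(path) -> cal.CalibrationModel:
    payload = yaml.safe_load(Path(path).read_text())
    return cal.CalibrationModel(
        A=payload["A"],
        X=payload["X"],
        edc_coefficient=payload.get("edc_coefficient", cal.DEFAULT_EDC_COEFFICIENT),
        drift_gas_mass=payload.get("drift_gas_mass", cal.N2_MASS),
        fit_r2=payload.get("fit_r2", float("nan")),
        residuals=np.asarray(payload.get("residuals", [])),
    )


def read_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _element_of(atom) -> str:
    elem = (atom.element or "").strip()
    if elem:
        return elem.upper()
    name = atom.get_name().strip()
    # strip leading digits (e.g. 1HB) then take the leading letter(s)
    stripped = name.lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def read_pdb(path, ligand_resnames: set[str] | None = None) -> list[StructureModel]:
    """Parse a (possibly multi-model) PDB file into StructureModel frames.

    Alternate locations: location 'A' is kept where present.  Atoms are
    labelled 'protein' or 'ligand' (HETATM or resname in *ligand_resnames*).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    frames = []
    for model in structure:
        elements, coords, names, resnames, resids, chains, labels = (
            [], [], [], [], [], [], [],
        )
        for chain in model:
            for residue in chain:
                hetflag = residue.id[0].strip()
                for atom in residue:
                    if atom.is_disordered():
                        if "A" in atom.disordered_get_id_list():
                            atom = atom.disordered_get("A")
                        else:
                            atom = atom.disordered_get_list()[0]
                    elements.append(_element_of(atom))
                    coords.append(atom.get_coord())
                    names.append(atom.get_name())
                    resnames.append(residue.get_resname())
                    resids.append(residue.id[1])
                    chains.append(chain.id)
                    is_ligand = bool(hetflag) or (
                        ligand_resnames is not None
                        and residue.get_resname() in ligand_resnames
                    )
                    labels.append("ligand" if is_ligand else "protein")
        if not elements:
            continue
        frames.append(
            StructureModel(
                elements=np.array(elements, dtype=object),
                coords=np.array(coords, dtype=float),
                atom_names=np.array(names, dtype=object),
                res_names=np.array(resnames, dtype=object),
                res_ids=np.array(resids, dtype=object),
                chain_ids=np.array(chains, dtype=object),
                labels=np.array(labels, dtype=object),
            )
        )
    if not frames:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    return frames
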