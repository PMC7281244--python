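"""File I/O and instrument conversions.

On-disk dialects: SAXS curves as 2- or 3-column ASCII ``.dat`` (Q in Å⁻¹,
dΣ/dΩ in cm⁻¹, optional 1-σ; ``#`` comments), atomic structures as PDB
(via gemmi; occupancy-weighted, altloc A preferred) or as a compact
``element,x,y,z,occupancy`` CSV, spectra and kinetic traces as CSV, fit
configurations as YAML/JSON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .saxs_models import AtomicStructure, ScatteringCurve

__all__ = [
    "InstrumentConfig",
    "q_from_angle",
    "read_saxs_dat",
    "write_saxs_dat",
    "read_pdb",
    "read_structure_csv",
    "write_structure_csv",
]


@dataclass
class InstrumentConfig:
    """Beamline geometry: X-ray wavelength λ in Å (1.54 Å for Cu Kα-energy
    beams) and sample–detector distance in m (metadata only)."""

    wavelength: float = 1.54
    sample_detector_distance: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")


def q_from_angle(two_theta, instrument: InstrumentConfig | None = None) -> np.ndarray:
    """Momentum transfer Q = 4π sin(θ)/λ for scattering angle 2θ (radians)."""
    if instrument is None:
        instrument = InstrumentConfig()
    two_theta = np.asarray(two_theta, dtype=float)
    if np.any(two_theta < 0) or np.any(two_theta >= np.pi):
        raise ValueError("scattering angle 2θ must lie in [0, π)")
    q = 4.0 * np.pi * np.sin(0.5 * two_theta) / instrument.wavelength
    return float(q) if q.ndim == 0 else q


def read_saxs_dat(path, q_unit: str = "1/angstrom") -> ScatteringCurve:
    """Read a 2- or 3-column ASCII SAXS curve.

    ``#`` comment lines are skipped; non-numeric rows raise with the line
    number.  A decreasing Q grid is sorted with a warning.  ``q_unit`` may
    be ``"1/angstrom"`` (native) or ``"1/nm"`` (converted on read).
    """
    path = Path(path)
    rows: list[list[float]] = []
    ncol = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            parts = stripped.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric data on line {lineno}: {line.rstrip()!r}"
                ) from None
            if len(vals) < 2:
                raise ValueError(
                    f"{path}: expected 2 or 3 columns on line {lineno}"
                )
            if ncol is None:
                ncol = min(len(vals), 3)
            rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    q, i = arr[:, 0], arr[:, 1]
    sigma = arr[:, 2] if ncol == 3 else None
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/angstrom":
        raise ValueError(f"unknown q_unit {q_unit!r}")
    if np.any(np.diff(q) < 0):
        warnings.warn(f"{path}: Q grid not increasing; sorting", UserWarning)
        order = np.argsort(q)
        q, i = q[order], i[order]
        sigma = sigma[order] if sigma is not None else None
    return ScatteringCurve(q=q, intensity=i, sigma=sigma, label=path.stem)


def write_saxs_dat(curve: ScatteringCurve, path) -> None:
    """Write a curve as 3- (or 2-) column ASCII with a unit header."""
    cols = [curve.q, curve.intensity]
    header = "Q[1/angstrom]  I[1/cm]"
    if curve.sigma is not None:
        cols.append(curve.sigma)
        header += "  sigma[1/cm]"
    if curve.label:
        header = f"{curve.label}\n{header}"
    np.savetxt(path, np.column_stack(cols), header=header, fmt="%.9e")


def read_pdb(
    path,
    shell_contrast: float = 0.03,
    shell_thickness: float = 3.0,
    heavy_only: bool = True,
) -> AtomicStructure:
    """Parse ATOM/HETATM records of a PDB file into an AtomicStructure.

    Occupancies are kept; for alternate locations only altloc A (or blank)
    is used; waters are dropped; hydrogens are dropped when ``heavy_only``
    (their scattering is merged into the heavy-atom form factors).
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    atoms: list[tuple[str, float, float, float, float]] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            for atom in residue:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                el = atom.element.name.upper()
                if heavy_only and el == "H":
                    continue
                atoms.append(
                    (el, atom.pos.x, atom.pos.y, atom.pos.z, atom.occ)
                )
    if not atoms:
        raise ValueError(f"{path}: no usable ATOM/HETATM records")
    return AtomicStructure(
        atoms=atoms, shell_contrast=shell_contrast, shell_thickness=shell_thickness
    )


def read_structure_csv(
    path, shell_contrast: float = 0.03, shell_thickness: float = 3.0
) -> AtomicStructure:
    """Read the compact ``element,x,y,z,occupancy`` coordinate CSV."""
    atoms = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.lower().startswith("element"):
                continue
            parts = s.split(",")
            if len(parts) < 4:
                raise ValueError(f"{path}: expected >= 4 fields on line {lineno}")
            occ = float(parts[4]) if len(parts) > 4 else 1.0
            atoms.append(
                (parts[0].strip().upper(), float(parts[1]), float(parts[2]),
                 float(parts[3]), occ)
            )
    if not atoms:
        raise ValueError(f"{path}: no atom rows")
    return AtomicStructure(
        atoms=atoms, shell_contrast=shell_contrast, shell_thickness=shell_thickness
    )


def write_structure_csv(structure: AtomicStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write("element,x,y,z,occupancy\n")
        for el, x, y, z, occ in structure.atoms:
            fh.write(f"{el},{x:.3f},{y:.3f},{z:.3f},{occ:.2f}\n")
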