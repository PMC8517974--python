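"""Readers/writers for the coordinate and log formats the pipeline touches.

Coordinate carriers are multi-model PDB (fixed-width, 1e-3 Å round-trip) and
XYZ (free precision, exact round-trip).  Atom labelling convention:

* metal sites: element Zn, atom name ``ZN``, residue name ``ZNB``, atom id
  ``Zn<resid>``;
* Cys S-gamma ligands: element S, atom name ``SG``, residue name ``CYS``,
  atom id ``SG<resid>`` with resid the 1-based residue index.

PLUMED-style HILLS/COLVAR text files carry a ``#! FIELDS ...`` header line
followed by whitespace-delimited columns.  SMD force logs are CSV with
columns ``time_ns, extension_A, force_pN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TrajectoryFormatError, ValidationError

__all__ = [
    "AtomLabel",
    "Trajectory",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz",
    "write_xyz",
    "read_force_log",
    "write_force_log",
    "read_plumed_table",
    "write_plumed_table",
]


@dataclass(frozen=True)
class AtomLabel:
    """Identity of one labelled atom: stable id, 1-based residue index,
    element symbol."""

    atom_id: str
    residue_index: int
    element: str


@dataclass
class Trajectory:
    """Time-ordered frames of labelled coordinates (Å)."""

    atoms: list[AtomLabel]
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValidationError("atom label count does not match coordinates")
        if self.times is None:
            self.times = np.arange(self.coords.shape[0], dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.times.shape != (self.coords.shape[0],):
            raise ValidationError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_index(self, atom_id: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.atom_id == atom_id:
                return i
        raise ValidationError(f"atom id {atom_id!r} not in trajectory")


def _label_to_pdb_fields(a: AtomLabel) -> tuple[str, str, int]:
    """(atom name, residue name, resid) for our labelling convention.

    Metals carry the numeric part of their id as resid so ids survive the
    PDB round trip (``Zn3`` -> resid 3 / resname ZNB)."""
    if a.element.capitalize() == "Zn":
        digits = "".join(ch for ch in a.atom_id if ch.isdigit())
        return "ZN", "ZNB", int(digits) if digits else a.residue_index
    return "SG", "CYS", a.residue_index


def _label_from_pdb_fields(name: str, resname: str, resid: int) -> AtomLabel:
    if resname.strip() == "ZNB" or name.strip() == "ZN":
        return AtomLabel(f"Zn{resid}", resid, "Zn")
    return AtomLabel(f"SG{resid}", resid, "S")


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL framing, occupancy/B zero)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n = traj.n_atoms
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    names, resnames, resids = [], [], []
    for a in traj.atoms:
        nm, rn, ri = _label_to_pdb_fields(a)
        names.append(nm)
        resnames.append(rn)
        resids.append(ri)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    u.load_new(traj.coords.copy(), format=MemoryReader, order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _validate_pdb_models(path: str | Path) -> None:
    """Pre-pass: every MODEL must carry the same number of atom records."""
    counts: list[int] = []
    current: int | None = None
    model_no = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                model_no += 1
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                    model_no = max(model_no, 1)
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current is not None:
        counts.append(current)
    if counts and len(set(counts)) > 1:
        bad = next(i + 1 for i, c in enumerate(counts) if c != counts[0])
        raise TrajectoryFormatError(
            f"model {bad} has {counts[bad - 1]} atoms, expected {counts[0]}"
        )


def read_multimodel_pdb(path: str | Path) -> Trajectory:
    """Read a multi-model PDB written under the package convention."""
    import MDAnalysis as mda

    _validate_pdb_models(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        atoms = [
            _label_from_pdb_fields(nm, rn, int(ri))
            for nm, rn, ri in zip(u.atoms.names, u.atoms.resnames, u.atoms.resids)
        ]
        coords = np.array([ts.positions.copy() for ts in u.trajectory], dtype=float)
    return Trajectory(atoms=atoms, coords=coords)


def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write an XYZ trajectory; the name column carries the atom id verbatim
    and coordinates are printed at full double precision (exact round-trip)."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f} time {float(traj.times[f])!r}\n")
            for a, xyz in zip(traj.atoms, traj.coords[f]):
                fh.write(
                    f"{a.atom_id} {float(xyz[0])!r} {float(xyz[1])!r} "
                    f"{float(xyz[2])!r}\n"
                )


def read_xyz(path: str | Path) -> Trajectory:
    """Read an XYZ trajectory written by :func:`write_xyz` (atom ids in the
    name column; ``Zn*`` names are metals, ``SG<resid>`` names are ligands)."""
    frames: list[np.ndarray] = []
    atoms: list[AtomLabel] | None = None
    times: list[float] = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"line {lineno}: expected atom count, got {header!r}"
                ) from exc
            comment = fh.readline()
            lineno += 1
            t = None
            parts = comment.split()
            if "time" in parts:
                try:
                    t = float(parts[parts.index("time") + 1])
                except (IndexError, ValueError):
                    t = None
            times.append(t if t is not None else float(len(frames)))
            frame_atoms: list[AtomLabel] = []
            xyz = np.empty((n, 3), dtype=float)
            for i in range(n):
                line = fh.readline()
                lineno += 1
                cols = line.split()
                if len(cols) < 4:
                    raise TrajectoryFormatError(f"line {lineno}: malformed XYZ record")
                aid = cols[0]
                xyz[i] = [float(c) for c in cols[1:4]]
                digits = "".join(ch for ch in aid if ch.isdigit())
                resid = int(digits) if digits else i + 1
                elem = "Zn" if aid.lower().startswith("zn") else "S"
                frame_atoms.append(AtomLabel(aid, resid, elem))
            if atoms is None:
                atoms = frame_atoms
            elif [a.atom_id for a in atoms] != [a.atom_id for a in frame_atoms]:
                raise TrajectoryFormatError(
                    f"frame {len(frames)}: atom labels differ from first frame"
                )
            frames.append(xyz)
    if not frames or atoms is None:
        raise TrajectoryFormatError(f"no frames found in {path}")
    return Trajectory(atoms=atoms, coords=np.array(frames), times=np.array(times))


def write_force_log(df: pd.DataFrame, path: str | Path) -> None:
    """Write an SMD force log (CSV: time_ns, extension_A, force_pN)."""
    missing = {"time_ns", "extension_A", "force_pN"} - set(df.columns)
    if missing:
        raise ValidationError(f"force log missing columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_force_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"time_ns", "extension_A", "force_pN"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: force log missing columns {sorted(missing)}")
    return df


def write_plumed_table(path: str | Path, fields: Sequence[str],
                       data: np.ndarray) -> None:
    """Write a PLUMED-style table: '#! FIELDS ...' header then columns."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[1] != len(fields):
        raise ValidationError("field count does not match data columns")
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        np.savetxt(fh, data, fmt="%.10g")


def read_plumed_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a PLUMED-style table; returns (field names, data array)."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#!"):
            raise TrajectoryFormatError(f"{path}: missing '#! FIELDS' header")
        tokens = header.split()
        if len(tokens) < 3 or tokens[1] != "FIELDS":
            raise TrajectoryFormatError(f"{path}: malformed FIELDS header")
        fields = tokens[2:]
        data = np.loadtxt(fh, ndmin=2)
    if data.size and data.shape[1] != len(fields):
        raise TrajectoryFormatError(f"{path}: column count does not match header")
    return fields, data
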