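"""Core data model for coordinate trajectories.

Holds atoms, frames and trajectories; reads and writes fixed-column GRO
(multi-frame concatenated) and simple XYZ; provides the minimum-image
displacement that every distance-based analysis builds on.

All internal lengths are nanometres; times are picoseconds; masses are
atomic mass units. Boxes are orthorhombic (three edge lengths); triclinic
input is rejected rather than silently truncated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "SpeciesMap",
    "ParseError",
    "UnsupportedFormatError",
    "ConfigurationError",
    "read_gro",
    "write_gro",
    "read_xyz",
    "minimum_image",
    "wrap_positions",
    "assign_species",
    "infer_mass",
]

SPECIES = ("Surf", "Ch", "Cl", "HBD", "CounterIon", "Other")
SITE_ROLES = (
    "head",
    "tail",
    "bend_center",
    "donor_heavy",
    "donor_hydrogen",
    "acceptor",
    "none",
)

# Masses (amu) keyed on the first alphabetic character of the atom name.
# Two-letter elements (Cl, Na, Br...) need an explicit SpeciesMap override.
_ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
}


class ParseError(ValueError):
    """A coordinate file violates its format contract."""


class UnsupportedFormatError(ValueError):
    """A file is syntactically valid but uses an unsupported dialect."""


class ConfigurationError(ValueError):
    """A selection/species configuration is inconsistent with the data."""


def infer_mass(atom_name: str) -> float:
    """Guess an atomic mass from the first alphabetic character of a name.

    'C12' -> carbon, 'HY' -> hydrogen.  Unknown leading characters raise;
    supply an explicit mass through the SpeciesMap for those atoms.
    """
    for ch in atom_name:
        if ch.isalpha():
            key = ch.upper()
            if key in _ELEMENT_MASSES:
                return _ELEMENT_MASSES[key]
            raise ConfigurationError(
                f"cannot infer element/mass for atom name {atom_name!r}; "
                "provide a mass override in the species map"
            )
    raise ConfigurationError(f"atom name {atom_name!r} has no alphabetic character")


@dataclass(frozen=True)
class Atom:
    index: int
    atom_name: str
    residue_name: str
    residue_id: int
    mass: float
    species: str = "Other"
    site_role: str = "none"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name}: mass must be > 0, got {self.mass}")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species category {self.species!r}")
        if self.site_role not in SITE_ROLES:
            raise ValueError(f"unknown site role {self.site_role!r}")


@dataclass
class Frame:
    """One snapshot: (N, 3) coordinates in nm, orthorhombic box edges, time in ps."""

    coords: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if np.any(self.box <= 0):
            raise ValueError(f"box edges must be > 0, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    topology: list[Atom]
    frames: list[Frame]
    # optional unwrapped coordinate channel (n_frames, n_atoms, 3), used by MSD
    unwrapped: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = len(self.topology)
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(
                    f"frame {i} has {fr.n_atoms} coordinates for {n} topology atoms"
                )
        times = [fr.time for fr in self.frames]
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def masses(self, selection: Optional[Sequence[int]] = None) -> np.ndarray:
        atoms = self.topology if selection is None else [self.topology[i] for i in selection]
        return np.array([a.mass for a in atoms])

    def select(self, species: Optional[str] = None, atom_name: Optional[str] = None,
               residue_name: Optional[str] = None, site_role: Optional[str] = None) -> np.ndarray:
        """Indices of atoms matching all given attribute filters."""
        out = []
        for a in self.topology:
            if species is not None and a.species != species:
                continue
            if atom_name is not None and a.atom_name != atom_name:
                continue
            if residue_name is not None and a.residue_name != residue_name:
                continue
            if site_role is not None and a.site_role != site_role:
                continue
            out.append(a.index)
        return np.array(out, dtype=int)

    def molecule_ids(self) -> np.ndarray:
        """Residue id per atom — the molecule identity convention."""
        return np.array([a.residue_id for a in self.topology], dtype=int)


# ---------------------------------------------------------------------------
# periodic geometry


def minimum_image(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a, each component wrapped into (-L/2, L/2].

    Accepts broadcastable arrays of points; the exact boundary maps to +L/2.
    """
    box = np.asarray(box, dtype=float)
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - box * np.ceil(d / box - 0.5)


def wrap_positions(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the primary cell [0, L)."""
    box = np.asarray(box, dtype=float)
    return np.mod(coords, box)


# ---------------------------------------------------------------------------
# GRO reader / writer

_GRO_BOX_TOL = 1e-9


def _parse_gro_time(title: str) -> Optional[float]:
    m = re.search(r"t=\s*([-+0-9.eE]+)", title)
    if m:
        try:
            return float(m.group(1))
        except ValueError:
            return None
    return None


def read_gro(path: str | Path, multi_frame: bool = True,
             species_map: "Optional[SpeciesMap]" = None) -> Trajectory:
    """Read a (possibly multi-frame concatenated) fixed-column GRO file.

    Velocities are ignored.  Masses come from element inference on the atom
    name, overridable through a species map.  Frames without a ``t=`` tag in
    the title line get times 0, 1, 2, ... ps.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[Frame] = []
    topology: Optional[list[Atom]] = None
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip() and pos + 1 >= len(lines):
            break  # trailing blank line
        title = lines[pos]
        if pos + 1 >= len(lines):
            raise ParseError(f"{path}: truncated frame at line {pos + 1}")
        try:
            natoms = int(lines[pos + 1].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}: expected atom count at line {pos + 2}, got {lines[pos + 1]!r}"
            ) from exc
        body_start = pos + 2
        box_line_idx = body_start + natoms
        if box_line_idx >= len(lines):
            raise ParseError(
                f"{path}: truncated frame at line {len(lines)}; header at line "
                f"{pos + 2} promises {natoms} atoms"
            )
        coords = np.empty((natoms, 3))
        atoms: list[Atom] = []
        for i in range(natoms):
            ln = lines[body_start + i]
            if len(ln) < 44:
                raise ParseError(
                    f"{path}: line {body_start + i + 1} too short for a GRO record"
                )
            try:
                resid = int(ln[0:5])
                resname = ln[5:10].strip()
                name = ln[10:15].strip()
                x = float(ln[20:28])
                y = float(ln[28:36])
                z = float(ln[36:44])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: malformed GRO record at line {body_start + i + 1}"
                ) from exc
            coords[i] = (x, y, z)
            if topology is None:
                mass = None
                if species_map is not None:
                    mass = species_map.mass_override(resname, name)
                atoms.append(
                    Atom(index=i, atom_name=name, residue_name=resname,
                         residue_id=resid, mass=mass if mass else infer_mass(name))
                )
        box_fields = lines[box_line_idx].split()
        if len(box_fields) not in (3, 9):
            raise ParseError(
                f"{path}: box line {box_line_idx + 1} must have 3 or 9 numbers"
            )
        vals = [float(v) for v in box_fields]
        if len(vals) == 9 and any(abs(v) > _GRO_BOX_TOL for v in vals[3:]):
            raise UnsupportedFormatError(
                f"{path}: triclinic box at line {box_line_idx + 1} is not supported"
            )
        box = np.array(vals[:3])
        t = _parse_gro_time(title)
        frames.append(Frame(coords=coords, box=box, time=float(frame_no) if t is None else t))
        if topology is None:
            topology = atoms
        frame_no += 1
        pos = box_line_idx + 1
        if not multi_frame:
            break
    if topology is None:
        raise ParseError(f"{path}: no frames found")
    traj = Trajectory(topology=topology, frames=frames)
    if species_map is not None:
        traj = assign_species(traj, species_map)
    return traj


def write_gro(traj: Trajectory, path: str | Path, title: str = "micellekit") -> None:
    """Write a trajectory as concatenated fixed-column GRO blocks (%8.3f positions)."""
    path = Path(path)
    out = []
    for fr in traj.frames:
        out.append(f"{title} t= {fr.time:.4f}\n")
        out.append(f"{traj.n_atoms:5d}\n")
        for a, (x, y, z) in zip(traj.topology, fr.coords):
            out.append(
                f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}{a.atom_name:>5.5s}"
                f"{(a.index + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        out.append(f"{fr.box[0]:10.5f}{fr.box[1]:10.5f}{fr.box[2]:10.5f}\n")
    path.write_text("".join(out))


# ---------------------------------------------------------------------------
# XYZ reader


def read_xyz(path: str | Path, box: Optional[Sequence[float]] = None) -> Trajectory:
    """Read (multi-frame) XYZ with coordinates in Angstrom, converted to nm.

    XYZ carries no box; pass one (in nm) if periodic analyses will follow,
    otherwise a generous dummy box bounding the coordinates is attached and
    PBC-requiring analyses will be geometrically meaningless.
    A comment line containing ``t= <val>`` sets the frame time in ps.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos = 0
    frames: list[Frame] = []
    topology: Optional[list[Atom]] = None
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"{path}: expected atom count at line {pos + 1}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        if pos + 2 + natoms > len(lines):
            raise ParseError(
                f"{path}: count line {pos + 1} promises {natoms} atoms but the file ends early"
            )
        coords = np.empty((natoms, 3))
        atoms: list[Atom] = []
        for i in range(natoms):
            fields = lines[pos + 2 + i].split()
            if len(fields) < 4:
                raise ParseError(f"{path}: malformed XYZ record at line {pos + 3 + i}")
            name = fields[0]
            coords[i] = [float(v) / 10.0 for v in fields[1:4]]  # Angstrom -> nm
            if topology is None:
                atoms.append(Atom(index=i, atom_name=name, residue_name="MOL",
                                  residue_id=1, mass=infer_mass(name)))
        t = _parse_gro_time(comment)
        if box is None:
            lo, hi = coords.min(axis=0), coords.max(axis=0)
            fbox = np.maximum(hi - lo, 1.0) * 10.0  # effectively non-periodic
        else:
            fbox = np.asarray(box, dtype=float)
        frames.append(Frame(coords=coords, box=fbox,
                            time=float(frame_no) if t is None else t))
        if topology is None:
            topology = atoms
        frame_no += 1
        pos += 2 + natoms
    if topology is None:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(topology=topology, frames=frames)


# ---------------------------------------------------------------------------
# species assignment


@dataclass
class SpeciesMap:
    """Rules mapping (residue_name, atom_name) to (species, site_role, mass).

    ``rules[res][atom]`` is a dict with optional keys ``species``,
    ``site_role`` and ``mass``.  An atom key of ``"*"`` is a per-residue
    default applied to atoms without an explicit rule.
    """

    rules: dict[str, dict[str, dict]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesMap":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: species map must be a mapping")
        rules = data.get("species_map", data)
        norm: dict[str, dict[str, dict]] = {}
        for res, atoms in rules.items():
            if not isinstance(atoms, dict):
                raise ConfigurationError(f"{path}: residue {res!r} entry must be a mapping")
            norm[str(res)] = {}
            for atom, rule in atoms.items():
                if rule is None:
                    rule = {}
                if not isinstance(rule, dict):
                    raise ConfigurationError(
                        f"{path}: rule for {res}/{atom} must be a mapping"
                    )
                sp = rule.get("species", "Other")
                if sp not in SPECIES:
                    raise ConfigurationError(
                        f"{path}: {res}/{atom}: unknown species {sp!r}"
                    )
                role = rule.get("site_role", "none")
                if role not in SITE_ROLES:
                    raise ConfigurationError(
                        f"{path}: {res}/{atom}: unknown site_role {role!r}"
                    )
                norm[str(res)][str(atom)] = {
                    "species": sp,
                    "site_role": role,
                    "mass": rule.get("mass"),
                }
        return cls(rules=norm)

    def to_yaml(self, path: str | Path) -> None:
        clean = {
            res: {atom: {k: v for k, v in rule.items() if v not in (None, "none")}
                  for atom, rule in atoms.items()}
            for res, atoms in self.rules.items()
        }
        Path(path).write_text(yaml.safe_dump({"species_map": clean}, sort_keys=False))

    def lookup(self, residue_name: str, atom_name: str) -> Optional[dict]:
        res = self.rules.get(residue_name)
        if res is None:
            return None
        return res.get(atom_name, res.get("*"))

    def mass_override(self, residue_name: str, atom_name: str) -> Optional[float]:
        rule = self.lookup(residue_name, atom_name)
        return None if rule is None else rule.get("mass")


def assign_species(traj: Trajectory, smap: SpeciesMap, permissive: bool = False) -> Trajectory:
    """Label every atom with its species and site role from the map.

    Unmapped atoms are an error unless ``permissive``, in which case they
    become species ``Other``.
    """
    missing = []
    new_atoms = []
    for a in traj.topology:
        rule = smap.lookup(a.residue_name, a.atom_name)
        if rule is None:
            if not permissive:
                key = (a.residue_name, a.atom_name)
                if key not in missing:
                    missing.append(key)
            new_atoms.append(replace(a, species="Other", site_role="none"))
            continue
        mass = rule.get("mass") or a.mass
        new_atoms.append(
            replace(a, species=rule["species"], site_role=rule["site_role"], mass=mass)
        )
    if missing:
        keys = ", ".join(f"{r}/{n}" for r, n in missing)
        raise ConfigurationError(
            f"species map does not cover: {keys} (set permissive=True to label them Other)"
        )
    return Trajectory(topology=new_atoms, frames=traj.frames, unwrapped=traj.unwrapped)
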