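"""Shared containers, file I/O, and coordinate conventions.

Conventions used throughout the package:

* lengths in Å, times in ns, voltages in mV, electric fields in mV/Å,
  currents in pA, conductances in pS, energies in kcal/mol;
* the channel axis is +z with the extracellular side at +z, so "outward"
  means motion from −z to +z and outward cation current is positive;
* the transmembrane potential of a fixed-field simulation is
  ΔV_m = E_z · L_z with L_z the z box length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ionflux")

#: Elementary charge in coulomb.
E_CHARGE = 1.602176634e-19
#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Bondi-style van der Waals radii (Å).  Used whenever a structure file does
#: not carry radii of its own; user-overridable via ``load_structure(radii=...)``.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "NA": 2.27, "K": 2.75,
    "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 2.05, "SE": 1.90, "B": 1.92,
}
DEFAULT_VDW = 1.70

#: Column order of the tabular trajectory dialect (CSV, one row per
#: ion per frame, frames grouped together and time-ordered).
TABULAR_COLUMNS = ["frame", "time_ns", "ion_id", "x", "y", "z", "Lx", "Ly", "Lz"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """A static set of atoms with van der Waals radii.

    Parameters
    ----------
    positions : (N, 3) array, Å
    labels : (N,) array of element or atom-name strings
    radii : (N,) array of vdW radii, Å
    subunits : optional (N,) array of subunit (chain) labels
    """

    positions: np.ndarray
    labels: np.ndarray
    radii: np.ndarray
    subunits: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.labels = np.asarray(self.labels)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        n = len(self.positions)
        if n < 1:
            raise ValueError("AtomSet needs at least one atom")
        if len(self.labels) != n or len(self.radii) != n:
            raise ValueError("labels/radii length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if np.any(self.radii <= 0):
            raise ValueError("all vdW radii must be positive")
        if self.subunits is not None:
            self.subunits = np.asarray(self.subunits)
            if len(self.subunits) != n:
                raise ValueError("subunits length mismatch")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class IonTrajectory:
    """Time-ordered ion coordinates with a periodic orthorhombic box.

    ``positions`` holds the raw (wrapped) coordinates as stored on disk;
    ``unwrapped`` is derived at construction by minimal-image unwrapping of
    each ion independently, so that the displacement between consecutive
    frames never exceeds half a box length in any dimension.

    Shapes: ``times`` (F,), ``box`` (F, 3), ``positions`` (n_ions, F, 3).
    """

    times: np.ndarray
    box: np.ndarray
    positions: np.ndarray
    ion_ids: np.ndarray
    z_ion: int = 1
    species: str = "NA"
    unwrapped: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.ion_ids = np.asarray(self.ion_ids)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.box.shape != (len(self.times), 3):
            raise ValueError("box must be (F, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (len(self.times), 3):
            raise ValueError(
                "positions must be (n_ions, F, 3); every ion must be present "
                "in every frame"
            )
        if len(self.ion_ids) != self.positions.shape[0]:
            raise ValueError("ion_ids length mismatch")
        self.unwrapped = unwrap_positions(self.positions, self.box)

    @property
    def n_ions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Total simulated time spanned by the trajectory, ns."""
        return float(self.times[-1] - self.times[0])

    # -- tabular dialect ----------------------------------------------------

    def to_tabular(self, path) -> None:
        """Write the raw (wrapped) coordinates in the CSV tabular dialect."""
        n_ions, n_frames = self.positions.shape[:2]
        frames = np.repeat(np.arange(n_frames), n_ions)
        rows = {
            "frame": frames,
            "time_ns": np.repeat(self.times, n_ions),
            "ion_id": np.tile(self.ion_ids, n_frames),
            "x": self.positions[:, :, 0].T.ravel(),
            "y": self.positions[:, :, 1].T.ravel(),
            "z": self.positions[:, :, 2].T.ravel(),
            "Lx": np.repeat(self.box[:, 0], n_ions),
            "Ly": np.repeat(self.box[:, 1], n_ions),
            "Lz": np.repeat(self.box[:, 2], n_ions),
        }
        pd.DataFrame(rows, columns=TABULAR_COLUMNS).to_csv(path, index=False)

    @classmethod
    def from_tabular(cls, path, z_ion: int = 1, species: str = "NA") -> "IonTrajectory":
        df = pd.read_csv(path)
        missing = [c for c in TABULAR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"tabular trajectory missing columns: {missing}")
        frames = np.sort(df["frame"].unique())
        ions = df[df["frame"] == frames[0]]["ion_id"].to_numpy()
        n_frames, n_ions = len(frames), len(ions)
        if len(df) != n_frames * n_ions:
            raise ValueError("frame/ion count mismatch: every ion must appear "
                             "exactly once in every frame")
        df = df.sort_values(["frame", "ion_id"], kind="stable")
        ions_sorted = np.sort(ions)
        pos = df[["x", "y", "z"]].to_numpy().reshape(n_frames, n_ions, 3)
        pos = np.transpose(pos, (1, 0, 2))
        per_frame = df.drop_duplicates("frame").sort_values("frame")
        times = per_frame["time_ns"].to_numpy()
        box = per_frame[["Lx", "Ly", "Lz"]].to_numpy()
        return cls(times=times, box=box, positions=pos, ion_ids=ions_sorted,
                   z_ion=z_ion, species=species)


@dataclass
class ChannelGeometry:
    """Idealized channel geometry used by event detection and classification.

    The transmembrane gate is the slab between ``z_lower`` and ``z_upper``;
    a permeation event is a full traversal of that slab inside the pore
    cylinder of radius ``r_pore``.  Above the gate sits the extracellular
    vestibule (band ``[z_vest_lo, z_vest_hi]``, radius ``r_vest``), which
    communicates with the extracellular bulk through an apical aperture of
    radius ``r_apical`` at height ``z_apical`` and through ``n_sectors``
    lateral fenestrations in the band ``[z_fen_lo, z_fen_hi]`` beyond inner
    radius ``r_fen``.
    """

    z_lower: float = -20.0
    z_upper: float = 0.0
    r_pore: float = 5.0
    z_vest_lo: float = 2.0
    z_vest_hi: float = 24.0
    r_vest: float = 12.0
    z_apical: float = 28.0
    r_apical: float = 4.0
    z_fen_lo: float = 8.0
    z_fen_hi: float = 18.0
    r_fen: float = 12.0
    wall_thickness: float = 4.0
    n_sectors: int = 5
    sector_phase: float = 0.0
    axis_origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.z_lower < self.z_upper < self.z_vest_lo < self.z_vest_hi):
            raise ValueError("need z_lower < z_upper < z_vest_lo < z_vest_hi")
        for name in ("r_pore", "r_vest", "r_apical", "r_fen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_sectors < 1:
            raise ValueError("n_sectors must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelGeometry":
        return cls(**d)

    def radial(self, positions: np.ndarray) -> np.ndarray:
        """Distance from the channel axis (Å) for (..., 3) positions."""
        dx = positions[..., 0] - self.axis_origin[0]
        dy = positions[..., 1] - self.axis_origin[1]
        return np.hypot(dx, dy)

    def azimuth(self, positions: np.ndarray) -> np.ndarray:
        """Azimuth about the channel axis in [0, 2π)."""
        dx = positions[..., 0] - self.axis_origin[0]
        dy = positions[..., 1] - self.axis_origin[1]
        return np.mod(np.arctan2(dy, dx), 2.0 * np.pi)


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def unwrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap per-ion coordinates so consecutive displacements are minimal-image.

    Parameters
    ----------
    positions : (n_ions, F, 3) wrapped coordinates
    box : (F, 3) box lengths per frame
    """
    positions = np.asarray(positions, dtype=float)
    disp = np.diff(positions, axis=1)
    b = box[1:][None, :, :]
    disp -= b * np.round(disp / b)
    out = np.empty_like(positions)
    out[:, 0] = positions[:, 0]
    np.cumsum(disp, axis=1, out=disp)
    out[:, 1:] = positions[:, [0]] + disp
    return out


def wrap_positions(positions: np.ndarray, box: np.ndarray,
                   center: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Wrap coordinates into the primary box centred on ``center``."""
    box = np.asarray(box, dtype=float)
    if box.ndim == 1:
        box = box[None, :]
    b = box[None, :, :] if positions.ndim == 3 else box
    c = np.asarray(center, dtype=float)
    return (positions - c + b / 2.0) % b - b / 2.0 + c


def voltage_from_field(e_z: float, l_z: float) -> float:
    """Transmembrane potential ΔV_m (mV) from a uniform field E_z (mV/Å).

    ΔV_m = E_z · L_z with L_z the z box length (Å).
    """
    if l_z <= 0:
        raise ValueError("L_z must be positive")
    return e_z * l_z


def field_from_voltage(dv_m: float, l_z: float) -> float:
    """Inverse of :func:`voltage_from_field`: E_z = ΔV_m / L_z."""
    if l_z <= 0:
        raise ValueError("L_z must be positive")
    return dv_m / l_z


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def _element_of(name: str, element: str = "") -> str:
    el = (element or "").strip().upper()
    if el:
        return el
    name = name.strip().upper()
    if len(name) >= 2 and name[:2] in VDW_RADII and not name[0].isdigit():
        return name[:2]
    for ch in name:
        if ch.isalpha():
            return ch
    return name or "X"


def load_structure(path, include_hetero: bool = False,
                   radii: Optional[dict] = None) -> AtomSet:
    """Read a PDB file into an :class:`AtomSet`.

    Waters and other HETATM records are excluded unless ``include_hetero``
    is set.  vdW radii come from :data:`VDW_RADII` (overridable per element
    via ``radii``); unknown elements fall back to 1.70 Å.
    """
    import MDAnalysis as mda

    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    try:
        u = mda.Universe(str(path))
    except Exception as exc:  # unreadable / not a PDB
        raise ValueError(f"could not read structure file {path}: {exc}") from exc
    atoms = u.atoms
    if not include_hetero:
        atoms = atoms.select_atoms("not resname HOH WAT TIP3 TIP3P SOL")
        try:
            atoms = atoms[atoms.record_types == "ATOM"]
        except Exception:
            pass
    if len(atoms) == 0:
        raise ValueError(f"no atoms left after filtering in {path}")
    try:
        elements = atoms.elements
    except Exception:
        elements = [""] * len(atoms)
    labels = np.array([_element_of(n, e) for n, e in zip(atoms.names, elements)])
    rad = np.array([table.get(lbl, DEFAULT_VDW) for lbl in labels])
    try:
        subunits = np.asarray(atoms.chainIDs)
    except Exception:
        subunits = np.asarray(atoms.segids)
    return AtomSet(positions=atoms.positions.astype(float).copy(),
                   labels=labels, radii=rad, subunits=subunits)


def load_trajectory(topology, trajectory=None, selection: str = "name NA SOD",
                    z_ion: int = 1, species: str = "NA") -> IonTrajectory:
    """Load an ion trajectory.

    With one argument ending in ``.csv`` the tabular dialect is read
    directly; otherwise ``topology`` + ``trajectory`` are handed to
    MDAnalysis (PDB/PSF + DCD/XTC) and ``selection`` picks the ions.
    Times missing from the trajectory default to the frame index in ns.
    """
    if trajectory is None:
        return IonTrajectory.from_tabular(topology, z_ion=z_ion, species=species)

    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(trajectory))
    ions = u.select_atoms(selection)
    if len(ions) == 0:
        raise ValueError(f"selection {selection!r} matched no atoms")
    n_frames = len(u.trajectory)
    pos = np.empty((len(ions), n_frames, 3))
    box = np.empty((n_frames, 3))
    times = np.empty(n_frames)
    for i, ts in enumerate(u.trajectory):
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise ValueError("trajectory has no periodic box")
        if not np.allclose(dims[3:], 90.0):
            raise ValueError("only orthorhombic boxes are supported")
        pos[:, i] = ions.positions
        box[i] = dims[:3]
        times[i] = ts.time / 1000.0 if ts.time else float(i)  # ps → ns
    if np.any(np.diff(times) <= 0):
        times = np.arange(n_frames, dtype=float)
    return IonTrajectory(times=times, box=box, positions=pos,
                         ion_ids=np.asarray(ions.ids), z_ion=z_ion,
                         species=species)


def write_dcd(traj: IonTrajectory, pdb_path, dcd_path) -> None:
    """Write an ion trajectory as a PDB topology plus DCD coordinates.

    Useful for exercising the binary-format reading path against the
    tabular dialect of the same data.
    """
    import MDAnalysis as mda

    n = traj.n_ions
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    u.add_TopologyAttr("name", [traj.species] * n)
    u.add_TopologyAttr("resname", [traj.species] * n)
    u.add_TopologyAttr("id", list(range(1, n + 1)))
    u.atoms.positions = traj.positions[:, 0]
    u.dimensions = [*traj.box[0], 90.0, 90.0, 90.0]
    u.atoms.write(str(pdb_path))
    with mda.Writer(str(dcd_path), n) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.positions[:, f]
            u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
            u.trajectory.ts.frame = f
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Read a YAML config; a ``geometry:`` block becomes a ChannelGeometry."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "geometry" in cfg:
        cfg["geometry"] = ChannelGeometry.from_dict(cfg["geometry"])
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
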