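"""Micelle shape descriptors.

Per frame: mass-weighted centre of mass under periodic boundaries, inertia
tensor and its principal moments, eccentricity e = 1 - I_min/I_mean, and the
radius of gyration Rg.  Over a run: mean e, mean Rg with its spread, the
effective micellar radius Rs = sqrt(5/3) * <Rg> (the radius of the uniform
sphere with the same Rg), and a drift check on the Rg time series used as an
equilibration diagnostic.

Eccentricity is 0 for a perfect sphere and grows toward 1 with elongation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .trajectory import Frame, Trajectory, minimum_image, wrap_positions

__all__ = [
    "ShapeResult",
    "make_whole",
    "micelle_com",
    "inertia_tensor",
    "eccentricity",
    "radius_of_gyration",
    "effective_radius",
    "shape_series",
]

RS_FACTOR = np.sqrt(5.0 / 3.0)


def _circular_mean_center(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Cluster-centre estimate that ignores wrapping.

    Each axis is mapped onto a circle (angle 2 pi x / L) and the vector mean
    taken; correct whenever the cluster occupies well under a full box edge,
    regardless of where the boundary cuts it.
    """
    theta = 2.0 * np.pi * coords / box
    mean_angle = np.arctan2(np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    return np.mod(mean_angle / (2.0 * np.pi), 1.0) * box


def make_whole(coords: np.ndarray, box: np.ndarray,
               reference: Optional[np.ndarray] = None) -> np.ndarray:
    """Undo periodic wrapping of a compact selection.

    Every point is translated by box multiples so it sits within half a box
    of the reference point (default: a circular-mean centre estimate, robust
    for any cluster whose true extent stays below the box edge — the case
    for one micelle in its simulation cell).
    """
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float)
    if reference is None:
        ref = _circular_mean_center(coords, box)
    else:
        ref = np.asarray(reference, dtype=float)
    return ref + minimum_image(ref, coords, box)


def micelle_com(frame: Frame, selection: Sequence[int], masses: np.ndarray,
                wrap: bool = True) -> np.ndarray:
    """Mass-weighted centre of mass of a selection, made PBC-whole first.

    The result is wrapped back into the primary cell unless ``wrap=False``.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    masses = np.asarray(masses, dtype=float)
    whole = make_whole(frame.coords[selection], frame.box)
    com = np.average(whole, axis=0, weights=masses)
    return wrap_positions(com, frame.box) if wrap else com


def inertia_tensor(coords: np.ndarray, masses: np.ndarray,
                   com: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """Moment-of-inertia tensor sum_i m_i [(r.r) 1 - r r^T] about the COM.

    ``coords`` must already be PBC-whole.  Returns (tensor, ascending
    eigenvalues) in amu nm^2.
    """
    coords = np.asarray(coords, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if com is None:
        com = np.average(coords, axis=0, weights=masses)
    r = coords - com
    if coords.shape[0] < 2 or np.allclose(r, r[0], atol=1e-12):
        raise ValueError("inertia tensor needs at least two non-collocated atoms")
    r2 = np.einsum("ij,ij->i", r, r)
    tensor = np.eye(3) * np.sum(masses * r2) - np.einsum("i,ij,ik->jk", masses, r, r)
    eigvals = np.linalg.eigvalsh(tensor)
    return tensor, eigvals


def eccentricity(eigenvalues: np.ndarray) -> float:
    """e = 1 - I_min / I_mean over the three principal moments."""
    ev = np.asarray(eigenvalues, dtype=float)
    if np.all(ev == 0):
        raise ValueError("all-zero inertia eigenvalues")
    return float(1.0 - ev.min() / ev.mean())


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray,
                       com: Optional[np.ndarray] = None) -> float:
    """Mass-weighted Rg = sqrt(sum m_i |r_i - com|^2 / sum m_i), in nm."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    masses = np.asarray(masses, dtype=float)
    if com is None:
        com = np.average(coords, axis=0, weights=masses)
    r2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * r2) / np.sum(masses)))


def effective_radius(mean_rg: float) -> float:
    """Rs = sqrt(5/3) * <Rg>: same units as the input."""
    if mean_rg < 0:
        raise ValueError("mean Rg must be >= 0")
    return RS_FACTOR * mean_rg


@dataclass
class ShapeResult:
    times: np.ndarray            # ps
    eigenvalues: np.ndarray      # (n_frames, 3), ascending, amu nm^2
    e: np.ndarray                # per-frame eccentricity
    rg: np.ndarray               # per-frame Rg, nm
    mean_e: float
    mean_rg: float               # nm
    sd_rg: float                 # nm
    rs: float                    # nm, sqrt(5/3) * mean_rg
    drift_flag: bool             # Rg trend over the last half exceeds 2 SE

    def as_table_row(self, system: str = "") -> dict:
        """Row mirroring the shape summary tables (radii in Angstrom)."""
        return {
            "system": system,
            "e": round(self.mean_e, 3),
            "Rg_A": round(self.mean_rg * 10.0, 1),
            "Rg_sd_A": round(self.sd_rg * 10.0, 1),
            "Rs_A": round(self.rs * 10.0, 1),
            "drift_flag": self.drift_flag,
        }


def _rg_drift_flag(times: np.ndarray, rg: np.ndarray) -> bool:
    """True when the linear Rg trend over the last half is > 2 standard errors."""
    half = len(rg) // 2
    t, y = times[half:], rg[half:]
    if len(y) < 3 or np.ptp(y) == 0 or np.ptp(t) == 0:
        return False
    fit = stats.linregress(t, y)
    if fit.stderr == 0 or not np.isfinite(fit.stderr):
        return bool(fit.slope != 0)
    return bool(abs(fit.slope) > 2.0 * fit.stderr)


def shape_series(traj: Trajectory, selection: Sequence[int],
                 burn_in: int = 0) -> ShapeResult:
    """Per-frame shape descriptors and run summary for one micelle selection.

    ``burn_in`` frames are dropped from the front before averaging (default
    keeps the whole production run).
    """
    selection = np.asarray(selection, dtype=int)
    masses = traj.masses(selection)
    frames = traj.frames[burn_in:]
    times = traj.times[burn_in:]
    eig = np.empty((len(frames), 3))
    e = np.empty(len(frames))
    rg = np.empty(len(frames))
    for k, fr in enumerate(frames):
        whole = make_whole(fr.coords[selection], fr.box)
        com = np.average(whole, axis=0, weights=masses)
        _, ev = inertia_tensor(whole, masses, com)
        eig[k] = ev
        e[k] = eccentricity(ev)
        rg[k] = radius_of_gyration(whole, masses, com)
    mean_rg = float(rg.mean())
    return ShapeResult(
        times=times,
        eigenvalues=eig,
        e=e,
        rg=rg,
        mean_e=float(e.mean()),
        mean_rg=mean_rg,
        sd_rg=float(rg.std(ddof=1)) if len(rg) > 1 else 0.0,
        rs=effective_radius(mean_rg),
        drift_flag=_rg_drift_flag(times, rg),
    )
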