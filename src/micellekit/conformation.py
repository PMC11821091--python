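"""Per-surfactant conformation metrics: head-to-tail distance and bend angle.

For an atom triplet (head, centre, tail) named per molecule, the distance is
the minimum-image head-tail separation and the angle is measured at the
centre atom between the centre->head and centre->tail vectors.  Molecule
values are averaged within each frame; the run mean and the headline spread
are over frame means, with the molecule-level spread also reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import ConfigurationError, Trajectory, minimum_image

__all__ = ["ConformationResult", "head_tail_metrics"]


@dataclass
class ConformationResult:
    triplet: tuple[str, str, str]
    distances: np.ndarray        # (n_frames, n_molecules), nm
    angles: np.ndarray           # (n_frames, n_molecules), degrees
    mean_distance: float         # nm, mean of frame means
    sd_distance: float           # nm, SD over frame means
    mean_angle: float            # degrees
    sd_angle: float              # degrees, SD over frame means
    sd_distance_molecules: float # nm, SD over per-molecule run means
    sd_angle_molecules: float    # degrees

    def as_table_row(self, system: str = "") -> dict:
        """Row mirroring the head-tail summary tables (distance in Angstrom)."""
        h, c, t = self.triplet
        return {
            "system": system,
            "distance_atoms": f"{h}-{t}",
            "distance_A": round(self.mean_distance * 10.0, 1),
            "distance_sd_A": round(self.sd_distance * 10.0, 1),
            "angle_atoms": f"{h}-{c}-{t}",
            "angle_deg": round(self.mean_angle, 0),
            "angle_sd_deg": round(self.sd_angle, 0),
        }


def _triplet_indices(traj: Trajectory, triplet: tuple[str, str, str],
                     selection: np.ndarray) -> np.ndarray:
    """(n_molecules, 3) atom indices of (head, centre, tail) per molecule."""
    by_mol: dict[int, dict[str, int]] = {}
    wanted = set(triplet)
    for i in selection:
        a = traj.topology[i]
        if a.atom_name in wanted:
            slot = by_mol.setdefault(a.residue_id, {})
            if a.atom_name in slot:
                raise ConfigurationError(
                    f"molecule {a.residue_id}: duplicate atom {a.atom_name!r} in triplet"
                )
            slot[a.atom_name] = i
    rows = []
    for mol_id in sorted(by_mol):
        slot = by_mol[mol_id]
        missing = [n for n in triplet if n not in slot]
        if missing:
            raise ConfigurationError(
                f"molecule {mol_id} is missing triplet atom(s): {', '.join(missing)}"
            )
        rows.append([slot[n] for n in triplet])
    if not rows:
        raise ConfigurationError(f"no molecule carries the triplet {triplet}")
    return np.array(rows, dtype=int)


def head_tail_metrics(traj: Trajectory, triplet: tuple[str, str, str],
                      selection: np.ndarray | None = None) -> ConformationResult:
    """Head-to-tail distance and bend-angle statistics over the run.

    ``selection`` restricts which atoms are searched for the triplet names
    (default: the whole topology); every molecule contributing any triplet
    atom must contain all three exactly once.
    """
    if selection is None:
        selection = np.arange(traj.n_atoms)
    idx = _triplet_indices(traj, triplet, np.asarray(selection, dtype=int))
    n_frames, n_mol = traj.n_frames, idx.shape[0]
    dist = np.empty((n_frames, n_mol))
    ang = np.empty((n_frames, n_mol))
    for k, fr in enumerate(traj.frames):
        head = fr.coords[idx[:, 0]]
        center = fr.coords[idx[:, 1]]
        tail = fr.coords[idx[:, 2]]
        dist[k] = np.linalg.norm(minimum_image(head, tail, fr.box), axis=1)
        v1 = minimum_image(center, head, fr.box)
        v2 = minimum_image(center, tail, fr.box)
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        ang[k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    frame_d, frame_a = dist.mean(axis=1), ang.mean(axis=1)
    mol_d, mol_a = dist.mean(axis=0), ang.mean(axis=0)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return ConformationResult(
        triplet=triplet, distances=dist, angles=ang,
        mean_distance=float(frame_d.mean()), sd_distance=sd(frame_d),
        mean_angle=float(frame_a.mean()), sd_angle=sd(frame_a),
        sd_distance_molecules=sd(mol_d), sd_angle_molecules=sd(mol_a),
    )
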