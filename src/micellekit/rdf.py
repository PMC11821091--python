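"""Radial distribution functions under periodic boundaries.

Two flavours:

- site-site g(r) between two atom selections, normalised per frame by
  N_A * rho_B * V_shell with V_shell = (4 pi / 3) [(r + dr)^3 - r^3], so an
  uncorrelated fluid gives g = 1;
- g(r) of a target selection measured from the micelle centre of mass
  (a single reference point per frame, N_A = 1), with the target's own bulk
  number density as the normalisation.

Distances are minimum-image; r_max may not exceed half the smallest box
edge.  Neighbour searches use periodic k-d trees; tests hold the O(N^2)
enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .shape import micelle_com
from .trajectory import Trajectory, minimum_image, wrap_positions

__all__ = ["RdfResult", "rdf_site_site", "rdf_from_com"]

DEFAULT_BIN_WIDTH = 0.002  # nm, resolves peak positions to the 0.02 nm level


@dataclass
class RdfResult:
    bin_centers: np.ndarray   # nm
    g: np.ndarray             # dimensionless
    counts: np.ndarray        # raw pair counts summed over frames
    bin_width: float          # nm
    r_max: float              # nm
    n_frames: int

    def to_text(self, path) -> None:
        """Two-column (r_nm, g) plain text."""
        body = "\n".join(f"{r:.6f}\t{g:.6f}" for r, g in zip(self.bin_centers, self.g))
        with open(path, "w") as fh:
            fh.write("# r_nm\tg\n" + body + "\n")


def _check_rmax(r_max: Optional[float], box: np.ndarray, bin_width: float) -> float:
    half = float(box.min()) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-12:
        raise ValueError(f"r_max {r_max} nm exceeds half the smallest box edge ({half} nm)")
    if r_max <= bin_width:
        raise ValueError("r_max must exceed the bin width")
    return float(r_max)


def _shell_volumes(edges: np.ndarray) -> np.ndarray:
    return 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)


def rdf_site_site(traj: Trajectory, sel_a: Sequence[int], sel_b: Sequence[int],
                  bin_width: float = DEFAULT_BIN_WIDTH,
                  r_max: Optional[float] = None,
                  exclude_same_molecule: bool = True) -> RdfResult:
    """Site-site g(r) between selections A and B, averaged over frames.

    Self-pairs are always excluded; pairs within one molecule are excluded
    by default (the inter-molecular convention for same-species site pairs),
    controllable via ``exclude_same_molecule``.
    """
    sel_a = np.asarray(sel_a, dtype=int)
    sel_b = np.asarray(sel_b, dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("empty selection")
    mol = traj.molecule_ids()
    box0 = traj.frames[0].box
    r_max = _check_rmax(r_max, box0, bin_width)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    counts = np.zeros(len(edges) - 1)
    identical = sel_a.size == sel_b.size and np.array_equal(np.sort(sel_a), np.sort(sel_b))
    norm_acc = 0.0
    for fr in traj.frames:
        box = fr.box
        pa = wrap_positions(fr.coords[sel_a], box)
        pb = wrap_positions(fr.coords[sel_b], box)
        if identical:
            tree = cKDTree(pa, boxsize=box)
            pairs = tree.query_pairs(r_max, output_type="ndarray")
            if pairs.size:
                ia, ib = sel_a[pairs[:, 0]], sel_a[pairs[:, 1]]
                keep = np.ones(len(pairs), dtype=bool)
                if exclude_same_molecule:
                    keep &= mol[ia] != mol[ib]
                d = np.linalg.norm(
                    minimum_image(fr.coords[ia[keep]], fr.coords[ib[keep]], box), axis=1)
                h, _ = np.histogram(d, bins=edges)
                counts += 2.0 * h  # ordered-pair convention
        else:
            tree_b = cKDTree(pb, boxsize=box)
            tree_a = cKDTree(pa, boxsize=box)
            neighbor_lists = tree_a.query_ball_tree(tree_b, r_max)
            ia_list, ib_list = [], []
            for i, lst in enumerate(neighbor_lists):
                for j in lst:
                    ia_list.append(i)
                    ib_list.append(j)
            if ia_list:
                ia = sel_a[np.array(ia_list)]
                ib = sel_b[np.array(ib_list)]
                keep = ia != ib
                if exclude_same_molecule:
                    keep &= mol[ia] != mol[ib]
                d = np.linalg.norm(
                    minimum_image(fr.coords[ia[keep]], fr.coords[ib[keep]], box), axis=1)
                h, _ = np.histogram(d, bins=edges)
                counts += h
        volume = float(np.prod(box))
        rho_b = sel_b.size / volume
        norm_acc += sel_a.size * rho_b
    shells = _shell_volumes(edges)
    g = counts / (norm_acc * shells)
    return RdfResult(bin_centers=0.5 * (edges[:-1] + edges[1:]), g=g,
                     counts=counts, bin_width=bin_width, r_max=r_max,
                     n_frames=traj.n_frames)


def rdf_from_com(traj: Trajectory, micelle_selection: Sequence[int],
                 target_selection: Sequence[int],
                 bin_width: float = DEFAULT_BIN_WIDTH,
                 r_max: Optional[float] = None) -> RdfResult:
    """g(r) of target atoms measured from the micelle centre of mass.

    The COM is recomputed each frame after making the micelle PBC-whole;
    the curve is normalised like a pair RDF with one reference site, using
    the target selection's bulk number density.
    """
    micelle_selection = np.asarray(micelle_selection, dtype=int)
    target_selection = np.asarray(target_selection, dtype=int)
    if micelle_selection.size == 0 or target_selection.size == 0:
        raise ValueError("empty selection")
    masses = traj.masses(micelle_selection)
    box0 = traj.frames[0].box
    r_max = _check_rmax(r_max, box0, bin_width)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    if edges[-1] < r_max - 1e-12:
        edges = np.append(edges, r_max)
    counts = np.zeros(len(edges) - 1)
    norm_acc = 0.0
    for fr in traj.frames:
        com = micelle_com(fr, micelle_selection, masses)
        d = np.linalg.norm(minimum_image(com, fr.coords[target_selection], fr.box), axis=1)
        h, _ = np.histogram(d[d <= r_max], bins=edges)
        counts += h
        norm_acc += target_selection.size / float(np.prod(fr.box))
    shells = _shell_volumes(edges)
    g = counts / (norm_acc * shells)
    return RdfResult(bin_centers=0.5 * (edges[:-1] + edges[1:]), g=g,
                     counts=counts, bin_width=bin_width, r_max=r_max,
                     n_frames=traj.n_frames)
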