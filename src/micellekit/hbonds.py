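"""Geometric hydrogen-bond detection and species-pair classification.

A donor-hydrogen-acceptor triplet is a hydrogen bond when the minimum-image
donor-acceptor distance is at most 0.35 nm AND the angle at the donor heavy
atom between donor->hydrogen and donor->acceptor is at most 30 degrees
(both boundaries inclusive) — the standard geometric criterion for
hydrogen-bonded liquids.  Detected bonds are classified by the unordered
species pair of donor and acceptor into the table layout used for
surfactant/DES systems: Surf-Surf, Surf-Ch, Surf-HBD, Surf-Cl, Ch-Ch,
Ch-HBD, Ch-Cl, Cl-HBD, HBD-HBD, other.

The production path uses a periodic k-d tree for the distance pre-filter;
it must (and, by test, does) agree exactly with brute-force enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory, minimum_image, wrap_positions

__all__ = [
    "HbondCriterion",
    "HbondTable",
    "CATEGORIES",
    "detect_hbonds_frame",
    "derive_donors_acceptors",
    "hbond_table",
    "aggregate_shares",
    "percent_change",
]

# numeric guard so exactly-on-boundary constructed geometries classify
# deterministically under floating-point rounding
_EPS = 1e-12

CATEGORIES = (
    "Surf-Surf", "Surf-Ch", "Surf-HBD", "Surf-Cl",
    "Ch-Ch", "Ch-HBD", "Ch-Cl", "Cl-HBD", "HBD-HBD", "other",
)

_SURF_CATEGORIES = ("Surf-Surf", "Surf-Ch", "Surf-HBD", "Surf-Cl")

# canonical member order inside an unordered pair label
_PAIR_RANK = {"Surf": 0, "Ch": 1, "Cl": 2, "HBD": 3}


def pair_category(species_a: str, species_b: str) -> str:
    """Unordered species pair -> table category (or 'other')."""
    if species_a in _PAIR_RANK and species_b in _PAIR_RANK:
        x, y = sorted((species_a, species_b), key=_PAIR_RANK.get)
        label = f"{x}-{y}"
        if label in CATEGORIES:
            return label
    return "other"


@dataclass(frozen=True)
class HbondCriterion:
    r_da_max: float = 0.35        # nm, donor-acceptor distance cutoff
    angle_max_deg: float = 30.0   # degrees, H-donor-acceptor angle at the donor

    def __post_init__(self) -> None:
        if self.r_da_max <= 0 or self.angle_max_deg <= 0:
            raise ValueError("cutoffs must be > 0")


def detect_hbonds_frame(
    frame: Frame,
    donors: Sequence[tuple[int, int]],
    acceptors: Sequence[int],
    criterion: HbondCriterion = HbondCriterion(),
    molecule_ids: Optional[np.ndarray] = None,
    include_intramolecular: bool = False,
) -> list[tuple[int, int, int]]:
    """All (donor_heavy, hydrogen, acceptor) triplets satisfying the criterion.

    ``donors`` pairs each donor heavy atom with one of its hydrogens (a heavy
    atom with several hydrogens appears once per hydrogen).  Donor-acceptor
    pairs within one molecule are skipped unless ``include_intramolecular``;
    an acceptor that *is* the donor heavy atom or the hydrogen is always
    skipped.  A hydrogen further than 0.15 nm from its heavy atom triggers a
    topology warning.
    """
    donors = list(donors)
    acceptors = np.asarray(acceptors, dtype=int)
    if not donors or acceptors.size == 0:
        return []
    box = frame.box
    heavy = np.array([d for d, _ in donors], dtype=int)
    hydro = np.array([h for _, h in donors], dtype=int)
    dh = np.linalg.norm(minimum_image(frame.coords[heavy], frame.coords[hydro], box), axis=1)
    bad = np.nonzero(dh > 0.15)[0]
    for i in bad:
        warnings.warn(
            f"hydrogen {hydro[i]} is {dh[i]:.3f} nm from its donor heavy atom "
            f"{heavy[i]} (> 0.15 nm); check the donor topology", stacklevel=2)

    acc_pos = wrap_positions(frame.coords[acceptors], box)
    tree = cKDTree(acc_pos, boxsize=np.asarray(box, dtype=float))
    heavy_pos = wrap_positions(frame.coords[heavy], box)
    neighbor_lists = tree.query_ball_point(heavy_pos, criterion.r_da_max * (1 + 1e-9) + 1e-9)

    cos_max = np.cos(np.radians(criterion.angle_max_deg))
    out: list[tuple[int, int, int]] = []
    for di, lst in enumerate(neighbor_lists):
        if not lst:
            continue
        d_idx, h_idx = heavy[di], hydro[di]
        acc = acceptors[np.asarray(lst, dtype=int)]
        acc = acc[(acc != d_idx) & (acc != h_idx)]
        if not include_intramolecular and molecule_ids is not None and acc.size:
            acc = acc[molecule_ids[acc] != molecule_ids[d_idx]]
        if acc.size == 0:
            continue
        v_da = minimum_image(frame.coords[d_idx], frame.coords[acc], box)
        dist = np.linalg.norm(v_da, axis=1)
        ok = dist <= criterion.r_da_max + _EPS
        if not np.any(ok):
            continue
        v_dh = minimum_image(frame.coords[d_idx], frame.coords[h_idx], box)
        nh = np.linalg.norm(v_dh)
        cosang = (v_da[ok] @ v_dh) / (dist[ok] * nh)
        for a_idx, c in zip(acc[ok], cosang):
            if c >= cos_max - _EPS:
                out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


def derive_donors_acceptors(traj: Trajectory) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Build the donor (heavy, hydrogen) pairs and acceptor list from site roles.

    Atoms labelled ``donor_hydrogen`` are attached to the nearest
    ``donor_heavy`` atom of the same molecule in the first frame; atoms
    labelled ``acceptor`` form the acceptor list.
    """
    fr = traj.frames[0]
    mol = traj.molecule_ids()
    heavy_by_mol: dict[int, list[int]] = {}
    hydrogens: list[int] = []
    acceptors: list[int] = []
    for a in traj.topology:
        if a.site_role == "donor_heavy":
            heavy_by_mol.setdefault(a.residue_id, []).append(a.index)
        elif a.site_role == "donor_hydrogen":
            hydrogens.append(a.index)
        if a.site_role == "acceptor":
            acceptors.append(a.index)
    donors: list[tuple[int, int]] = []
    for h in hydrogens:
        cands = heavy_by_mol.get(mol[h], [])
        if not cands:
            warnings.warn(f"donor hydrogen {h} has no donor heavy atom in its molecule",
                          stacklevel=2)
            continue
        d = np.linalg.norm(minimum_image(fr.coords[h], fr.coords[cands], fr.box), axis=1)
        donors.append((int(np.asarray(cands)[np.argmin(d)]), h))
    return donors, np.array(acceptors, dtype=int)


@dataclass
class HbondTable:
    """Per-category mean counts over frames, spreads, shares — table layout."""

    categories: tuple[str, ...]
    mean_counts: np.ndarray       # per category, mean over frames
    sd_counts: np.ndarray         # SD over frames
    percentages: np.ndarray       # mean / total * 100
    total_mean: float
    surfactant_share: float       # % of bonds involving the surfactant
    des_share: float              # % of bonds among DES components only
    n_frames: int
    empty: bool = False           # no bonds at all: shares undefined

    def counts_by_category(self) -> dict[str, float]:
        return dict(zip(self.categories, self.mean_counts))


def hbond_table(traj: Trajectory,
                criterion: HbondCriterion = HbondCriterion(),
                include_intramolecular: bool = False,
                donors: Optional[Sequence[tuple[int, int]]] = None,
                acceptors: Optional[Sequence[int]] = None) -> HbondTable:
    """Detect per frame, classify by species pair, average over frames.

    Donor/acceptor roles default to the ``site_role`` labels assigned by the
    species map; all species act as both donors and acceptors wherever those
    roles are present.
    """
    if donors is None or acceptors is None:
        donors_, acceptors_ = derive_donors_acceptors(traj)
        donors = donors if donors is not None else donors_
        acceptors = acceptors if acceptors is not None else acceptors_
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) == 0 or acceptors.size == 0:
        warnings.warn("no donors or no acceptors: emitting an empty table", stacklevel=2)
        z = np.zeros(len(CATEGORIES))
        return HbondTable(categories=CATEGORIES, mean_counts=z, sd_counts=z.copy(),
                          percentages=z.copy(), total_mean=0.0, surfactant_share=np.nan,
                          des_share=np.nan, n_frames=traj.n_frames, empty=True)
    mol = traj.molecule_ids()
    species = np.array([a.species for a in traj.topology])
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    per_frame = np.zeros((traj.n_frames, len(CATEGORIES)))
    for k, fr in enumerate(traj.frames):
        bonds = detect_hbonds_frame(fr, donors, acceptors, criterion,
                                    molecule_ids=mol,
                                    include_intramolecular=include_intramolecular)
        for d_idx, _, a_idx in bonds:
            per_frame[k, cat_index[pair_category(species[d_idx], species[a_idx])]] += 1
    mean = per_frame.mean(axis=0)
    sd = per_frame.std(axis=0, ddof=1) if traj.n_frames > 1 else np.zeros_like(mean)
    total = float(mean.sum())
    if total == 0:
        warnings.warn("no hydrogen bonds detected in any frame", stacklevel=2)
        return HbondTable(categories=CATEGORIES, mean_counts=mean, sd_counts=sd,
                          percentages=np.zeros_like(mean), total_mean=0.0,
                          surfactant_share=np.nan, des_share=np.nan,
                          n_frames=traj.n_frames, empty=True)
    pct = mean / total * 100.0
    surf_share, des_share = aggregate_shares(dict(zip(CATEGORIES, mean)), total)
    return HbondTable(categories=CATEGORIES, mean_counts=mean, sd_counts=sd,
                      percentages=pct, total_mean=total,
                      surfactant_share=surf_share, des_share=des_share,
                      n_frames=traj.n_frames)


def aggregate_shares(counts: dict[str, float], total: float) -> tuple[float, float]:
    """(surfactant-involving %, remainder %) of the total bond count.

    The surfactant share sums the Surf-Surf, Surf-Ch, Surf-HBD and Surf-Cl
    categories; the remainder covers bonds among DES components only.
    """
    if total <= 0:
        raise ValueError("total bond count must be > 0")
    surf = sum(counts.get(c, 0.0) for c in _SURF_CATEGORIES)
    surf_pct = surf / total * 100.0
    return surf_pct, 100.0 - surf_pct


def percent_change(sum_a: float, sum_b: float) -> float:
    """Percent change from a to b: (b/a - 1) * 100."""
    if sum_a == 0:
        raise ValueError("reference sum must be nonzero")
    return (sum_b / sum_a - 1.0) * 100.0
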