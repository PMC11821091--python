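"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately avoid the code paths they validate: eigenvalues come
from the closed-form characteristic polynomial of a symmetric 3x3 matrix
(not numpy's eigensolver), pair counts and hydrogen bonds from plain
O(N^2) loops over minimum-image distances.
"""

from __future__ import annotations

import numpy as np


def minimum_image_ref(a, b, box):
    """Reference minimum-image displacement, written independently."""
    d = np.asarray(b, float) - np.asarray(a, float)
    box = np.asarray(box, float)
    while np.any(d > box / 2):
        d = np.where(d > box / 2, d - box, d)
    while np.any(d <= -box / 2):
        d = np.where(d <= -box / 2, d + box, d)
    return d


def sym3_eigvals_charpoly(m: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a symmetric 3x3 via the trigonometric closed form."""
    m = np.asarray(m, dtype=float)
    p1 = m[0, 1] ** 2 + m[0, 2] ** 2 + m[1, 2] ** 2
    q = np.trace(m) / 3.0
    if p1 == 0.0:
        return np.sort(np.diag(m))
    p2 = sum((m[i, i] - q) ** 2 for i in range(3)) + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    b = (m - q * np.eye(3)) / p
    r = np.clip(np.linalg.det(b) / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    return np.sort([e1, 3.0 * q - e1 - e3, e3])


def inertia_eccentricity_oracle(coords: np.ndarray, masses: np.ndarray) -> float:
    """Eccentricity 1 - I_min/I_mean from an explicitly summed inertia tensor."""
    coords = np.asarray(coords, float)
    masses = np.asarray(masses, float)
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    t = np.zeros((3, 3))
    for mi, ri in zip(masses, coords - com):
        t += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
    ev = sym3_eigvals_charpoly(t)
    return 1.0 - ev.min() / ev.mean()


def count_pairs_in_range(coords_a, coords_b, box, r_max, *,
                         mol_a=None, mol_b=None, idx_a=None, idx_b=None,
                         ordered=False) -> int:
    """O(N^2) count of minimum-image pairs with distance <= r_max.

    Same-atom pairs (by global index) are skipped, as are same-molecule
    pairs when molecule ids are given.  ``ordered`` doubles symmetric pairs
    the way the RDF's ordered-pair normalisation counts them.
    """
    n = 0
    for i in range(len(coords_a)):
        for j in range(len(coords_b)):
            if idx_a is not None and idx_b is not None and idx_a[i] == idx_b[j]:
                continue
            if mol_a is not None and mol_b is not None and mol_a[i] == mol_b[j]:
                continue
            d = np.linalg.norm(minimum_image_ref(coords_a[i], coords_b[j], box))
            if d <= r_max:
                n += 1
    return n


def brute_hbonds(frame, donors, acceptors, r_da_max, angle_max_deg,
                 molecule_ids=None, include_intramolecular=False):
    """Triple-loop hydrogen-bond detection with inclusive cutoffs."""
    out = []
    cos_max = np.cos(np.radians(angle_max_deg))
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx == d_idx or a_idx == h_idx:
                continue
            if (not include_intramolecular and molecule_ids is not None
                    and molecule_ids[a_idx] == molecule_ids[d_idx]):
                continue
            v_da = minimum_image_ref(frame.coords[d_idx], frame.coords[a_idx], frame.box)
            dist = np.linalg.norm(v_da)
            if dist > r_da_max:
                continue
            v_dh = minimum_image_ref(frame.coords[d_idx], frame.coords[h_idx], frame.box)
            cosang = np.dot(v_da, v_dh) / (dist * np.linalg.norm(v_dh))
            if cosang >= cos_max:
                out.append((int(d_idx), int(h_idx), int(a_idx)))
    return out


def msd_direct(x: np.ndarray, n_lag: int) -> np.ndarray:
    """All-origin MSD of (T, 3) paths by direct summation."""
    T = x.shape[0]
    out = np.zeros(n_lag)
    for m in range(n_lag):
        d = x[m:] - x[: T - m] if m else np.zeros_like(x)
        out[m] = np.mean(np.sum(d * d, axis=-1)) if m else 0.0
    return out
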