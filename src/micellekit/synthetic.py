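"""Synthetic inputs with known ground truth for every analysis stage.

Each generator is a pure function of its spec (including the seed): identical
inputs give identical outputs.  Fixtures carry their ground truth alongside
the data so tests never read the expected answer from the analysis under
test.

Generators
----------
- :func:`build_micelle` — ellipsoidal micelle of radial surfactant chains,
  heads outward, with controllable anisotropy, chain bend and jitter.
- :func:`ellipsoid_cloud` — uniform point samples on/in an ellipsoid, whose
  inertia has a closed form (solid ellipsoid: I_a = m (b^2 + c^2) / 5).
- :func:`brownian_trajectory` — free Brownian particles with exact diffusion
  coefficient, wrapped plus unwrapped coordinates.
- :func:`ideal_gas_box` — uniform uncorrelated positions, the g(r) = 1 null.
- :func:`make_hbond_fixture` — donor/hydrogen/acceptor triplets at
  prescribed distance and angle with their expected bond status.
- :func:`harmonic_fep_samples` — harmonic-oscillator lambda ladder whose
  total free-energy change is (kB T / 2) ln(k1 / k0) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fep import KB_KJ_PER_MOL_K, FepLadder
from .trajectory import Atom, Frame, Trajectory

__all__ = [
    "MicelleSpec",
    "BrownianSpec",
    "FepFixtureSpec",
    "GeometryError",
    "default_chain_sites",
    "build_micelle",
    "ellipsoid_cloud",
    "brownian_trajectory",
    "ideal_gas_box",
    "make_hbond_fixture",
    "harmonic_fep_samples",
]


class GeometryError(ValueError):
    """A generator spec describes an impossible geometry."""


def default_chain_sites() -> list[tuple[str, float, float]]:
    """SDS-like 13-site chain: (label, radial offset nm, mass amu).

    S1 head on the outside at 2.0 nm, terminal tail carbon C12 at 0.68 nm;
    head-to-tail span ~1.3 nm, in the range of dodecyl-chain micelles.
    """
    sites = [("S1", 2.0, 32.06)]
    for i in range(1, 13):
        sites.append((f"C{i}", 2.0 - 0.11 * i, 12.011))
    return sites


@dataclass(frozen=True)
class MicelleSpec:
    """Geometric micelle: chains on quasi-uniform outward directions.

    semi_axes scale the envelope (a >= b >= c gives prolate shapes along x);
    ``bend_angle_deg`` puts a kink at the bend-centre site (180 = straight).
    """

    n_surfactants: int = 60
    semi_axes: tuple[float, float, float] = (2.0, 2.0, 2.0)
    chain_sites: Sequence[tuple[str, float, float]] = field(
        default_factory=default_chain_sites)
    jitter: float = 0.02
    bend_angle_deg: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise GeometryError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if self.n_surfactants < 1:
            raise GeometryError("need at least one surfactant")
        offs = [o for _, o, _ in self.chain_sites]
        if any(np.diff(offs) >= 0):
            raise GeometryError("chain radial offsets must strictly decrease head to tail")
        if offs[0] > max(self.semi_axes):
            raise GeometryError(
                f"head offset {offs[0]} nm exceeds the largest semi-axis {max(self.semi_axes)} nm"
            )
        if self.jitter < 0:
            raise GeometryError("jitter must be >= 0")


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _tangent(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector orthogonal to u."""
    e = np.zeros(3)
    e[np.argmin(np.abs(u))] = 1.0
    t = np.cross(u, e)
    return t / np.linalg.norm(t)


def build_micelle(spec: MicelleSpec) -> Trajectory:
    """One-frame micelle trajectory: heads outward, tails inward.

    Chains sit on Fibonacci-sphere directions; the direction-dependent radial
    scale |(a u1, b u2, c u3)| / mean(a,b,c) maps the spherical arrangement
    onto the requested ellipsoid.  The cubic box leaves >= 1 nm of margin.
    """
    rng = np.random.default_rng(spec.seed)
    a, b, c = spec.semi_axes
    mean_ax = (a + b + c) / 3.0
    dirs = fibonacci_sphere(spec.n_surfactants)
    offsets = np.array([o for _, o, _ in spec.chain_sites])
    labels = [lab for lab, _, _ in spec.chain_sites]
    masses = [m for _, _, m in spec.chain_sites]
    n_sites = len(spec.chain_sites)
    bend_idx = 1 if n_sites > 2 else None  # kink at the second site (bend centre)

    coords = np.empty((spec.n_surfactants * n_sites, 3))
    atoms: list[Atom] = []
    for k in range(spec.n_surfactants):
        u = dirs[k]
        scale = np.linalg.norm(u * spec.semi_axes) / mean_ax
        chain = np.empty((n_sites, 3))
        if spec.bend_angle_deg is None or bend_idx is None:
            chain[:] = offsets[:, None] * scale * u
        else:
            theta = np.radians(spec.bend_angle_deg)
            w = np.cos(theta) * u + np.sin(theta) * _tangent(u)
            for i in range(n_sites):
                if i <= bend_idx:
                    chain[i] = offsets[i] * scale * u
                else:
                    arc = (offsets[bend_idx] - offsets[i]) * scale
                    chain[i] = chain[bend_idx] + arc * w
        if spec.jitter > 0:
            # truncated jitter: redraw until the head stays outside every
            # tail site, so the heads-outward invariant holds for any seed
            for attempt in range(100):
                jittered = chain + rng.normal(0.0, spec.jitter, size=chain.shape)
                if np.all(np.linalg.norm(jittered[1:], axis=1)
                          < np.linalg.norm(jittered[0])):
                    chain = jittered
                    break
            else:
                raise GeometryError(
                    f"chain {k}: jitter {spec.jitter} nm keeps pushing tail sites "
                    "outside the head; reduce it or the bend angle"
                )
        else:
            head_r = np.linalg.norm(chain[0])
            if np.any(np.linalg.norm(chain[1:], axis=1) >= head_r):
                raise GeometryError(
                    f"chain {k}: a tail site sits outside the head "
                    "(check offsets and bend angle)"
                )
        coords[k * n_sites:(k + 1) * n_sites] = chain
        for i in range(n_sites):
            role = "head" if i == 0 else ("tail" if i == n_sites - 1 else
                                          ("bend_center" if i == bend_idx else "none"))
            atoms.append(Atom(index=k * n_sites + i, atom_name=labels[i],
                              residue_name="SUR", residue_id=k + 1,
                              mass=masses[i], species="Surf", site_role=role))

    extent = np.abs(coords).max()
    edge = 2.0 * (extent + 1.0)
    coords += edge / 2.0  # centre the micelle in the box
    frame = Frame(coords=coords, box=np.full(3, edge), time=0.0)
    return Trajectory(topology=atoms, frames=[frame])


def ellipsoid_cloud(semi_axes: Sequence[float], n_points: int,
                    mode: str = "solid", seed: int = 0) -> Frame:
    """Uniform unit-mass point samples on (shell) or in (solid) an ellipsoid.

    Solid sampling maps a uniform ball through the axis scaling; shell
    sampling uses rejection against the surface-area element so the points
    are uniform on the surface, not merely on the parameter sphere.
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    ax = np.asarray(semi_axes, dtype=float)
    rng = np.random.default_rng(seed)
    if mode == "solid":
        v = rng.normal(size=(n_points, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(size=n_points) ** (1.0 / 3.0)
        pts = v * r[:, None] * ax
    elif mode == "shell":
        a, b, c = ax
        pts_list = []
        need = n_points
        gmax = max(b * c, a * c, a * b)
        while need > 0:
            m = max(4 * need, 1024)
            u = rng.normal(size=(m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            g = np.sqrt((u[:, 0] * b * c) ** 2 + (u[:, 1] * a * c) ** 2
                        + (u[:, 2] * a * b) ** 2)
            keep = rng.uniform(size=m) < g / gmax
            pts_list.append((u * ax)[keep])
            need = n_points - sum(len(p) for p in pts_list)
        pts = np.concatenate(pts_list)[:n_points]
    else:
        raise ValueError(f"mode must be 'solid' or 'shell', got {mode!r}")
    edge = 2.0 * (ax.max() + 1.0)
    return Frame(coords=pts + edge / 2.0, box=np.full(3, edge), time=0.0)


@dataclass(frozen=True)
class BrownianSpec:
    n_particles: int = 1000
    d_true: float = 1e-4          # nm^2/ps
    dt: float = 1.0               # ps between stored frames
    n_steps: int = 2000           # number of stored frames
    box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.d_true < 0 or self.dt <= 0 or self.n_steps < 2:
            raise ValueError("invalid Brownian spec")
        if any(e <= 0 for e in self.box):
            raise ValueError("box edges must be > 0")


def brownian_trajectory(spec: BrownianSpec) -> Trajectory:
    """Free Brownian motion: per-axis step variance 2 D dt.

    Frames hold wrapped positions; the exact unwrapped paths ride along in
    ``Trajectory.unwrapped`` so MSD recovery can be checked without relying
    on the unwrapping heuristic under test.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    start = rng.uniform(0.0, box, size=(spec.n_particles, 3))
    sigma = np.sqrt(2.0 * spec.d_true * spec.dt)
    steps = rng.normal(0.0, sigma, size=(spec.n_steps - 1, spec.n_particles, 3)) \
        if sigma > 0 else np.zeros((spec.n_steps - 1, spec.n_particles, 3))
    unwrapped = np.empty((spec.n_steps, spec.n_particles, 3))
    unwrapped[0] = start
    np.cumsum(steps, axis=0, out=unwrapped[1:])
    unwrapped[1:] += start
    atoms = [Atom(index=i, atom_name="P", residue_name="PAR", residue_id=i + 1,
                  mass=1.008) for i in range(spec.n_particles)]
    frames = [Frame(coords=np.mod(unwrapped[t], box), box=box, time=t * spec.dt)
              for t in range(spec.n_steps)]
    return Trajectory(topology=atoms, frames=frames, unwrapped=unwrapped)


def ideal_gas_box(n: int, box: Sequence[float] | float, seed: int = 0) -> Frame:
    """n uniform independent positions: the uncorrelated g(r) = 1 reference."""
    if n < 2:
        raise ValueError("need at least 2 particles")
    box = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    rng = np.random.default_rng(seed)
    return Frame(coords=rng.uniform(0.0, box, size=(n, 3)), box=box, time=0.0)


_DH_BOND = 0.1  # nm, donor-hydrogen covalent distance in fixtures


def make_hbond_fixture(
    cases: Sequence[tuple[float, float, tuple[str, str]]],
    r_da_max: float = 0.35,
    angle_max_deg: float = 30.0,
) -> tuple[Trajectory, list[bool]]:
    """Donor/H/acceptor triplets at prescribed geometry with known status.

    Each case is (donor-acceptor distance nm, H-donor-acceptor angle deg,
    (donor species, acceptor species)).  Cases are spaced 2 nm apart so no
    cross-case bond is geometrically possible.  Returns the one-frame
    trajectory and the expected bond flags (distance <= 0.35 nm and angle
    <= 30 deg by default).
    """
    atoms: list[Atom] = []
    coords = []
    expected = []
    spacing = 2.0
    for k, (dist, angle_deg, (sp_d, sp_a)) in enumerate(cases):
        if dist <= 0.12:
            raise ValueError(f"case {k}: donor-acceptor distance must exceed 0.12 nm")
        base = np.array([1.0 + spacing * k, 1.0, 1.0])
        alpha = np.radians(angle_deg)
        donor = base
        acceptor = base + np.array([dist, 0.0, 0.0])
        hydrogen = base + _DH_BOND * np.array([np.cos(alpha), np.sin(alpha), 0.0])
        i0 = 3 * k
        atoms.append(Atom(index=i0, atom_name="OD", residue_name="DON",
                          residue_id=2 * k + 1, mass=15.999, species=sp_d,
                          site_role="donor_heavy"))
        atoms.append(Atom(index=i0 + 1, atom_name="HD", residue_name="DON",
                          residue_id=2 * k + 1, mass=1.008, species=sp_d,
                          site_role="donor_hydrogen"))
        atoms.append(Atom(index=i0 + 2, atom_name="OA", residue_name="ACC",
                          residue_id=2 * k + 2, mass=15.999, species=sp_a,
                          site_role="acceptor"))
        coords.extend([donor, hydrogen, acceptor])
        expected.append(bool(dist <= r_da_max and angle_deg <= angle_max_deg))
    edge = max(spacing * (len(cases) + 1), 4.0)
    frame = Frame(coords=np.array(coords), box=np.full(3, edge), time=0.0)
    return Trajectory(topology=atoms, frames=[frame]), expected


@dataclass(frozen=True)
class FepFixtureSpec:
    """Harmonic-oscillator alchemical ladder with closed-form free energy.

    The spring constant interpolates k(lambda) = (1-lambda) k0 + lambda k1;
    the exact total is DeltaG = (kB T / 2) ln(k1 / k0).
    """

    k0: float = 100.0             # kJ mol^-1 nm^-2
    k1: float = 400.0
    temperature: float = 298.15   # K
    n_lambda: int = 21
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 <= 0 or self.k1 <= 0 or self.temperature <= 0:
            raise ValueError("force constants and temperature must be > 0")
        if self.n_lambda < 2:
            raise ValueError("need at least 2 lambda values")
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample per window")


def harmonic_fep_samples(spec: FepFixtureSpec) -> FepLadder:
    """Per-window Delta-U samples for the harmonic ladder.

    For each adjacent window (lambda_i -> lambda_{i+1}) positions are drawn
    from the Boltzmann distribution at k(lambda_i) and
    Delta U = (k_{i+1} - k_i) x^2 / 2 is recorded.  The ladder's ``meta``
    carries the exact total under ``dg_true`` (kJ/mol).
    """
    rng = np.random.default_rng(spec.seed)
    lambdas = np.linspace(0.0, 1.0, spec.n_lambda)
    kbt = KB_KJ_PER_MOL_K * spec.temperature
    k_of = spec.k0 + lambdas * (spec.k1 - spec.k0)  # exact when k1 == k0
    windows = []
    for i in range(spec.n_lambda - 1):
        x = rng.normal(0.0, np.sqrt(kbt / k_of[i]), size=spec.n_samples)
        windows.append(0.5 * (k_of[i + 1] - k_of[i]) * x * x)
    dg_true = 0.5 * kbt * np.log(spec.k1 / spec.k0)
    return FepLadder(lambdas=lambdas, windows=windows,
                     temperature=spec.temperature, meta={"dg_true": dg_true})
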