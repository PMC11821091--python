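"""Free-energy perturbation over a coupling-parameter ladder.

Accumulates a solvation free energy from per-window potential-energy
difference samples by forward exponential averaging (Zwanzig),

    dG_i = -kB T ln < exp(-dU_i / kB T) >_i ,

summed over adjacent lambda windows from the decoupled (gas) to the fully
coupled (solvated) state.  Negative totals mean favourable solvation.
Uncertainty comes from a seeded bootstrap over each window's samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB_KJ_PER_MOL_K",
    "FepLadder",
    "FepResult",
    "zwanzig_increment",
    "fep_total",
    "read_ladder_dir",
    "write_ladder_dir",
]

KB_KJ_PER_MOL_K = 0.0083144621  # Boltzmann constant, kJ mol^-1 K^-1


@dataclass
class FepLadder:
    """Ordered lambda values in [0, 1] with Delta-U samples per adjacent window."""

    lambdas: np.ndarray                  # strictly increasing, first 0, last 1
    windows: list[np.ndarray]            # len == len(lambdas) - 1, kJ/mol
    temperature: float                   # K
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or len(self.lambdas) < 2:
            raise ValueError("need at least 2 lambda values")
        if not np.all(np.diff(self.lambdas) > 0):
            raise ValueError("lambda values must be strictly increasing")
        if len(self.windows) != len(self.lambdas) - 1:
            raise ValueError("need exactly one sample window per adjacent lambda pair")
        self.windows = [np.asarray(w, dtype=float) for w in self.windows]
        for i, w in enumerate(self.windows):
            if w.size == 0:
                raise ValueError(f"window {i} is empty")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class FepResult:
    window_dg: np.ndarray    # kJ/mol, per adjacent window
    total_dg: float          # kJ/mol, sum of window_dg
    uncertainty: float       # kJ/mol, bootstrap SD of the total
    temperature: float


def zwanzig_increment(samples: Sequence[float] | np.ndarray, temperature: float) -> float:
    """One-window free-energy increment, log-sum-exp stabilised.

    dG = -kB T [logsumexp(-dU / kB T) - ln n]; exact for all dU equal.
    """
    du = np.asarray(samples, dtype=float)
    if du.size == 0:
        raise ValueError("need at least one sample")
    if not np.all(np.isfinite(du)):
        raise ValueError("non-finite Delta-U samples")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    kbt = KB_KJ_PER_MOL_K * temperature
    return float(-kbt * (logsumexp(-du / kbt) - np.log(du.size)))


def fep_total(ladder: FepLadder, n_bootstrap: int = 200, seed: int = 0) -> FepResult:
    """Sum the Zwanzig increments over the ladder, with bootstrap uncertainty.

    Bootstrap resamples each window's Delta-U values independently with
    replacement and recomputes the total; the reported uncertainty is the
    standard deviation of the resampled totals.
    """
    window_dg = np.array([zwanzig_increment(w, ladder.temperature)
                          for w in ladder.windows])
    total = float(window_dg.sum())
    rng = np.random.default_rng(seed)
    totals = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        acc = 0.0
        for w in ladder.windows:
            resampled = w[rng.integers(0, w.size, size=w.size)]
            acc += zwanzig_increment(resampled, ladder.temperature)
        totals[b] = acc
    return FepResult(window_dg=window_dg, total_dg=total,
                     uncertainty=float(totals.std(ddof=1)) if n_bootstrap > 1 else 0.0,
                     temperature=ladder.temperature)


# ---------------------------------------------------------------------------
# plain-text window files: one Delta-U column, lambda pair in the header


def write_ladder_dir(ladder: FepLadder, directory: str | Path) -> None:
    """One ``window_NN.dat`` per adjacent lambda pair, plus ``ladder.info``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(ladder.windows):
        header = (f"# lambda_i= {ladder.lambdas[i]:.6f} "
                  f"lambda_j= {ladder.lambdas[i + 1]:.6f} "
                  f"temperature_K= {ladder.temperature:.4f}\n")
        body = "\n".join(f"{v:.10g}" for v in w)
        (directory / f"window_{i:02d}.dat").write_text(header + body + "\n")
    info = [f"temperature_K= {ladder.temperature:.4f}"]
    if "dg_true" in ladder.meta:
        info.append(f"dg_true_kJ_per_mol= {ladder.meta['dg_true']:.10g}")
    (directory / "ladder.info").write_text("\n".join(info) + "\n")


def read_ladder_dir(directory: str | Path) -> FepLadder:
    """Rebuild a FepLadder from a directory written by :func:`write_ladder_dir`."""
    directory = Path(directory)
    files = sorted(directory.glob("window_*.dat"))
    if not files:
        raise FileNotFoundError(f"no window_*.dat files in {directory}")
    lambdas: list[float] = []
    windows: list[np.ndarray] = []
    temperature: Optional[float] = None
    for f in files:
        lines = f.read_text().splitlines()
        head = lines[0]
        fields = dict(zip(head.replace("#", "").split()[::2],
                          head.replace("#", "").split()[1::2]))
        li, lj = float(fields["lambda_i="]), float(fields["lambda_j="])
        temperature = float(fields["temperature_K="])
        if not lambdas:
            lambdas.append(li)
        lambdas.append(lj)
        windows.append(np.array([float(v) for v in lines[1:] if v.strip()]))
    meta = {}
    info = directory / "ladder.info"
    if info.exists():
        for ln in info.read_text().splitlines():
            if ln.startswith("dg_true_kJ_per_mol="):
                meta["dg_true"] = float(ln.split("=")[1])
    assert temperature is not None
    return FepLadder(lambdas=np.array(lambdas), windows=windows,
                     temperature=temperature, meta=meta)
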