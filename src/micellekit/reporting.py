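"""TSV report emission for every analysis stage.

All tables are tab-separated with ``#`` header comments carrying units, and
re-parseable with pandas (``comment='#'``).  Radii are printed in Angstrom
in the summary tables (the reporting convention of the field), everything
else stays in nm/ps/kJ-mol.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conformation import ConformationResult
from .fep import FepResult
from .hbonds import HbondTable
from .shape import ShapeResult
from .transport import D_SI_FACTOR, BetaResult, MsdResult

__all__ = [
    "write_shape_report",
    "write_rg_series",
    "write_conformation_report",
    "write_hbond_report",
    "write_msd_report",
    "write_fep_report",
    "read_tsv",
]


def _write(df: pd.DataFrame, path: Path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_comment if header_comment.endswith("\n") else header_comment + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_shape_report(results: dict[str, ShapeResult], path: str | Path) -> None:
    df = pd.DataFrame([r.as_table_row(system=name) for name, r in results.items()])
    _write(df, Path(path), "# micelle shape summary: e dimensionless, radii in Angstrom\n")


def write_rg_series(result: ShapeResult, path: str | Path) -> None:
    df = pd.DataFrame({"time_ps": result.times, "Rg_nm": result.rg})
    _write(df, Path(path), "# Rg time series (equilibration check)\n")


def write_conformation_report(results: dict[str, ConformationResult],
                              path: str | Path) -> None:
    df = pd.DataFrame([r.as_table_row(system=name) for name, r in results.items()])
    _write(df, Path(path),
           "# head-to-tail conformation: distance in Angstrom, angle in degrees;"
           " spreads are over frame means\n")


def write_hbond_report(tables: dict[str, HbondTable], path: str | Path) -> None:
    rows = []
    for name, t in tables.items():
        row: dict = {"system": name, "row": "count"}
        for c, m, s in zip(t.categories, t.mean_counts, t.sd_counts):
            row[c] = f"{m:.1f} ({s:.1f})"
        row["total"] = f"{t.total_mean:.1f}"
        rows.append(row)
        pct: dict = {"system": name, "row": "percent"}
        for c, p in zip(t.categories, t.percentages):
            pct[c] = f"{p:.1f}"
        pct["total"] = "100" if not t.empty else "0"
        rows.append(pct)
        share: dict = {"system": name, "row": "grouped_share"}
        share[t.categories[0]] = ("" if t.empty else f"surf {t.surfactant_share:.1f}")
        share[t.categories[1]] = ("" if t.empty else f"des {t.des_share:.1f}")
        rows.append(share)
    _write(pd.DataFrame(rows), Path(path),
           "# hydrogen-bond table: mean count (SD) per species pair, percent of"
           " total, grouped surfactant/DES shares in %\n")


def write_msd_report(entries: dict[str, tuple[MsdResult, BetaResult, float, float]],
                     path: str | Path) -> None:
    """entries: name -> (msd, beta, D nm^2/ps, fit SE nm^2/ps)."""
    rows = []
    for name, (m, b, d, se) in entries.items():
        w = b.window_lags()
        rows.append({
            "species": name,
            "D_1e-11_m2_s": round(d * D_SI_FACTOR, 4),
            "fit_SE_1e-11_m2_s": round(se * D_SI_FACTOR, 4),
            "beta_window_ps": "" if w is None else f"{w[0]:.1f}-{w[1]:.1f}",
            "diffusive": b.diffusive,
            "n_entities": m.n_entities,
        })
    _write(pd.DataFrame(rows), Path(path),
           "# self-diffusion: Einstein relation D = slope/6 over the diffusive window\n")


def write_msd_curve(result: MsdResult, path: str | Path) -> None:
    df = pd.DataFrame({"lag_ps": result.lags, "msd_nm2": result.msd})
    _write(df, Path(path), "# mean-squared displacement\n")


def write_fep_report(result: FepResult, lambdas: np.ndarray, path: str | Path) -> None:
    rows = [{"window": i, "lambda_i": lambdas[i], "lambda_j": lambdas[i + 1],
             "dG_kJ_mol": round(float(g), 4)} for i, g in enumerate(result.window_dg)]
    rows.append({"window": "total", "lambda_i": lambdas[0], "lambda_j": lambdas[-1],
                 "dG_kJ_mol": round(result.total_dg, 4)})
    _write(pd.DataFrame(rows), Path(path),
           f"# FEP ladder at T= {result.temperature} K; "
           f"total dG = {result.total_dg:.3f} +/- {result.uncertainty:.3f} kJ/mol\n")
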