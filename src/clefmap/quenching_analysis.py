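"""Stern-Volmer analysis of acrylamide quench series.

F_0/F is regressed on quencher molarity by ordinary least squares with a
free intercept; the slope is reported as K_SV. A free (rather than fixed)
intercept exposes static-quenching deviations as a QC flag without biasing
the slope on well-behaved collisional data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cli_io

__all__ = [
    "SternVolmerSeries",
    "SternVolmerFit",
    "fit_stern_volmer",
    "half_quench_concentration",
    "ksv_surface",
    "correct_quench_counts",
    "analyze_quench_table",
]


@dataclass(frozen=True)
class SternVolmerSeries:
    """Dilution-corrected quench series starting at [Q] = 0."""

    quencher_conc: tuple[float, ...]  # M, strictly increasing from 0
    F: tuple[float, ...]

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_conc)
        if len(q) != len(self.F):
            raise ValueError("quencher_conc and F lengths differ")
        if len(q) == 0 or q[0] != 0:
            raise ValueError("series must start at [Q] = 0")
        if len(q) >= 2 and not np.all(np.diff(q) > 0):
            raise ValueError("quencher concentrations must be strictly increasing")
        if np.any(np.asarray(self.F) <= 0):
            raise ValueError("fluorescence values must be positive")

    @property
    def f0(self) -> float:
        return self.F[0]

    @property
    def ratio(self) -> tuple[float, ...]:
        """F_0/F at each point."""
        return tuple(self.f0 / f for f in self.F)


@dataclass(frozen=True)
class SternVolmerFit:
    K_SV: float  # slope, 1/M
    intercept: float
    stderr: float
    r_squared: float
    n_points: int

    @property
    def flagged(self) -> bool:
        """QC flag: negative slope or intercept far from 1."""
        return self.K_SV < 0 or abs(self.intercept - 1.0) > 0.1


def fit_stern_volmer(series: SternVolmerSeries) -> SternVolmerFit:
    """OLS of F_0/F against [Q]; the slope is K_SV."""
    q = np.asarray(series.quencher_conc)
    y = np.asarray(series.ratio)
    if len(q) < 3:
        raise ValueError(f"need at least 3 points, got {len(q)}")
    if np.ptp(q) == 0:
        raise ValueError("zero variance in quencher concentrations")
    res = stats.linregress(q, y)
    return SternVolmerFit(
        K_SV=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points=len(q),
    )


def half_quench_concentration(fit: SternVolmerFit) -> float:
    """Quencher molarity at which F_0/F = 2, i.e. 1/K_SV."""
    if fit.K_SV <= 0:
        raise ValueError(f"non-positive K_SV ({fit.K_SV}); no half-quench point")
    return 1.0 / fit.K_SV


def correct_quench_counts(counts, volumes, v0: float) -> np.ndarray:
    """Undo the stock-addition dilution of the fluorophore: counts * V_i/V_0."""
    return np.asarray(counts, dtype=float) * np.asarray(volumes, dtype=float) / v0


def ksv_surface(fits: pd.DataFrame) -> dict:
    """Summarize fitted K_SV values over position x protein ratio.

    ``fits`` needs columns position, gp32_ratio, K_SV. Returns the pivoted
    matrix, per-ratio means, the no-protein mean reference, and the position
    of the per-ratio minimum (ties resolved to the lowest position index).
    Missing cells are reported, not imputed.
    """
    required = {"position", "gp32_ratio", "K_SV"}
    if not required.issubset(fits.columns):
        raise ValueError(f"fits table needs columns {sorted(required)}")
    agg = fits.groupby(["position", "gp32_ratio"], as_index=False)["K_SV"].mean()
    matrix = agg.pivot(index="position", columns="gp32_ratio", values="K_SV")
    missing = [
        (int(p), float(r))
        for p in matrix.index for r in matrix.columns
        if pd.isna(matrix.loc[p, r])
    ]
    per_ratio_mean = matrix.mean(axis=0)
    min_position = {}
    for r in matrix.columns:
        col = matrix[r].dropna()
        # idxmin on a position-sorted index breaks ties at the lowest position
        min_position[float(r)] = int(col.sort_index().idxmin())
    free_mean = (
        float(per_ratio_mean.loc[0.0]) if 0.0 in matrix.columns else float("nan")
    )
    return {
        "matrix": matrix,
        "per_ratio_mean": per_ratio_mean,
        "no_protein_mean": free_mean,
        "min_position": min_position,
        "missing_cells": missing,
    }


def analyze_quench_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit every (construct, ratio, replicate) quench series in a raw table.

    Expects the generator/reader schema (construct, replicate, gp32_ratio,
    q_conc, volume, counts); applies the dilution correction before fitting.
    """
    rows = []
    for (name, ratio, rep), grp in df.groupby(
        ["construct", "gp32_ratio", "replicate"]
    ):
        grp = grp.sort_values("q_conc")
        construct = cli_io.parse_construct_name(name)
        corrected = correct_quench_counts(
            grp["counts"], grp["volume"], float(grp["volume"].min())
        )
        series = SternVolmerSeries(
            tuple(grp["q_conc"]), tuple(corrected)
        )
        fit = fit_stern_volmer(series)
        rows.append({
            "construct": name,
            "position": (
                construct.probe_positions[0] if construct.probe_positions else -1
            ),
            "gp32_ratio": ratio,
            "replicate": rep,
            "K_SV": fit.K_SV,
            "intercept": fit.intercept,
            "stderr": fit.stderr,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
        })
    return pd.DataFrame(rows)
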