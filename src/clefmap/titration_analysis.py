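"""Fluorescence titration pipeline: corrections, normalization, stoichiometry.

The stoichiometric equivalence point is read from the intersection of
ordinary-least-squares lines through the first six (rising) and last six
(plateau) points of each titration, replicate by replicate; replicate
estimates are aggregated afterwards. The enhancement ratio F_P/F_0 is the
mean over-saturation plateau intensity divided by the zero-protein intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import cli_io
from .lattice_model import (
    LatticeConstruct,
    LigandParams,
    count_saturating_ligands,
    mean_bound_and_coverage,
    solve_mass_balance,
)
from .observable_models import default_enhancement_ratio

__all__ = [
    "TitrationSeries",
    "EquivalencePointResult",
    "BindingFitResult",
    "DegenerateLinesError",
    "correct_series",
    "normalize",
    "equivalence_point",
    "equivalence_point_replicates",
    "enhancement_ratio",
    "fit_binding_model",
    "analyze_titration_table",
]


class DegenerateLinesError(ValueError):
    """Slope and plateau lines are too close to parallel to intersect."""


@dataclass(frozen=True)
class TitrationSeries:
    """A corrected titration: added-monomer ratios vs corrected intensity."""

    ratio: tuple[float, ...]
    intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ratio)
        if len(r) != len(self.intensity):
            raise ValueError("ratio and intensity lengths differ")
        if len(r) >= 2 and not np.all(np.diff(r) > 0):
            raise ValueError("ratios must be strictly increasing")

    @property
    def f0(self) -> float:
        """Zero-protein intensity (requires a ratio-0 point)."""
        if self.ratio[0] != 0:
            raise ValueError("series lacks a zero-protein point")
        return self.intensity[0]

    @property
    def f_max(self) -> float:
        return max(self.intensity)

    @property
    def normalized(self) -> tuple[float, ...]:
        fmax = self.f_max
        return tuple(f / fmax for f in self.intensity)


@dataclass(frozen=True)
class EquivalencePointResult:
    """Line-intersection stoichiometry with the two fitted lines."""

    stoichiometry: float
    slope_line: tuple[float, float]  # (slope, intercept) of the rising fit
    plateau_line: tuple[float, float]
    uncertainty: float = float("nan")  # SD across replicates, if aggregated
    n_replicates: int = 1


@dataclass(frozen=True)
class BindingFitResult:
    K_a: float
    omega: float
    active_fraction: float
    residual_norm: float
    converged: bool
    warnings: tuple[str, ...] = ()


def correct_series(
    ratios,
    counts,
    volumes,
    bg_ratios,
    bg_counts,
    v0: float,
    stock: float | None = None,
    lattice_conc: float | None = None,
) -> TitrationSeries:
    """Background-subtract, dilution-correct, and recompute ratios.

    The interpolated background is removed from the raw counts first (both
    carry the same dilution factor), then intensities are rescaled by
    V_i/V_0 to undo probe dilution. If stock and lattice concentrations are
    given, the ratio axis is recomputed from added moles and volumes as
    stock * (V_i - V_0) / (lattice_conc * V_0).
    """
    ratios = np.asarray(ratios, dtype=float)
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    bg_ratios = np.asarray(bg_ratios, dtype=float)
    bg_counts = np.asarray(bg_counts, dtype=float)
    if len(volumes) >= 2 and np.any(np.diff(volumes) < 0):
        raise ValueError("volumes must be non-decreasing through a titration")
    if len(bg_ratios) and (
        ratios.min() < bg_ratios.min() - 1e-9 or ratios.max() > bg_ratios.max() + 1e-9
    ):
        raise ValueError(
            "background series does not cover the sample ratio range "
            f"[{ratios.min()}, {ratios.max()}]"
        )
    bg = np.interp(ratios, bg_ratios, bg_counts) if len(bg_ratios) else 0.0
    intensity = (counts - bg) * volumes / v0
    if stock is not None and lattice_conc is not None and lattice_conc > 0:
        ratios = stock * (volumes - v0) / (lattice_conc * v0)
        ratios = np.round(ratios, 9)
    return TitrationSeries(tuple(ratios), tuple(intensity))


def normalize(series: TitrationSeries) -> TitrationSeries:
    """Scale intensities to a maximum of 1 (idempotent)."""
    return replace(series, intensity=series.normalized)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def equivalence_point(
    series: TitrationSeries, n_edge: int = 6, slope_tol: float = 1e-6
) -> EquivalencePointResult:
    """Stoichiometry from first-``n_edge``/last-``n_edge`` line intersection."""
    x = np.asarray(series.ratio)
    y = np.asarray(series.normalized)
    if len(x) < 2 * n_edge:
        raise ValueError(
            f"need at least {2 * n_edge} points, got {len(x)}"
        )
    m1, b1 = _ols_line(x[:n_edge], y[:n_edge])
    m2, b2 = _ols_line(x[-n_edge:], y[-n_edge:])
    if abs(m1 - m2) < slope_tol * max(abs(m1), abs(m2), slope_tol):
        raise DegenerateLinesError(
            f"slope ({m1:.3g}) and plateau ({m2:.3g}) lines are near-parallel"
        )
    x_star = (b2 - b1) / (m1 - m2)
    return EquivalencePointResult(float(x_star), (m1, b1), (m2, b2))


def equivalence_point_replicates(
    series_list, n_edge: int = 6
) -> EquivalencePointResult:
    """Per-replicate intersections, aggregated afterwards (mean and SD)."""
    if not series_list:
        raise ValueError("no titration series supplied")
    results = [equivalence_point(s, n_edge=n_edge) for s in series_list]
    values = np.array([r.stoichiometry for r in results])
    return EquivalencePointResult(
        float(values.mean()),
        results[0].slope_line,
        results[0].plateau_line,
        uncertainty=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_replicates=len(values),
    )


def enhancement_ratio(
    series: TitrationSeries,
    stoichiometry: float | None = None,
    oversat_factor: float = 1.5,
) -> float:
    """Plateau-to-baseline intensity ratio F_P/F_0.

    F_P averages points at ratios at or beyond ``oversat_factor`` times the
    stoichiometric equivalence point (estimated from the series itself when
    not given; a flat series falls back to its trailing points).
    """
    x = np.asarray(series.ratio)
    f0 = series.f0
    if stoichiometry is None:
        try:
            stoichiometry = equivalence_point(series).stoichiometry
        except DegenerateLinesError:
            stoichiometry = x[max(len(x) - 6, 0)] / oversat_factor
    mask = x >= oversat_factor * stoichiometry
    if not mask.any():
        raise ValueError(
            f"no points at or beyond {oversat_factor} x stoichiometry "
            f"({oversat_factor * stoichiometry:.3g})"
        )
    fp = float(np.asarray(series.intensity)[mask].mean())
    return fp / f0


def _predict_normalized(
    construct: LatticeConstruct,
    ratios: np.ndarray,
    params: LigandParams,
    active_fraction: float,
    lattice_conc: float,
    R: float,
) -> np.ndarray:
    pos = construct.probe_midpoint
    grid = np.arange(1, construct.length_nt + 1, dtype=float)
    signal = np.empty(len(ratios))
    for i, r in enumerate(ratios):
        state = solve_mass_balance(
            (r / active_fraction) * lattice_conc, lattice_conc,
            construct.length_nt, params,
        )
        prof = mean_bound_and_coverage(
            construct.length_nt, params, state.free_ligand
        )
        theta = float(np.interp(pos, grid, np.asarray(prof.coverage)))
        signal[i] = 1.0 + (R - 1.0) * theta
    return signal / signal.max()


def fit_binding_model(
    series_list,
    construct: LatticeConstruct,
    site_size_n: int = 7,
    lattice_conc: float = 1e-6,
    enhancement: float | None = None,
    x0: tuple[float, float, float] = (6.5, 2.0, 0.95),
) -> BindingFitResult:
    """Least-squares inversion of the titration for (K_a, omega, active fraction).

    Optimizes (log10 K_a, log10 omega, active_fraction) against the pooled
    normalized intensities. In the stoichiometric regime K_a is identifiable
    only as a lower bound; this is detected and reported as a warning, never
    silently.
    """
    if not series_list:
        raise ValueError("no titration series supplied")
    if enhancement is None:
        enhancement = default_enhancement_ratio(
            int(round(construct.probe_midpoint))
        )
    ratios = np.asarray(series_list[0].ratio)
    data = np.vstack([np.asarray(s.normalized) for s in series_list])

    def residuals(p):
        lka, lw, af = p
        pred = _predict_normalized(
            construct, ratios,
            LigandParams(10.0**lka, 10.0**lw, site_size_n),
            af, lattice_conc, enhancement,
        )
        return (data - pred).ravel()

    sol = least_squares(
        residuals, x0=np.asarray(x0),
        bounds=([3.0, 0.0, 0.5], [12.0, 6.0, 1.0]),
        xtol=1e-10, ftol=1e-12, max_nfev=200,
    )
    if not sol.success:
        raise RuntimeError(f"binding-model fit did not converge: {sol.message}")
    lka, lw, af = sol.x
    warnings = []
    cost = float(np.sum(sol.fun**2))
    probe = np.sum(residuals([min(lka + 1.0, 12.0), lw, af]) ** 2)
    if abs(probe - cost) <= 1e-6 * max(cost, 1e-12):
        warnings.append(
            "K_a is lower-bounded only: titration is in the stoichiometric "
            "(binding-limited) regime"
        )
    return BindingFitResult(
        10.0**lka, 10.0**lw, float(af), cost, True, tuple(warnings)
    )


def analyze_titration_table(df: pd.DataFrame, config=None) -> pd.DataFrame:
    """Per-construct stoichiometry and F_P/F_0 summary from a raw table.

    Expects the generator/reader schema (construct, replicate, ratio, volume,
    counts) with unlabeled background rows named ``<length>T``.
    """
    out = []
    backgrounds: dict[int, pd.DataFrame] = {}
    for name, grp in df.groupby("construct"):
        c = cli_io.parse_construct_name(name)
        if c.probe_kind == "none":
            backgrounds[c.length_nt] = (
                grp.groupby("ratio", as_index=False)["counts"].mean()
            )
    for name, grp in df.groupby("construct"):
        c = cli_io.parse_construct_name(name)
        if c.probe_kind == "none":
            continue
        bg = backgrounds.get(c.length_nt)
        if bg is None:
            raise ValueError(
                f"no unlabeled background series for length {c.length_nt}"
            )
        m_max = count_saturating_ligands(c.length_nt, 7)
        stoichs, ratios_fp = [], []
        for _, rep in grp.groupby("replicate"):
            rep = rep.sort_values("ratio")
            series = correct_series(
                rep["ratio"], rep["counts"], rep["volume"],
                bg["ratio"], bg["counts"], v0=float(rep["volume"].min()),
            )
            eq = equivalence_point(series)
            stoichs.append(eq.stoichiometry)
            ratios_fp.append(enhancement_ratio(series, stoichiometry=m_max))
        stoichs = np.asarray(stoichs)
        ratios_fp = np.asarray(ratios_fp)
        out.append({
            "construct": name,
            "n_replicates": len(stoichs),
            "stoichiometry_mean": stoichs.mean(),
            "stoichiometry_sd": stoichs.std(ddof=1) if len(stoichs) > 1 else 0.0,
            "fp_over_f0_mean": ratios_fp.mean(),
            "fp_over_f0_sd": ratios_fp.std(ddof=1) if len(ratios_fp) > 1 else 0.0,
        })
    return pd.DataFrame(out)
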