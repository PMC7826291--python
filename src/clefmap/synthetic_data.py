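"""Instrument-like synthetic datasets for the three assays.

Everything downstream of the binding model is generated here: stock-addition
fluorescence titrations, acrylamide quench series and CD exciton titrations,
with multiplicative Gaussian noise per measured channel and full determinism
under a fixed seed.

Two phenomenological knobs stand in for effects the equilibrium model cannot
produce:

* ``active_fraction`` scales the nominal added-ligand ratio so that the
  apparent equivalence point of a 21-mer titration lands near 2.9 monomers
  per lattice rather than the ideal 3.0 (the nominal axis over-counts the
  binding-competent material by 1/active_fraction).
* ``fill_priority`` blends the (polarity-free) equilibrium coverage with a
  strictly 5'-first sequential filling profile, giving 5'-proximal dimer
  probes their earlier CD amplitude loss.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from . import cli_io
from .cd_analysis import MDEG_PER_DELTA_EPSILON
from .lattice_model import (
    LatticeConstruct,
    LigandParams,
    count_saturating_ligands,
    mean_bound_and_coverage,
    solve_mass_balance,
)
from .observable_models import (
    DEFAULT_CD_PLATEAU,
    DEFAULT_KSV_BOUND,
    DEFAULT_KSV_FREE,
    DEFAULT_KSV_TRANSIENT,
    DEFAULT_TRANSIENT_WEIGHT,
    CDModelParams,
    FluorescenceModelParams,
    QuenchModelParams,
    cd_amplitude,
    default_enhancement_ratio,
    fluorescence_signal,
    ksv_signal,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate_fluorescence_titration",
    "generate_quench_series",
    "generate_cd_titration",
    "generate_all",
    "ratio_grid",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic instrument."""

    constructs: tuple[str, ...] = cli_io.MONOMER_PROBE_CONSTRUCTS
    cd_constructs: tuple[str, ...] = cli_io.DIMER_PROBE_CONSTRUCTS
    lattice_conc: float = 1e-6  # M, fluorescence/quench samples
    lattice_conc_cd: float = 6e-6  # M
    gp32_stock: float = 40e-6  # M
    acrylamide_stock: float = 1.0  # M
    ratio_step: float = 0.25  # monomers per lattice, titration grid spacing
    saturation_factor: float = 2.0  # titrate to this multiple of saturation
    quench_max: float = 0.30  # M acrylamide
    quench_points: int = 16
    quench_ratios: tuple[float, ...] = (0.0, 0.75, 1.5, 3.0, 6.0)
    cd_ratio_step: float = 0.5
    noise_rel: float = 0.02
    replicates_fluorescence: int = 3
    replicates_quench: int = 4
    cd_scans: int = 20
    active_fraction: float = 0.9667
    fill_priority: float = 0.6  # in [0, 1]; 0 = pure equilibrium coverage
    # Strongly cooperative defaults: binding must be sharply stoichiometric
    # (all-or-none lattice filling) for the two-line intercept to sit at the
    # capacity break, as in the real titrations.
    binding: LigandParams = field(
        default_factory=lambda: LigandParams(K_a=1e8, omega=1e10)
    )
    baseline_counts: float = 1.0e5
    background_counts: float = 2.0e3
    sample_volume: float = 1.0  # arbitrary volume unit
    cd_amplitude_free: float = 2.5  # delta-epsilon per 2-AP
    cd_band_width: float = 12.0  # nm
    cd_path_length: float = 1.0  # cm
    wavelength_min: float = 300.0
    wavelength_max: float = 400.0
    wavelength_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction <= 1:
            raise ValueError("active_fraction must be in (0, 1]")
        if not 0 <= self.fill_priority <= 1:
            raise ValueError("fill_priority must be in [0, 1]")
        for name in ("lattice_conc", "lattice_conc_cd", "gp32_stock",
                     "acrylamide_stock", "sample_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["binding"] = asdict(self.binding)
        return d


@dataclass(frozen=True)
class SyntheticDataset:
    """Bundle of generated tables plus a provenance block."""

    fluorescence: pd.DataFrame
    quench: pd.DataFrame
    cd: pd.DataFrame
    provenance: dict


def ratio_grid(m_max: int, step: float = 0.25, factor: float = 2.0) -> np.ndarray:
    """Added-monomer ratio grid from 0 to ``factor`` times saturation."""
    top = factor * m_max
    return np.round(np.arange(0.0, top + step / 2, step), 10)


@lru_cache(maxsize=4096)
def _coverage_cached(
    length_nt: int, ratio_eff: float, lattice_conc: float, params: LigandParams
) -> tuple[float, ...]:
    """Per-position coverage at an effective added ratio (mass balance solved)."""
    state = solve_mass_balance(
        ratio_eff * lattice_conc, lattice_conc, length_nt, params
    )
    return mean_bound_and_coverage(length_nt, params, state.free_ligand).coverage


def _theta_at(
    length_nt: int,
    position: float,
    ratio_eff: float,
    lattice_conc: float,
    params: LigandParams,
) -> float:
    cov = np.asarray(_coverage_cached(length_nt, ratio_eff, lattice_conc, params))
    grid = np.arange(1, length_nt + 1, dtype=float)
    return float(np.interp(position, grid, cov))


def _noise(rng: np.random.Generator, rel: float) -> float:
    return 1.0 + rel * rng.standard_normal() if rel > 0 else 1.0


def generate_fluorescence_titration(
    config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Raw titration counts per construct and replicate, plus background rows.

    Counts follow baseline * (1 + (R_p - 1) * theta) plus an unlabeled-lattice
    background, both scaled by the stock-addition dilution factor V0/V_i.
    Ratios on the nominal axis are added monomers per lattice; binding is
    computed at the effective ratio ``ratio / active_fraction``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    lengths_seen = []
    for name in config.constructs:
        construct = cli_io.parse_construct_name(name)
        if construct.probe_kind == "none":
            raise ValueError(f"fluorescence construct {name!r} carries no probe")
        if construct.length_nt not in lengths_seen:
            lengths_seen.append(construct.length_nt)
        m_max = count_saturating_ligands(
            construct.length_nt, config.binding.site_size_n
        )
        grid = ratio_grid(m_max, config.ratio_step, config.saturation_factor)
        pos = construct.probe_midpoint
        R = default_enhancement_ratio(int(round(pos)))
        fparams = FluorescenceModelParams(R, config.baseline_counts)
        for rep in range(1, config.replicates_fluorescence + 1):
            for r in grid:
                theta = _theta_at(
                    construct.length_nt, pos, r / config.active_fraction,
                    config.lattice_conc, config.binding,
                )
                v = config.sample_volume * (
                    1.0 + r * config.lattice_conc / config.gp32_stock
                )
                dilution = config.sample_volume / v
                signal = fparams.baseline * fluorescence_signal(theta, fparams)
                counts = (signal + config.background_counts) * dilution
                rows.append((name, rep, r, v, counts * _noise(rng, config.noise_rel)))
    # unlabeled background series, one per lattice length
    for length in lengths_seen:
        name = f"{length}T"
        m_max = count_saturating_ligands(length, config.binding.site_size_n)
        grid = ratio_grid(m_max, config.ratio_step, config.saturation_factor)
        for rep in range(1, config.replicates_fluorescence + 1):
            for r in grid:
                v = config.sample_volume * (
                    1.0 + r * config.lattice_conc / config.gp32_stock
                )
                dilution = config.sample_volume / v
                counts = config.background_counts * dilution
                rows.append((name, rep, r, v, counts * _noise(rng, config.noise_rel)))
    return pd.DataFrame(rows, columns=list(cli_io.FLUOR_COLUMNS))


def _true_ksv(
    construct: LatticeConstruct, gp32_ratio: float, config: GeneratorConfig
) -> float:
    """Ground-truth Stern-Volmer constant for a monomer probe construct."""
    pos = int(round(construct.probe_midpoint))
    m_max = count_saturating_ligands(construct.length_nt, config.binding.site_size_n)
    theta = _theta_at(
        construct.length_nt, construct.probe_midpoint,
        gp32_ratio / config.active_fraction, config.lattice_conc, config.binding,
    )
    decay = float(np.clip(1.0 - gp32_ratio / m_max, 0.0, 1.0))
    weight = DEFAULT_TRANSIENT_WEIGHT.get(pos, 1.0)
    transient = theta * weight * decay
    qp = QuenchModelParams(
        K_free=DEFAULT_KSV_FREE,
        K_bound=DEFAULT_KSV_BOUND.get(pos, 2.0),
        K_transient=DEFAULT_KSV_TRANSIENT.get(pos, 5.0),
    )
    return ksv_signal(theta, transient, qp)


def generate_quench_series(
    config: GeneratorConfig, gp32_ratio: float, seed: int | None = None
) -> pd.DataFrame:
    """Acrylamide quench series at a fixed protein:lattice ratio.

    Quencher is added from a concentrated stock; the tabulated ``q_conc`` is
    the dilution-corrected molarity actually present, and raw ``counts``
    carry the probe-dilution factor so the analysis must undo it.
    """
    if gp32_ratio < 0:
        raise ValueError("gp32_ratio must be >= 0")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    q_grid = np.linspace(0.0, config.quench_max, config.quench_points)
    rows = []
    for name in config.constructs:
        construct = cli_io.parse_construct_name(name)
        k_true = _true_ksv(construct, gp32_ratio, config)
        theta = _theta_at(
            construct.length_nt, construct.probe_midpoint,
            gp32_ratio / config.active_fraction, config.lattice_conc, config.binding,
        )
        pos = int(round(construct.probe_midpoint))
        R = default_enhancement_ratio(pos)
        f0 = config.baseline_counts * (1.0 + (R - 1.0) * theta)
        for rep in range(1, config.replicates_quench + 1):
            for q in q_grid:
                v_add = q * config.sample_volume / (config.acrylamide_stock - q)
                v = config.sample_volume + v_add
                dilution = config.sample_volume / v
                counts = f0 / (1.0 + k_true * q) * dilution
                rows.append((
                    name, rep, gp32_ratio, q, v,
                    counts * _noise(rng, config.noise_rel),
                ))
    return pd.DataFrame(rows, columns=list(cli_io.QUENCH_COLUMNS))


def _stacked_fraction(
    construct: LatticeConstruct, ratio: float, config: GeneratorConfig
) -> float:
    """Residual stacked fraction of a dimer probe during the titration.

    Blends the equilibrium midpoint coverage with a 5'-first sequential
    filling profile, weighted by ``fill_priority``.
    """
    n = config.binding.site_size_n
    m_max = count_saturating_ligands(construct.length_nt, n)
    r_eff = ratio / config.active_fraction
    mid = construct.probe_midpoint
    theta_eq = _theta_at(
        construct.length_nt, mid, r_eff, config.lattice_conc_cd, config.binding
    )
    covered_nt = min(r_eff, float(m_max)) * n
    theta_seq = float(np.clip(covered_nt - (mid - 1.0), 0.0, 1.0))
    s = config.fill_priority
    theta_eff = (1.0 - s) * theta_eq + s * theta_seq
    return float(np.clip(1.0 - theta_eff, 0.0, 1.0))


def generate_cd_titration(
    config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Replicate CD scans (raw mdeg) over 300-400 nm per construct and ratio.

    The exciton band is a single Gaussian at 325 nm whose amplitude tracks
    the residual stacked fraction of the dimer probe; scan noise is additive.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    wl = np.round(
        np.arange(
            config.wavelength_min,
            config.wavelength_max + config.wavelength_step / 2,
            config.wavelength_step,
        ), 6,
    )
    conv = (
        MDEG_PER_DELTA_EPSILON * config.lattice_conc_cd * config.cd_path_length * 2
    )  # mdeg per (delta-epsilon per 2-AP), dimer probes have n_ap = 2
    noise_sd = config.noise_rel * config.cd_amplitude_free * conv
    rows = []
    for name in config.cd_constructs:
        construct = cli_io.parse_construct_name(name)
        if construct.probe_kind != "dimer":
            raise ValueError(f"CD construct {name!r} must carry a dimer probe")
        key = tuple(sorted(construct.probe_positions))
        plateau = DEFAULT_CD_PLATEAU.get(key, 0.3)
        cd_params = CDModelParams(
            config.cd_amplitude_free, plateau, 325.0, config.cd_band_width
        )
        m_max = count_saturating_ligands(
            construct.length_nt, config.binding.site_size_n
        )
        grid = ratio_grid(m_max, config.cd_ratio_step, config.saturation_factor)
        for r in grid:
            stacked = _stacked_fraction(construct, r, config)
            amp = cd_amplitude(stacked, cd_params)
            band = amp * np.exp(-((wl - 325.0) ** 2) / (2 * config.cd_band_width**2))
            for scan in range(1, config.cd_scans + 1):
                noisy = band * conv + (
                    rng.standard_normal(wl.size) * noise_sd
                    if config.noise_rel > 0 else 0.0
                )
                for lam, val in zip(wl, noisy):
                    rows.append((
                        name, r, scan, lam, val,
                        config.lattice_conc_cd, config.cd_path_length, 2,
                    ))
    return pd.DataFrame(rows, columns=list(cli_io.CD_COLUMNS))


def generate_all(config: GeneratorConfig) -> SyntheticDataset:
    """All three assays under one seed, with a provenance block."""
    seq = np.random.SeedSequence(config.seed)
    s_fluor, s_quench, s_cd = (int(s.generate_state(1)[0]) for s in seq.spawn(3))
    fluor = generate_fluorescence_titration(config, seed=s_fluor)
    quench = pd.concat(
        [
            generate_quench_series(config, r, seed=s_quench + i)
            for i, r in enumerate(config.quench_ratios)
        ],
        ignore_index=True,
    )
    cd = generate_cd_titration(config, seed=s_cd)
    provenance = {"config": config.to_dict(), "seed": config.seed}
    return SyntheticDataset(fluor, quench, cd, provenance)
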