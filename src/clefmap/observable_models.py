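"""Maps from lattice occupancy to the three measured observables.

All three signal maps are affine ("two-state mixing") in their occupancy
argument: the data constrain only endpoint values and monotone titration
behavior, so the minimal consistent model is linear interpolation between
the free-lattice and saturated endpoints. Solvent accessibility carries a
third, explicitly transient state to represent rapidly exchanging,
sub-saturation binding.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FluorescenceModelParams",
    "QuenchModelParams",
    "CDModelParams",
    "GeometryConstants",
    "DEFAULT_ENHANCEMENT_RATIO",
    "DEFAULT_KSV_FREE",
    "DEFAULT_KSV_BOUND",
    "DEFAULT_KSV_TRANSIENT",
    "DEFAULT_TRANSIENT_WEIGHT",
    "DEFAULT_CD_PLATEAU",
    "fluorescence_signal",
    "ksv_signal",
    "cd_amplitude",
    "dimer_separation_increase",
    "default_enhancement_ratio",
]

# Saturated F_P/F_0 per monomer-probe position: 5'-proximal positions (7-10)
# enhance more strongly than 3'-proximal ones (11-14).
DEFAULT_ENHANCEMENT_RATIO: dict[int, float] = {
    7: 4.5, 8: 4.5, 9: 4.5, 10: 4.5,
    11: 4.0, 12: 4.0, 13: 4.0, 14: 4.0,
}

DEFAULT_KSV_FREE = 3.5  # 1/M, probe on protein-free lattice

# Per-position Stern-Volmer constant at full stable coverage; minimum at
# position 9 with its immediate neighbors below half the free-probe value.
DEFAULT_KSV_BOUND: dict[int, float] = {
    7: 2.6, 8: 1.7, 9: 1.4, 10: 1.5,
    11: 1.8, 12: 2.1, 13: 2.4, 14: 2.6,
}

# Constant applying to transiently exchanging coverage (above K_free: rapid
# association/dissociation transiently unstacks and exposes the probe).
DEFAULT_KSV_TRANSIENT: dict[int, float] = {p: 5.0 for p in range(7, 15)}

# Relative weight of the transient state per position: strongest at the
# footprint edges, weakest near the middle of the central site.
DEFAULT_TRANSIENT_WEIGHT: dict[int, float] = {
    7: 1.0, 8: 0.8, 9: 0.15, 10: 0.2,
    11: 0.5, 12: 0.7, 13: 0.9, 14: 1.0,
}

# Saturation plateau of the exciton CD amplitude per dimer-probe location.
DEFAULT_CD_PLATEAU: dict[tuple[int, int], float] = {
    (8, 9): 0.2,
    (13, 14): 0.4,
    (22, 23): 0.5,
}


def default_enhancement_ratio(position: int) -> float:
    """Default saturated F_P/F_0 for a monomer probe at ``position``."""
    return DEFAULT_ENHANCEMENT_RATIO.get(position, 4.5 if position <= 10 else 4.0)


@dataclass(frozen=True)
class FluorescenceModelParams:
    """Monomer-probe enhancement model: saturated ratio and baseline counts."""

    enhancement_ratio: float  # saturated F_P/F_0, >= 1 for this system
    baseline: float = 1.0  # F_0, arbitrary counts

    def __post_init__(self) -> None:
        if self.enhancement_ratio < 1:
            raise ValueError("enhancement_ratio must be >= 1 (binding enhances)")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")


@dataclass(frozen=True)
class QuenchModelParams:
    """Stern-Volmer constants of the free, stably bound and transient states."""

    K_free: float = DEFAULT_KSV_FREE
    K_bound: float = 1.6
    K_transient: float = 5.0

    def __post_init__(self) -> None:
        if min(self.K_free, self.K_bound, self.K_transient) < 0:
            raise ValueError("Stern-Volmer constants must be >= 0")


@dataclass(frozen=True)
class CDModelParams:
    """Exciton CD band parameters for a dimer probe."""

    amplitude_free: float  # delta-epsilon per 2-AP at zero protein
    amplitude_sat: float  # plateau at saturation
    peak_wavelength: float = 325.0  # nm
    band_width: float = 12.0  # Gaussian sigma, nm

    def __post_init__(self) -> None:
        if self.amplitude_sat > self.amplitude_free:
            raise ValueError("amplitude_sat must not exceed amplitude_free")
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")


@dataclass(frozen=True)
class GeometryConstants:
    """Per-nucleotide rise of the lattice, free and at binding saturation."""

    rise_free: float = 3.4  # Angstrom/nt, stacked ssDNA
    rise_saturated: float = 4.6  # Angstrom/nt, protein-extended ssDNA

    def __post_init__(self) -> None:
        if self.rise_saturated < self.rise_free:
            raise ValueError("rise_saturated must be >= rise_free")


def fluorescence_signal(theta_p: float, params: FluorescenceModelParams) -> float:
    """Relative intensity F/F_0 = 1 + (R - 1) * theta at one probe position."""
    if not 0.0 <= theta_p <= 1.0:
        raise ValueError(f"theta_p must be in [0, 1], got {theta_p}")
    return 1.0 + (params.enhancement_ratio - 1.0) * theta_p


def ksv_signal(
    theta_p: float, transient_fraction: float, params: QuenchModelParams
) -> float:
    """Position-resolved Stern-Volmer constant as a three-state mixture.

    K_SV = K_free*(1 - theta) + K_bound*(theta - t) + K_transient*t
    where ``t`` is the transiently exchanging part of the coverage.
    """
    if not 0.0 <= theta_p <= 1.0:
        raise ValueError(f"theta_p must be in [0, 1], got {theta_p}")
    if not 0.0 <= transient_fraction <= theta_p + 1e-12:
        raise ValueError(
            f"transient_fraction {transient_fraction} must lie in [0, theta_p]"
        )
    t = min(transient_fraction, theta_p)
    return (
        params.K_free * (1.0 - theta_p)
        + params.K_bound * (theta_p - t)
        + params.K_transient * t
    )


def cd_amplitude(stacked_fraction: float, params: CDModelParams) -> float:
    """Exciton-peak amplitude, affine in the residual stacked fraction."""
    if not 0.0 <= stacked_fraction <= 1.0:
        raise ValueError(f"stacked_fraction must be in [0, 1], got {stacked_fraction}")
    return params.amplitude_sat + (
        params.amplitude_free - params.amplitude_sat
    ) * stacked_fraction


def dimer_separation_increase(geometry: GeometryConstants) -> float:
    """Increase in center-to-center dimer-probe separation at saturation (A)."""
    return geometry.rise_saturated - geometry.rise_free
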