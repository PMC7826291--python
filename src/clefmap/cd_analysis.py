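"""CD titration processing: scan averaging, unit conversion, exciton profiles.

Raw ellipticity (mdeg) converts to molar CD per probe residue via
delta_epsilon = mdeg / (32980 * c * l * n_ap); the 32980 deg M^-1 cm^-1
factor is the standard ellipticity-to-delta-epsilon conversion. The exciton
statistic is read at a fixed 325 nm rather than by local-maximum search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MDEG_PER_DELTA_EPSILON",
    "CDSpectrum",
    "CDTitrationProfile",
    "average_scans",
    "to_delta_epsilon_per_ap",
    "peak_amplitude",
    "titration_profile",
    "analyze_cd_table",
]

MDEG_PER_DELTA_EPSILON = 32980.0  # mdeg per (M^-1 cm^-1) at c = 1 M, l = 1 cm


@dataclass(frozen=True)
class CDSpectrum:
    """One spectrum on a strictly increasing wavelength grid."""

    wavelength: tuple[float, ...]  # nm
    values: tuple[float, ...]
    sd: tuple[float, ...] | None = None  # per-wavelength replicate SD
    n_scans: int = 1
    units: str = "delta_epsilon_per_ap"  # or "mdeg"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength)
        if len(wl) != len(self.values):
            raise ValueError("wavelength and value lengths differ")
        if len(wl) >= 2 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.sd is not None and len(self.sd) != len(wl):
            raise ValueError("sd length differs from grid")


@dataclass(frozen=True)
class CDTitrationProfile:
    """Peak amplitude vs ratio, with plateau and initial-slope statistics."""

    ratio: tuple[float, ...]
    amplitude: tuple[float, ...]
    plateau: float
    initial_slope: float


def average_scans(
    spectra: list[CDSpectrum], interpolate: bool = False
) -> CDSpectrum:
    """Pointwise mean of replicate scans, retaining the per-wavelength SD.

    Grids must be identical unless ``interpolate`` is set, in which case all
    scans are linearly interpolated onto the first scan's grid restricted to
    the common wavelength range.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    units = {s.units for s in spectra}
    if len(units) > 1:
        raise ValueError(f"mixed units in replicate scans: {sorted(units)}")
    ref = np.asarray(spectra[0].wavelength)
    grids = [np.asarray(s.wavelength) for s in spectra]
    if all(len(g) == len(ref) and np.allclose(g, ref) for g in grids):
        common = ref
        stack = np.vstack([np.asarray(s.values) for s in spectra])
    elif interpolate:
        lo = max(g.min() for g in grids)
        hi = min(g.max() for g in grids)
        common = ref[(ref >= lo) & (ref <= hi)]
        if len(common) == 0:
            raise ValueError("no overlapping wavelength range to interpolate")
        stack = np.vstack([
            np.interp(common, g, np.asarray(s.values))
            for g, s in zip(grids, spectra)
        ])
    else:
        raise ValueError("incompatible wavelength grids (pass interpolate=True)")
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return CDSpectrum(
        tuple(common), tuple(mean), tuple(sd), n_scans=n, units=spectra[0].units
    )


def to_delta_epsilon_per_ap(
    spectrum: CDSpectrum, concentration: float, path_length: float, n_ap: int
) -> CDSpectrum:
    """Convert raw mdeg to delta-epsilon per probe residue."""
    if spectrum.units != "mdeg":
        raise ValueError(f"expected mdeg spectrum, got units={spectrum.units!r}")
    if concentration <= 0 or path_length <= 0:
        raise ValueError("concentration and path_length must be positive")
    if n_ap not in (1, 2):
        raise ValueError(f"n_ap must be 1 or 2, got {n_ap}")
    scale = MDEG_PER_DELTA_EPSILON * concentration * path_length * n_ap
    values = tuple(v / scale for v in spectrum.values)
    sd = (
        tuple(s / scale for s in spectrum.sd) if spectrum.sd is not None else None
    )
    return CDSpectrum(
        spectrum.wavelength, values, sd, spectrum.n_scans, "delta_epsilon_per_ap"
    )


def peak_amplitude(spectrum: CDSpectrum, target_wavelength: float = 325.0) -> float:
    """Spectrum value at the target wavelength (linear interpolation off-grid)."""
    wl = np.asarray(spectrum.wavelength)
    if not wl.min() <= target_wavelength <= wl.max():
        raise ValueError(
            f"{target_wavelength} nm outside grid [{wl.min()}, {wl.max()}]"
        )
    return float(np.interp(target_wavelength, wl, np.asarray(spectrum.values)))


def titration_profile(
    spectra_by_ratio: dict[float, CDSpectrum],
    saturation_ratio: float,
    slope_window: float = 2.0,
    target_wavelength: float = 325.0,
) -> CDTitrationProfile:
    """Amplitude-vs-ratio profile with plateau and initial-slope estimates.

    Plateau is the mean amplitude over post-saturation ratios; the initial
    slope is an OLS fit over ratios within ``slope_window`` of zero.
    """
    if len(spectra_by_ratio) < 3:
        raise ValueError("need at least 3 titration points")
    ratios = np.array(sorted(spectra_by_ratio))
    if ratios[0] != 0:
        raise ValueError("titration must include a zero-protein point")
    amps = np.array([
        peak_amplitude(spectra_by_ratio[r], target_wavelength) for r in ratios
    ])
    post = ratios >= saturation_ratio
    if not post.any():
        raise ValueError(
            f"no post-saturation points (ratio >= {saturation_ratio})"
        )
    plateau = float(amps[post].mean())
    window = ratios <= slope_window
    if window.sum() >= 2:
        slope = float(np.polyfit(ratios[window], amps[window], 1)[0])
    else:
        slope = float("nan")
    return CDTitrationProfile(
        tuple(float(r) for r in ratios), tuple(float(a) for a in amps),
        plateau, slope,
    )


def analyze_cd_table(df: pd.DataFrame) -> pd.DataFrame:
    """Average scans, convert units and extract 325 nm amplitudes per ratio.

    Expects the generator/reader schema (construct, ratio, scan, wavelength,
    mdeg, lattice_conc, path_length, n_ap). Returns a tidy table of
    construct, ratio, amplitude (delta-epsilon per 2-AP), plateau and
    initial slope.
    """
    from .cli_io import parse_construct_name
    from .lattice_model import count_saturating_ligands

    rows = []
    for name, grp in df.groupby("construct"):
        construct = parse_construct_name(name)
        m_max = count_saturating_ligands(construct.length_nt, 7)
        spectra: dict[float, CDSpectrum] = {}
        for ratio, sub in grp.groupby("ratio"):
            scans = []
            conc = float(sub["lattice_conc"].iloc[0])
            path = float(sub["path_length"].iloc[0])
            n_ap = int(sub["n_ap"].iloc[0])
            for _, scan in sub.groupby("scan"):
                scan = scan.sort_values("wavelength")
                scans.append(CDSpectrum(
                    tuple(scan["wavelength"]), tuple(scan["mdeg"]), units="mdeg"
                ))
            avg = average_scans(scans)
            spectra[float(ratio)] = to_delta_epsilon_per_ap(avg, conc, path, n_ap)
        profile = titration_profile(spectra, saturation_ratio=float(m_max))
        for r, a in zip(profile.ratio, profile.amplitude):
            rows.append({
                "construct": name,
                "ratio": r,
                "amplitude": a,
                "plateau": profile.plateau,
                "initial_slope": profile.initial_slope,
            })
    return pd.DataFrame(rows)
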