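"""Exact equilibrium statistics of cooperative ligand binding to finite 1-D lattices.

A ligand occupies ``n`` contiguous nucleotides of an ``N``-nucleotide lattice;
bound ligands may not overlap. A configuration with ``m`` bound ligands and
``j`` directly abutting ligand-ligand interfaces carries statistical weight

    w = (K_a * L)**m * omega**j

relative to the empty lattice, where ``L`` is the free ligand concentration,
``K_a`` the intrinsic association constant and ``omega`` the nearest-neighbor
cooperativity factor. Two independent routes to the partition function and
occupancy moments are provided: explicit enumeration of configurations (the
oracle, capped at small ``N``) and a linear two-state recursion with a
log-domain fallback for extreme parameter values.

Positions are 1-based, counted from the 5' end. The model carries no binding
polarity: all observables are invariant under lattice reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DEFAULT_SITE_SIZE",
    "ENUMERATION_CAP",
    "LigandParams",
    "LatticeConstruct",
    "BindingConfiguration",
    "OccupancyProfile",
    "SolutionState",
    "count_saturating_ligands",
    "enumerate_configurations",
    "configuration_weight",
    "partition_function",
    "log_partition_function",
    "mean_bound_and_coverage",
    "saturated_exponent",
    "solve_mass_balance",
    "titration_curve",
]

DEFAULT_SITE_SIZE = 7
ENUMERATION_CAP = 40


class EnumerationCapError(ValueError):
    """Lattice too long for the brute-force configuration enumeration."""


class MassBalanceError(RuntimeError):
    """Mass-balance bisection failed to meet its residual tolerance."""


@dataclass(frozen=True)
class LigandParams:
    """Thermodynamic parameters of the binding ligand.

    Parameters
    ----------
    K_a : float
        Intrinsic association constant (1/M). Must be positive.
    omega : float
        Nearest-neighbor cooperativity parameter (dimensionless, >= 0).
    site_size_n : int
        Nucleotides occluded per bound ligand (default 7).
    """

    K_a: float
    omega: float
    site_size_n: int = DEFAULT_SITE_SIZE

    def __post_init__(self) -> None:
        if self.site_size_n < 1:
            raise ValueError(f"site_size_n must be >= 1, got {self.site_size_n}")
        if not self.K_a > 0:
            raise ValueError(f"K_a must be positive, got {self.K_a}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")


@dataclass(frozen=True)
class LatticeConstruct:
    """A finite ssDNA lattice with optional fluorescent probe annotation."""

    length_nt: int
    probe_positions: tuple[int, ...] = ()
    probe_kind: str = "none"  # one of {"monomer", "dimer", "none"}
    name: str = ""

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"length_nt must be >= 1, got {self.length_nt}")
        if self.probe_kind not in ("monomer", "dimer", "none"):
            raise ValueError(f"unknown probe_kind {self.probe_kind!r}")
        for p in self.probe_positions:
            if not 1 <= p <= self.length_nt:
                raise ValueError(
                    f"probe position {p} outside lattice [1, {self.length_nt}]"
                )
        if self.probe_kind == "dimer":
            if len(self.probe_positions) != 2:
                raise ValueError("dimer probe needs exactly two positions")
            a, b = sorted(self.probe_positions)
            if b != a + 1:
                raise ValueError(
                    f"dimer probe positions must be adjacent, got {a},{b}"
                )
        if self.probe_kind == "monomer" and len(self.probe_positions) != 1:
            raise ValueError("monomer probe needs exactly one position")
        if self.probe_kind == "none" and self.probe_positions:
            raise ValueError("probe_kind 'none' must not carry positions")

    @property
    def probe_midpoint(self) -> float:
        """Mean probe position (fractional for dimer probes)."""
        if not self.probe_positions:
            raise ValueError(f"construct {self.name!r} has no probe")
        return float(np.mean(self.probe_positions))


@dataclass(frozen=True)
class BindingConfiguration:
    """One placement of nonoverlapping ligands, given by sorted 5' starts."""

    start_positions: tuple[int, ...]
    site_size_n: int
    length_nt: int

    def __post_init__(self) -> None:
        n = self.site_size_n
        starts = self.start_positions
        if tuple(sorted(starts)) != starts:
            raise ValueError("start_positions must be sorted")
        for s in starts:
            if not (1 <= s and s + n - 1 <= self.length_nt):
                raise ValueError(f"ligand at {s} exceeds lattice {self.length_nt}")
        for a, b in zip(starts, starts[1:]):
            if b < a + n:
                raise ValueError(f"ligands at {a} and {b} overlap (n={n})")

    @property
    def m(self) -> int:
        """Number of bound ligands."""
        return len(self.start_positions)

    @property
    def j(self) -> int:
        """Number of abutting ligand-ligand interfaces (gap exactly zero)."""
        n = self.site_size_n
        return sum(
            1 for a, b in zip(self.start_positions, self.start_positions[1:])
            if b == a + n
        )

    def covers(self, position: int) -> bool:
        n = self.site_size_n
        return any(s <= position <= s + n - 1 for s in self.start_positions)


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-nucleotide coverage probabilities and ligand-count moments."""

    coverage: tuple[float, ...]  # index 0 <-> lattice position 1
    mean_bound: float
    saturation_fraction: float

    def theta(self, position: int) -> float:
        """Coverage probability at a 1-based lattice position."""
        return self.coverage[position - 1]

    def theta_at(self, position: float) -> float:
        """Coverage linearly interpolated at a fractional position."""
        grid = np.arange(1, len(self.coverage) + 1, dtype=float)
        return float(np.interp(position, grid, np.asarray(self.coverage)))


@dataclass(frozen=True)
class SolutionState:
    """Free/total ligand split from the mass-balance solve."""

    free_ligand: float
    total_ligand: float
    lattice_conc: float
    residual: float


def count_saturating_ligands(length_nt: int, site_size_n: int = DEFAULT_SITE_SIZE) -> int:
    """Maximum number of nonoverlapping ligands on the lattice: floor(N/n)."""
    if site_size_n < 1:
        raise ValueError(f"site_size_n must be >= 1, got {site_size_n}")
    if length_nt < 0:
        raise ValueError(f"length_nt must be >= 0, got {length_nt}")
    return length_nt // site_size_n


def enumerate_configurations(
    length_nt: int,
    site_size_n: int = DEFAULT_SITE_SIZE,
    cap: int = ENUMERATION_CAP,
) -> list[BindingConfiguration]:
    """Every valid ligand placement on the lattice, including the empty one.

    The number of placements with exactly ``m`` ligands equals
    ``C(N - m*n + m, m)``. Raises :class:`EnumerationCapError` above ``cap``.
    """
    if length_nt > cap:
        raise EnumerationCapError(
            f"length {length_nt} exceeds enumeration cap {cap}"
        )
    if site_size_n < 1:
        raise ValueError(f"site_size_n must be >= 1, got {site_size_n}")
    n = site_size_n
    out: list[BindingConfiguration] = []

    def _extend(prefix: tuple[int, ...], next_start: int) -> None:
        out.append(BindingConfiguration(prefix, n, length_nt))
        for s in range(next_start, length_nt - n + 2):
            _extend(prefix + (s,), s + n)

    _extend((), 1)
    return out


def configuration_weight(
    config: BindingConfiguration, params: LigandParams, free_ligand: float
) -> float:
    """Boltzmann weight (K_a L)^m * omega^j relative to the empty lattice."""
    x = params.K_a * free_ligand
    return x ** config.m * params.omega ** config.j


def _prefix_arrays(N: int, n: int, x: float, w: float) -> tuple[np.ndarray, np.ndarray]:
    # Ff[p]: partition of sites 1..p with p uncovered; Fb[p]: ligand ends at p.
    Ff = np.zeros(N + 1)
    Fb = np.zeros(N + 1)
    Ff[0] = 1.0
    for p in range(1, N + 1):
        Ff[p] = Ff[p - 1] + Fb[p - 1]
        if p >= n:
            Fb[p] = x * (Ff[p - n] + w * Fb[p - n])
    return Ff, Fb


def _suffix_arrays(N: int, n: int, x: float, w: float) -> tuple[np.ndarray, np.ndarray]:
    # Sf[p]: partition of sites p..N given p-1 uncovered; Sb[p]: ligand ends at p-1.
    Sf = np.ones(N + 2)
    Sb = np.ones(N + 2)
    for p in range(N, 0, -1):
        tail = x * Sb[p + n] if p + n - 1 <= N else 0.0
        Sf[p] = Sf[p + 1] + tail
        Sb[p] = Sf[p + 1] + w * tail
    return Sf, Sb


def _log_prefix_arrays(N: int, n: int, lx: float, lw: float):
    NEG = -math.inf
    Ff = np.full(N + 1, NEG)
    Fb = np.full(N + 1, NEG)
    Ff[0] = 0.0
    for p in range(1, N + 1):
        Ff[p] = np.logaddexp(Ff[p - 1], Fb[p - 1])
        if p >= n:
            Fb[p] = lx + np.logaddexp(Ff[p - n], lw + Fb[p - n])
    return Ff, Fb


def _log_suffix_arrays(N: int, n: int, lx: float, lw: float):
    NEG = -math.inf
    Sf = np.zeros(N + 2)
    Sb = np.zeros(N + 2)
    for p in range(N, 0, -1):
        tail = lx + Sb[p + n] if p + n - 1 <= N else NEG
        Sf[p] = np.logaddexp(Sf[p + 1], tail)
        Sb[p] = np.logaddexp(Sf[p + 1], lw + tail)
    return Sf, Sb


def partition_function(length_nt: int, params: LigandParams, free_ligand: float) -> float:
    """Finite-lattice partition function Z(N) relative to the empty lattice.

    Computed by the two-state linear recursion; agrees with the sum of
    :func:`configuration_weight` over :func:`enumerate_configurations`.
    May return ``inf`` for parameter values whose Z exceeds float range;
    use :func:`log_partition_function` there.
    """
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    if free_ligand == 0:
        return 1.0
    N, n = length_nt, params.site_size_n
    x = params.K_a * free_ligand
    with np.errstate(over="ignore"):
        Ff, Fb = _prefix_arrays(N, n, x, params.omega)
        Z = Ff[N] + Fb[N]
    if np.isfinite(Z):
        return float(Z)
    return math.exp(log_partition_function(length_nt, params, free_ligand))


def log_partition_function(
    length_nt: int, params: LigandParams, free_ligand: float
) -> float:
    """log Z(N), overflow-safe."""
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    if free_ligand == 0:
        return 0.0
    N, n = length_nt, params.site_size_n
    lx = math.log(params.K_a * free_ligand)
    lw = math.log(params.omega) if params.omega > 0 else -math.inf
    Ff, Fb = _log_prefix_arrays(N, n, lx, lw)
    return float(np.logaddexp(Ff[N], Fb[N]))


def mean_bound_and_coverage(
    length_nt: int, params: LigandParams, free_ligand: float
) -> OccupancyProfile:
    """Mean ligands per lattice and per-nucleotide coverage probabilities.

    Uses forward/backward recursion products; falls back to a log-domain
    evaluation when the linear recursion overflows. Satisfies
    ``sum(theta_p) == n * mean_bound`` and lattice-reversal symmetry.
    """
    N, n = length_nt, params.site_size_n
    m_max = count_saturating_ligands(N, n)
    if free_ligand < 0:
        raise ValueError("free_ligand must be >= 0")
    if free_ligand == 0 or m_max == 0:
        return OccupancyProfile(tuple([0.0] * N), 0.0, 0.0)
    x = params.K_a * free_ligand
    w = params.omega

    with np.errstate(over="ignore"):
        Ff, Fb = _prefix_arrays(N, n, x, w)
        Sf, Sb = _suffix_arrays(N, n, x, w)
        Z = Ff[N] + Fb[N]
    finite = np.isfinite(Z) and Z < 1e290 and np.all(np.isfinite(Sb))
    if finite:
        # P(ligand starts at s) = x * (Ff[s-1] + w*Fb[s-1]) * Sb[s+n] / Z
        starts = np.arange(1, N - n + 2)
        p_start = x * (Ff[starts - 1] + w * Fb[starts - 1]) * Sb[starts + n] / Z
    else:
        lx = math.log(x)
        lw = math.log(w) if w > 0 else -math.inf
        lFf, lFb = _log_prefix_arrays(N, n, lx, lw)
        lSf, lSb = _log_suffix_arrays(N, n, lx, lw)
        logZ = np.logaddexp(lFf[N], lFb[N])
        starts = np.arange(1, N - n + 2)
        log_p = (
            lx
            + np.logaddexp(lFf[starts - 1], lw + lFb[starts - 1])
            + lSb[starts + n]
            - logZ
        )
        p_start = np.exp(log_p)

    coverage = np.zeros(N)
    for idx, s in enumerate(starts):
        coverage[s - 1 : s - 1 + n] += p_start[idx]
    coverage = np.clip(coverage, 0.0, 1.0)
    mean_bound = float(np.sum(p_start))
    return OccupancyProfile(
        tuple(float(t) for t in coverage), mean_bound, mean_bound / m_max
    )


def _oracle_occupancy(
    length_nt: int, params: LigandParams, free_ligand: float
) -> OccupancyProfile:
    """Enumeration route for cross-checks; requires N within the cap."""
    configs = enumerate_configurations(length_nt, params.site_size_n)
    weights = np.array(
        [configuration_weight(c, params, free_ligand) for c in configs]
    )
    Z = weights.sum()
    coverage = np.zeros(length_nt)
    for c, wgt in zip(configs, weights):
        for s in c.start_positions:
            coverage[s - 1 : s - 1 + params.site_size_n] += wgt
    coverage /= Z
    mean_bound = float(sum(c.m * wgt for c, wgt in zip(configs, weights)) / Z)
    m_max = count_saturating_ligands(length_nt, params.site_size_n)
    return OccupancyProfile(
        tuple(float(t) for t in coverage),
        mean_bound,
        mean_bound / m_max if m_max else 0.0,
    )


def saturated_exponent(length_nt: int, site_size_n: int = DEFAULT_SITE_SIZE) -> float:
    """Interfaces-per-ligand ratio (m-1)/m of the saturated cluster.

    This is the exponent on the cooperativity parameter in the effective
    per-ligand association constant for a fully saturated finite lattice.
    """
    m = count_saturating_ligands(length_nt, site_size_n)
    if m < 1:
        raise ValueError(
            f"lattice of {length_nt} nt holds no {site_size_n}-nt ligand"
        )
    return (m - 1) / m


def solve_mass_balance(
    total_ligand: float,
    lattice_conc: float,
    length_nt: int,
    params: LigandParams,
    rtol: float = 1e-10,
    abs_floor: float = 1e-18,
) -> SolutionState:
    """Free-ligand concentration satisfying total = L + D * mean_bound(L).

    Monotone in ``L`` on the bracket [0, total], so the root is unique.
    """
    if total_ligand < 0 or lattice_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if total_ligand == 0:
        return SolutionState(0.0, 0.0, lattice_conc, 0.0)
    if lattice_conc == 0:
        return SolutionState(total_ligand, total_ligand, 0.0, 0.0)

    def residual(L: float) -> float:
        mb = mean_bound_and_coverage(length_nt, params, L).mean_bound
        return L + lattice_conc * mb - total_ligand

    lo, hi = 0.0, total_ligand
    if residual(hi) < 0:  # cannot happen: bound <= total at L = total
        raise MassBalanceError(f"no root in bracket [0, {total_ligand}]")
    L = brentq(residual, lo, hi, xtol=1e-30, rtol=8.9e-16, maxiter=300)
    res = residual(L)
    tol = max(rtol * total_ligand, abs_floor)
    if abs(res) > tol:
        # Where the isotherm is near-vertical the residual can jump by more
        # than tol between adjacent floats of L; accept the root if it is
        # bracketed at (near) machine precision in L.
        lo_mp = max(L * (1.0 - 5e-15) - 1e-30, 0.0)
        hi_mp = L * (1.0 + 5e-15) + 1e-30
        if not (residual(lo_mp) <= 0.0 <= residual(hi_mp)):
            raise MassBalanceError(
                f"residual {res:.3e} exceeds tolerance {tol:.3e} at L={L:.6e} "
                f"(bracket [0, {total_ligand}])"
            )
    return SolutionState(float(L), total_ligand, lattice_conc, float(res))


def titration_curve(
    construct: LatticeConstruct,
    params: LigandParams,
    ratios: Sequence[float],
    lattice_conc: float,
) -> list[tuple[float, OccupancyProfile]]:
    """Occupancy profile at each added-ligand : lattice ratio.

    ``ratios`` are total added ligand monomers per lattice construct; each
    point is converted to concentrations and solved for free ligand.
    """
    ratios = list(ratios)
    if any(r < 0 for r in ratios):
        raise ValueError("ratios must be >= 0")
    if sorted(ratios) != ratios:
        raise ValueError("ratios must be sorted ascending")
    out = []
    for r in ratios:
        state = solve_mass_balance(
            r * lattice_conc, lattice_conc, construct.length_nt, params
        )
        out.append(
            (r, mean_bound_and_coverage(construct.length_nt, params, state.free_ligand))
        )
    return out
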