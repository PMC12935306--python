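"""Two-strain colony-biofilm competition model.

Each strain's density B_i(x, t) (carrying capacity nondimensionalised to 1)
evolves on a masked domain Omega by logistic local growth and negative
density-dependent spatial spread::

    dB_i/dt = d_i div( phi(B) grad B_i ) + r_i B_i (1 - B),   B = B1 + B2

with phi(B) = max(0, 1 - B) by default: the effective diffusivity falls to
zero as total biomass approaches capacity (degenerate diffusion), which is
what freezes the strain arrangement into sectors and lets small growth-rate
differences compound into competitive exclusion. Zero-flux boundary
conditions hold on the domain edge.

Discretisation is explicit forward-Euler in time with a second-order central
flux form in space; face diffusivity is the arithmetic mean of phi at the two
cells, and fluxes across the domain boundary are zeroed. Within the stability
bound dt <= h^2 / (4 max_i d_i) the update is a nonnegative combination of
cell values, so nonnegativity (and, for equal motilities, B1 + B2 <= 1) hold
by construction rather than by clipping. The flux divergence is accumulated
pairwise ((east + west) + (north + south)), so a mirror-symmetric initial
condition evolves bitwise mirror-symmetrically and a mirrored equal-rate
competition ends at exactly f1 = f2 = 1/2.

Nondimensionalisation fixes r1 = 1 (time unit = strain-1 growth time scale);
the relative growth rate rho = r2 / r1 is the sweep parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd


class StabilityError(ValueError):
    """dt violates the explicit-scheme stability bound."""


@dataclass
class SimGrid:
    """Regular grid of spacing h covering a masked domain Omega."""

    nx: int
    ny: int
    h: float
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.h <= 0:
            raise ValueError("grid spacing h must be > 0")
        if self.mask.shape != (self.ny, self.nx):
            raise ValueError("mask shape must be (ny, nx)")
        if not self.mask.any():
            raise ValueError("mask has no interior cell")

    @classmethod
    def disc(cls, radius: float = 30.0, nx: int = 256, pad: float = 1.05) -> "SimGrid":
        """Disc-shaped domain of the given nondimensional radius."""
        L = 2.0 * radius * pad
        h = L / nx
        # coordinates antisymmetric about 0 exactly in floating point, so a
        # mirrored layout rasterises to an exactly mirrored field
        x = (np.arange(nx) - (nx - 1) / 2.0) * h
        X, Y = np.meshgrid(x, x)
        return cls(nx, nx, h, (X ** 2 + Y ** 2) <= radius ** 2)

    @property
    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.h
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.h
        return np.meshgrid(x, y)

    @property
    def cell_area(self) -> float:
        return self.h ** 2


@dataclass
class StrainParams:
    name: str
    r: float = 1.0
    d: float = 1.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("growth rate r must be > 0")
        if self.d < 0:
            raise ValueError("motility coefficient d must be >= 0")


@dataclass(frozen=True)
class FounderSpot:
    x: float
    y: float
    radius: float
    strain: int
    b0: float


@dataclass
class FounderLayout:
    spots: list[FounderSpot]
    seed: int = 0


@dataclass
class BiofilmState:
    B1: np.ndarray
    B2: np.ndarray
    t: float = 0.0


@dataclass
class OutcomeSummary:
    f1: float
    f2: float
    percent_challenger_remaining: float
    area_fraction: tuple[float, float]


@dataclass
class SimResult:
    state: BiofilmState
    outcome: OutcomeSummary
    snapshots: list[BiofilmState] = field(default_factory=list)


@dataclass
class SimulationConfig:
    grid: SimGrid
    strains: tuple[StrainParams, StrainParams]
    layout: FounderLayout
    dt: float | None = None           # None => 0.5 x stability bound
    t_end: float = 50.0
    coverage_stop: float = 0.90       # stop when occupied area reaches this
    occupancy_threshold: float = 0.05
    snapshot_every: float | None = None
    diffusivity: Callable[[np.ndarray], np.ndarray] | None = None


def stability_dt_max(grid: SimGrid, strains: Sequence[StrainParams]) -> float:
    dmax = max(s.d for s in strains)
    if dmax == 0:
        return math.inf
    return grid.h ** 2 / (4.0 * dmax)


def make_founder_layout(n_per_strain: int, inoculum_radius: float,
                        spot_radius: float, b0: float, seed: int,
                        grid: SimGrid | None = None) -> FounderLayout:
    """Founder spots for both strains placed uniformly in the central disc of
    the inoculum (emulating a 1:1 mixed inoculum drop)."""
    if not 0 < b0 <= 1:
        raise ValueError("founder density b0 must be in (0, 1]")
    if grid is not None:
        extent = min(grid.nx, grid.ny) * grid.h / 2.0
        if inoculum_radius + spot_radius > extent:
            raise ValueError("inoculum_radius exceeds the domain")
    rng = np.random.default_rng(seed)
    spots: list[FounderSpot] = []
    for strain in (0, 1):
        for _ in range(n_per_strain):
            rad = inoculum_radius * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            spots.append(FounderSpot(rad * math.cos(theta),
                                     rad * math.sin(theta),
                                     spot_radius, strain, b0))
    return FounderLayout(spots, seed)


def mirrored_layout(n_per_strain: int, inoculum_radius: float,
                    spot_radius: float, b0: float, seed: int) -> FounderLayout:
    """A layout that is exactly mirror-symmetric across x = 0 with the strain
    labels swapped: strain-2 spots are the x-reflections of strain-1 spots."""
    rng = np.random.default_rng(seed)
    spots: list[FounderSpot] = []
    for _ in range(n_per_strain):
        rad = inoculum_radius * math.sqrt(rng.uniform())
        theta = rng.uniform(0.0, 2.0 * math.pi)
        x, y = rad * math.cos(theta), rad * math.sin(theta)
        spots.append(FounderSpot(x, y, spot_radius, 0, b0))
        spots.append(FounderSpot(-x, y, spot_radius, 1, b0))
    return FounderLayout(spots, seed)


def initial_state(grid: SimGrid, layout: FounderLayout) -> BiofilmState:
    """Rasterise founder spots; overlaps are resolved by proportional scaling
    so that B1 + B2 <= 1 everywhere."""
    X, Y = grid.coords
    B = [np.zeros_like(X), np.zeros_like(X)]
    for s in layout.spots:
        inside = ((X - s.x) ** 2 + (Y - s.y) ** 2 <= s.radius ** 2) & grid.mask
        B[s.strain] = B[s.strain] + s.b0 * inside
    tot = B[0] + B[1]
    scale = np.where(tot > 1.0, 1.0 / np.where(tot > 0, tot, 1.0), 1.0)
    return BiofilmState(B[0] * scale, B[1] * scale, 0.0)


def _default_phi(Btot: np.ndarray) -> np.ndarray:
    return np.maximum(1.0 - Btot, 0.0)


def _flux_divergence(B: np.ndarray, phi: np.ndarray,
                     mask: np.ndarray) -> np.ndarray:
    """Sum over faces of phi_face * (B_neighbour - B_cell); zero flux across
    the domain boundary. Accumulated pairwise for exact mirror symmetry."""
    east = np.zeros_like(B)
    west = np.zeros_like(B)
    north = np.zeros_like(B)
    south = np.zeros_like(B)
    tx = 0.5 * (phi[:, 1:] + phi[:, :-1]) * (mask[:, 1:] & mask[:, :-1])
    fx = tx * (B[:, 1:] - B[:, :-1])
    east[:, :-1] = fx
    west[:, 1:] = -fx
    ty = 0.5 * (phi[1:, :] + phi[:-1, :]) * (mask[1:, :] & mask[:-1, :])
    fy = ty * (B[1:, :] - B[:-1, :])
    south[:-1, :] = fy
    north[1:, :] = -fy
    return (east + west) + (south + north)


def step(state: BiofilmState, strains: Sequence[StrainParams], grid: SimGrid,
         dt: float,
         diffusivity: Callable[[np.ndarray], np.ndarray] | None = None
         ) -> BiofilmState:
    """One explicit time step of the two-strain model."""
    bound = stability_dt_max(grid, strains)
    if dt > bound * (1.0 + 1e-12):
        raise StabilityError(
            f"dt = {dt} violates the stability bound h^2/(4 max d) = {bound}")
    phi_fn = diffusivity or _default_phi
    mask = grid.mask
    Btot = state.B1 + state.B2
    phi = np.where(mask, phi_fn(Btot), 0.0)
    one_minus = 1.0 - Btot
    out = []
    for B, p in ((state.B1, strains[0]), (state.B2, strains[1])):
        div = _flux_divergence(B, phi, mask)
        Bn = B + dt * ((p.d / grid.h ** 2) * div + p.r * B * one_minus)
        Bn = np.where(mask, Bn, 0.0)
        lowest = Bn.min()
        if lowest < -1e-12:
            raise RuntimeError(
                f"scheme produced negative density {lowest}; dt too large "
                "for the chosen diffusivity")
        np.maximum(Bn, 0.0, out=Bn)
        out.append(Bn)
    return BiofilmState(out[0], out[1], state.t + dt)


def _masked_fsum(arr: np.ndarray, mask: np.ndarray) -> float:
    # order-independent exact summation keeps mirrored outcomes exactly equal
    return math.fsum(arr[mask].tolist())


def outcome_summary(state: BiofilmState, grid: SimGrid,
                    occupancy_threshold: float = 0.05) -> OutcomeSummary:
    s1 = _masked_fsum(state.B1, grid.mask)
    s2 = _masked_fsum(state.B2, grid.mask)
    total = s1 + s2
    if total <= 0:
        return OutcomeSummary(math.nan, math.nan, math.nan, (0.0, 0.0))
    f1, f2 = s1 / total, s2 / total
    n_omega = int(grid.mask.sum())
    a1 = float(((state.B1 > occupancy_threshold) & grid.mask).sum()) / n_omega
    a2 = float(((state.B2 > occupancy_threshold) & grid.mask).sum()) / n_omega
    return OutcomeSummary(f1, f2, 100.0 * f1, (a1, a2))


def simulate(config: SimulationConfig) -> SimResult:
    """Integrate until the stop rule (front coverage or t_end); the outcome
    summary is computed on the final state."""
    grid, strains = config.grid, config.strains
    dt = config.dt if config.dt is not None else 0.5 * stability_dt_max(grid, strains)
    if not math.isfinite(dt) or dt <= 0:
        raise ValueError("dt must be positive and finite (set dt explicitly "
                         "when both motilities are zero)")
    state = initial_state(grid, config.layout)
    snapshots: list[BiofilmState] = []
    next_snap = 0.0
    n_omega = int(grid.mask.sum())
    while state.t < config.t_end - 1e-12:
        if config.snapshot_every is not None and state.t >= next_snap - 1e-12:
            snapshots.append(BiofilmState(state.B1.copy(), state.B2.copy(),
                                          state.t))
            next_snap += config.snapshot_every
        state = step(state, strains, grid, min(dt, config.t_end - state.t),
                     config.diffusivity)
        if not (np.isfinite(state.B1).all() and np.isfinite(state.B2).all()):
            raise RuntimeError(
                f"instability detected at t = {state.t}: non-finite density")
        occupied = (((state.B1 + state.B2) > config.occupancy_threshold)
                    & grid.mask).sum() / n_omega
        if occupied >= config.coverage_stop:
            break
    snapshots.append(BiofilmState(state.B1.copy(), state.B2.copy(), state.t))
    return SimResult(state, outcome_summary(state, grid,
                                            config.occupancy_threshold),
                     snapshots)


def sweep_relative_growth(base_config: SimulationConfig,
                          ratios: Sequence[float]) -> pd.DataFrame:
    """One simulation per relative growth rate rho = r2/r1 (layout, grid and
    seed held fixed); returns a table sorted by rho."""
    if any(r <= 0 for r in ratios):
        raise ValueError("growth-rate ratios must be > 0")
    rows = []
    for rho in sorted(ratios):
        s1, s2 = base_config.strains
        cfg = replace(base_config,
                      strains=(s1, replace(s2, r=rho * s1.r)))
        res = simulate(cfg)
        rows.append({"rho": rho, "f2_final": res.outcome.f2,
                     "percent_challenger_remaining":
                         res.outcome.percent_challenger_remaining})
    return pd.DataFrame(rows)


def merged_rgb(B1: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Pseudo-colour merge: strain 1 green, strain 2 magenta, overlap grey."""
    scale = max(float(B1.max()), float(B2.max()), 1e-12)
    g = np.clip(B1 / scale, 0, 1)
    m = np.clip(B2 / scale, 0, 1)
    rgb = np.stack([m, g, m], axis=-1)
    return (255 * rgb).astype(np.uint8)
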