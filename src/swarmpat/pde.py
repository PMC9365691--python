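"""Continuum reaction-diffusion-adhesion model of swarming colonies.

Each strain ``i`` is a spatio-temporal density split into a free (motile)
part ``rho_i(r, t)`` and a bound (immobilized) part ``b_i(r, t)``.  Free
cells swarm with effective diffusivity ``D_i``, grow logistically at rate
``g_i`` towards the shared carrying capacity ``rho_max``, and bind
irreversibly, at rate constant ``K``, to free or bound cells of any strain
carrying a cross-complementary adhesin.  Bound cells do not move and act as
sinks for further adhesive swarmers:

    d rho_i / dt = div( D_i * m(rho_T) * grad rho_i )
                   + g_i * rho_i * (1 - rho_T / rho_max)
                   - rho_i * sum_{j ~ i} K * (rho_j + b_j)
    d b_i   / dt = rho_i * sum_{j ~ i} K * (rho_j + b_j)

where ``j ~ i`` ranges over strains whose element is cross-complementary to
strain i's element and ``rho_T = sum_i (rho_i + b_i)``.

The mobility factor ``m`` encodes how swarming motility responds to
crowding.  The default ``m = 1`` (plain Fickian active diffusion)
reproduces the characteristic total-density peak at the interface with
troughs on either side: free cells keep streaming into the adhesion zone,
where immobilized clusters ratchet them up beyond the carrying capacity.
``ModelParams.motility = "crowding"`` instead uses
``m = max(0, 1 - rho_T / rho_max)`` (motility ceases in the saturated
lawn), which freezes interpenetration after the fronts merge but caps the
density at ``rho_max`` and so suppresses the interface peak.  Either way
the leading edge of an isolated colony is dilute (``rho_T -> 0``), so the
pulled-front expansion speed is the Fisher-KPP value ``2*sqrt(g*D)``.

Units: lengths in mm, times in h, densities normalized to ``rho_max = 1``.
The experimentally fitted parameters are D = 47 um^2/s = 0.16920 mm^2/h,
g = 14 / h and K = 130 / h.  At these rates the front advances at
~3.1 mm/h, so the model clock covers the *active swarming window* of an
assay; the standard two-colony interface assay (seeds 9 mm apart) runs
2.5 h of active swarming -- fronts meet after ~1.2 h and the profile is
read ~1.3 h later, when the colonies extend a few mm beyond the 6-mm
measurement window.  (Wall-clock protocol times are much longer because
they include the pre-swarming lag, which the model does not describe.)

Numerics: method of lines on a regular grid (3-point / 5-point Laplacian in
flux form, no-flux boundaries), first-order operator splitting per step:
an *exact* exponential update for the adhesion exchange (the per-strain
total ``rho_i + b_i`` is invariant under adhesion, so the sink rate is
constant within a step), explicit Euler for growth, explicit Euler for
diffusion with dt <= safety * dx^2 / (2 * ndim * max D) and dt * g <= 0.2.
The flux-form diffusion and the exact adhesion exchange conserve mass to
round-off when growth is switched off.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .adhesion import Element, parse_element, visible_interface

__all__ = [
    "UM2_PER_S_TO_MM2_PER_H",
    "PAPER_D_MM2_H",
    "PAPER_G_PER_H",
    "PAPER_K_PER_H",
    "ModelParams",
    "SeedInit",
    "FieldState",
    "SolverError",
    "simulate",
    "fluorescence_profile",
    "delay_from_dilution",
    "front_position",
]

#: 1 um^2/s in mm^2/h.
UM2_PER_S_TO_MM2_PER_H = 3600.0 / 1.0e6

#: Fitted swarming diffusivity, 47 um^2/s, in mm^2/h.
PAPER_D_MM2_H = 47.0 * UM2_PER_S_TO_MM2_PER_H
#: Fitted logistic growth rate (1/h).
PAPER_G_PER_H = 14.0
#: Fitted adhesion strength (1/h, densities normalized to carrying capacity).
PAPER_K_PER_H = 130.0


class SolverError(RuntimeError):
    """Numerical instability (NaN or significantly negative density)."""


@dataclass(frozen=True)
class ModelParams:
    """Physical and numerical parameters of the continuum model.

    Parameters
    ----------
    D : float or sequence of float
        Effective diffusivity per strain, mm^2/h.  A scalar applies to all
        strains.  Default: the fitted 47 um^2/s.
    g : float or sequence of float
        Logistic growth rate per strain, 1/h.
    K : float
        Adhesion strength, 1/h, for densities normalized to ``rho_max``.
        An adhesin inhibitor (such as the competitive peptide EPEA) is
        modelled purely as a scalar multiplier on K.
    rho_max : float
        Carrying capacity; densities are reported in units of it.
    dx : float
        Grid spacing, mm.  Defaults: 0.025 in 1-D, 0.1 in 2-D (an
        interface ~0.5 mm wide is then resolved by >= 5-20 cells).
    extent : float or (float, float)
        Domain length(s), mm; the dish is closed (no-flux boundaries).
    motility : {"constant", "crowding"}
        Plain Fickian mobility ``D`` (default) or crowding-limited
        ``D*(1 - rho_T)``.
    bound_growth : bool
        Whether the immobilized phase also grows logistically (off by
        default: bound clusters are treated as passive sinks).
    safety : float
        Fraction of the explicit diffusion stability bound used for dt.
    """

    D: float | Sequence[float] = PAPER_D_MM2_H
    g: float | Sequence[float] = PAPER_G_PER_H
    K: float = PAPER_K_PER_H
    rho_max: float = 1.0
    dx: float | None = None
    extent: float | tuple[float, float] = 40.0
    motility: str = "constant"
    bound_growth: bool = False
    safety: float = 0.8

    def __post_init__(self) -> None:
        for name in ("rho_max",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if np.any(np.asarray(self.D, dtype=float) <= 0):
            raise ValueError("D must be strictly positive")
        if np.any(np.asarray(self.g, dtype=float) < 0):
            raise ValueError("g must be non-negative")
        if self.motility not in ("crowding", "constant"):
            raise ValueError("motility must be 'crowding' or 'constant'")
        if not 0 < self.safety <= 1:
            raise ValueError("safety must lie in (0, 1]")
        if self.dx is not None and self.dx <= 0:
            raise ValueError("dx must be strictly positive")

    def per_strain(self, name: str, n: int) -> np.ndarray:
        v = np.asarray(getattr(self, name), dtype=float)
        if v.ndim == 0:
            return np.full(n, float(v))
        if v.shape != (n,):
            raise ValueError(f"{name} must be scalar or length {n}")
        return v


@dataclass(frozen=True)
class SeedInit:
    """One seeded colony: a smoothed disc of free density.

    ``position`` is in mm (a scalar in 1-D, an (x, y) pair in 2-D);
    ``amount`` is the plateau amplitude as a fraction of ``rho_max``
    (a 1-ul drop of overnight culture is far below carrying capacity);
    ``radius`` the footprint radius in mm; ``delay`` an onset delay in h
    (the drop appears in the field once t >= delay, emulating a lower
    seeding concentration, see :func:`delay_from_dilution`).
    """

    position: float | tuple[float, float]
    strain: int = 0
    amount: float = 0.1
    radius: float = 1.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.amount <= 1:
            raise ValueError("amount must lie in (0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be strictly positive")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")


@dataclass
class FieldState:
    """Gridded free and bound densities for every strain at one time.

    ``rho`` and ``bound`` have shape (n_strains, nx) in 1-D or
    (n_strains, ny, nx) in 2-D; ``dx`` is the spacing and ``origin`` the
    coordinate of the first grid point (pixel-centre convention).
    """

    rho: np.ndarray
    bound: np.ndarray
    t: float
    dx: float
    origin: tuple[float, ...] = (0.0,)

    @property
    def total(self) -> np.ndarray:
        """Per-strain total density rho_i + b_i."""
        return self.rho + self.bound

    @property
    def rho_T(self) -> np.ndarray:
        """Total density over strains, free plus bound."""
        return self.total.sum(axis=0)

    @property
    def ndim(self) -> int:
        return self.rho.ndim - 1

    def axis_coords(self, axis: int = -1) -> np.ndarray:
        n = self.rho.shape[axis]
        o = self.origin[axis] if self.ndim > 1 else self.origin[0]
        return o + self.dx * np.arange(n)

    def mass(self, strain: int | None = None) -> float:
        """Spatial integral of free + bound density (mm^ndim units)."""
        cell = self.dx ** self.ndim
        if strain is None:
            return float(self.rho_T.sum() * cell)
        return float(self.total[strain].sum() * cell)


def _seed_profile(shape, dx, origin, seed: SeedInit) -> np.ndarray:
    """Smoothed-disc footprint, 1 inside, 0 outside, tanh shoulder ~2*dx."""
    if len(shape) == 1:
        x = origin[0] + dx * np.arange(shape[0])
        r = np.abs(x - float(np.atleast_1d(seed.position)[0]))
    else:
        y = origin[0] + dx * np.arange(shape[0])
        x = origin[1] + dx * np.arange(shape[1])
        px, py = seed.position  # type: ignore[misc]
        r = np.hypot(x[None, :] - px, y[:, None] - py)
    smooth = 2.0 * dx
    return 0.5 * (1.0 - np.tanh((r - seed.radius) / smooth))


def _laplacian_flux(f: np.ndarray, mob: np.ndarray | None, dx: float) -> np.ndarray:
    """Conservative div(mob * grad f) with no-flux boundaries.

    ``mob`` is the cell-centred mobility (or None for unit mobility);
    face mobilities are arithmetic means.  Zero boundary flux makes the
    operator exactly mass-conserving.
    """
    out = np.zeros_like(f)
    for ax in range(f.ndim):
        df = np.diff(f, axis=ax) / dx  # gradient at interior faces
        if mob is not None:
            m0 = np.take(mob, range(mob.shape[ax] - 1), axis=ax)
            m1 = np.take(mob, range(1, mob.shape[ax]), axis=ax)
            flux = 0.5 * (m0 + m1) * df
        else:
            flux = df
        # divergence: (flux_right - flux_left) / dx, zero flux at walls
        pad = [(0, 0)] * f.ndim
        pad[ax] = (1, 1)
        flux = np.pad(flux, pad)
        out += np.diff(flux, axis=ax) / dx
    return out


def _complementarity_matrix(elements: Sequence[Element | str]) -> np.ndarray:
    els = [parse_element(e) if isinstance(e, str) else e for e in elements]
    n = len(els)
    C = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        C[i, j] = C[j, i] = visible_interface(els[i], els[j])
    return C


def simulate(
    seeds: Sequence[SeedInit],
    params: ModelParams,
    elements: Sequence[Element | str] | None = None,
    *,
    t_end: float = 18.0,
    snapshot_every: float | None = None,
    interaction: np.ndarray | None = None,
) -> list[FieldState]:
    """Integrate the model and return a trajectory of snapshots.

    Parameters
    ----------
    seeds
        Initial colonies.  ``seed.strain`` indexes into ``elements``.
    params
        Model and grid parameters.
    elements
        One adhesion element per strain (Element or text syntax such as
        ``"Nb2"`` / ``"Nb2+Ag3"``).  Strains i, j interact adhesively iff
        their elements are cross-complementary.  If omitted, ``interaction``
        must give the boolean strain-interaction matrix directly.
    t_end, snapshot_every
        Total simulated time (h) and snapshot cadence; the final state is
        always included.  ``snapshot_every=None`` records only start/end.
    interaction
        Explicit symmetric boolean matrix overriding ``elements``.

    Returns
    -------
    list of FieldState

    Raises
    ------
    SolverError
        If densities go NaN or significantly negative, naming the violated
        stability bound.
    """
    if len(seeds) == 0:
        raise ValueError("at least one seed required")
    n_strains = max(s.strain for s in seeds) + 1
    if interaction is None:
        if elements is None:
            raise ValueError("provide elements or an interaction matrix")
        if len(elements) < n_strains:
            raise ValueError("fewer elements than strains")
        C = _complementarity_matrix(elements)[:n_strains, :n_strains]
    else:
        C = np.asarray(interaction, dtype=bool)
        if C.shape != (n_strains, n_strains) or not np.array_equal(C, C.T):
            raise ValueError("interaction must be a symmetric n_strains matrix")

    ndim = 1 if np.ndim(seeds[0].position) == 0 else 2
    extent = params.extent
    if np.ndim(extent) == 0:
        extent = (float(extent),) * ndim
    dx = params.dx if params.dx is not None else (0.025 if ndim == 1 else 0.1)
    shape = tuple(int(round(e / dx)) + 1 for e in reversed(extent))  # (ny, nx)
    if ndim == 1:
        shape = (int(round(extent[0] / dx)) + 1,)
    origin = (0.0,) * ndim

    D = params.per_strain("D", n_strains)
    g = params.per_strain("g", n_strains)
    K = params.K
    rho_max = params.rho_max

    # explicit stability: dt <= dx^2 / (2*ndim*Dmax); growth accuracy cap.
    dt = params.safety * dx * dx / (2.0 * ndim * D.max())
    if g.max() > 0:
        dt = min(dt, 0.2 / g.max())
    n_steps = max(1, int(np.ceil(t_end / dt)))
    dt = t_end / n_steps

    rho = np.zeros((n_strains,) + shape)
    bnd = np.zeros_like(rho)
    pending = sorted(seeds, key=lambda s: s.delay)
    footprints = {id(s): s.amount * rho_max * _seed_profile(shape, dx, origin, s)
                  for s in pending}

    def place(t_now: float) -> None:
        while pending and pending[0].delay <= t_now + 1e-12:
            s = pending.pop(0)
            rho[s.strain] = np.maximum(rho[s.strain], footprints.pop(id(s)))

    place(0.0)
    traj = [FieldState(rho.copy(), bnd.copy(), 0.0, dx, origin)]
    next_snap = snapshot_every if snapshot_every else np.inf
    neg_tol = 1e-9 * rho_max

    for step in range(n_steps):
        t_now = (step + 1) * dt
        rho_T = (rho + bnd).sum(axis=0)

        # adhesion: exact exponential exchange (c_i = rho_i + b_i invariant)
        if K > 0 and C.any():
            c = rho + bnd
            rate = K * np.tensordot(C.astype(float), c, axes=(1, 0))
            rho_new = rho * np.exp(-rate * dt)
            bnd = c - rho_new
            rho = rho_new
            rho_T = c.sum(axis=0)

        # logistic growth (explicit)
        if g.max() > 0:
            factor = 1.0 - rho_T / rho_max
            grew = rho * (g[(...,) + (None,) * ndim] * factor)
            if params.bound_growth:
                bnd = bnd + dt * bnd * (g[(...,) + (None,) * ndim] * factor)
            rho = rho + dt * grew
            rho_T = (rho + bnd).sum(axis=0)

        # diffusion of the free phase only
        mob = None
        if params.motility == "crowding":
            mob = np.clip(1.0 - rho_T / rho_max, 0.0, None)
        for i in range(n_strains):
            rho[i] += dt * D[i] * _laplacian_flux(rho[i], mob, dx)

        if not np.all(np.isfinite(rho)) or rho.min() < -1e4 * neg_tol:
            raise SolverError(
                f"instability at t = {t_now:.3f} h (min rho = {rho.min():.3e}): "
                f"explicit bound dt <= dx^2/(2*ndim*D) = "
                f"{dx * dx / (2 * ndim * D.max()):.3e} h violated or parameters "
                "too stiff; reduce dt via ModelParams.safety or refine dx"
            )
        np.clip(rho, 0.0, None, out=rho)

        place(t_now)
        if t_now >= next_snap - 1e-9 and step < n_steps - 1:
            traj.append(FieldState(rho.copy(), bnd.copy(), t_now, dx, origin))
            next_snap += snapshot_every  # type: ignore[operator]

    traj.append(FieldState(rho.copy(), bnd.copy(), t_end, dx, origin))
    return traj


def fluorescence_profile(
    state: FieldState,
    strain: int,
    axis: tuple[tuple[float, float], tuple[float, float]] | None = None,
    *,
    bin_width: float = 1.5,
    normalize: bool = False,
    n_samples: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a strain's total (free + bound) density along a line.

    Cytoplasmic fluorophores label free and bound cells alike, so the
    modelled intensity is ``rho_i + b_i``.  In 2-D the intensity is averaged
    across ``bin_width`` (mm) perpendicular to the line, emulating the
    ~1.5-mm-thick measurement band used on micrographs.  In 1-D ``axis``
    may be a pair of scalars (x0, x1); default is the full domain.

    Returns ``(s, intensity)`` where ``s`` is the arc-length coordinate in
    mm from the start of the line.
    """
    if state.ndim == 1:
        x = state.axis_coords()
        prof = state.total[strain]
        if axis is not None:
            x0, x1 = float(np.ravel(axis)[0]), float(np.ravel(axis)[-1])
            if not (x[0] - 1e-9 <= x0 <= x[-1] + 1e-9 and
                    x[0] - 1e-9 <= x1 <= x[-1] + 1e-9):
                raise ValueError("axis extends outside the domain")
            m = (x >= min(x0, x1) - 1e-9) & (x <= max(x0, x1) + 1e-9)
            x, prof = x[m] - min(x0, x1), prof[m]
        intensity = prof.astype(float).copy()
        s = x - x[0] if axis is None else x
    else:
        if axis is None:
            raise ValueError("axis (two endpoints) required in 2-D")
        (x0, y0), (x1, y1) = axis
        length = float(np.hypot(x1 - x0, y1 - y0))
        n = n_samples or max(2, int(round(length / state.dx)) + 1)
        s = np.linspace(0.0, length, n)
        ux, uy = (x1 - x0) / length, (y1 - y0) / length
        # perpendicular unit vector for the averaging band
        px, py = -uy, ux
        offsets = np.linspace(-bin_width / 2, bin_width / 2,
                              max(1, int(round(bin_width / state.dx)) + 1))
        xs = x0 + s[None, :] * ux + offsets[:, None] * px
        ys = y0 + s[None, :] * uy + offsets[:, None] * py
        oy, ox = state.origin
        ny, nx = state.total[strain].shape
        ci = (ys - oy) / state.dx
        cj = (xs - ox) / state.dx
        if ci.min() < -0.5 or cj.min() < -0.5 or ci.max() > ny - 0.5 or cj.max() > nx - 0.5:
            raise ValueError("axis/bin extends outside the domain")
        vals = ndimage.map_coordinates(state.total[strain], [ci, cj],
                                       order=1, mode="nearest")
        intensity = vals.mean(axis=0)
    if normalize and intensity.max() > 0:
        intensity = intensity / intensity.max()
    return s, intensity


def delay_from_dilution(ratio: float, g: float) -> float:
    """Swarming-onset delay equivalent to a fold-dilution of the inoculum.

    Exponential growth recovers a ``ratio``-fold dilution after
    ``tau = ln(ratio) / g`` hours; a colony seeded that much more dilute
    behaves like an undiluted colony delayed by tau.
    """
    if ratio < 1:
        raise ValueError("dilution ratio must be >= 1")
    if g <= 0:
        raise ValueError("growth rate must be strictly positive")
    return float(np.log(ratio) / g)


def interface_assay(
    K: float = PAPER_K_PER_H,
    *,
    spacing: float = 9.0,
    t_end: float = 2.5,
    params: ModelParams | None = None,
    elements: tuple[str, str] = ("Nb2", "Ag2"),
    window: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, FieldState]:
    """Standard 1-D two-colony interface assay.

    Two complementary colonies seeded ``spacing`` mm apart on a 40-mm
    line, integrated for ``t_end`` h of active swarming; returns the
    normalized free+bound profile of the first strain along a ``window``-mm
    segment centred between the seeds (abscissa from the window start,
    mm), plus the final field state.  ``K`` overrides the adhesion
    strength (0 for the non-adhesive control).
    """
    p = params if params is not None else ModelParams()
    p = replace(p, K=K, extent=40.0, dx=p.dx if p.dx is not None else 0.025)
    mid = 20.0
    seeds = [SeedInit(mid - spacing / 2, 0), SeedInit(mid + spacing / 2, 1)]
    state = simulate(seeds, p, list(elements), t_end=t_end)[-1]
    x, inten = fluorescence_profile(
        state, 0, (mid - window / 2, mid + window / 2), normalize=True)
    x = np.where(x <= 0, 1e-6, x)
    return x, inten, state


def front_position(state: FieldState, strain: int = 0, level: float = 0.5,
                   direction: int = +1) -> float:
    """Outermost position (mm) where a strain's total density crosses level.

    1-D only; ``direction=+1`` scans for the rightmost crossing, ``-1`` for
    the leftmost.  Linear interpolation between grid points.
    """
    if state.ndim != 1:
        raise ValueError("front_position is defined for 1-D states")
    x = state.axis_coords()
    f = state.total[strain]
    above = f >= level
    if not above.any():
        raise ValueError("density never reaches the requested level")
    idx = np.flatnonzero(above)
    if direction >= 0:
        i = idx[-1]
        if i == len(x) - 1:
            return float(x[-1])
        frac = (f[i] - level) / (f[i] - f[i + 1]) if f[i] != f[i + 1] else 0.0
        return float(x[i] + frac * state.dx)
    i = idx[0]
    if i == 0:
        return float(x[0])
    frac = (f[i] - level) / (f[i] - f[i - 1]) if f[i] != f[i - 1] else 0.0
    return float(x[i] - frac * state.dx)
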