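"""Quantification statistics for interfaces and point patterns.

Interface profiles are fitted with a generalized Hill function plus a
Gaussian shoulder term,

    f(x) = z / (1 + (k_a / x)**n) + y + a * exp(-x**2 / b),

where ``n`` is the Hill coefficient, ``k_a`` the half-maximum position of
the transition, ``z`` the Hill weight (negative for a falling profile),
``y`` a vertical offset and ``a``, ``b`` the weight and squared length
scale of the Gaussian that absorbs plateau slope.  (``b`` multiplies
``x**2`` directly, so dimensionally it is a squared length, mm^2, despite
often being described loosely as a standard deviation.)  The interface
width ``w`` is the distance between the two points of maximum curvature

    kappa = |f''(x)| / (1 + f'(x)**2)**(3/2)

flanking the transition midpoint ``k_a``, with x in mm and the intensity
normalized to its maximum -- the convention used when reading widths off
normalized fluorescence profiles.

For microscopic point patterns the multicomponent (cross-type) pair
correlation ``g_ab(r)`` counts, around each type-a cell, the type-b cells
in the annulus r..r+dr, normalized by the annulus area clipped to the
observation window (exact circle-rectangle intersection areas; no border
points are discarded) and by the global type-b density; g = 1 for complete
spatial randomness, g > 1 indicates clustering.  The short-range excursion
of g(r) above baseline is summarized by an exponentially modified Gaussian
(EMG) fit whose variance sigma**2 + 1/lambda**2 serves as the
characteristic clustering width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, spatial, stats as sps

__all__ = [
    "ProfileFit",
    "PairCorrelation",
    "EMGFit",
    "FitError",
    "hill_gauss",
    "fit_profile",
    "interface_width",
    "pair_correlation",
    "emg_variance",
    "circle_rectangle_area",
]


class FitError(RuntimeError):
    """A least-squares fit failed to converge or is degenerate."""


# -- Hill + Gaussian profile model -------------------------------------------

def _hill_sigma(x, k_a, n):
    # 1 / (1 + (k_a/x)**n) written as a logistic in log-space: stable for
    # any n and x/k_a ratio
    from scipy.special import expit

    return expit(n * np.log(x / k_a))


def hill_gauss(x, z, k_a, n, y, a, b):
    """The heuristic profile model (see module docstring)."""
    x = np.asarray(x, dtype=float)
    return z * _hill_sigma(x, k_a, n) + y + a * np.exp(-x * x / b)


def _hill_gauss_d1(x, z, k_a, n, y, a, b):
    x = np.asarray(x, dtype=float)
    s = _hill_sigma(x, k_a, n)
    dh = z * n * s * (1.0 - s) / x
    dg = a * (-2.0 * x / b) * np.exp(-x * x / b)
    return dh + dg


def _hill_gauss_d2(x, z, k_a, n, y, a, b):
    x = np.asarray(x, dtype=float)
    s = _hill_sigma(x, k_a, n)
    dh = z * n * s * (1.0 - s) * (n * (1.0 - 2.0 * s) - 1.0) / (x * x)
    dg = a * (4.0 * x * x / (b * b) - 2.0 / b) * np.exp(-x * x / b)
    return dh + dg


@dataclass(frozen=True)
class ProfileFit:
    """Fitted profile parameters, curvature width and residual."""

    z: float
    k_a: float
    n: float
    y: float
    a: float
    b: float
    w: float            # curvature-based transition width, mm
    residual_rms: float
    x_range: tuple[float, float]

    def __call__(self, x):
        return hill_gauss(x, self.z, self.k_a, self.n, self.y, self.a, self.b)

    def curvature(self, x):
        """kappa(x) = |f''| / (1 + f'^2)^(3/2) of the fitted curve."""
        p = (self.z, self.k_a, self.n, self.y, self.a, self.b)
        d1 = _hill_gauss_d1(x, *p)
        d2 = _hill_gauss_d2(x, *p)
        return np.abs(d2) / (1.0 + d1 * d1) ** 1.5


def fit_profile(x: np.ndarray, intensity: np.ndarray) -> ProfileFit:
    """Least-squares fit of the Hill+Gaussian model to a profile.

    ``x`` must be strictly positive and increasing (the Hill term is
    defined for x > 0) with at least 20 points.  Initialization is
    deterministic: ``k_a`` at the mid-intensity crossing, ``n = 4``,
    ``z`` the signed intensity range, ``y`` the starting plateau,
    ``a = 0``, ``b = (x-range / 4)**2``; bounded trust-region
    optimization.  Identical inputs give bit-identical fits.

    Raises
    ------
    ValueError
        On invalid abscissae or too few points.
    FitError
        On non-convergence, with the initialization in the message.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(intensity, dtype=float)
    if x.ndim != 1 or x.shape != f.shape:
        raise ValueError("x and intensity must be 1-D arrays of equal length")
    if len(x) < 20:
        raise ValueError("need at least 20 profile points")
    if x[0] <= 0 or np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly positive and increasing")

    rng_f = float(f.max() - f.min())
    if rng_f == 0:
        raise FitError("flat profile: nothing to fit")
    rising = f[-1] >= f[0]
    z0 = rng_f if rising else -rng_f
    y0 = float(f.min() if rising else f.max())
    mid = y0 + z0 / 2.0
    sgn = np.sign(z0)
    crossings = np.flatnonzero(np.diff(np.sign(sgn * (f - mid))) > 0)
    k0 = float(x[crossings[0]]) if len(crossings) else float(np.median(x))
    b0 = ((x[-1] - x[0]) / 4.0) ** 2
    p0 = [z0, k0, 4.0, y0, 0.0, b0]
    span = float(x[-1] - x[0])
    lb = [-4 * rng_f, x[0] * 0.25, 0.5, f.min() - 2 * rng_f, -2 * rng_f,
          (span / 100.0) ** 2]
    ub = [4 * rng_f, x[-1] * 4.0, 64.0, f.max() + 2 * rng_f, 2 * rng_f,
          (10.0 * span) ** 2]
    p0 = np.clip(p0, lb, ub)
    try:
        popt, _ = optimize.curve_fit(
            hill_gauss, x, f, p0=p0, bounds=(lb, ub), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(
            f"profile fit did not converge (init z={p0[0]:.3g}, "
            f"k_a={p0[1]:.3g}, n={p0[2]:.3g}, y={p0[3]:.3g}, a={p0[4]:.3g}, "
            f"b={p0[5]:.3g}): {exc}"
        ) from exc
    resid = hill_gauss(x, *popt) - f
    fit = ProfileFit(*map(float, popt), w=np.nan,
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))),
                     x_range=(float(x[0]), float(x[-1])))
    w = interface_width(fit)
    object.__setattr__(fit, "w", w)
    return fit


def interface_width(fit: ProfileFit, n_grid: int = 10000) -> float:
    """Distance between the two curvature maxima flanking the transition.

    The curvature of the fitted curve is evaluated analytically on a dense
    grid over the fitted x-range; the local maxima nearest ``k_a`` on
    either side are polished by bounded scalar maximization and their
    separation returned (mm).  Translating the profile along x leaves the
    width unchanged.

    Raises
    ------
    FitError
        If fewer than two curvature maxima flank the midpoint.
    """
    x0, x1 = fit.x_range
    x0 = max(x0, 1e-9)
    xs = np.linspace(x0, x1, n_grid)
    k = fit.curvature(xs)
    interior = (k[1:-1] >= k[:-2]) & (k[1:-1] >= k[2:])
    peaks = np.flatnonzero(interior) + 1
    px = xs[peaks]
    left = px[px < fit.k_a]
    right = px[px > fit.k_a]
    h = (x1 - x0) / (n_grid - 1)
    # very gradual flanks can place the curvature maximum at the window
    # edge; fall back to the endpoint when the edge dominates that side
    if len(left) == 0 and fit.k_a > x0 and k[0] > 0:
        lo = x0
    elif len(left) == 0:
        raise FitError(
            "no curvature maximum below the transition midpoint k_a"
        )
    else:
        lo = left.max()
        lo = _polish_max(fit.curvature, lo - h, lo + h)
    if len(right) == 0 and fit.k_a < x1 and k[-1] > 0:
        hi = x1
    elif len(right) == 0:
        raise FitError(
            "no curvature maximum above the transition midpoint k_a"
        )
    else:
        hi = right.min()
        hi = _polish_max(fit.curvature, hi - h, hi + h)
    if not lo < fit.k_a < hi:
        raise FitError(
            "curvature maxima do not flank the transition midpoint k_a"
        )
    return float(hi - lo)


def _polish_max(f, a, b) -> float:
    res = optimize.minimize_scalar(
        lambda u: -f(u), bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# -- multicomponent pair correlation -----------------------------------------

def circle_rectangle_area(
    cx: np.ndarray, cy: np.ndarray, r: np.ndarray,
    rect: tuple[float, float, float, float],
) -> np.ndarray:
    """Exact area of circles (centres cx, cy; radii r) clipped to a rectangle.

    Closed form by inclusion-exclusion of the cumulative function
    F(x, y) = area of the circle within (-inf, x] x (-inf, y].
    Broadcasts over any common shape of cx, cy, r.
    """
    x0, y0, x1, y1 = rect
    cx, cy, r = np.broadcast_arrays(
        np.asarray(cx, float), np.asarray(cy, float), np.asarray(r, float)
    )
    return (_circ_cum(x1 - cx, y1 - cy, r) - _circ_cum(x0 - cx, y1 - cy, r)
            - _circ_cum(x1 - cx, y0 - cy, r) + _circ_cum(x0 - cx, y0 - cy, r))


def _int_halfchord(u: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Antiderivative of sqrt(r^2 - u^2): (u*c + r^2*asin(u/r)) / 2."""
    u = np.clip(u, -r, r)
    c = np.sqrt(np.maximum(r * r - u * u, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        asin = np.arcsin(np.where(r > 0, u / np.where(r > 0, r, 1.0), 0.0))
    return 0.5 * (u * c + r * r * asin)


def _circ_cum(x: np.ndarray, y: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Area of a radius-r circle at the origin inside {X <= x, Y <= y}."""
    xm = np.clip(x, -r, r)
    s = np.sqrt(np.maximum(r * r - np.minimum(y * y, r * r), 0.0))
    # integration split where the chord half-height c(u) crosses |y|
    lo, hi = -r, xm
    a = np.clip(-s, lo, hi)   # [-r, -s]: full chord if y >= 0 else empty
    b = np.clip(s, lo, hi)    # [-s, s]: mixed region
    ypos = y >= 0
    full = np.where(
        ypos,
        2.0 * (_int_halfchord(a, r) - _int_halfchord(lo, r))
        + 2.0 * (_int_halfchord(hi, r) - _int_halfchord(b, r)),
        0.0,
    )
    yy = np.clip(y, -r, r)
    mixed = (yy * (b - a)
             + (_int_halfchord(b, r) - _int_halfchord(a, r)))
    return full + np.where(b > a, mixed, 0.0)


@dataclass(frozen=True)
class PairCorrelation:
    """Radial cross-type pair correlation with its binning and window."""

    r: np.ndarray               # bin centres
    g: np.ndarray               # g(r) per bin
    bin_edges: np.ndarray
    window: tuple[float, float, float, float] | None
    n_a: int
    n_b: int


def pair_correlation(
    points_a: np.ndarray,
    points_b: np.ndarray,
    bin_edges: Sequence[float],
    window: tuple[float, float, float, float],
    *,
    periodic: bool = False,
) -> PairCorrelation:
    """Cross-type pair correlation g_ab(r) with exact edge correction.

    For each type-a point the type-b points are counted per annulus
    r..r+dr; counts are divided by the annulus area clipped to the
    rectangular ``window`` (xmin, ymin, xmax, ymax) and by the global
    type-b intensity, then averaged over type-a points.  Coordinates and
    bins share one length unit (typically um).  With ``periodic=True`` the
    window is treated as a torus (minimum-image distances, uncorrected
    annulus areas), which is the exact reference the corrected estimate
    converges to for large windows at fixed density.

    When ``points_a is points_b`` self-pairs are excluded (univariate g).

    Raises
    ------
    ValueError
        On an empty window or fewer than two points of a type.
    """
    pa = np.atleast_2d(np.asarray(points_a, dtype=float))
    pb = np.atleast_2d(np.asarray(points_b, dtype=float))
    edges = np.asarray(bin_edges, dtype=float)
    if len(pa) < 2 or len(pb) < 2:
        raise ValueError("need at least two points per type")
    if np.any(edges < 0) or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be non-negative and increasing")
    x0, y0, x1, y1 = window
    area_w = (x1 - x0) * (y1 - y0)
    if area_w <= 0:
        raise ValueError("empty observation window")
    lam_b = len(pb) / area_w
    same = points_a is points_b

    if periodic:
        Lx, Ly = x1 - x0, y1 - y0
        d = pa[:, None, :] - pb[None, :, :]
        d[..., 0] -= Lx * np.round(d[..., 0] / Lx)
        d[..., 1] -= Ly * np.round(d[..., 1] / Ly)
        dist = np.hypot(d[..., 0], d[..., 1])
    else:
        dist = spatial.distance.cdist(pa, pb)
    if same:
        np.fill_diagonal(dist, np.inf)

    counts = np.stack([
        np.histogram(row[np.isfinite(row)], bins=edges)[0] for row in dist
    ])  # (n_a, n_bins)

    if periodic:
        ring = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        areas = np.broadcast_to(ring, counts.shape)
    else:
        outer = circle_rectangle_area(
            pa[:, 0:1], pa[:, 1:2], edges[None, 1:], window)
        inner = circle_rectangle_area(
            pa[:, 0:1], pa[:, 1:2], edges[None, :-1], window)
        areas = outer - inner
    with np.errstate(divide="ignore", invalid="ignore"):
        g_per_a = counts / (areas * lam_b)
        g_per_a[~np.isfinite(g_per_a)] = np.nan
    g = np.nanmean(g_per_a, axis=0)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return PairCorrelation(centres, g, edges, None if periodic else window,
                           len(pa), len(pb))


# -- EMG clustering-width fit -------------------------------------------------

@dataclass(frozen=True)
class EMGFit:
    """Exponentially modified Gaussian fitted to g(r) above baseline 1.

    ``variance = sigma**2 + 1/lambda**2`` is the clustering-width summary.
    ``ok`` is False when no meaningful fit was possible (flat g(r) or
    excursion below twice the residual noise), mirroring how non-adhesive
    pairs admit no fit.
    """

    mu: float
    sigma: float
    lam: float
    amplitude: float
    ok: bool
    residual_rms: float

    @property
    def variance(self) -> float:
        if not self.ok:
            return np.nan
        return self.sigma ** 2 + 1.0 / self.lam ** 2

    def __call__(self, r):
        return self.amplitude * _emg_pdf(r, self.mu, self.sigma, self.lam) + 1.0


def _emg_pdf(r, mu, sigma, lam):
    return sps.exponnorm.pdf(r, K=1.0 / (sigma * lam), loc=mu, scale=sigma)


def emg_variance(corr: PairCorrelation | tuple[np.ndarray, np.ndarray]) -> EMGFit:
    """Fit ``amplitude * EMG(r; mu, sigma, lambda) + 1`` to g(r).

    The additive baseline is fixed at 1 (the large-r limit of g).
    Initialization is deterministic from the location, height and width of
    the excursion above baseline.  A *no-fit* result (``ok=False``) is
    returned when the fitted excursion amplitude is below twice the
    residual RMS.
    """
    if isinstance(corr, PairCorrelation):
        r, g = corr.r, corr.g
    else:
        r, g = corr
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    good = np.isfinite(g)
    r, g = r[good], g[good]
    if len(r) < 6:
        raise ValueError("too few finite g(r) bins")
    exc = g - 1.0
    i_pk = int(np.argmax(exc))
    height = float(exc[i_pk])
    if height <= 0:
        return EMGFit(np.nan, np.nan, np.nan, 0.0, False,
                      float(np.sqrt(np.mean(exc ** 2))))
    # crude width from the span above half height
    above = np.flatnonzero(exc >= height / 2.0)
    span = float(r[above[-1]] - r[above[0]]) if len(above) > 1 else float(
        r[1] - r[0])
    sig0 = max(span / 2.355, (r[1] - r[0]) / 2.0)
    lam0 = 1.0 / sig0
    mu0 = float(r[i_pk]) - sig0
    pdf_pk = _emg_pdf(r[i_pk], mu0, sig0, lam0)
    amp0 = height / pdf_pk if pdf_pk > 0 else height * sig0

    def model(rr, amp, mu, sigma, lam):
        return amp * _emg_pdf(rr, mu, sigma, lam) + 1.0

    rmax = float(r[-1])
    try:
        popt, _ = optimize.curve_fit(
            model, r, g, p0=[amp0, mu0, sig0, lam0],
            bounds=([0.0, -rmax, 1e-6, 1e-6],
                    [np.inf, rmax, rmax, 1e6]),
            maxfev=20000,
        )
    except RuntimeError:
        return EMGFit(np.nan, np.nan, np.nan, 0.0, False,
                      float(np.sqrt(np.mean(exc ** 2))))
    resid = model(r, *popt) - g
    rms = float(np.sqrt(np.mean(resid ** 2)))
    amp, mu, sigma, lam = map(float, popt)
    peak = float(np.max(amp * _emg_pdf(r, mu, sigma, lam)))
    ok = peak >= 2.0 * rms
    return EMGFit(mu, sigma, lam, amp, ok, rms)
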