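"""Spatial statistics: semivariograms, spherical fits, radial spectra, and
calibration of the smoothness multiplier against a target variogram range.

The empirical semivariogram uses the classical Matheron estimator

    gamma_hat(h) = sum (z_i - z_j)^2 / (2 N(h))

over all pixel pairs whose Euclidean separation falls in a lag bin.  On a
regular grid this is computed by enumerating lattice offset vectors, which
is exact (identical to an all-pairs loop) and fast.

The spherical model fitted to it is

    gamma(h) = c0 + c * (1.5 h/a - 0.5 (h/a)^3)   for h <= a
             = c0 + c                              for h > a

with nugget c0, partial sill c and range a.  Two fit modes exist:

* free: 3-parameter weighted nonlinear least squares (exact on noise-free
  model curves);
* constrained: the total sill c0 + c is pinned to a known field variance
  and only (c0, a) are fitted.  This is the mode used for ensemble range
  statistics of generated fields, whose population variance is enforced
  exactly by construction; it keeps the range identifiable even when the
  variogram has no plateau inside the maximum lag.

Calibration maps a target range to a multiplier gamma by fitting a
generalized logistic (Richards) curve to mean fitted range as a function of
log10(gamma) and inverting it in closed form.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .field_generator import FieldSpec, RasterGrid, build_difference_operator, build_smoother, generate_field

__all__ = [
    "Semivariogram",
    "SphericalFit",
    "RadialSpectrum",
    "CalibrationCurve",
    "EnsembleVariogramStats",
    "FitError",
    "empirical_semivariogram",
    "spherical_model",
    "fit_spherical",
    "radial_power_spectrum",
    "ensemble_range_statistics",
    "build_calibration_curve",
    "calibrate_gamma",
]

logger = logging.getLogger(__name__)

#: Fitted ranges may extend this many times past the largest lag; fits that
#: would run further are treated as unidentifiable rather than chased.
RANGE_BOUND_FACTOR = 20.0


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or was unidentifiable."""


@dataclass(frozen=True)
class Semivariogram:
    """Binned isotropic empirical semivariogram."""

    lag_centers: np.ndarray   # metres; pair-weighted mean distance per bin
    gamma_hat: np.ndarray     # semivariance per bin (variance units)
    pair_counts: np.ndarray   # pairs per bin

    def __post_init__(self) -> None:
        lags = np.asarray(self.lag_centers, dtype=float)
        g = np.asarray(self.gamma_hat, dtype=float)
        n = np.asarray(self.pair_counts, dtype=np.int64)
        if not (lags.size == g.size == n.size):
            raise ValueError("semivariogram arrays must have equal length")
        if lags.size == 0:
            raise ValueError("semivariogram has no bins")
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lag_centers must be strictly increasing")
        if np.any(g < 0) or np.any(n <= 0):
            raise ValueError("gamma_hat must be >= 0 and pair_counts > 0")
        object.__setattr__(self, "lag_centers", lags)
        object.__setattr__(self, "gamma_hat", g)
        object.__setattr__(self, "pair_counts", n)

    @property
    def n_bins(self) -> int:
        return self.lag_centers.size


def empirical_semivariogram(
    grid: RasterGrid,
    max_lag: Optional[float] = None,
    bin_width: Optional[float] = None,
) -> Semivariogram:
    """Isotropic Matheron semivariogram of a gridded field.

    Lags are binned at nominal centres ``k * bin_width`` (edges at
    ``(k -/+ 0.5) * bin_width``), the first bin starting at one pixel.
    ``max_lag`` defaults to half the longer grid side length in metres and
    ``bin_width`` to the pixel size.  Reported lag centres are the
    pair-count-weighted mean separation within each bin; empty bins are
    dropped.  A constant grid is legal and returns zeros.
    """
    z = grid.values
    n_rows, n_cols = z.shape
    if z.size < 2:
        raise ValueError("grid must contain at least 2 pixels")
    px = grid.pixel_size
    if max_lag is None:
        max_lag = 0.5 * max(n_rows, n_cols) * px
    if bin_width is None:
        bin_width = px
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    max_lag_pix = max_lag / px

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dist_sums: dict[int, float] = {}
    # half-plane of lattice offsets: each unordered pair counted once
    dmax = int(np.floor(max_lag_pix))
    for dy in range(0, min(dmax, n_rows - 1) + 1):
        for dx in range(-dmax, dmax + 1):
            if dy == 0 and dx <= 0:
                continue
            if abs(dx) > n_cols - 1:
                continue
            d_pix = np.hypot(dx, dy)
            if d_pix > max_lag_pix:
                continue
            n_r, n_c = n_rows - dy, n_cols - abs(dx)
            if dx >= 0:
                a = z[:n_r, :n_c]
                b = z[dy:, dx:]
            else:
                a = z[:n_r, -dx:]
                b = z[dy:, :n_c]
            d_m = d_pix * px
            k = int(np.floor(d_m / bin_width + 0.5))
            if k < 1:
                k = 1
            sums[k] = sums.get(k, 0.0) + float(np.sum((a - b) ** 2))
            counts[k] = counts.get(k, 0) + a.size
            dist_sums[k] = dist_sums.get(k, 0.0) + d_m * a.size
    if not counts:
        raise ValueError("no pixel pairs fall within max_lag")
    ks = sorted(counts)
    lag_centers = np.array([dist_sums[k] / counts[k] for k in ks])
    gamma_hat = np.array([sums[k] / (2.0 * counts[k]) for k in ks])
    pair_counts = np.array([counts[k] for k in ks], dtype=np.int64)
    return Semivariogram(lag_centers, gamma_hat, pair_counts)


@dataclass(frozen=True)
class SphericalFit:
    """Fitted spherical variogram model parameters."""

    nugget: float
    partial_sill: float
    range_m: float
    converged: bool = True
    identifiable: bool = True

    @property
    def total_sill(self) -> float:
        return self.nugget + self.partial_sill


def spherical_model(
    h: np.ndarray, nugget: float, partial_sill: float, range_m: float
) -> np.ndarray:
    """Evaluate the spherical variogram model at lags ``h`` (metres)."""
    h = np.asarray(h, dtype=float)
    r = np.minimum(h / range_m, 1.0)
    return nugget + partial_sill * (1.5 * r - 0.5 * r**3)


def _fit_sigma(sv: Semivariogram, weights: str) -> Optional[np.ndarray]:
    n = sv.pair_counts.astype(float)
    if weights == "counts":
        return 1.0 / np.sqrt(n)
    if weights == "cressie":
        return sv.lag_centers / np.sqrt(n)
    if weights == "equal":
        return None
    raise ValueError(f"unknown weighting scheme: {weights!r}")


def fit_spherical(
    sv: Semivariogram,
    total_sill: Optional[float] = None,
    weights: str = "cressie",
    on_flat: str = "raise",
) -> SphericalFit:
    """Fit the spherical model to an empirical semivariogram.

    Parameters
    ----------
    sv:
        Empirical semivariogram with at least 4 bins.
    total_sill:
        If given, constrain ``nugget + partial_sill`` to this value (e.g.
        the exactly-known field variance) and fit only nugget and range.
        If None, all three parameters are free.
    weights:
        ``"cressie"`` (default, sigma ~ h/sqrt(N)), ``"counts"``
        (sigma ~ 1/sqrt(N)) or ``"equal"``.
    on_flat:
        ``"raise"`` (default) or ``"flag"``: what to do when the
        semivariogram carries no variance structure, making the range
        unidentifiable.  Flagged fits return range at the first lag with
        ``identifiable=False``.
    """
    if sv.n_bins < 4:
        raise ValueError("spherical fit requires at least 4 semivariogram bins")
    if on_flat not in ("raise", "flag"):
        raise ValueError("on_flat must be 'raise' or 'flag'")
    h, g = sv.lag_centers, sv.gamma_hat
    plateau = total_sill if total_sill is not None else float(np.mean(g[-max(1, g.size // 4):]))
    if plateau <= 0 or np.allclose(g, g[0], atol=1e-15):
        if on_flat == "raise":
            raise FitError("flat semivariogram: range is unidentifiable")
        return SphericalFit(0.0, 0.0, float(h[0]), converged=False, identifiable=False)

    sigma = _fit_sigma(sv, weights)
    nugget0 = float(np.clip(g[0], 0.0, plateau))
    above = h[g >= 0.95 * plateau]
    range0 = float(above[0]) if above.size else float(h[-1])
    range_bound = RANGE_BOUND_FACTOR * float(h[-1])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if total_sill is None:
                psill0 = max(plateau - nugget0, 1e-12)
                popt, _ = curve_fit(
                    spherical_model, h, g,
                    p0=[nugget0, psill0, range0],
                    sigma=sigma, absolute_sigma=False,
                    bounds=(0.0, [np.inf, np.inf, range_bound]),
                    maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                nugget, psill, rng_m = (float(v) for v in popt)
            else:
                ts = float(total_sill)

                def constrained(hh, nug, a):
                    return spherical_model(hh, nug, ts - nug, a)

                popt, _ = curve_fit(
                    constrained, h, g,
                    p0=[min(nugget0, ts), range0],
                    sigma=sigma, absolute_sigma=False,
                    bounds=([0.0, 0.0], [ts, range_bound]),
                    maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                nugget, rng_m = float(popt[0]), float(popt[1])
                psill = ts - nugget
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"spherical fit did not converge: {exc}") from exc
    return SphericalFit(nugget, psill, rng_m, converged=True, identifiable=True)


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged power spectrum of a field."""

    frequencies: np.ndarray  # cycles per metre, zero frequency excluded
    power: np.ndarray        # mean squared spectral magnitude per annulus
    counts: np.ndarray       # Fourier coefficients per annulus

    @property
    def total_power(self) -> float:
        """Sum of power over all coefficients; equals the field variance."""
        return float(np.sum(self.power * self.counts))

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelengths (m) corresponding to the annulus frequencies."""
        return 1.0 / self.frequencies


def radial_power_spectrum(grid: RasterGrid) -> RadialSpectrum:
    """Radially averaged power spectrum of a mean-removed field.

    The 2D DFT power ``|F|^2 / N^2`` is averaged over annuli one
    fundamental frequency wide; with this normalization the power summed
    over all nonzero frequencies equals the field's population variance
    (Parseval).  Frequencies are reported in cycles per metre.
    """
    z = grid.values
    n_rows, n_cols = z.shape
    if n_rows < 4 or n_cols < 4:
        raise ValueError("radial spectrum requires a grid of at least 4x4")
    px = grid.pixel_size
    F = np.fft.fft2(z - z.mean())
    power = np.abs(F) ** 2 / z.size**2

    fy = np.fft.fftfreq(n_rows, d=px)
    fx = np.fft.fftfreq(n_cols, d=px)
    freq = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (max(n_rows, n_cols) * px)  # fundamental frequency
    k = np.floor(freq / df + 0.5).astype(int)
    mask = k > 0
    n_bins = int(k.max()) + 1
    counts = np.bincount(k[mask], minlength=n_bins)
    sums = np.bincount(k[mask], weights=power[mask], minlength=n_bins)
    nonzero = np.flatnonzero(counts > 0)
    return RadialSpectrum(
        frequencies=nonzero * df,  # nominal annulus centres
        power=(sums[nonzero] / counts[nonzero]),
        counts=counts[nonzero],
    )


@dataclass(frozen=True)
class EnsembleVariogramStats:
    """Range/sill/nugget statistics of an ensemble of generated fields."""

    gamma: float
    n_requested: int
    n_fitted: int
    ranges: np.ndarray
    partial_sills: np.ndarray
    nuggets: np.ndarray

    @property
    def mean_range(self) -> float:
        return float(np.mean(self.ranges))

    @property
    def sd_range(self) -> float:
        return float(np.std(self.ranges))

    @property
    def mean_partial_sill(self) -> float:
        return float(np.mean(self.partial_sills))

    @property
    def mean_nugget(self) -> float:
        return float(np.mean(self.nuggets))


def ensemble_range_statistics(
    template: FieldSpec,
    gamma: float,
    n_iter: int,
    rng: Optional[np.random.Generator] = None,
    max_lag: Optional[float] = None,
    bin_width: Optional[float] = None,
) -> EnsembleVariogramStats:
    """Generate ``n_iter`` fields at ``gamma`` and fit spherical variograms.

    The fit is sill-constrained to each field's (exactly enforced)
    population variance with Cressie weights; unidentifiable or
    non-converged fits are dropped with a logged count.
    """
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    spec = template.with_gamma(gamma)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    smoother = build_smoother(
        build_difference_operator(spec.n_rows, spec.n_cols), gamma
    )
    ranges, psills, nuggets = [], [], []
    for _ in range(n_iter):
        grid, _rec = generate_field(spec, smoother=smoother, rng=rng)
        sv = empirical_semivariogram(grid, max_lag=max_lag, bin_width=bin_width)
        try:
            fit = fit_spherical(sv, total_sill=grid.var(), weights="cressie")
        except FitError:
            continue
        ranges.append(fit.range_m)
        psills.append(fit.partial_sill)
        nuggets.append(fit.nugget)
    n_fitted = len(ranges)
    if n_fitted < n_iter:
        logger.info(
            "gamma=%g: dropped %d/%d unidentifiable fits", gamma, n_iter - n_fitted, n_iter
        )
    if n_fitted == 0:
        raise FitError(f"no identifiable spherical fits at gamma={gamma}")
    return EnsembleVariogramStats(
        gamma=float(gamma),
        n_requested=n_iter,
        n_fitted=n_fitted,
        ranges=np.asarray(ranges),
        partial_sills=np.asarray(psills),
        nuggets=np.asarray(nuggets),
    )


def _richards(x, A, K, growth, inflection, nu):
    return A + (K - A) / (1.0 + np.exp(-growth * (x - inflection))) ** (1.0 / nu)


@dataclass(frozen=True)
class CalibrationCurve:
    """Mean fitted range as a function of log10(gamma), with a Richards fit.

    The generalized logistic is
    ``R(x) = A + (K - A) / (1 + exp(-growth (x - inflection)))^(1/nu)``
    with lower asymptote A, upper asymptote K, growth rate, inflection point
    and shape exponent nu.
    """

    log10_gamma: np.ndarray
    mean_range: np.ndarray
    sd_range: np.ndarray
    n_fitted: np.ndarray
    lower_asymptote: float
    upper_asymptote: float
    growth_rate: float
    inflection: float
    shape: float

    def predict(self, log10_gamma: np.ndarray) -> np.ndarray:
        """Fitted mean range (m) at the given log10 multiplier values."""
        return _richards(
            np.asarray(log10_gamma, dtype=float),
            self.lower_asymptote,
            self.upper_asymptote,
            self.growth_rate,
            self.inflection,
            self.shape,
        )


def build_calibration_curve(
    template: FieldSpec,
    log10_gamma_grid: Sequence[float],
    n_iter: int,
    rng: Optional[np.random.Generator] = None,
) -> CalibrationCurve:
    """Map the smoothness multiplier to ensemble mean variogram range.

    For each grid point, generates ``n_iter`` fields, fits spherical
    variograms, and records mean and sd of the fitted range; a Richards
    curve of log10(gamma) is then fitted to the means by nonlinear least
    squares (falling back to a fixed shape exponent nu = 1 if the
    5-parameter fit is ill-conditioned).
    """
    grid_pts = np.asarray(sorted(log10_gamma_grid), dtype=float)
    if grid_pts.size < 4:
        raise ValueError("calibration needs at least 4 gamma grid points")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if rng is None:
        rng = np.random.default_rng(template.seed)

    means, sds, ns = [], [], []
    for x in grid_pts:
        stats = ensemble_range_statistics(template, 10.0**x, n_iter, rng=rng)
        if stats.n_fitted < 0.5 * n_iter:
            warnings.warn(
                f"log10(gamma)={x:g}: more than half of the variogram fits "
                f"were unidentifiable ({stats.n_fitted}/{n_iter} kept)",
                stacklevel=2,
            )
        means.append(stats.mean_range)
        sds.append(stats.sd_range)
        ns.append(stats.n_fitted)
    means = np.asarray(means)
    sds = np.asarray(sds)

    A0 = float(means.min())
    K0 = float(means.max())
    p0 = [A0 * 0.9, K0 * 1.1, 2.0, float(np.median(grid_pts)), 1.0]
    bounds = ([0.0, 0.0, 1e-6, grid_pts[0] - 5.0, 0.05],
              [K0 * 2.0, K0 * 10.0, 50.0, grid_pts[-1] + 5.0, 20.0])
    try:
        popt, _ = curve_fit(
            _richards, grid_pts, means, p0=p0, bounds=bounds, maxfev=50000
        )
    except (RuntimeError, ValueError):
        def richards_nu1(x, A, K, growth, inflection):
            return _richards(x, A, K, growth, inflection, 1.0)

        try:
            popt4, _ = curve_fit(
                richards_nu1, grid_pts, means, p0=p0[:4],
                bounds=([b[:4] for b in bounds]), maxfev=50000
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"generalized logistic fit failed: {exc}") from exc
        popt = list(popt4) + [1.0]
    A, K, growth, inflection, nu = (float(v) for v in popt)
    if K < A:
        A, K = K, A
    return CalibrationCurve(
        log10_gamma=grid_pts,
        mean_range=means,
        sd_range=sds,
        n_fitted=np.asarray(ns, dtype=np.int64),
        lower_asymptote=A,
        upper_asymptote=K,
        growth_rate=growth,
        inflection=inflection,
        shape=nu,
    )


def calibrate_gamma(curve: CalibrationCurve, target_range: float) -> float:
    """Invert the fitted logistic to the multiplier matching a target range.

    Solves ``R(x) = target_range`` in closed form and returns ``10**x``.
    The target must lie strictly between the fitted asymptotes.
    """
    A, K = curve.lower_asymptote, curve.upper_asymptote
    if not (A < target_range < K):
        raise ValueError(
            f"target range {target_range:g} m outside the achievable "
            f"interval ({A:g}, {K:g}) m of the fitted calibration curve"
        )
    ratio = ((K - A) / (target_range - A)) ** curve.shape - 1.0
    if ratio <= 0:
        raise ValueError("target range too close to the upper asymptote")
    x = curve.inflection - np.log(ratio) / curve.growth_rate
    return float(10.0**x)
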