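"""Rhythmicity and circular-phase statistics for short, equally spaced series.

The central quantities are the 24-h Fourier component (F24) of a time series
sampled at 4-h intervals over full days, the exact specific-period test of
its significance against Gaussian white noise, and circular statistics on
the resulting peak phases (circular mean, equality-of-dispersion testing
across groups of phases).

The specific-period test statistic is

    g = I(period) / sum_k I(f_k),

the periodogram ordinate at the single period of interest divided by the
total over all positive frequencies up to and including the Nyquist
frequency, after removing the series mean.  Under i.i.d. Gaussian noise the
interior ordinates are independent Exp-distributed and the (even-N) Nyquist
ordinate is a scaled 1-df chi-square, which yields a closed-form tail
probability (see :func:`fisher_specific_period_pvalue`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RhythmResult",
    "fourier_component",
    "fisher_specific_period_pvalue",
    "rhythm_statistics",
    "circular_mean",
    "resultant_length",
    "rao_dispersion_homogeneity",
]

_TWOPI = 2.0 * np.pi


@dataclass(frozen=True)
class RhythmResult:
    """Amplitude/phase of the fitted 24-h cosine plus test results.

    ``phase`` is the ZT hour at which the fitted cosine attains its maximum,
    or ``None`` for a flat series.  ``g_statistic`` is the fraction of
    periodogram power at the period of interest.
    """

    f24_amplitude: float
    phase: float | None
    g_statistic: float
    p_value: float


def _check_series(values, timepoints, period):
    values = np.asarray(values, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    if values.ndim != 1 or timepoints.ndim != 1 or values.size != timepoints.size:
        raise ValueError("values and timepoints must be 1-D and equal length")
    n = values.size
    if n < 4:
        raise ValueError("need at least 4 timepoints")
    dt = np.diff(timepoints)
    if not np.allclose(dt, dt[0]):
        raise ValueError("timepoints must be equally spaced")
    span = n * dt[0]
    cycles = span / period
    if not np.isclose(cycles, np.round(cycles)):
        raise ValueError(
            f"series span {span} h is not an integer number of {period}-h periods"
        )
    return values, timepoints, float(dt[0])


def fourier_component(values, timepoints, period: float = 24.0):
    """Amplitude and peak phase of the harmonic at ``period``.

    Computes the complex Fourier coefficient ``c = (2/N) sum_t x_t
    exp(2*pi*i*t/period)`` so that the best-fitting cosine is
    ``|c| * cos(2*pi*(t - phase)/period)``.  Returns ``(amplitude, phase)``
    with phase in hours in ``[0, period)``; the phase of a zero-amplitude
    series is undefined and reported as ``None``.
    """
    values, timepoints, _ = _check_series(values, timepoints, period)
    c = 2.0 / values.size * np.sum(values * np.exp(1j * _TWOPI * timepoints / period))
    amplitude = float(np.abs(c))
    if amplitude < 1e-12 * max(1.0, float(np.abs(values).max())):
        return 0.0, None
    phase = float((period / _TWOPI) * np.angle(c) % period)
    return amplitude, phase


def _periodogram_fraction(values, timepoints, period):
    """g statistic plus the harmonic index and ordinate count."""
    values, timepoints, dt = _check_series(values, timepoints, period)
    n = values.size
    x = values - values.mean()
    # harmonic index of the period of interest: k cycles over the span
    k = int(round(n * dt / period))
    n_pos = n // 2  # positive frequencies incl. Nyquist for even n
    if k < 1 or k > n_pos:
        raise ValueError("period of interest outside the resolvable range")
    spec = np.fft.rfft(x)
    ords = np.abs(spec[1 : n_pos + 1]) ** 2
    total = ords.sum()
    if total <= 0:
        return 0.0, k, n_pos, True
    return float(ords[k - 1] / total), k, n_pos, False


def fisher_specific_period_pvalue(values, timepoints, period: float = 24.0) -> float:
    """Exact one-period rhythmicity p-value against Gaussian white noise.

    The mean-detrended periodogram fraction ``g`` at the tested harmonic is
    compared with its exact null distribution.  For even ``N`` the tested
    (interior) ordinate is exponential, the remaining ``N/2 - 2`` interior
    ordinates are i.i.d. exponential and the Nyquist ordinate is an
    independent Gamma(1/2) with twice the scale, so with ``r = g/(1-g)``

        P(G > g) = (1 + r)^-(N/2 - 2) * (1 + 2r)^-1/2.

    For odd ``N`` there is no Nyquist term and the classical
    ``(1 - g)^((N-1)/2 - 1)`` tail applies.  A zero-variance series returns
    ``p = 1`` by convention.
    """
    g, k, n_pos, degenerate = _periodogram_fraction(values, timepoints, period)
    n = np.asarray(values).size
    if degenerate:
        return 1.0
    even = n % 2 == 0
    if even and k == n_pos:
        raise ValueError("tested period sits at the Nyquist frequency")
    if g >= 1.0:
        return 0.0
    r = g / (1.0 - g)
    if even:
        # n_pos - 2 competing interior ordinates + the half-df Nyquist term
        return float((1.0 + r) ** -(n_pos - 2) * (1.0 + 2.0 * r) ** -0.5)
    return float((1.0 - g) ** (n_pos - 1))


def rhythm_statistics(values, timepoints, period: float = 24.0) -> RhythmResult:
    """Bundle amplitude, phase, g and p for one series."""
    amplitude, phase = fourier_component(values, timepoints, period)
    g, _, _, degenerate = _periodogram_fraction(values, timepoints, period)
    p = fisher_specific_period_pvalue(values, timepoints, period)
    return RhythmResult(amplitude, phase, 0.0 if degenerate else g, p)


def _to_angles(phases, period):
    return np.asarray(phases, dtype=float) * (_TWOPI / period)


def circular_mean(phases, period: float = 24.0) -> float | None:
    """Direction of the mean resultant vector, in hours in ``[0, period)``.

    Returns ``None`` when the resultant length is numerically zero (the mean
    of e.g. two antipodal phases is undefined).
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    z = np.exp(1j * _to_angles(phases, period)).mean()
    if np.abs(z) < 1e-9:
        return None
    return float((period / _TWOPI) * np.angle(z) % period)


def resultant_length(phases, period: float = 24.0) -> float:
    """Mean resultant length in [0, 1]; 1 = perfectly concentrated."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    return float(np.abs(np.exp(1j * _to_angles(phases, period)).mean()))


def _dispersion_stat(angles: np.ndarray, sizes: np.ndarray) -> float:
    """Cochran-type heterogeneity statistic on per-group circular dispersions.

    For group j the dispersion is the circular variance d_j = 1 - Rbar_j;
    its sampling variance is estimated by the delta method from the second
    trigonometric moment about the group mean direction.
    """
    stats_ = []
    start = 0
    for n in sizes:
        a = angles[start : start + n]
        start += n
        z = np.exp(1j * a).mean()
        rbar = np.abs(z)
        mu = np.angle(z)
        alpha2 = np.cos(2.0 * (a - mu)).mean()
        var = ((1.0 + alpha2) / 2.0 - rbar**2) / n
        stats_.append((1.0 - rbar, max(var, 1e-12)))
    d = np.array([s[0] for s in stats_])
    w = 1.0 / np.array([s[1] for s in stats_])
    dbar = np.sum(w * d) / np.sum(w)
    return float(np.sum(w * (d - dbar) ** 2))


def rao_dispersion_homogeneity(
    groups,
    period: float = 24.0,
    method: str = "permutation",
    n_perm: int = 999,
    rng=None,
) -> float:
    """Test equality of polar dispersions across groups of circular phases.

    Parameters
    ----------
    groups
        Two or more sequences of phases in hours modulo ``period``; each
        group needs at least 3 phases.
    method
        ``"permutation"`` (default): null distribution of the dispersion
        heterogeneity statistic from random reassignment of the pooled
        phases to groups -- exact under exchangeability.  ``"chisq"``: the
        asymptotic chi-square reference with ``k - 1`` degrees of freedom.

    The statistic depends on phases only through deviations from each
    group's mean direction, so the p-value is invariant under rotating all
    phases by a constant.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([len(g) for g in groups])
    if (sizes < 3).any():
        raise ValueError("each group needs at least 3 phases")
    angles = np.concatenate([_to_angles(g, period) for g in groups])
    observed = _dispersion_stat(angles, sizes)
    if method == "chisq":
        return float(stats.chi2.sf(observed, df=len(groups) - 1))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(rng)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(angles)
        if _dispersion_stat(perm, sizes) >= observed:
            exceed += 1
    return float((1 + exceed) / (1 + n_perm))
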