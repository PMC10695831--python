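"""Curve-level analysis: spectra, laurdan melting, folding kinetics, titrations.

Covers the optical assays around OMP folding experiments:

* non-negative deconvolution of liposome absorbance spectra into reference
  components (least-squares over 300–600 nm),
* ordinary linear calibration with inverse prediction (e.g. anthrone MβCD
  assay),
* laurdan generalized polarization GP = (I440 − I490)/(I440 + I490) and the
  first-differential extraction of the lipid melting midpoint Tm,
* folded-fraction estimates from the tryptophan 335/350 nm ratio or from
  cold SDS–PAGE monomer band densitometry,
* one-/two-phase exponential fits of folding fluorescence traces yielding
  k_obs, with the rule that traces folding to an amplitude below ~75% are
  not accepted for rate determination,
* four-parameter logistic fits of urea titrations yielding the
  half-amplitude midpoint P_m and its covariance-based uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import (
    DegenerateCalibrationError,
    DomainError,
    FitError,
    LowAmplitudeError,
    NoTransitionError,
)

__all__ = [
    "Spectrum",
    "DeconvolutionResult",
    "KineticTrace",
    "KineticFit",
    "TitrationFit",
    "deconvolute_spectrum",
    "linear_calibration",
    "gp_value",
    "melting_midpoint",
    "folded_fraction",
    "fit_folding_kinetics",
    "fit_urea_titration",
]


# ---------------------------------------------------------------------------
# spectra


@dataclass(frozen=True)
class Spectrum:
    """Wavelength-indexed intensities (absorbance or fluorescence, a.u.)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.size != v.size:
            raise DomainError("wavelengths and values differ in length")
        if wl.size >= 2 and not np.all(np.diff(wl) > 0):
            raise DomainError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def resampled(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values))


@dataclass(frozen=True)
class DeconvolutionResult:
    component_concentrations: Dict[str, float]
    residual_ss: float
    reconvoluted: Spectrum
    ill_conditioned: bool = False


def deconvolute_spectrum(
    raw: Spectrum, references: Dict[str, Spectrum]
) -> DeconvolutionResult:
    """Decompose a raw spectrum into non-negative scales of reference spectra.

    Minimizes sum_λ (A_reconvoluted − A_raw)² over the raw wavelength grid
    subject to scale >= 0 (concentrations are physical).  References on a
    different grid are linearly resampled onto the raw grid.  Linearly
    dependent references are flagged via ``ill_conditioned`` rather than
    raising, since the fit itself is still well-posed under non-negativity.
    """
    if not references:
        raise DomainError("at least one reference spectrum required")
    grid = raw.wavelengths
    names = list(references)
    A = np.column_stack([references[n].resampled(grid).values for n in names])
    ill = False
    if A.shape[1] > 1:
        with np.errstate(all="ignore"):
            cond = np.linalg.cond(A)
        ill = not np.isfinite(cond) or cond > 1e10
    scales, rnorm = optimize.nnls(A, raw.values)
    recon = A @ scales
    return DeconvolutionResult(
        component_concentrations={n: float(s) for n, s in zip(names, scales)},
        residual_ss=float(rnorm**2),
        reconvoluted=Spectrum(grid, recon),
        ill_conditioned=ill,
    )


def linear_calibration(x: Sequence[float], y: Sequence[float]):
    """OLS line through calibration standards, with inverse prediction.

    Returns (slope, intercept, inverse) where inverse maps a measured signal
    back to concentration: inverse(y) = (y − intercept)/slope.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise DegenerateCalibrationError("need >= 2 distinct x values")
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope == 0:
        raise DegenerateCalibrationError("zero slope: inverse prediction undefined")

    def inverse(signal: float) -> float:
        return (signal - intercept) / slope

    return slope, intercept, inverse


# ---------------------------------------------------------------------------
# laurdan


def gp_value(i440: float, i490: float) -> float:
    """Laurdan generalized polarization (I440 − I490)/(I440 + I490)."""
    total = i440 + i490
    if total <= 0:
        raise DomainError("I440 + I490 must be positive")
    return (i440 - i490) / total


def melting_midpoint(
    temperatures: Sequence[float],
    gp: Sequence[float],
    min_prominence: float = 2.0,
) -> float:
    """Lipid melting midpoint Tm from the first differential of GP vs T.

    The transition appears as an extremum of the numerical derivative
    dGP/dT; its location is refined by fitting a parabola through the
    extremum and its two neighbours.  On dense, uniformly sampled curves the
    derivative is taken with a short Savitzky–Golay filter to keep
    measurement noise from displacing the extremum; otherwise plain central
    differences are used.  A curve whose derivative magnitude never rises
    above ``min_prominence`` times its median (e.g. a linear or flat curve)
    has no resolvable transition and raises NoTransitionError.
    """
    t = np.asarray(temperatures, dtype=float)
    g = np.asarray(gp, dtype=float)
    if t.size != g.size or t.size < 5:
        raise DomainError("need >= 5 (temperature, GP) points")
    steps = np.diff(t)
    if not np.all(steps > 0):
        raise DomainError("temperatures must be strictly increasing")

    uniform = np.allclose(steps, steps[0], rtol=1e-6)
    if uniform and t.size >= 11:
        from scipy.signal import savgol_filter

        dg_full = savgol_filter(g, window_length=9, polyorder=2, deriv=1, delta=steps[0])
        dg = dg_full[1:-1]
    else:
        dg = (g[2:] - g[:-2]) / (t[2:] - t[:-2])
    mag = np.abs(dg)
    if mag.max() <= 0 or mag.max() < min_prominence * np.median(mag):
        raise NoTransitionError("derivative never exceeds the noise floor")
    i = int(np.argmax(mag))
    ti = t[1:-1]
    if i == 0 or i == mag.size - 1:
        return float(ti[i])
    # quadratic refinement through (t, |dGP/dT|) about the extremum
    x = ti[i - 1 : i + 2]
    y = mag[i - 1 : i + 2]
    denom = (y[0] - 2 * y[1] + y[2])
    if denom == 0:
        return float(ti[i])
    # vertex of the parabola on a possibly non-uniform grid
    coeffs = np.polyfit(x, y, 2)
    if coeffs[0] == 0:
        return float(ti[i])
    return float(-coeffs[1] / (2 * coeffs[0]))


# ---------------------------------------------------------------------------
# folded fraction


def folded_fraction(mode: str, **inputs) -> float:
    """Folded-protein fraction from fluorescence ratio or gel densitometry.

    mode="trp_ratio": keyword args sample_ratio, folded_ref, unfolded_ref —
    the sample's 335/350 nm intensity ratio interpolated linearly between
    the unfolded (0) and folded (1) reference ratios, clipped to [0, 1].

    mode="gel_monomer": keyword args folded, unfolded — monomer band
    densities from cold SDS–PAGE; returns folded/(folded + unfolded).
    """
    if mode == "trp_ratio":
        s = inputs["sample_ratio"]
        f = inputs["folded_ref"]
        u = inputs["unfolded_ref"]
        if f == u:
            raise DegenerateCalibrationError("folded and unfolded references identical")
        return float(np.clip((s - u) / (f - u), 0.0, 1.0))
    if mode == "gel_monomer":
        fol = inputs["folded"]
        unf = inputs["unfolded"]
        if fol < 0 or unf < 0:
            raise DomainError("band densities must be >= 0")
        if fol + unf == 0:
            raise DomainError("both band densities zero")
        return fol / (fol + unf)
    raise DomainError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# folding kinetics


@dataclass(frozen=True)
class KineticTrace:
    """A folding fluorescence time course (280/335 nm ex/em)."""

    time_s: np.ndarray
    signal: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.size != s.size:
            raise DomainError("time and signal differ in length")
        if t.size and (t[0] < 0 or not np.all(np.diff(t) > 0)):
            raise DomainError("time must be non-negative and strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class KineticFit:
    """Result of an exponential folding fit.

    k_obs holds one rate for a one-phase fit and (fast, slow) for a
    two-phase fit; ``accepted`` is False when the trace folds to less than
    75% of its fitted amplitude, in which case the rate is not usable.
    """

    n_phases: int
    k_obs: Tuple[float, ...]
    amplitudes: Tuple[float, ...]
    baseline: float
    completion_fraction: float
    accepted: bool
    rmse: float


def _one_phase(t, f0, a, k):
    return f0 + a * (1.0 - np.exp(-k * t))


def _two_phase(t, f0, a1, k1, a2, k2):
    return f0 + a1 * (1.0 - np.exp(-k1 * t)) + a2 * (1.0 - np.exp(-k2 * t))


def _fit_best(model, t, y, starts, bounds):
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    model, t, y, p0=p0, bounds=bounds, maxfev=20000
                )
        except (RuntimeError, ValueError):
            continue
        rmse = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    return best


def fit_folding_kinetics(
    trace: KineticTrace,
    max_phases: int = 2,
    folded_fraction_estimate: Optional[float] = None,
    completion_threshold: float = 0.75,
) -> KineticFit:
    """Fit a folding trace to a one- or two-phase exponential.

    F(t) = F0 + A·(1 − e^(−k·t)), or the two-term analogue with k1 > k2.
    Initial guesses span k0 in {1, 10, 100}/t_max.  The two-phase model is
    adopted only when it lowers the RMSE by at least 20% AND the two rates
    separate by at least 3-fold — otherwise the one-phase fit stands.

    The completion fraction is the observed end-of-trace signal rise over
    the fitted total amplitude (or, when a folding-yield estimate from an
    orthogonal assay is supplied, that estimate); fits completing below the
    threshold are returned with ``accepted=False`` and their rate constants
    should not be used.
    """
    t = trace.time_s
    y = trace.signal
    if t.size < 20:
        raise DomainError("need >= 20 time points")
    t_max = t[-1]
    span = y[-1] - y[0]
    a0 = span if span != 0 else (np.ptp(y) or 1.0)
    k_grid = [1.0 / t_max, 10.0 / t_max, 100.0 / t_max]

    starts1 = [(y[0], a0, k0) for k0 in k_grid]
    b1 = ([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf])
    best1 = _fit_best(_one_phase, t, y, starts1, b1)
    if best1 is None:
        raise FitError("one-phase fit failed from every start")
    (f0, a, k), rmse1 = best1
    n_phases, ks, amps, rmse = 1, (float(k),), (float(a),), rmse1
    baseline = float(f0)

    if max_phases >= 2:
        starts2 = [
            (y[0], a0 / 2, kf, a0 / 2, ks_)
            for kf in k_grid
            for ks_ in k_grid
            if kf > ks_
        ] or [(y[0], a0 / 2, 10.0 / t_max, a0 / 2, 1.0 / t_max)]
        b2 = (
            [-np.inf, -np.inf, 1e-12, -np.inf, 1e-12],
            [np.inf, np.inf, np.inf, np.inf, np.inf],
        )
        best2 = _fit_best(_two_phase, t, y, starts2, b2)
        if best2 is not None:
            (f0b, a1, k1, a2, k2), rmse2 = best2
            if k2 > k1:  # order fast, slow
                a1, k1, a2, k2 = a2, k2, a1, k1
            if rmse2 <= 0.8 * rmse1 and k1 >= 3.0 * k2:
                n_phases = 2
                ks = (float(k1), float(k2))
                amps = (float(a1), float(a2))
                baseline = float(f0b)
                rmse = rmse2

    a_total = sum(amps)
    if folded_fraction_estimate is not None:
        completion = float(folded_fraction_estimate)
    elif a_total == 0:
        completion = 0.0
    else:
        tail = max(3, t.size // 50)
        s_end = float(np.mean(y[-tail:]))
        completion = (s_end - baseline) / a_total
    accepted = completion >= completion_threshold

    return KineticFit(
        n_phases=n_phases,
        k_obs=ks,
        amplitudes=amps,
        baseline=baseline,
        completion_fraction=float(completion),
        accepted=accepted,
        rmse=float(rmse),
    )


# ---------------------------------------------------------------------------
# urea titrations


@dataclass(frozen=True)
class TitrationFit:
    """Four-parameter logistic fit of folded fraction vs urea concentration."""

    Pm: float
    slope: float
    upper: float
    lower: float
    Pm_sd: float
    rmse: float


def _logistic(u, lower, upper, pm, s):
    return lower + (upper - lower) / (1.0 + np.exp((u - pm) / s))


def fit_urea_titration(
    urea_M: Sequence[float],
    fraction_folded: Sequence[float],
    min_amplitude: float = 0.2,
) -> TitrationFit:
    """Fit a urea titration and return the half-amplitude midpoint P_m.

    f(u) = lower + (upper − lower)/(1 + e^((u − Pm)/s)); Pm_sd comes from
    the fit parameter covariance.  When the fitted amplitude (upper − lower)
    is below ``min_amplitude`` the transition is too shallow to place a
    midpoint and LowAmplitudeError is raised.
    """
    u = np.asarray(urea_M, dtype=float)
    f = np.asarray(fraction_folded, dtype=float)
    if u.size != f.size or u.size < 6:
        raise DomainError("need >= 6 titration points")
    if np.unique(u).size != u.size:
        raise DomainError("urea concentrations must be distinct")
    order = np.argsort(u)
    u, f = u[order], f[order]

    if np.ptp(f) < min_amplitude / 2:
        raise LowAmplitudeError(
            f"titration amplitude {np.ptp(f):.3f} too low to fit a midpoint"
        )

    lo0, hi0 = float(f.min()), float(f.max())
    mid = (lo0 + hi0) / 2
    pm0 = float(u[np.argmin(np.abs(f - mid))])
    best = None
    for s0 in (0.2, 0.5, 1.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    _logistic,
                    u,
                    f,
                    p0=(lo0, hi0, pm0, s0),
                    bounds=([-0.5, -0.5, u[0] - 2, 1e-4], [1.5, 1.5, u[-1] + 2, 10.0]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        rmse = float(np.sqrt(np.mean((_logistic(u, *popt) - f) ** 2)))
        if best is None or rmse < best[2]:
            best = (popt, pcov, rmse)
    if best is None:
        raise FitError("titration fit failed from every start")
    (lower, upper, pm, s), pcov, rmse = best
    if upper - lower < min_amplitude:
        raise LowAmplitudeError(
            f"fitted amplitude {upper - lower:.3f} below {min_amplitude}"
        )
    pm_sd = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else float("nan")
    return TitrationFit(
        Pm=float(pm),
        slope=float(s),
        upper=float(upper),
        lower=float(lower),
        Pm_sd=pm_sd,
        rmse=rmse,
    )
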