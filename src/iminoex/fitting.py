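"""Curve fitting and error propagation for imino-proton exchange data.

Covers the whole estimation chain: spectral-noise estimation, the
inversion/saturation recovery fits giving the relaxation rates R1a and
R1w, the water-magnetization-transfer fit giving k_ex, the correction for
linear sample leakage over the acquisition sequence, Monte-Carlo
propagation of intensity noise into k_ex error bars, and the two
averaging modes used when peaks overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .core_model import RelaxationRates, intensity_ratio

__all__ = [
    "IntensitySeries",
    "KineticResult",
    "FitFailure",
    "estimate_noise_sigma",
    "fit_inversion_recovery",
    "fit_saturation_recovery",
    "fit_exchange_rate",
    "correct_leakage",
    "monte_carlo_kex",
    "average_intensity_fit",
    "average_kex_over_residues",
    "control_exchange_ratio",
]

KEX_UPPER_BOUND = 1e4  # s^-1, generous cap for the bounded fit


class FitFailure(RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class IntensitySeries:
    """Per-residue signal intensities versus delay time.

    ``acquisition_order[i]`` is the 0-based rank at which sample ``i`` was
    recorded; the study design records the delays in scrambled order
    (0.1, 0.001, 0.01, 0.06, 0.03 s), so leakage correction must follow
    acquisition rank, not delay order.
    """

    residue: str
    condition: str
    delays: np.ndarray
    intensities: np.ndarray
    acquisition_order: np.ndarray | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if delays.ndim != 1 or delays.shape != intensities.shape:
            raise ValueError("delays and intensities must be 1-D of equal length")
        if np.any(delays < 0):
            raise ValueError("delays must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        order = self.acquisition_order
        if order is not None:
            order = np.asarray(order, dtype=int)
            if sorted(order.tolist()) != list(range(len(delays))):
                raise ValueError("acquisition_order must be a permutation of 0..n-1")
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "acquisition_order", order)

    def __len__(self) -> int:
        return len(self.delays)


@dataclass(frozen=True)
class KineticResult:
    """A k_ex estimate with Monte-Carlo statistics and fit diagnostics."""

    residue: str
    condition: str
    kex_point: float
    kex_mean: float
    kex_sd: float
    n_mc: int = 1
    residual_sum: float = np.nan
    converged: bool = True
    n_failed: int = 0
    flagged: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kex_sd < 0:
            raise ValueError("kex_sd must be >= 0")
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")


def estimate_noise_sigma(spectrum_trace, signal_free_window: slice | tuple) -> float:
    """Sample standard deviation over a signal-free window of a 1D trace.

    The caller is responsible for choosing a window that contains no
    signal; no detection is attempted.
    """
    trace = np.asarray(spectrum_trace, dtype=float)
    if isinstance(signal_free_window, tuple):
        signal_free_window = slice(*signal_free_window)
    window = trace[signal_free_window]
    if window.size < 2:
        raise ValueError("signal-free window must contain at least 2 points")
    return float(np.std(window, ddof=1))


def _recovery_fit(series: IntensitySeries, inversion_factor: float, label: str):
    """Shared mono-exponential recovery fit I(t)=I_inf*(1-a*exp(-R1*t))."""
    t = series.delays
    y = series.intensities
    if len(np.unique(t)) < 3:
        raise ValueError(f"{label} needs >= 3 distinct delays")

    def model(tt, i_inf, r1):
        return i_inf * (1.0 - inversion_factor * np.exp(-r1 * tt))

    i_inf0 = y[np.argmax(t)] if np.any(y != 0) else 1.0
    if i_inf0 == 0:
        i_inf0 = 1.0
    # rate guess from the earliest point: a*exp(-R1*t0) = 1 - y0/I_inf
    i0 = np.argmin(t)
    frac = (1.0 - y[i0] / i_inf0) / inversion_factor
    if 0 < frac < 1 and t[i0] > 0:
        r1_0 = -np.log(frac) / t[i0]
    else:
        r1_0 = 1.0 / max(t.max() - t.min(), 1e-12)
    r1_0 = float(np.clip(r1_0, 1e-3, 1e3))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[i_inf0, r1_0], maxfev=20000
            )
        except RuntimeError as exc:
            raise FitFailure(
                f"{label} fit did not converge", {"residue": series.residue}
            ) from exc
    r1 = float(popt[1])
    r1_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    resid = float(np.sum((model(t, *popt) - y) ** 2))
    if abs(popt[0]) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        raise FitFailure(
            f"{label} fit degenerate (vanishing amplitude)",
            {"residue": series.residue, "residual_sum": resid},
        )
    if not np.isfinite(r1) or r1 <= 0:
        raise FitFailure(
            f"{label} fit degenerate (R1={r1!r})",
            {"residue": series.residue, "residual_sum": resid},
        )
    return r1, r1_err


def fit_inversion_recovery(series: IntensitySeries) -> tuple[float, float]:
    """Apparent imino R1a from selective inversion recovery.

    Fits I(t) = I_inf * (1 - 2*exp(-R1*t)) with amplitude and rate free;
    returns (R1, asymptotic standard error).
    """
    return _recovery_fit(series, 2.0, "inversion recovery")


def fit_saturation_recovery(series: IntensitySeries) -> tuple[float, float]:
    """Water R1w from saturation recovery: I(t) = I_inf * (1 - exp(-R1*t))."""
    return _recovery_fit(series, 1.0, "saturation recovery")


def _transfer_shape(t: np.ndarray, rates: RelaxationRates) -> np.ndarray:
    """h(t) such that the transfer model is I0 * (1 - k_ex * h(t))."""
    R1a, R1w = rates.R1a, rates.R1w
    from .core_model import DEGENERATE_RATE_TOL

    if abs(R1w - R1a) < DEGENERATE_RATE_TOL:
        return 2.0 * t * np.exp(-R1a * t)
    return 2.0 / (R1w - R1a) * (np.exp(-R1a * t) - np.exp(-R1w * t))


def fit_exchange_rate(
    series: IntensitySeries,
    rates: RelaxationRates,
    intensities: np.ndarray | None = None,
) -> KineticResult:
    """k_ex from a water-magnetization-transfer series.

    Least-squares fit of I(t) = I0 * [1 - 2*k_ex/(R1w-R1a)*(e^-R1a t -
    e^-R1w t)] with k_ex in [0, 1e4] s^-1 and the amplitude I0 free.
    R1a and R1w are held fixed at the values from the recovery fits.

    Because the model can be written I0*(1 - k_ex*h(t)) it is linear in
    the parameters (a, b) = (I0, I0*k_ex): the unconstrained optimum is
    obtained exactly by linear least squares on the design [1, -h(t)]
    and k_ex = b/a.  A negative unconstrained k_ex is projected onto the
    bound k_ex = 0 (constant fit), mirroring the bounded fit.
    """
    t = series.delays
    y = series.intensities if intensities is None else np.asarray(intensities, float)
    if len(np.unique(t)) < 3:
        raise ValueError("exchange fit needs >= 3 distinct delays")

    h = _transfer_shape(t, rates)
    design = np.column_stack([np.ones_like(t), -h])
    (a, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    if a == 0 or not np.isfinite(a) or not np.isfinite(b):
        raise FitFailure(
            "exchange-rate fit degenerate (zero amplitude)",
            {"residue": series.residue},
        )
    kex = b / a
    if kex < 0.0 or kex > KEX_UPPER_BOUND or a < 0:
        # constrained optimum on the nearest bound of k_ex
        kex = float(np.clip(kex, 0.0, KEX_UPPER_BOUND))
        shape = 1.0 - kex * h
        a = float(shape @ y / (shape @ shape))
    fitted = a * (1.0 - kex * h)
    resid = float(np.sum((fitted - y) ** 2))
    return KineticResult(
        residue=series.residue,
        condition=series.condition,
        kex_point=float(kex),
        kex_mean=float(kex),
        kex_sd=0.0,
        n_mc=1,
        residual_sum=resid,
        extras={"I0": float(a)},
    )


def correct_leakage(series: IntensitySeries, total_fraction_lost: float) -> IntensitySeries:
    """Undo a linear loss of sample over the acquisition sequence.

    If a fraction ``total_fraction_lost`` of the signal is lost linearly
    between the first and last recorded spectrum, the spectrum recorded
    k-th (k = 1..n) is multiplied by 1/(1 - L*(k-1)/(n-1)); the first
    spectrum is unchanged.  Correction follows acquisition order, which
    for scrambled delays differs from delay order.
    """
    if not (0.0 <= total_fraction_lost < 1.0):
        raise ValueError(
            f"total_fraction_lost must be in [0, 1), got {total_fraction_lost!r}"
        )
    if series.acquisition_order is None:
        raise ValueError("series lacks acquisition_order; cannot correct leakage")
    n = len(series)
    if n < 2 or total_fraction_lost == 0.0:
        return series
    ranks = series.acquisition_order.astype(float)  # 0-based rank
    multipliers = 1.0 / (1.0 - total_fraction_lost * ranks / (n - 1))
    return replace(series, intensities=series.intensities * multipliers)


def monte_carlo_kex(
    series: IntensitySeries,
    rates: RelaxationRates,
    n_mc: int = 50,
    seed: int | np.random.Generator | None = None,
    fail_flag_fraction: float = 0.2,
) -> KineticResult:
    """k_ex with Monte-Carlo error bars from the spectral noise sd.

    Draws ``n_mc`` replicate intensity sets, each point perturbed by
    independent Gaussian noise of sd ``series.noise_sd``, refits each and
    returns the mean and standard deviation of the replicate k_ex values
    alongside the unperturbed point estimate.  Replicate fit failures are
    counted; if more than ``fail_flag_fraction`` fail the result is
    flagged.
    """
    point = fit_exchange_rate(series, rates)
    if series.noise_sd == 0.0:
        return replace(point, n_mc=n_mc, kex_mean=point.kex_point, kex_sd=0.0)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kex_values = []
    n_failed = 0
    for _ in range(n_mc):
        perturbed = series.intensities + rng.normal(0.0, series.noise_sd, len(series))
        try:
            res = fit_exchange_rate(series, rates, intensities=perturbed)
            kex_values.append(res.kex_point)
        except FitFailure:
            n_failed += 1
    if not kex_values:
        raise FitFailure("all Monte-Carlo replicates failed", {"n_mc": n_mc})
    kex_values = np.asarray(kex_values)
    sd = float(np.std(kex_values, ddof=1)) if len(kex_values) > 1 else 0.0
    return replace(
        point,
        kex_mean=float(np.mean(kex_values)),
        kex_sd=sd,
        n_mc=n_mc,
        n_failed=n_failed,
        flagged=n_failed > fail_flag_fraction * n_mc,
    )


def average_intensity_fit(
    series_list: list[IntensitySeries],
    rates: RelaxationRates,
) -> KineticResult:
    """Single k_ex from intensities averaged across overlapping peaks.

    Each series is normalised to its shortest-delay intensity, the
    normalised intensities are averaged per delay across residues, and
    the transfer equation is fitted once to the averaged curve.  Used
    when individual peaks are too broad/overlapped to fit separately.
    """
    if not series_list:
        raise ValueError("series_list must be non-empty")
    ref = series_list[0]
    for s in series_list[1:]:
        if len(s) != len(ref) or not np.allclose(s.delays, ref.delays):
            raise ValueError("all series must share the same delay grid")
    i_ref = np.argmin(ref.delays)
    stack = []
    for s in series_list:
        norm = s.intensities[i_ref]
        if norm == 0:
            raise ValueError(f"series {s.residue} has zero shortest-delay intensity")
        stack.append(s.intensities / norm)
    mean_curve = np.mean(stack, axis=0)
    avg_series = IntensitySeries(
        residue="average",
        condition=ref.condition,
        delays=ref.delays,
        intensities=mean_curve,
        acquisition_order=ref.acquisition_order,
        noise_sd=float(np.mean([s.noise_sd for s in series_list])),
    )
    return fit_exchange_rate(avg_series, rates)


def average_kex_over_residues(results: list[KineticResult]) -> tuple[float, float]:
    """Unweighted mean of per-residue k_ex means; sample sd across residues.

    A single result returns (its mean, 0).
    """
    if not results:
        raise ValueError("results must be non-empty")
    means = np.array([r.kex_mean for r in results])
    sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
    return float(np.mean(means)), sd


def control_exchange_ratio(
    on_resonance: float,
    off_resonance: float,
    on_sd: float = 0.0,
    off_sd: float = 0.0,
) -> tuple[float, float]:
    """Intensity ratio I_on/I_off of the water-inversion control.

    Comparing spectra acquired with the selective pulse on the water
    resonance versus far off resonance isolates the transfer effect.
    The sd follows the first-order quotient rule.
    """
    if off_resonance <= 0:
        raise ValueError("off-resonance intensity must be > 0")
    ratio = on_resonance / off_resonance
    sd = np.hypot(on_sd / off_resonance, ratio * off_sd / off_resonance)
    return float(ratio), float(sd)
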