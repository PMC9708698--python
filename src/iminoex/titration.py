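"""From catalyst titrations to opening rates, and the in-cell comparison.

Raising the base-catalyst concentration accelerates open-state exchange
until closing no longer competes (EX1): the observed k_ex then plateaus
at the opening rate k_open.  In cells the catalyst content is unknown, so
only the one-sided bound k_open >= k_ex applies; a base pair is called
"opened more frequently in cells" when its in-cell k_ex exceeds the
in-vitro k_open beyond the combined error bars.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .catalyst import BufferSpec, base_form_concentration
from .fitting import FitFailure, KineticResult

__all__ = [
    "TitrationSeries",
    "OpeningComparison",
    "build_titration",
    "kopen_from_plateau",
    "fit_saturation_model",
    "classify_in_cell_opening",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Per-residue k_ex estimates indexed by base-form catalyst concentration (mM)."""

    residue: str
    condition: str
    concentrations: np.ndarray  # base-form mM, ascending
    results: tuple[KineticResult, ...]

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(np.diff(conc) < 0):
            raise ValueError("concentrations must be ascending")
        if len(conc) != len(self.results):
            raise ValueError("concentrations and results must match in length")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "results", tuple(self.results))

    @property
    def kex_means(self) -> np.ndarray:
        return np.array([r.kex_mean for r in self.results])

    @property
    def kex_sds(self) -> np.ndarray:
        return np.array([r.kex_sd for r in self.results])


@dataclass(frozen=True)
class OpeningComparison:
    """Verdict of the in-cell vs in-vitro opening-rate comparison.

    The bound k_open(in-cell) >= k_ex(in-cell) is one-sided, so the only
    possible verdicts are ``increased_in_cell`` and ``indeterminate``.
    """

    residue: str
    k_open_invitro: float
    k_open_invitro_sd: float
    k_ex_incell: float
    k_ex_incell_sd: float
    verdict: str
    sd_multiplier: float = 1.0


def build_titration(
    points: list[tuple[BufferSpec, KineticResult]],
    residue: str | None = None,
    condition: str = "in_vitro",
) -> TitrationSeries:
    """Assemble a titration series keyed by base-form concentration.

    x-values are base-form (catalytically active) concentrations computed
    from each buffer, not totals.  Points are sorted ascending; duplicate
    concentrations are collapsed to the mean of their estimates with a
    warning.
    """
    if len(points) < 2:
        raise ValueError("a titration needs >= 2 points")
    residue = residue or points[0][1].residue
    conc = np.array([base_form_concentration(b) for b, _ in points])
    order = np.argsort(conc)
    conc = conc[order]
    results = [points[i][1] for i in order]

    # collapse duplicates (same base-form concentration measured twice)
    uniq_conc: list[float] = []
    uniq_res: list[KineticResult] = []
    i = 0
    while i < len(conc):
        j = i
        while j + 1 < len(conc) and np.isclose(conc[j + 1], conc[i]):
            j += 1
        group = results[i : j + 1]
        if len(group) > 1:
            _warnings.warn(
                f"duplicate concentration {conc[i]:g} mM: averaging {len(group)} points",
                stacklevel=2,
            )
            mean_kex = float(np.mean([r.kex_mean for r in group]))
            rep = KineticResult(
                residue=residue,
                condition=condition,
                kex_point=mean_kex,
                kex_mean=mean_kex,
                kex_sd=float(np.mean([r.kex_sd for r in group])),
                n_mc=group[0].n_mc,
            )
            uniq_res.append(rep)
        else:
            uniq_res.append(group[0])
        uniq_conc.append(float(conc[i]))
        i = j + 1
    return TitrationSeries(residue, condition, np.array(uniq_conc), tuple(uniq_res))


def kopen_from_plateau(series: TitrationSeries) -> tuple[float, float, bool]:
    """k_open as the maximum k_ex over the titration (plateau rule).

    At saturating catalyst the observed exchange rate equals the opening
    rate, so the maximum k_ex over titration points is taken as k_open,
    carrying that point's Monte-Carlo sd.  Returns (k_open, sd,
    plateau_reached); the flag is False when the two highest-concentration
    points still differ by more than 2 combined sd, i.e. k_ex was still
    rising at the top of the titration.
    """
    if len(series.results) < 2:
        raise ValueError("plateau rule needs >= 2 titration points")
    means = series.kex_means
    sds = series.kex_sds
    i_max = int(np.argmax(means))
    last, prev = means[-1], means[-2]
    combined = float(np.hypot(sds[-1], sds[-2]))
    plateau = abs(last - prev) <= 2.0 * combined
    return float(means[i_max]), float(sds[i_max]), plateau


def fit_saturation_model(series: TitrationSeries) -> tuple[float, float]:
    """Fit k_ex([B]) = k_open*[B]/(K_half + [B]) to the titration.

    Assumes open-state exchange proportional to the base-catalyst
    concentration (k_ex_open = k_B*[B]), whence K_half = k_close/k_B.
    Returns (k_open, K_half).  This is a model-based extension of the
    plateau rule; a vanishing K_half corresponds to the EX1 regime where
    every point already sits on the plateau.
    """
    if len(series.results) < 3:
        raise ValueError("saturation fit needs >= 3 titration points")
    b = series.concentrations
    y = series.kex_means

    def model(bb, k_open, k_half):
        return k_open * bb / (k_half + bb)

    p0 = [max(y.max(), 1e-6), max(np.median(b), 1e-3)]
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            popt, _ = curve_fit(
                model, b, y, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000
            )
        except RuntimeError as exc:
            raise FitFailure("saturation-model fit did not converge") from exc
    return float(popt[0]), float(popt[1])


def classify_in_cell_opening(
    k_open_invitro: float,
    k_open_invitro_sd: float,
    k_ex_incell: float,
    k_ex_incell_sd: float,
    residue: str = "",
    sd_multiplier: float = 1.0,
) -> OpeningComparison:
    """Compare the in-cell k_ex bound with the in-vitro opening rate.

    Because k_open(in-cell) >= k_ex(in-cell), the verdict is
    ``increased_in_cell`` iff the in-cell k_ex minus its error bar lies
    above the in-vitro k_open plus its error bar; otherwise
    ``indeterminate`` (the bound is one-sided, a decrease can never be
    established).  The error-bar multiplier defaults to 1 sd.
    """
    if sd_multiplier < 0:
        raise ValueError("sd_multiplier must be >= 0")
    increased = (k_ex_incell - sd_multiplier * k_ex_incell_sd) > (
        k_open_invitro + sd_multiplier * k_open_invitro_sd
    )
    return OpeningComparison(
        residue=residue,
        k_open_invitro=k_open_invitro,
        k_open_invitro_sd=k_open_invitro_sd,
        k_ex_incell=k_ex_incell,
        k_ex_incell_sd=k_ex_incell_sd,
        verdict="increased_in_cell" if increased else "indeterminate",
        sd_multiplier=sd_multiplier,
    )
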