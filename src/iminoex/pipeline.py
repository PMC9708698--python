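"""Stage drivers chaining the modules into the full analysis.

Each function consumes/produces the tabular interchange formats so the
numbered analysis scripts and the CLI stay thin wrappers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalyst import BufferSpec
from .core_model import RelaxationRates
from .fitting import (
    IntensitySeries,
    KineticResult,
    correct_leakage,
    fit_inversion_recovery,
    fit_saturation_recovery,
    monte_carlo_kex,
)
from .interface import StudyConfig
from .titration import (
    OpeningComparison,
    build_titration,
    classify_in_cell_opening,
    kopen_from_plateau,
)

__all__ = [
    "fit_relaxation_table",
    "fit_exchange_table",
    "titrate_table",
    "compare_table",
]


def _condition_base(label: str) -> str:
    return label.rsplit(":", 1)[0]


def fit_relaxation_table(recovery: list[IntensitySeries]) -> pd.DataFrame:
    """Fit every recovery series; tabulate R1a (imino) and R1w (water).

    Series whose condition label ends in ``:inversion`` are fit with the
    selective inversion model, ``:saturation`` with the saturation model.
    """
    rows = []
    for s in recovery:
        if s.condition.endswith(":inversion"):
            rate, err = fit_inversion_recovery(s)
            kind = "inversion"
        elif s.condition.endswith(":saturation"):
            rate, err = fit_saturation_recovery(s)
            kind = "saturation"
        else:
            raise ValueError(
                f"recovery condition {s.condition!r} lacks :inversion/:saturation suffix"
            )
        rows.append((s.residue, _condition_base(s.condition), kind, rate, err))
    return pd.DataFrame(rows, columns=["residue", "condition", "kind", "rate", "stderr"])


def _rates_lookup(rates_df: pd.DataFrame, residue: str, condition: str) -> RelaxationRates:
    sel_a = rates_df[
        (rates_df.residue == residue)
        & (rates_df.condition == condition)
        & (rates_df.kind == "inversion")
    ]
    sel_w = rates_df[
        (rates_df.condition == condition) & (rates_df.kind == "saturation")
    ]
    if sel_a.empty or sel_w.empty:
        raise ValueError(f"no relaxation rates for ({residue!r}, {condition!r})")
    return RelaxationRates(
        R1a=float(sel_a.rate.iloc[0]),
        R1w=float(sel_w.rate.iloc[0]),
        R1a_err=float(sel_a.stderr.iloc[0]),
        R1w_err=float(sel_w.stderr.iloc[0]),
    )


def fit_exchange_table(
    transfer: list[IntensitySeries],
    rates_df: pd.DataFrame,
    config: StudyConfig,
) -> pd.DataFrame:
    """Monte-Carlo k_ex fits for every transfer series.

    Applies the leakage correction first when the config declares a
    nonzero leakage fraction.  All randomness flows from the single
    config seed through one generator consumed in series order.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for s in transfer:
        if config.leakage_fraction > 0:
            s = correct_leakage(s, config.leakage_fraction)
        rates = _rates_lookup(rates_df, s.residue, s.condition)
        res = monte_carlo_kex(s, rates, n_mc=config.n_mc, seed=rng)
        rows.append(
            (
                s.residue,
                s.condition,
                res.kex_point,
                res.kex_mean,
                res.kex_sd,
                res.n_mc,
                res.n_failed,
                res.flagged,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "residue",
            "condition",
            "kex_point",
            "kex_mean",
            "kex_sd",
            "n_mc",
            "n_failed",
            "flagged",
        ],
    )


def titrate_table(kex_df: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Plateau k_open per residue from the in-vitro titration points."""
    rows = []
    for residue, grp in kex_df.groupby("residue", sort=False):
        points = []
        for _, row in grp.iterrows():
            spec = config.conditions.get(row.condition)
            if spec is None or spec.total_mM is None:
                continue  # not an in-vitro titration point
            buf = BufferSpec(
                total_mM=spec.total_mM,
                pH=spec.pH,
                pKa=spec.pKa,
                temperature_c=spec.temperature_c if spec.temperature_c is not None else 18.0,
            )
            res = KineticResult(
                residue=residue,
                condition=row.condition,
                kex_point=row.kex_point,
                kex_mean=row.kex_mean,
                kex_sd=row.kex_sd,
                n_mc=int(row.n_mc),
            )
            points.append((buf, res))
        if len(points) < 2:
            continue
        series = build_titration(points, residue=residue)
        k_open, sd, plateau = kopen_from_plateau(series)
        rows.append((residue, k_open, sd, plateau))
    return pd.DataFrame(rows, columns=["residue", "k_open", "k_open_sd", "plateau"])


def compare_table(
    kopen_df: pd.DataFrame,
    kex_df: pd.DataFrame,
    sd_multiplier: float = 1.0,
    incell_condition: str = "in_cell",
) -> list[OpeningComparison]:
    """Classify each residue's in-cell opening against the in-vitro k_open."""
    incell = kex_df[kex_df.condition == incell_condition].set_index("residue")
    out = []
    for _, row in kopen_df.iterrows():
        if row.residue not in incell.index:
            continue
        cell = incell.loc[row.residue]
        out.append(
            classify_in_cell_opening(
                k_open_invitro=float(row.k_open),
                k_open_invitro_sd=float(row.k_open_sd),
                k_ex_incell=float(cell.kex_mean),
                k_ex_incell_sd=float(cell.kex_sd),
                residue=str(row.residue),
                sd_multiplier=sd_multiplier,
            )
        )
    return out
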