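"""Synthetic study generator.

No raw spectra accompany the measurements this package analyses, so
every pipeline stage is exercised on synthetic data generated here from
declared ground truth: water-magnetization-transfer curves built from
the two-state exchange model and the closed-form transfer equation,
inversion/saturation recovery curves for the relaxation rates, an
in-vitro catalyst titration, an in-cell condition generated directly
from an in-cell k_ex (the intracellular catalyst content is unknown by
construction), optional linear sample leakage over the acquisition
sequence, and additive Gaussian spectral noise.

The default ground truth emulates a 20-nt hairpin RNA study: five imino
residues whose two-state parameters are chosen so that the generated
titration reproduces the published exchange rates at 10 and 300 mM total
catalyst, the five delay times 0.1, 0.001, 0.01, 0.06 and 0.03 s
recorded in that (scrambled) order, and an in-cell condition with
several-fold larger spectral noise emulating broad, noisy in-cell lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .catalyst import BufferSpec, base_form_concentration, tris_pka
from .core_model import RelaxationRates, intensity_ratio, overall_exchange_rate
from .fitting import IntensitySeries, monte_carlo_kex

__all__ = [
    "ResidueTruth",
    "GroundTruth",
    "default_hprna20_truth",
    "saturation_params_from_two_points",
    "generate_transfer_series",
    "generate_recovery_series",
    "generate_study",
    "noise_for_target_kex_sd",
]

#: the study's delay times in the order they are recorded (scrambled)
DEFAULT_DELAYS_ACQ_ORDER = (0.1, 0.001, 0.01, 0.06, 0.03)

#: published exchange rates (s^-1) of the hairpin imino protons at
#: 10 mM / 300 mM total catalyst in vitro and in cells; these are the
#: study conditions the default ground truth reproduces
HPRNA20_TABLE = {
    "G4": (0.9, 1.2, 3.0),
    "U14": (6.7, 34.5, 6.2),
    "G15": (0.7, 1.1, 3.2),
    "U18": (1.4, 12.5, 4.2),
    "G19": (1.4, 11.6, 6.7),
}


@dataclass(frozen=True)
class ResidueTruth:
    """Ground-truth kinetics of one base pair."""

    k_open: float  # s^-1, in vitro
    k_close: float  # s^-1, in vitro
    k_B: float  # per-mM-per-s catalysis coefficient: k_ex_open = k_B * [B]
    kex_incell: float  # s^-1, the in-cell overall exchange rate
    k_open_incell: float | None = None  # s^-1; None -> mid-saturation default

    def kex_at(self, base_form_mM: float) -> float:
        """Overall exchange rate at a given base-catalyst concentration."""
        return overall_exchange_rate(self.k_open, self.k_close, self.k_B * base_form_mM)

    @property
    def k_open_incell_effective(self) -> float:
        """In-cell opening rate consistent with the in-cell k_ex.

        The intracellular catalyst content is unknown; when no in-cell
        opening rate is declared the condition is taken at mid-saturation
        (open-state exchange equal to closing), i.e. k_open = 2 * k_ex.
        """
        if self.k_open_incell is not None:
            return self.k_open_incell
        return 2.0 * self.kex_incell


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to generate a full synthetic study."""

    residues: dict[str, ResidueTruth]
    R1a_intrinsic: float = 2.0  # s^-1, exchange-free imino relaxation
    R1w: float = 0.4  # s^-1, water longitudinal relaxation
    I0: float = 1.0  # arbitrary units
    noise_sd_invitro: float = 0.01  # intensity units
    noise_sd_incell: float = 0.05  # ~5x in vitro: broad, noisy in-cell lines
    leakage_fraction: float = 0.0
    buffers: tuple[BufferSpec, ...] = ()
    delays: tuple[float, ...] = DEFAULT_DELAYS_ACQ_ORDER  # acquisition order
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.delays):
            raise ValueError("delays must be >= 0")
        if self.noise_sd_invitro < 0 or self.noise_sd_incell < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0.0 <= self.leakage_fraction < 1.0):
            raise ValueError("leakage_fraction must be in [0, 1)")

    def noise_sd(self, condition: str) -> float:
        return self.noise_sd_incell if condition.startswith("in_cell") else self.noise_sd_invitro

    def apparent_rates(self, kex: float) -> RelaxationRates:
        """Apparent relaxation rates entering the transfer equation."""
        return RelaxationRates(R1a=self.R1a_intrinsic + kex, R1w=self.R1w)


def saturation_params_from_two_points(
    b1: float, kex1: float, b2: float, kex2: float
) -> tuple[float, float]:
    """(k_open, K_half) of k_ex = k_open*[B]/(K_half+[B]) through two points.

    Closed-form two-point inversion of the saturation model; requires
    kex2/b2 < kex1/b1 ordering consistent with saturation (the rate per
    unit catalyst must fall as the catalyst increases).
    """
    denom = kex1 * b2 - kex2 * b1
    if denom <= 0:
        raise ValueError("points are inconsistent with a saturating titration")
    k_half = b1 * b2 * (kex2 - kex1) / denom
    k_open = kex1 * (k_half + b1) / b1
    if k_half < 0 or k_open <= 0:
        raise ValueError("points are inconsistent with a saturating titration")
    return k_open, k_half


def default_hprna20_truth(
    seed: int = 0,
    leakage_fraction: float = 0.0,
    pH: float = 8.0,
    temperature_c: float = 18.0,
    k_B: float = 1.0,
) -> GroundTruth:
    """Ground truth emulating the hairpin study.

    Per-residue (k_open, k_close) are solved so that the two-state model
    reproduces the published exchange rates at 10 and 300 mM total
    catalyst; the in-cell rates are taken directly from the published
    in-cell column.  The catalysis coefficient k_B only sets the scale of
    k_close (K_half = k_close/k_B) and is not separately identifiable.
    """
    pKa = tris_pka(temperature_c)
    totals = (10.0, 300.0)
    b1, b2 = (
        base_form_concentration(BufferSpec(c, pH, pKa, temperature_c)) for c in totals
    )
    residues = {}
    for name, (kex_lo, kex_hi, kex_cell) in HPRNA20_TABLE.items():
        k_open, k_half = saturation_params_from_two_points(b1, kex_lo, b2, kex_hi)
        residues[name] = ResidueTruth(
            k_open=k_open, k_close=k_half * k_B, k_B=k_B, kex_incell=kex_cell
        )
    buffers = tuple(BufferSpec(c, pH, pKa, temperature_c) for c in totals)
    return GroundTruth(
        residues=residues,
        buffers=buffers,
        seed=seed,
        leakage_fraction=leakage_fraction,
    )


def _apply_leakage_decay(
    intensities: np.ndarray, acq_ranks: np.ndarray, fraction: float
) -> np.ndarray:
    """Linear signal loss over the acquisition sequence (inverse of the correction)."""
    n = len(intensities)
    if fraction == 0.0 or n < 2:
        return intensities
    return intensities * (1.0 - fraction * acq_ranks / (n - 1))


def _series_kex(truth: GroundTruth, residue: str, buffer: BufferSpec | None, condition: str) -> float:
    rt = truth.residues[residue]
    if condition.startswith("in_cell"):
        return rt.kex_incell
    if buffer is None:
        raise ValueError("in-vitro series need a BufferSpec")
    return rt.kex_at(base_form_concentration(buffer))


def generate_transfer_series(
    truth: GroundTruth,
    residue: str,
    buffer: BufferSpec | None = None,
    condition: str = "in_vitro",
    rng: np.random.Generator | None = None,
) -> IntensitySeries:
    """One noisy water-magnetization-transfer series.

    The overall k_ex comes from the two-state model at the buffer's
    base-form concentration (or from the in-cell ground truth), the ideal
    ratios from the closed-form transfer equation with the apparent
    imino relaxation rate R1a_intrinsic + k_ex, then leakage decay in
    acquisition order and additive Gaussian noise.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    kex = _series_kex(truth, residue, buffer, condition)
    delays = np.asarray(truth.delays, dtype=float)
    # truth.delays are listed in recording order; store ascending, so the
    # acquisition rank of the i-th sorted delay is its original position
    order = np.argsort(delays, kind="stable")
    acq_rank_sorted = order
    rates = truth.apparent_rates(kex)
    ratios = intensity_ratio(delays[order], kex, rates)
    ideal = truth.I0 * ratios
    noise_sd = truth.noise_sd(condition)
    decayed = _apply_leakage_decay(ideal, acq_rank_sorted, truth.leakage_fraction)
    noisy = decayed + rng.normal(0.0, noise_sd, len(decayed)) if noise_sd else decayed
    return IntensitySeries(
        residue=residue,
        condition=condition,
        delays=delays[order],
        intensities=noisy,
        acquisition_order=acq_rank_sorted,
        noise_sd=noise_sd,
    )


#: log-spaced recovery delays covering apparent rates from ~0.3 to ~40 s^-1
DEFAULT_RECOVERY_DELAYS = (
    0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0,
)


def generate_recovery_series(
    truth: GroundTruth,
    kind: str,
    residue: str | None = None,
    buffer: BufferSpec | None = None,
    condition: str = "in_vitro",
    delays: tuple[float, ...] = DEFAULT_RECOVERY_DELAYS,
    rng: np.random.Generator | None = None,
) -> IntensitySeries:
    """A relaxation-recovery series.

    ``kind="inversion"`` gives the imino selective inversion recovery
    I(t) = I0*(1 - 2*exp(-R1a*t)) with the *apparent* R1a of the chosen
    residue/buffer; ``kind="saturation"`` gives the water recovery
    I(t) = I0*(1 - exp(-R1w*t)).
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    t = np.asarray(delays, dtype=float)
    if kind == "inversion":
        if residue is None:
            raise ValueError("inversion recovery needs a residue")
        kex = _series_kex(truth, residue, buffer, condition)
        r1 = truth.R1a_intrinsic + kex
        ideal = truth.I0 * (1.0 - 2.0 * np.exp(-r1 * t))
        label = residue
    elif kind == "saturation":
        ideal = truth.I0 * (1.0 - np.exp(-truth.R1w * t))
        label = "water"
    else:
        raise ValueError(f"kind must be 'inversion' or 'saturation', got {kind!r}")
    noise_sd = truth.noise_sd(condition)
    noisy = ideal + rng.normal(0.0, noise_sd, len(t)) if noise_sd else ideal
    return IntensitySeries(
        residue=label,
        condition=f"{condition}:{kind}",
        delays=t,
        intensities=noisy,
        acquisition_order=np.arange(len(t)),
        noise_sd=noise_sd,
    )


def noise_for_target_kex_sd(
    truth: GroundTruth,
    residue: str,
    target_sd: float,
    buffer: BufferSpec | None = None,
    condition: str = "in_vitro",
    n_mc: int = 50,
    probe_sd: float = 0.01,
    seed: int = 0,
) -> float:
    """Intensity noise sd whose Monte-Carlo k_ex sd matches ``target_sd``.

    The MC sd is first-order linear in the intensity noise at the small
    noise levels relevant here, so a single probe run at ``probe_sd``
    fixes the scale: sd_noise = probe_sd * target_sd / sd_probe.
    """
    from dataclasses import replace as _replace

    probe_truth = _replace(truth, noise_sd_invitro=probe_sd, noise_sd_incell=probe_sd)
    rng = np.random.default_rng(seed)
    series = generate_transfer_series(probe_truth, residue, buffer, condition, rng=rng)
    kex = _series_kex(truth, residue, buffer, condition)
    res = monte_carlo_kex(series, truth.apparent_rates(kex), n_mc=n_mc, seed=seed)
    if res.kex_sd == 0:
        raise RuntimeError("probe Monte-Carlo sd is zero; cannot calibrate")
    return probe_sd * target_sd / res.kex_sd


def generate_study(truth: GroundTruth, outdir: str | Path) -> dict:
    """Write a full synthetic study bundle to ``outdir``.

    Produces ``transfer.tsv`` (all residues, every in-vitro titration
    point plus the in-cell condition), ``recovery.tsv`` (per-residue
    inversion recoveries and a water saturation recovery for every
    condition — the apparent imino R1a contains the exchange
    contribution and therefore changes with the catalyst concentration),
    a ``config.json`` sidecar mapping condition labels to buffer
    metadata and noise sds, and a ``manifest.json`` recording the ground
    truth and seed for downstream assertions.  Returns the manifest.
    """
    from . import interface

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)

    conditions: dict[str, dict] = {}
    transfer: list[IntensitySeries] = []
    recovery: list[IntensitySeries] = []

    points: list[tuple[str, BufferSpec | None]] = []
    for buf in truth.buffers:
        label = f"in_vitro@{buf.total_mM:g}mM"
        conditions[label] = {
            "total_mM": buf.total_mM,
            "pH": buf.pH,
            "pKa": buf.pKa,
            "temperature_c": buf.temperature_c,
            "noise_sd": truth.noise_sd("in_vitro"),
        }
        points.append((label, buf))
    conditions["in_cell"] = {"noise_sd": truth.noise_sd("in_cell")}
    points.append(("in_cell", None))

    for label, buf in points:
        for residue in truth.residues:
            transfer.append(
                generate_transfer_series(truth, residue, buf, condition=label, rng=rng)
            )
            recovery.append(
                generate_recovery_series(
                    truth, "inversion", residue=residue, buffer=buf,
                    condition=label, rng=rng,
                )
            )
        recovery.append(
            generate_recovery_series(truth, "saturation", condition=label, rng=rng)
        )

    interface.write_intensity_table(outdir / "transfer.tsv", transfer)
    interface.write_intensity_table(outdir / "recovery.tsv", recovery)
    with open(outdir / "config.json", "w") as fh:
        json.dump({"conditions": conditions, "seed": truth.seed}, fh, indent=1)

    manifest = {
        "seed": truth.seed,
        "delays_acquisition_order": list(truth.delays),
        "R1a_intrinsic": truth.R1a_intrinsic,
        "R1w": truth.R1w,
        "I0": truth.I0,
        "leakage_fraction": truth.leakage_fraction,
        "noise_sd_invitro": truth.noise_sd_invitro,
        "noise_sd_incell": truth.noise_sd_incell,
        "residues": {
            name: {
                "k_open": rt.k_open,
                "k_close": rt.k_close,
                "k_B": rt.k_B,
                "kex_incell": rt.kex_incell,
                "k_open_incell": rt.k_open_incell_effective,
            }
            for name, rt in truth.residues.items()
        },
        "conditions": conditions,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
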