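"""Base-catalyst speciation arithmetic for Tris titrations.

Imino-proton exchange in the open state is catalysed by the unprotonated
(base) form of Tris.  Its concentration follows from the total Tris
concentration, the pH and the pKa via Henderson-Hasselbalch speciation.
All concentrations are in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BufferSpec",
    "TRIS_PKA_25C",
    "TRIS_PKA_TEMP_COEFF",
    "tris_pka",
    "base_form_concentration",
    "total_for_target_base_form",
    "titration_mixing_schedule",
]

#: Tris pKa at 25 degC and its temperature coefficient (per K)
TRIS_PKA_25C = 8.06
TRIS_PKA_TEMP_COEFF = -0.028


def tris_pka(temperature_c: float) -> float:
    """Tris pKa at a given temperature (degC), linear in T around 25 degC.

    At the 18 degC of the NMR experiments this gives 8.26, which
    reproduces the correspondence of ~100 mM base form with ~300 mM total
    Tris at pH 8.0.
    """
    return TRIS_PKA_25C + TRIS_PKA_TEMP_COEFF * (temperature_c - 25.0)


@dataclass(frozen=True)
class BufferSpec:
    """A Tris buffer condition: total concentration (mM), pH, pKa.

    Temperature is carried as metadata; the default pKa corresponds to
    18 degC.
    """

    total_mM: float
    pH: float
    pKa: float = tris_pka(18.0)
    temperature_c: float = 18.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.total_mM) or self.total_mM < 0:
            raise ValueError(f"total_mM must be finite and >= 0, got {self.total_mM!r}")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH must be in (0, 14), got {self.pH!r}")
        if not (0.0 < self.pKa < 14.0):
            raise ValueError(f"pKa must be in (0, 14), got {self.pKa!r}")

    @property
    def base_form_mM(self) -> float:
        return base_form_concentration(self)


def base_form_concentration(buffer: BufferSpec) -> float:
    """Concentration of the base (unprotonated) form of the catalyst, mM.

    [B] = c0 * 10^(-pKa) / (10^(-pH) + 10^(-pKa)).
    """
    c0, pH, pKa = buffer.total_mM, buffer.pH, buffer.pKa
    return c0 * 10.0 ** (-pKa) / (10.0 ** (-pH) + 10.0 ** (-pKa))


def total_for_target_base_form(target_mM: float, pH: float, pKa: float) -> float:
    """Total catalyst concentration whose base form equals ``target_mM``.

    Exact algebraic inverse of :func:`base_form_concentration`.
    """
    if not np.isfinite(target_mM) or target_mM < 0:
        raise ValueError(f"target_mM must be finite and >= 0, got {target_mM!r}")
    return target_mM * (10.0 ** (-pH) + 10.0 ** (-pKa)) / 10.0 ** (-pKa)


def titration_mixing_schedule(
    c1_start: float,
    c2_start: float,
    swap_fraction: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration trajectories of the two-sample exchange titration.

    The titration swaps equal volumes between a low- and a high-catalyst
    sample so that pH and crowder concentrations stay constant while the
    catalyst concentrations converge.  Per step each sample becomes
    (1-f)*own + f*other.

    Returns two arrays of length ``n_steps + 1`` including the starting
    concentrations.
    """
    if not (0.0 <= swap_fraction <= 0.5):
        raise ValueError(f"swap_fraction must be in [0, 0.5], got {swap_fraction!r}")
    if c1_start < 0 or c2_start < 0:
        raise ValueError("concentrations must be >= 0")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    c1 = np.empty(n_steps + 1)
    c2 = np.empty(n_steps + 1)
    c1[0], c2[0] = c1_start, c2_start
    f = swap_fraction
    for i in range(n_steps):
        c1[i + 1] = (1.0 - f) * c1[i] + f * c2[i]
        c2[i + 1] = (1.0 - f) * c2[i] + f * c1[i]
    return c1, c2
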