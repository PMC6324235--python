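"""Two-step evolutionary-rate correction of Ks distributions and event dating.

Lineages evolve at different synonymous rates, so the same event leaves
different Ks peaks in different genomes.  Step 1 aligns every lineage's
peak for the shared ancient hexaploidization to the slowest lineage's
(grape's) peak via a multiplicative coefficient ``c1 = mu_grape / mu_lineage``.
Cross-genome samples are corrected by the algebraic mean of the two
lineages' coefficients.  Because the cotton lineage accelerated again after
its own polyploidy, a second step aligns the (step-1 corrected)
cotton-outgroup distribution onto the durian-outgroup one with
``c2 = mu_durian_cacao / mu_cotton_cacao``, applied to every cotton-lineage
sample.  Corrected peaks date linearly against the calibrated age range of
the shared hexaploidization.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np


@dataclasses.dataclass
class CorrectionModel:
    """Correction coefficients with the fits that supplied each mean."""

    step1: dict[str, float]            # lineage -> c1 (grape fixed at 1)
    step2: float | None = None         # c2 for the cotton lineage, if computed
    provenance: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        for lineage, c in self.step1.items():
            if c <= 0:
                raise ValueError(f"nonpositive step-1 coefficient for {lineage!r}")
        if self.step2 is not None and self.step2 <= 0:
            raise ValueError("nonpositive step-2 coefficient")


@dataclasses.dataclass(frozen=True)
class EventDate:
    """A linearly calibrated event age range."""

    event: str
    corrected_peak: float
    calibration_peak: float
    calibration_range: tuple[float, float]  # mya
    date_range: tuple[float, float]         # mya

    def __post_init__(self):
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date range bounds out of order")


def step1_coefficient(mu_grape: float, mu_lineage: float) -> float:
    """``c1 = mu_grape / mu_lineage``: rescales a lineage's event peak onto grape's."""
    if mu_grape <= 0 or mu_lineage <= 0:
        raise ValueError("peak means must be positive")
    return mu_grape / mu_lineage


def apply_correction(ks_values: Sequence[float], coefficient: float) -> np.ndarray:
    """Multiply a Ks sample by a correction coefficient (order-preserving)."""
    if coefficient <= 0:
        raise ValueError("correction coefficient must be positive")
    return np.asarray(ks_values, float) * coefficient


def correct_between(ks_values: Sequence[float], c_i: float, c_j: float) -> np.ndarray:
    """Correct a cross-genome Ks sample by the mean of the two coefficients.

    ``Ks' = Ks * (c_i + c_j) / 2``; when one genome is grape its coefficient
    is 1 by construction.  Symmetric in the two coefficients.
    """
    if c_i <= 0 or c_j <= 0:
        raise ValueError("correction coefficients must be positive")
    return np.asarray(ks_values, float) * (c_i + c_j) / 2.0


def step2_coefficient(mu_durian_cacao: float, mu_cotton_cacao: float) -> float:
    """``c2 = mu_durian_cacao / mu_cotton_cacao`` (both step-1 corrected)."""
    if mu_durian_cacao <= 0 or mu_cotton_cacao <= 0:
        raise ValueError("peak means must be positive")
    return mu_durian_cacao / mu_cotton_cacao


def step2_correction(ks_values: Sequence[float], mu_cotton_cacao: float,
                     mu_durian_cacao: float) -> np.ndarray:
    """Apply the second-round correction to a cotton-lineage Ks sample.

    Applied multiplicatively to the whole sample (not just its mean) so that
    refitted distributions, not only their means, align.
    """
    c2 = step2_coefficient(mu_durian_cacao, mu_cotton_cacao)
    return apply_correction(ks_values, c2)


def date_event(corrected_peak: float, ech_peak: float, t_lo: float = 115.0,
               t_hi: float = 130.0, event: str = "event") -> EventDate:
    """Date an event linearly against the shared-hexaploidization calibration.

    ``date = corrected_peak / ech_peak * calibration``, endpoint-wise.
    """
    if ech_peak <= 0:
        raise ValueError("calibration peak must be positive")
    if corrected_peak < 0:
        raise ValueError("corrected peak must be nonnegative")
    if corrected_peak > ech_peak:
        warnings.warn(f"{event}: corrected peak exceeds the calibration peak "
                      "(event older than the calibration)")
    ratio = corrected_peak / ech_peak
    return EventDate(event=event, corrected_peak=corrected_peak,
                     calibration_peak=ech_peak, calibration_range=(t_lo, t_hi),
                     date_range=(ratio * t_lo, ratio * t_hi))


def rate_elevation(mu_fast_outgroup: float, mu_slow_outgroup: float) -> float:
    """Percent rate elevation of the fast lineage over the slow one.

    Both means are peaks of each lineage's Ks distribution against the same
    outgroup; ``100 * (mu_fast - mu_slow) / mu_slow``.
    """
    if mu_fast_outgroup <= 0 or mu_slow_outgroup <= 0:
        raise ValueError("peak means must be positive")
    return 100.0 * (mu_fast_outgroup - mu_slow_outgroup) / mu_slow_outgroup


def build_correction_model(ech_peaks: Mapping[str, float],
                           reference: str = "grape") -> CorrectionModel:
    """Step-1 coefficients for every lineage from its shared-event peak."""
    if reference not in ech_peaks:
        raise ValueError(f"reference lineage {reference!r} missing from peaks")
    mu_ref = ech_peaks[reference]
    step1 = {lin: step1_coefficient(mu_ref, mu) for lin, mu in ech_peaks.items()}
    prov = {lin: f"ECH peak {mu:.4f}" for lin, mu in ech_peaks.items()}
    return CorrectionModel(step1=step1, provenance=prov)
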