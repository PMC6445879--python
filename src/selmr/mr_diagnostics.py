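"""Heterogeneity, pleiotropy and weak-instrument diagnostics.

Cochran's Q measures dispersion of the per-variant Wald ratios around the
fixed-effect pooled estimate; excess dispersion signals heterogeneity, often
from horizontal pleiotropy.  The MR-Egger intercept test inspects whether the
average direct (pleiotropic) effect differs from zero — reported here on the
exponentiated scale, where deviation from 1 flags directional pleiotropy.
I2_GX quantifies regression dilution of the MR-Egger slope under violation of
the NO Measurement Error (NOME) assumption on the exposure effects: values
near 1 mean the measured exposure effects are precise enough that the Egger
slope is essentially undiluted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .mr_estimators import EggerResult, EstimatorError, WaldRatio, cochran_q_components
from .summary_data import HarmonizedInstrument


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square reference distribution."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PleiotropyTest:
    """Exponentiated MR-Egger intercept with CI, p-value and a decision flag."""

    exponentiated_intercept: float
    ci_low: float
    ci_high: float
    pval: float
    directional: bool


@dataclass(frozen=True)
class NomeDiagnostic:
    """Weighted dispersion of exposure effects and the derived I2_GX."""

    q_gx: float
    i2_gx: float
    weighting_mode: str


def cochran_q(ratios: Sequence[WaldRatio]) -> HeterogeneityResult:
    """Heterogeneity of Wald ratios around the fixed-effect IVW estimate."""
    if len(ratios) < 2:
        raise EstimatorError("Cochran's Q needs at least two ratios")
    _, q = cochran_q_components(ratios)
    df = len(ratios) - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(result: EggerResult) -> PleiotropyTest:
    """Directional-pleiotropy test: does the exponentiated intercept's CI exclude 1?"""
    lo, hi = result.exponentiated_intercept_ci
    return PleiotropyTest(
        exponentiated_intercept=result.exponentiated_intercept,
        ci_low=lo,
        ci_high=hi,
        pval=result.intercept.pval,
        directional=not (lo <= 1.0 <= hi),
    )


def i2_gx(
    instruments: Sequence[HarmonizedInstrument],
    weighting_mode: str = "outcome_se",
) -> NomeDiagnostic:
    """NOME diagnostic for MR-Egger: I2_GX = max(0, (Q_GX - (L-1)) / Q_GX).

    Exposure effects are oriented positive (the Egger convention) and their
    weighted dispersion Q_GX is computed with the MR-Egger regression weights
    1/se_out^2 (``outcome_se``) or with exposure precisions 1/se_exp^2
    (``exposure_se``).  Negative raw values are truncated to 0.
    """
    if len(instruments) < 2:
        raise EstimatorError("I2_GX needs at least two instruments")
    if weighting_mode == "outcome_se":
        v = np.array([1.0 / (i.se_out**2) for i in instruments])
    elif weighting_mode == "exposure_se":
        v = np.array([1.0 / (i.se_exp**2) for i in instruments])
    else:
        raise EstimatorError(f"unknown weighting mode {weighting_mode!r}")
    gamma = np.abs(np.array([i.beta_exp for i in instruments], dtype=float))
    gbar = float(np.sum(v * gamma) / np.sum(v))
    q_gx = float(np.sum(v * (gamma - gbar) ** 2))
    L = len(instruments)
    i2 = max(0.0, (q_gx - (L - 1)) / q_gx) if q_gx > 0 else 0.0
    return NomeDiagnostic(q_gx=q_gx, i2_gx=i2, weighting_mode=weighting_mode)
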