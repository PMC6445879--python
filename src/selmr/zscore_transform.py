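"""Z-score to beta/SE conversion and instrument-strength metrics.

Selenium GWAS meta-analyses report per-allele effects as signed Z-scores.
For ratio-based Mendelian randomization these are rescaled to an effect and
standard error using the allele-frequency/sample-size identity

    beta = Z / sqrt(N * eaf * (1 - eaf)),      se = beta / Z,

so that beta/se reproduces Z exactly and se = 1 / sqrt(N * eaf * (1 - eaf))
regardless of Z.  The per-variant proportion of exposure variance explained
is r2 = Z^2 / (N - 2 + Z^2), additive over independent instruments.

Two conventions coexist in the literature for the variance term (with or
without the diploid factor 2); both are available via ``variance_form`` and
the default, ``"pq"``, is the one that reproduces published two-sample MR
conversions of this kind.  Similarly, "F statistic" is exposed in two modes:
``paper`` (the reciprocal of the converted SE, i.e. sqrt(N*eaf*(1-eaf)),
the form printed in instrument-strength tables of the source analyses) and
``conventional`` (the squared Z-score, the textbook single-variant F).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of the transform."""


def _variance_term(eaf: float, n: float, variance_form: str) -> float:
    if not 0.0 < eaf < 1.0:
        raise DomainError(f"eaf {eaf} outside (0, 1)")
    if n < 2:
        raise DomainError(f"sample size {n} must be >= 2")
    if variance_form == "pq":
        return n * eaf * (1.0 - eaf)
    if variance_form == "2pq":
        return 2.0 * n * eaf * (1.0 - eaf)
    raise DomainError(f"unknown variance form {variance_form!r}")


def z_to_beta(zscore: float, eaf: float, n: float, variance_form: str = "pq") -> float:
    """Convert a signed Z-score to a per-allele effect estimate."""
    return zscore / math.sqrt(_variance_term(eaf, n, variance_form))


def z_to_se(zscore: float, eaf: float, n: float, variance_form: str = "pq") -> float:
    """Standard error of the converted effect; independent of Z (se = beta/Z)."""
    return 1.0 / math.sqrt(_variance_term(eaf, n, variance_form))


def variant_r2(zscore: float, n: float) -> float:
    """Proportion of exposure variance explained by one variant."""
    if n <= 2:
        raise DomainError(f"sample size {n} must be > 2")
    z2 = zscore * zscore
    return z2 / (n - 2.0 + z2)


def f_statistic(zscore: float, eaf: float, n: float, mode: str = "paper") -> float:
    """Instrument-strength F statistic.

    ``paper`` returns 1 / converted SE = sqrt(N*eaf*(1-eaf)); ``conventional``
    returns Z^2 (the Wald F of the variant-exposure regression).
    """
    if mode == "paper":
        return 1.0 / z_to_se(zscore, eaf, n)
    if mode == "conventional":
        _variance_term(eaf, n, "pq")  # validate the shared domain
        return zscore * zscore
    raise DomainError(f"unknown F-statistic mode {mode!r}")


@dataclass(frozen=True)
class InstrumentStrength:
    """Strength metrics of one instrument at the exposure study's scale."""

    rsid: str
    r2_variant: float
    f_paper: float
    f_conventional: float
    n_effective: float

    def __post_init__(self) -> None:
        if self.r2_variant < 0:
            raise DomainError(f"{self.rsid}: r2 must be non-negative")
        if not self.f_paper > 0:
            raise DomainError(f"{self.rsid}: F must be positive")


def instrument_strength(rsid: str, zscore: float, eaf: float, n: float) -> InstrumentStrength:
    """Bundle the per-variant strength metrics for one instrument."""
    return InstrumentStrength(
        rsid=rsid,
        r2_variant=variant_r2(zscore, n),
        f_paper=f_statistic(zscore, eaf, n, mode="paper"),
        f_conventional=f_statistic(zscore, eaf, n, mode="conventional"),
        n_effective=n,
    )


def combined_r2(strengths: Sequence[InstrumentStrength]) -> float:
    """Total variance explained by mutually independent instruments (sum of r2)."""
    if not strengths:
        raise DomainError("combined r2 of an empty instrument set is undefined")
    return float(sum(s.r2_variant for s in strengths))
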