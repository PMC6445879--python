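"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator mirrors the summary-level model the estimators assume: each of
L independent variants j has a true exposure effect gamma_j drawn uniformly,
a direct (pleiotropic) outcome effect alpha_j drawn Normal(mean, sd), and the
true outcome effect is theta * gamma_j + alpha_j.  Observed effects add
sampling noise with standard errors 1/sqrt(N * eaf * (1 - eaf)) driven by the
two studies' sample sizes — the same frequency/sample-size identity the
Z-score conversion uses, so simulated tables round-trip through the whole
pipeline.  Setting ``inside_violation`` couples alpha_j to gamma_j
(alpha_j = mean + rho * gamma_j + noise), breaking the InSIDE assumption.

Default parameters echo the selenium/endometrial-cancer study conditions:
exposure sample size 9,639 and outcome size 121,885, exposure effects in the
0.1-0.4 range the four published instruments span, and a 50-variant panel for
estimator calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import mr_estimators as est
from .summary_data import DEFAULT_COLUMN_MAP, HarmonizedInstrument, VariantAssociation

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))  # non-palindromic
_P_FLOOR = 1e-300


class SimulationError(ValueError):
    """A simulation parameter set is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    n_instruments: int = 50
    theta: float = 0.0
    gamma_low: float = 0.1
    gamma_high: float = 0.4
    n_exp: int = 9639
    n_out: int = 121885
    eaf_low: float = 0.10
    eaf_high: float = 0.90
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: bool = False
    inside_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instruments < 1:
            raise SimulationError("n_instruments must be >= 1")
        if not 0.0 < self.eaf_low <= self.eaf_high < 1.0:
            raise SimulationError("need 0 < eaf_low <= eaf_high < 1")
        if self.n_exp < 2 or self.n_out < 2:
            raise SimulationError("sample sizes must be >= 2")
        if self.gamma_low > self.gamma_high:
            raise SimulationError("gamma_low must not exceed gamma_high")
        if self.pleiotropy_sd < 0:
            raise SimulationError("pleiotropy_sd must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    theta: float
    gamma: np.ndarray
    alpha: np.ndarray


@dataclass(frozen=True)
class SyntheticDataset:
    exposure_table: tuple[VariantAssociation, ...]
    outcome_table: tuple[VariantAssociation, ...]
    truth: SimulationTruth

    def instruments(self) -> list[HarmonizedInstrument]:
        """Harmonized view (tables share alleles, so no flips are needed)."""
        out = []
        for e, o in zip(self.exposure_table, self.outcome_table):
            out.append(HarmonizedInstrument(
                rsid=e.rsid, effect_allele=e.effect_allele,
                beta_exp=e.beta, se_exp=e.se, beta_out=o.beta, se_out=o.se,
                eaf_exp=e.eaf, eaf_out=o.eaf,
            ))
        return out


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(beta) / se), _P_FLOOR)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one two-sample summary-statistics dataset; reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    L = config.n_instruments
    eaf = rng.uniform(config.eaf_low, config.eaf_high, size=L)
    gamma = rng.uniform(config.gamma_low, config.gamma_high, size=L)
    alpha = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=L)
    if config.inside_violation:
        alpha = alpha + config.inside_rho * gamma
    se_exp = 1.0 / np.sqrt(config.n_exp * eaf * (1.0 - eaf))
    se_out = 1.0 / np.sqrt(config.n_out * eaf * (1.0 - eaf))
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(config.theta * gamma + alpha, se_out)
    p_exp = _pvalue(beta_exp, se_exp)
    p_out = _pvalue(beta_out, se_out)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=L)

    exposure, outcome = [], []
    for j in range(L):
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        common = dict(
            rsid=f"rs{1000 + j}", chrom="chr1", pos=10_000 + 1_000 * j,
            effect_allele=ea, other_allele=oa, eaf=float(eaf[j]),
        )
        exposure.append(VariantAssociation(
            beta=float(beta_exp[j]), se=float(se_exp[j]),
            zscore=float(beta_exp[j] / se_exp[j]),
            pval=float(p_exp[j]), n=config.n_exp, **common,
        ))
        outcome.append(VariantAssociation(
            beta=float(beta_out[j]), se=float(se_out[j]),
            pval=float(p_out[j]), n=config.n_out, **common,
        ))
    return SyntheticDataset(
        exposure_table=tuple(exposure),
        outcome_table=tuple(outcome),
        truth=SimulationTruth(theta=config.theta, gamma=gamma, alpha=alpha),
    )


def dataset_to_frame(table: Sequence[VariantAssociation]) -> pd.DataFrame:
    """Render a variant table in the default summary-statistics dialect."""
    rows = []
    for v in table:
        rows.append({
            DEFAULT_COLUMN_MAP["rsid"]: v.rsid,
            DEFAULT_COLUMN_MAP["chrom"]: v.chrom,
            DEFAULT_COLUMN_MAP["pos"]: v.pos,
            DEFAULT_COLUMN_MAP["effect_allele"]: v.effect_allele,
            DEFAULT_COLUMN_MAP["other_allele"]: v.other_allele,
            DEFAULT_COLUMN_MAP["eaf"]: v.eaf,
            DEFAULT_COLUMN_MAP["beta"]: v.beta,
            DEFAULT_COLUMN_MAP["se"]: v.se,
            DEFAULT_COLUMN_MAP["zscore"]: v.zscore,
            DEFAULT_COLUMN_MAP["pval"]: v.pval,
            DEFAULT_COLUMN_MAP["n"]: v.n,
        })
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, exposure_path, outcome_path) -> None:
    """Write the two summary tables as TSV files readable by read_summary_table."""
    dataset_to_frame(dataset.exposure_table).to_csv(exposure_path, sep="\t", index=False)
    dataset_to_frame(dataset.outcome_table).to_csv(outcome_path, sep="\t", index=False)


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo calibration summary for one estimator."""

    method: str
    mean_bias: float
    empirical_sd: float
    rejection_rate: float
    coverage: float
    n_reps: int


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    alpha: float = 0.05,
    methods: Sequence[str] = ("ivw", "egger", "weighted_median"),
    ivw_model: str = "multiplicative_re",
    median_boot: int = 1000,
) -> dict[str, RecoverySummary]:
    """Repeatedly simulate and estimate; report bias, SD, size and coverage.

    Replicate r uses seed ``config.seed + r`` so the experiment is exactly
    reproducible yet replicates are independent.  ``rejection_rate`` is the
    fraction of replicates rejecting the no-effect null at ``alpha``;
    ``coverage`` the fraction of 95% CIs containing the true theta.
    """
    if n_reps < 1:
        raise SimulationError("n_reps must be >= 1")
    unknown = set(methods) - {"ivw", "egger", "weighted_median"}
    if unknown:
        raise SimulationError(f"unknown methods {sorted(unknown)}")
    records: dict[str, list[tuple[float, float, float, float]]] = {m: [] for m in methods}
    for rep in range(n_reps):
        rep_config = replace(config, seed=config.seed + rep)
        instruments = simulate_dataset(rep_config).instruments()
        for m in methods:
            try:
                if m == "ivw":
                    e = est.ivw(instruments, effects_model=ivw_model)
                elif m == "egger":
                    e = est.mr_egger(instruments).slope
                else:
                    e = est.weighted_median(
                        instruments, n_boot=median_boot, seed=rep_config.seed,
                    )
            except est.EstimatorError as exc:
                raise SimulationError(f"replicate {rep}: {exc}") from exc
            records[m].append((e.beta, e.pval, e.ci_low, e.ci_high))
    theta = config.theta
    out: dict[str, RecoverySummary] = {}
    for m, rows in records.items():
        betas = np.array([r[0] for r in rows])
        pvals = np.array([r[1] for r in rows])
        los = np.array([r[2] for r in rows])
        his = np.array([r[3] for r in rows])
        out[m] = RecoverySummary(
            method=m,
            mean_bias=float(np.mean(betas) - theta),
            empirical_sd=float(np.std(betas, ddof=1)) if n_reps > 1 else 0.0,
            rejection_rate=float(np.mean(pvals < alpha)),
            coverage=float(np.mean((los <= theta) & (theta <= his))),
            n_reps=n_reps,
        )
    return out
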