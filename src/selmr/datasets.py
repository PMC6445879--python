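"""Packaged selenium / endometrial-cancer instrument fixture.

The four-variant instrument set (two approximately independent variants at
each of the 5q14 and 21q22 selenium loci) ships with the package as plain
TSV tables in the default summary-statistics dialect: exposure associations
on the Z-score scale from the combined circulating + toenail selenium GWAS
meta-analyses (n = 5,477 + 4,162 = 9,639), outcome associations on the
log-odds scale from the endometrial-cancer GWAS (12,906 cases, 108,979
controls), the two published within-locus LD r2 values, and an empty
confounder-association table (no instrument showed a risk-factor
association at the screening threshold).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .summary_data import HarmonizedInstrument

#: effective sample size of the combined selenium GWAS meta-analyses
SELENIUM_GWAS_N = 9639

# Published per-variant summary statistics (exposure effects converted to
# beta/SE at 2 dp; outcome effects as released): rsid, ea, oa, eaf_exp,
# zscore, beta_exp, se_exp, eaf_out, beta_out, se_out.
_TABLE1 = (
    ("rs1789953", "T", "C", 0.14, 5.52, 0.16, 0.03, 0.13, -0.04, 0.02),
    ("rs6586282", "T", "C", 0.17, -5.89, -0.16, 0.03, 0.17, -0.04, 0.02),
    ("rs6859667", "T", "C", 0.96, -6.92, -0.36, 0.05, 0.96, 0.02, 0.04),
    ("rs921943", "T", "C", 0.29, 13.14, 0.29, 0.02, 0.29, 0.00, 0.02),
)


def _data_path(name: str) -> Path:
    return Path(resources.files("selmr.data") / name)


def exposure_path() -> Path:
    """Selenium exposure summary statistics (Z-score scale), TSV."""
    return _data_path("selenium_exposure.tsv")


def outcome_path() -> Path:
    """Endometrial-cancer outcome summary statistics (log-odds scale), TSV."""
    return _data_path("endometrial_cancer_outcome.tsv")


def ld_path() -> Path:
    """Pairwise LD r2 matrix for the four instruments (published values)."""
    return _data_path("ld_r2.tsv")


def confounder_path() -> Path:
    """Risk-factor association table for the screen (empty: none were found)."""
    return _data_path("confounder_associations.tsv")


def published_zscores() -> dict[str, tuple[float, float]]:
    """Per-variant (zscore, eaf) of the exposure associations."""
    return {row[0]: (row[4], row[3]) for row in _TABLE1}


def load_instruments(rounded: bool = True) -> list[HarmonizedInstrument]:
    """The four harmonized instruments of the published analysis.

    ``rounded=True`` uses the exposure betas/SEs exactly as printed (2 dp);
    ``rounded=False`` re-derives them from the Z-scores at full precision.
    """
    from .zscore_transform import z_to_beta, z_to_se

    out = []
    for rsid, ea, _oa, eaf_exp, z, beta, se, eaf_out, beta_out, se_out in _TABLE1:
        if not rounded:
            beta = z_to_beta(z, eaf_exp, SELENIUM_GWAS_N)
            se = z_to_se(z, eaf_exp, SELENIUM_GWAS_N)
        out.append(HarmonizedInstrument(
            rsid=rsid, effect_allele=ea, beta_exp=beta, se_exp=se,
            beta_out=beta_out, se_out=se_out, eaf_exp=eaf_exp, eaf_out=eaf_out,
        ))
    return out


def fixture_config(seed: int = 1) -> dict:
    """A ready-to-run pipeline configuration over the packaged fixture."""
    return {
        "exposure": {"file": str(exposure_path())},
        "outcome": {"file": str(outcome_path())},
        "ld": {"file": str(ld_path()), "r2_threshold": 0.05},
        "confounders": {"file": str(confounder_path()), "risk_factor_count": 7},
        "conversion": {"n": SELENIUM_GWAS_N, "variance_form": "pq", "f_mode": "paper"},
        "methods": {
            "ivw_model": "multiplicative_re",
            "wald_se_order": "first",
            "egger_pval_dist": "t",
            "median_boot": 1000,
        },
        "palindrome_policy": "keep_if_eaf_informative",
        "seed": seed,
    }
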