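"""Config-driven end-to-end two-sample Mendelian randomization pipeline.

``run_analysis`` executes read -> (screen, prune) -> Z-score conversion ->
harmonization -> estimation (IVW, MR-Egger, weighted median) -> diagnostics
and returns an :class:`AnalysisReport` that serializes losslessly to JSON,
renders as display-rounded TSV tables, or prints as a plain-text summary.
"""

from __future__ import annotations

import copy
import datetime
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from . import mr_diagnostics as diag
from . import mr_estimators as est
from . import summary_data as sd
from . import zscore_transform as zt

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    """The pipeline cannot proceed with the given configuration or data."""


DEFAULT_CONFIG: dict[str, Any] = {
    "exposure": {"file": None, "column_map": None},
    "outcome": {"file": None, "column_map": None},
    "ld": None,            # {"file": ..., "r2_threshold": 0.05}
    "confounders": None,   # {"file": ..., "risk_factor_count": 7}
    "conversion": {"n": None, "variance_form": "pq", "f_mode": "paper"},
    "methods": {
        "ivw_model": "multiplicative_re",
        "wald_se_order": "first",
        "egger_pval_dist": "t",
        "median_boot": 1000,
        "i2gx_weighting": "outcome_se",
    },
    "palindrome_policy": "keep_if_eaf_informative",
    "seed": None,
}


def _merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path) -> dict:
    """Load a YAML config file, merge defaults, resolve paths relative to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    config = _merge(DEFAULT_CONFIG, raw)
    base = path.parent
    for section in ("exposure", "outcome", "ld", "confounders"):
        sec = config.get(section)
        if sec and sec.get("file"):
            sec["file"] = str((base / sec["file"]).resolve())
    return config


@dataclass
class AnalysisReport:
    """Machine-readable result of one pipeline run."""

    instrument_table: list[dict]
    estimates: dict[str, est.MrEstimate]
    heterogeneity: diag.HeterogeneityResult | None
    egger_intercept: diag.PleiotropyTest | None
    i2_gx: diag.NomeDiagnostic | None
    combined_r2: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "instrument_table": self.instrument_table,
            "estimates": {k: asdict(v) for k, v in self.estimates.items()},
            "heterogeneity": asdict(self.heterogeneity) if self.heterogeneity else None,
            "egger_intercept": asdict(self.egger_intercept) if self.egger_intercept else None,
            "i2_gx": asdict(self.i2_gx) if self.i2_gx else None,
            "combined_r2": self.combined_r2,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "AnalysisReport":
        return cls(
            instrument_table=[dict(r) for r in payload["instrument_table"]],
            estimates={k: est.MrEstimate(**v) for k, v in payload["estimates"].items()},
            heterogeneity=(diag.HeterogeneityResult(**payload["heterogeneity"])
                           if payload.get("heterogeneity") else None),
            egger_intercept=(diag.PleiotropyTest(**payload["egger_intercept"])
                             if payload.get("egger_intercept") else None),
            i2_gx=diag.NomeDiagnostic(**payload["i2_gx"]) if payload.get("i2_gx") else None,
            combined_r2=payload.get("combined_r2"),
            provenance=dict(payload["provenance"]),
        )


def _convert_exposure(variants, conversion, warnings):
    """Fill in beta/se from Z-scores where absent, using the configured N."""
    out = []
    for v in variants:
        if v.beta is not None and v.se is not None:
            out.append(v)
            continue
        n = conversion.get("n") or v.n
        if n is None:
            raise PipelineError(
                f"{v.rsid}: Z-score conversion needs a sample size (conversion.n or table column)"
            )
        if v.eaf is None:
            raise PipelineError(f"{v.rsid}: Z-score conversion needs the effect-allele frequency")
        form = conversion.get("variance_form", "pq")
        beta = zt.z_to_beta(v.zscore, v.eaf, n, variance_form=form)
        se = zt.z_to_se(v.zscore, v.eaf, n, variance_form=form)
        out.append(sd.VariantAssociation(
            rsid=v.rsid, chrom=v.chrom, pos=v.pos,
            effect_allele=v.effect_allele, other_allele=v.other_allele,
            eaf=v.eaf, beta=beta, se=se, zscore=v.zscore, pval=v.pval, n=v.n,
        ))
    return out


def run_analysis(config: Mapping | str | Path) -> AnalysisReport:
    """Run the full summary-statistics MR analysis described by ``config``."""
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge(DEFAULT_CONFIG, config)
    warnings: list[str] = []

    for section in ("exposure", "outcome"):
        if not (config.get(section) or {}).get("file"):
            raise PipelineError(f"config must name an {section} summary-statistics file")
    exposure = sd.read_summary_table(
        config["exposure"]["file"], column_map=config["exposure"].get("column_map"))
    outcome = sd.read_summary_table(
        config["outcome"]["file"], column_map=config["outcome"].get("column_map"))

    screen_cfg = config.get("confounders")
    if screen_cfg and screen_cfg.get("file"):
        table = sd.read_association_table(screen_cfg["file"])
        screen = sd.screen_confounders(
            exposure, table, risk_factor_count=screen_cfg.get("risk_factor_count", 7))
        failing = [r for r in screen.values() if not r.passed]
        for r in failing:
            traits = ", ".join(t for t, _ in r.offending)
            warnings.append(f"dropped {r.rsid}: associated with risk factor(s) {traits}")
        dropped = {r.rsid for r in failing}
        exposure = [v for v in exposure if v.rsid not in dropped]

    ld_cfg = config.get("ld")
    if ld_cfg and ld_cfg.get("file"):
        ld = sd.read_ld_matrix(ld_cfg["file"])
        before = len(exposure)
        exposure = sd.ld_prune(exposure, ld, r2_threshold=ld_cfg.get("r2_threshold", 0.05))
        if len(exposure) < before:
            warnings.append(f"LD pruning removed {before - len(exposure)} of {before} variants")

    conversion = config.get("conversion") or {}
    exposure = _convert_exposure(exposure, conversion, warnings)

    outcome_by_rsid = {v.rsid: v for v in outcome}
    instruments: list[sd.HarmonizedInstrument] = []
    converted_by_rsid: dict[str, sd.VariantAssociation] = {}
    for v in exposure:
        o = outcome_by_rsid.get(v.rsid)
        if o is None:
            warnings.append(f"dropped {v.rsid}: absent from the outcome study (no proxy search)")
            logger.warning("dropped %s: absent from outcome study", v.rsid)
            continue
        inst = sd.harmonize(v, o, palindrome_policy=config["palindrome_policy"])
        if inst is None:
            warnings.append(f"dropped {v.rsid}: palindromic with uninformative allele frequency")
            continue
        instruments.append(inst)
        converted_by_rsid[v.rsid] = v
    if not instruments:
        raise PipelineError("no instruments remain after harmonization")

    methods = config["methods"]
    se_order = methods.get("wald_se_order", "first")
    seed = config.get("seed")

    estimates: dict[str, est.MrEstimate] = {}
    estimates["ivw"] = est.ivw(
        instruments, effects_model=methods.get("ivw_model", "multiplicative_re"),
        se_order=se_order) if len(instruments) > 1 else est.ivw(
        instruments, effects_model="fixed", se_order=se_order)

    egger_result = None
    if len(instruments) >= 3:
        egger_result = est.mr_egger(instruments, pval_dist=methods.get("egger_pval_dist", "t"))
        estimates["egger"] = egger_result.slope
        estimates["egger_intercept"] = egger_result.intercept
        estimates["weighted_median"] = est.weighted_median(
            instruments, n_boot=methods.get("median_boot", 1000), seed=seed,
            se_order=se_order)
    else:
        warnings.append(
            f"only {len(instruments)} instruments: MR-Egger and weighted median skipped")

    ratios = [est.wald_ratio(i, se_order=se_order) for i in instruments]
    heterogeneity = diag.cochran_q(ratios) if len(ratios) >= 2 else None
    intercept_test = diag.egger_intercept_test(egger_result) if egger_result else None
    nome = (diag.i2_gx(instruments, weighting_mode=methods.get("i2gx_weighting", "outcome_se"))
            if len(instruments) >= 2 else None)

    strengths = []
    n_conv = conversion.get("n")
    for inst in instruments:
        v = converted_by_rsid[inst.rsid]
        z = v.z_equivalent
        n = n_conv or v.n
        if n is not None and n > 2 and v.eaf is not None:
            strengths.append(zt.instrument_strength(v.rsid, z, v.eaf, n))
    r2_total = zt.combined_r2(strengths) if strengths else None
    strength_by_rsid = {s.rsid: s for s in strengths}

    table = []
    for inst, ratio in zip(instruments, ratios):
        s = strength_by_rsid.get(inst.rsid)
        v = converted_by_rsid[inst.rsid]
        table.append({
            "rsid": inst.rsid,
            "effect_allele": inst.effect_allele,
            "eaf_exp": inst.eaf_exp,
            "zscore": v.zscore,
            "beta_exp": inst.beta_exp,
            "se_exp": inst.se_exp,
            "pval_exp": v.pval,
            "beta_out": inst.beta_out,
            "se_out": inst.se_out,
            "flipped": inst.flipped,
            "f_statistic": None if s is None else s.f_paper,
            "r2": None if s is None else s.r2_variant,
            "wald_ratio": ratio.ratio,
            "wald_se": ratio.se,
        })

    provenance = {
        "config": _jsonable(config),
        "seed": seed,
        "software": f"selmr {__version__}",
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "warnings": warnings,
    }
    return AnalysisReport(
        instrument_table=table,
        estimates=estimates,
        heterogeneity=heterogeneity,
        egger_intercept=intercept_test,
        i2_gx=nome,
        combined_r2=r2_total,
        provenance=provenance,
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _fmt(x, nd=2):
    return "" if x is None else f"{x:.{nd}f}"


def write_report(report: AnalysisReport, path, format: str = "json") -> None:
    """Serialize a report: lossless ``json``, display-rounded ``tsv_tables``,
    or a human-readable ``text`` summary."""
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    elif format == "tsv_tables":
        base = path.with_suffix("") if path.suffix else path
        _write_tsv_tables(report, base)
    elif format == "text":
        path.write_text(render_text(report))
    else:
        raise PipelineError(f"unknown report format {format!r}")


def _write_tsv_tables(report: AnalysisReport, base: Path) -> None:
    inst_cols = ("rsid", "effect_allele", "eaf_exp", "zscore", "beta_exp", "se_exp",
                 "beta_out", "se_out", "f_statistic", "wald_ratio", "wald_se")
    lines = ["\t".join(inst_cols)]
    for row in report.instrument_table:
        rendered = []
        for c in inst_cols:
            v = row[c]
            rendered.append(str(v) if isinstance(v, (str, bool)) or v is None else _fmt(v))
        lines.append("\t".join(rendered))
    Path(f"{base}_instruments.tsv").write_text("\n".join(lines) + "\n")

    est_cols = ("method", "n_snps", "beta", "se", "ci_low", "ci_high", "pval",
                "odds_ratio", "or_ci_low", "or_ci_high")
    lines = ["\t".join(est_cols)]
    for key, e in report.estimates.items():
        lines.append("\t".join([
            key, str(e.n_snps), _fmt(e.beta), _fmt(e.se), _fmt(e.ci_low),
            _fmt(e.ci_high), _fmt(e.pval), _fmt(e.odds_ratio),
            _fmt(e.or_ci_low), _fmt(e.or_ci_high),
        ]))
    Path(f"{base}_estimates.tsv").write_text("\n".join(lines) + "\n")


def render_text(report: AnalysisReport) -> str:
    """Plain-text summary of estimates and diagnostics."""
    lines = [f"Two-sample MR analysis ({report.provenance['software']})",
             f"Instruments: {len(report.instrument_table)}"]
    if report.combined_r2 is not None:
        lines.append(f"Combined instrument R2: {100 * report.combined_r2:.1f}%")
    names = {"ivw": "IVW", "egger": "MR-Egger", "egger_intercept": "MR-Egger intercept",
             "weighted_median": "Weighted median"}
    for key, e in report.estimates.items():
        label = names.get(key, key)
        lines.append(
            f"{label}: OR {e.odds_ratio:.2f} (95% CI {e.or_ci_low:.2f}-{e.or_ci_high:.2f}), "
            f"p = {e.pval:.2f}"
        )
    if report.heterogeneity is not None:
        h = report.heterogeneity
        lines.append(f"Cochran's Q: {h.q:.2f} (df {h.df}), p = {h.pval:.2f}")
    if report.egger_intercept is not None:
        t = report.egger_intercept
        verdict = "evidence" if t.directional else "no evidence"
        lines.append(
            f"Exponentiated Egger intercept: {t.exponentiated_intercept:.2f} "
            f"(95% CI {t.ci_low:.2f}-{t.ci_high:.2f}), p = {t.pval:.2f} "
            f"({verdict} of directional pleiotropy)"
        )
    if report.i2_gx is not None:
        lines.append(f"I2_GX: {100 * report.i2_gx.i2_gx:.0f}% ({report.i2_gx.weighting_mode} weights)")
    for w in report.provenance.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines) + "\n"
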