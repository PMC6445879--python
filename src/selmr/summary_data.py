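"""Reading, validation, harmonization and pruning of GWAS summary statistics.

Two-sample Mendelian randomization works entirely from per-variant summary
association statistics: one table for the exposure study, one for the outcome
study.  This module defines the variant-level record types, a delimited-table
reader with per-row validation, allele harmonization onto a common effect
allele (sign flips, frequency complements, strand flips and palindromic-pair
policies), greedy LD pruning, and a local confounder screen that replaces a
live trait-association lookup with a user-supplied table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: allele pairs that are their own reverse complement (strand-ambiguous)
PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

#: default minor-allele-frequency cutoff above which a palindromic variant's
#: frequency no longer identifies the strand (community convention)
PALINDROME_EAF_THRESHOLD = 0.42


class SummaryDataError(ValueError):
    """Base class for summary-statistics handling errors."""


class ConfigurationError(SummaryDataError):
    """A column map, threshold or option is invalid."""


class RowParseError(SummaryDataError):
    """A data row holds an unparseable value; message carries the line number."""


class DuplicateVariantError(SummaryDataError):
    """The same rsid appears more than once in a table."""


class HarmonizationError(SummaryDataError):
    """Exposure and outcome records cannot be aligned to a common allele."""


@dataclass(frozen=True)
class VariantAssociation:
    """Summary statistics of one variant for one trait.

    Effects may be given either on the beta/SE scale or as a signed Z-score;
    at least one complete representation is required.  When all three are
    present they must be mutually consistent (beta/se == zscore).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    beta: float | None = None
    se: float | None = None
    zscore: float | None = None
    pval: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        ea, oa = self.effect_allele, self.other_allele
        if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
            raise SummaryDataError(
                f"{self.rsid}: alleles must be single nucleotides in ACGT, got {ea!r}/{oa!r}"
            )
        if ea == oa:
            raise SummaryDataError(f"{self.rsid}: effect and other allele are identical ({ea})")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise SummaryDataError(f"{self.rsid}: eaf {self.eaf} outside (0, 1)")
        if self.se is not None and not self.se > 0:
            raise SummaryDataError(f"{self.rsid}: se {self.se} must be > 0")
        if self.pval is not None and not 0.0 < self.pval <= 1.0:
            raise SummaryDataError(f"{self.rsid}: p-value {self.pval} outside (0, 1]")
        if self.n is not None and self.n < 1:
            raise SummaryDataError(f"{self.rsid}: sample size {self.n} must be positive")
        has_beta_se = self.beta is not None and self.se is not None
        if not has_beta_se and self.zscore is None:
            raise SummaryDataError(
                f"{self.rsid}: needs either beta+se or a Z-score"
            )
        if has_beta_se and self.zscore is not None:
            implied = self.beta / self.se
            if abs(implied - self.zscore) > 1e-6 * max(1.0, abs(self.zscore)):
                raise SummaryDataError(
                    f"{self.rsid}: beta/se = {implied:.6g} inconsistent with Z-score {self.zscore}"
                )

    @property
    def z_equivalent(self) -> float:
        """The signed standardized effect: zscore if given, else beta/se."""
        if self.zscore is not None:
            return self.zscore
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in PALINDROMIC_PAIRS


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one variant on a common effect allele."""

    rsid: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None = None
    eaf_out: float | None = None
    flipped: bool = False
    palindromic: bool = False

    def __post_init__(self) -> None:
        if not self.se_exp > 0:
            raise SummaryDataError(f"{self.rsid}: se_exp must be > 0")
        if not self.se_out > 0:
            raise SummaryDataError(f"{self.rsid}: se_out must be > 0")

    def reoriented(self) -> "HarmonizedInstrument":
        """The same instrument expressed on the opposite effect allele."""
        return replace(
            self,
            effect_allele=self.effect_allele,  # caller's bookkeeping; effects flip
            beta_exp=-self.beta_exp,
            beta_out=-self.beta_out,
            eaf_exp=None if self.eaf_exp is None else 1.0 - self.eaf_exp,
            eaf_out=None if self.eaf_out is None else 1.0 - self.eaf_out,
        )


@dataclass(frozen=True)
class LdMatrix:
    """Square pairwise LD r-squared matrix over an ordered set of rsids."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.r2, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.rsids):
            raise SummaryDataError("LD matrix must be square and match the rsid list")
        if not np.allclose(m, m.T, atol=1e-8):
            raise SummaryDataError("LD matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise SummaryDataError("LD matrix diagonal must be 1")
        if m.min() < -1e-12 or m.max() > 1.0 + 1e-12:
            raise SummaryDataError("LD r2 values must lie in [0, 1]")
        object.__setattr__(self, "r2", m)

    def lookup(self, a: str, b: str) -> float:
        try:
            i, j = self.rsids.index(a), self.rsids.index(b)
        except ValueError as exc:
            raise SummaryDataError(f"variant {exc.args[0].split()[0]!r} absent from LD matrix") from None
        return float(self.r2[i, j])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.rsids


def read_ld_matrix(source) -> LdMatrix:
    """Read a square delimited LD r2 matrix; first row and column are rsids."""
    df = pd.read_csv(source, sep=None, engine="python", index_col=0)
    if list(df.index) != list(df.columns):
        raise SummaryDataError("LD matrix row and column rsids must match in order")
    return LdMatrix(rsids=tuple(str(r) for r in df.index), r2=df.to_numpy(dtype=float))


# Canonical field -> default column header in the summary-statistics dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "zscore": "z",
    "pval": "p",
    "n": "n",
}

_REQUIRED_FIELDS = ("rsid", "effect_allele", "other_allele")
_FLOAT_FIELDS = ("eaf", "beta", "se", "zscore", "pval")
_INT_FIELDS = ("pos", "n")


def _parse_number(raw: str, field: str, line: int, as_int: bool):
    text = raw.strip()
    if text == "" or text.lower() in ("na", "nan", "."):
        return None
    try:
        value = float(text)
    except ValueError:
        raise RowParseError(f"line {line}: cannot parse {field} value {raw!r}") from None
    if as_int:
        if value != int(value):
            raise RowParseError(f"line {line}: {field} value {raw!r} is not an integer")
        return int(value)
    return value


def read_summary_table(
    source,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read a delimited summary-statistics table into validated records.

    ``column_map`` maps canonical field names (keys of
    :data:`DEFAULT_COLUMN_MAP`) to column headers in the file.  With the
    default map, optional columns absent from the header are simply not read;
    an explicitly supplied map naming a missing column is a configuration
    error.  Rows violating record invariants are rejected with a logged
    per-row diagnostic; unparseable numerics and duplicate rsids raise.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    header = list(df.columns)

    if column_map is None:
        mapping = {f: c for f, c in DEFAULT_COLUMN_MAP.items() if c in header}
    else:
        mapping = dict(column_map)
        unknown = set(mapping) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigurationError(f"unknown fields in column map: {sorted(unknown)}")
        missing = [c for c in mapping.values() if c not in header]
        if missing:
            raise ConfigurationError(f"mapped columns missing from header: {missing}")
    for field in _REQUIRED_FIELDS:
        if field not in mapping:
            raise ConfigurationError(f"column map must provide {field!r}")
    if "zscore" not in mapping and not ("beta" in mapping and "se" in mapping):
        raise ConfigurationError("column map must provide beta+se or zscore")

    records: list[VariantAssociation] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        values = dict(zip(header, row))
        kwargs: dict = {}
        for field, col in mapping.items():
            raw = str(values[col])
            if field in ("rsid", "chrom", "effect_allele", "other_allele"):
                text = raw.strip()
                kwargs[field] = text.upper() if field.endswith("allele") else text
                if kwargs[field] == "":
                    kwargs[field] = None
            elif field in _FLOAT_FIELDS:
                kwargs[field] = _parse_number(raw, field, line, as_int=False)
            elif field in _INT_FIELDS:
                kwargs[field] = _parse_number(raw, field, line, as_int=True)
        rsid = kwargs.get("rsid")
        if not rsid:
            raise RowParseError(f"line {line}: missing rsid")
        if rsid in seen:
            raise DuplicateVariantError(f"duplicate rsid {rsid!r} at line {line}")
        seen.add(rsid)
        try:
            records.append(VariantAssociation(**kwargs))
        except SummaryDataError as exc:
            logger.warning("rejected line %d: %s", line, exc)
    return records


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return _COMPLEMENT[ea], _COMPLEMENT[oa]


def harmonize(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_policy: str = "keep_if_eaf_informative",
    eaf_threshold: float = PALINDROME_EAF_THRESHOLD,
) -> HarmonizedInstrument | None:
    """Align an outcome record to the exposure record's effect allele.

    Returns the harmonized instrument, or ``None`` when the variant is
    dropped under the palindromic-variant policy.  A swap of the outcome's
    alleles negates its beta and complements its frequency; non-palindromic
    strand flips (e.g. G/T reported as C/A) are resolved by complementing
    before the match/swap test.
    """
    if exposure.rsid != outcome.rsid:
        raise HarmonizationError(
            f"cannot harmonize different variants {exposure.rsid!r} and {outcome.rsid!r}"
        )
    if palindrome_policy not in ("drop", "keep_if_eaf_informative", "keep"):
        raise ConfigurationError(f"unknown palindrome policy {palindrome_policy!r}")
    for rec, role in ((exposure, "exposure"), (outcome, "outcome")):
        if rec.beta is None or rec.se is None:
            raise HarmonizationError(
                f"{rec.rsid}: {role} record lacks beta/se (convert Z-scores first)"
            )

    e_pair = (exposure.effect_allele, exposure.other_allele)
    o_pair = (outcome.effect_allele, outcome.other_allele)
    palindromic = exposure.is_palindromic

    if palindromic:
        if palindrome_policy == "drop":
            return None
        if palindrome_policy == "keep_if_eaf_informative":
            freqs = (exposure.eaf, outcome.eaf)
            if any(f is None for f in freqs) or min(exposure.eaf, 1 - exposure.eaf) > eaf_threshold:
                return None
            # frequency decides the strand: align the outcome's eaf to the
            # exposure's side of 0.5
            flip = abs(exposure.eaf - outcome.eaf) > abs(exposure.eaf - (1 - outcome.eaf))
        else:  # keep: trust the reported strands, textual match/swap
            if o_pair == e_pair:
                flip = False
            elif o_pair == (e_pair[1], e_pair[0]):
                flip = True
            else:
                raise HarmonizationError(f"{exposure.rsid}: incompatible allele pairs {e_pair}/{o_pair}")
    else:
        if o_pair == e_pair:
            flip = False
        elif o_pair == (e_pair[1], e_pair[0]):
            flip = True
        else:
            comp = _complement_pair(*o_pair)
            if comp == e_pair:
                flip = False
            elif comp == (e_pair[1], e_pair[0]):
                flip = True
            else:
                raise HarmonizationError(
                    f"{exposure.rsid}: incompatible allele pairs {e_pair}/{o_pair}"
                )

    beta_out = -outcome.beta if flip else outcome.beta
    eaf_out = None
    if outcome.eaf is not None:
        eaf_out = 1.0 - outcome.eaf if flip else outcome.eaf
    return HarmonizedInstrument(
        rsid=exposure.rsid,
        effect_allele=exposure.effect_allele,
        beta_exp=exposure.beta,
        se_exp=exposure.se,
        beta_out=beta_out,
        se_out=outcome.se,
        eaf_exp=exposure.eaf,
        eaf_out=eaf_out,
        flipped=flip,
        palindromic=palindromic,
    )


def _prune_sort_key(v: VariantAssociation) -> tuple:
    pval = v.pval if v.pval is not None else 1.0
    return (pval, -abs(v.z_equivalent), v.rsid)


def ld_prune(
    variants: Sequence[VariantAssociation],
    ld: LdMatrix,
    r2_threshold: float = 0.05,
) -> list[VariantAssociation]:
    """Greedy LD pruning: keep the most significant variant of each LD cluster.

    Candidates are visited in ascending p-value order (ties broken by
    descending |Z|, then rsid); a variant is retained iff its r2 with every
    already-retained variant falls below ``r2_threshold``.  The result is
    therefore independent of input row order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ConfigurationError(f"r2 threshold {r2_threshold} outside (0, 1]")
    for v in variants:
        if v.rsid not in ld:
            raise SummaryDataError(f"variant {v.rsid!r} absent from LD matrix")
    retained: list[VariantAssociation] = []
    for cand in sorted(variants, key=_prune_sort_key):
        if all(ld.lookup(cand.rsid, kept.rsid) < r2_threshold for kept in retained):
            retained.append(cand)
    return retained


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the confounder screen for one variant."""

    rsid: str
    passed: bool
    offending: tuple[tuple[str, float], ...] = ()


def read_association_table(source) -> pd.DataFrame:
    """Read a local trait-association table with columns rsid, trait, pval."""
    df = pd.read_csv(source, sep=None, engine="python")
    missing = {"rsid", "trait", "pval"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"association table missing columns {sorted(missing)}")
    return df


def screen_confounders(
    variants: Sequence[VariantAssociation],
    assoc_table: pd.DataFrame | Iterable[tuple[str, str, float]],
    risk_factor_count: int = 7,
) -> dict[str, ScreenResult]:
    """Flag instruments associated with known risk factors of the outcome.

    The Bonferroni-style threshold is 0.05 / ``risk_factor_count``; a variant
    fails iff the table records any trait association below it.  An empty
    table passes every variant.
    """
    if risk_factor_count < 1:
        raise ConfigurationError("risk_factor_count must be a positive integer")
    threshold = 0.05 / risk_factor_count
    if isinstance(assoc_table, pd.DataFrame):
        rows = list(assoc_table[["rsid", "trait", "pval"]].itertuples(index=False))
    else:
        rows = list(assoc_table)
    results: dict[str, ScreenResult] = {}
    for v in variants:
        hits = tuple(
            (str(trait), float(p)) for rsid, trait, p in rows
            if str(rsid) == v.rsid and float(p) < threshold
        )
        results[v.rsid] = ScreenResult(rsid=v.rsid, passed=not hits, offending=hits)
    return results
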