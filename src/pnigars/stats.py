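"""Diagnostic-accuracy metrics and the 2x2 hypothesis-testing toolkit.

Sensitivity, specificity and agreement rate are computed from screening
contingency tables with Wald 95% confidence intervals. The testing toolkit
mirrors common biostatistical practice for fourfold tables: Pearson's
chi-square for large samples, the Yates continuity correction when the
smallest expected cell count falls below 5, Fisher's exact probability when
the sample is under 40 or an expected count falls below 1, and McNemar's
test for paired screening results.

Percent rendering follows a two-stage convention (proportion to four decimal
places, then percent to one decimal, both half-up) so that tabulated values
match the one-decimal percentages produced by mainstream statistics
packages even at double-rounding boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .records import DensityType, ScreenLabel

__all__ = [
    "ContingencyTable",
    "RateEstimate",
    "DiagnosticSummary",
    "FourfoldTable",
    "TestResult",
    "wald_ci",
    "sensitivity",
    "specificity",
    "agreement_rate",
    "diagnostic_summary",
    "pearson_chi2",
    "yates_chi2",
    "fisher_exact",
    "mcnemar",
    "select_test",
    "run_selected_test",
    "confusion",
    "compare_systems",
    "render_percent",
    "ComparisonResult",
    "StratumComparison",
]

_SCREEN_COLUMNS = {"pnigars": "pni_screen", "lungrads": "lungrads_screen"}
STRATA = ("SN", "PSN", "GGN", "all")


@dataclass(frozen=True)
class ContingencyTable:
    """Screening 2x2: test result (rows implicit) against pathology truth."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_malignant(self) -> int:
        return self.tp + self.fn

    @property
    def n_benign(self) -> int:
        return self.fp + self.tn

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.fn, self.fp, self.tn)


def render_percent(value: Union[float, Fraction]) -> str:
    """One-decimal percent string (two-stage half-up rounding).

    Exact 0 and 100 render without the decimal, matching tabular convention.
    """
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(float(value)))
    prop4 = dec.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP)
    pct = (prop4 * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    if pct == pct.to_integral_value() and pct in (Decimal(0), Decimal(100)):
        return str(int(pct))
    return str(pct)


@dataclass(frozen=True)
class RateEstimate:
    """A proportion with its 95% confidence interval and exact source counts."""

    point: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    def percent(self) -> str:
        return render_percent(self.fraction)

    def percent_ci(self) -> Tuple[str, str]:
        return (render_percent(self.ci_low), render_percent(self.ci_high))

    def formatted(self) -> str:
        lo, hi = self.percent_ci()
        if lo == hi:
            return f"{self.percent()}({lo})"
        return f"{self.percent()}({lo}-{hi})"


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity, specificity and agreement rate of one system on one stratum."""

    sensitivity: RateEstimate
    specificity: RateEstimate
    agreement: RateEstimate


def wald_ci(p: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Normal-approximation (Wald) confidence interval, clipped to [0, 1].

    Degenerate at p of 0 or 1, where the interval collapses to the point —
    the convention used when tabulating rates with empty complementary cells.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    z = sps.norm.ppf(0.5 * (1.0 + level))
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def _rate(numerator: int, denominator: int, level: float = 0.95) -> RateEstimate:
    if denominator <= 0:
        raise ValueError("rate denominator must be positive")
    p = numerator / denominator
    lo, hi = wald_ci(p, denominator, level)
    return RateEstimate(p, lo, hi, numerator, denominator)


def sensitivity(ct: ContingencyTable, level: float = 0.95) -> RateEstimate:
    """TP / (TP + FN) with Wald CI. Requires at least one malignant case."""
    if ct.n_malignant == 0:
        raise ValueError("sensitivity undefined: no malignant cases in stratum")
    return _rate(ct.tp, ct.n_malignant, level)


def specificity(ct: ContingencyTable, level: float = 0.95) -> RateEstimate:
    """TN / (TN + FP) with Wald CI. Requires at least one benign case."""
    if ct.n_benign == 0:
        raise ValueError("specificity undefined: no benign cases in stratum")
    return _rate(ct.tn, ct.n_benign, level)


def agreement_rate(ct: ContingencyTable, level: float = 0.95) -> RateEstimate:
    """(TP + TN) / total with Wald CI."""
    return _rate(ct.tp + ct.tn, ct.total, level)


def diagnostic_summary(ct: ContingencyTable, level: float = 0.95) -> DiagnosticSummary:
    return DiagnosticSummary(
        sensitivity=sensitivity(ct, level),
        specificity=specificity(ct, level),
        agreement=agreement_rate(ct, level),
    )


@dataclass(frozen=True)
class FourfoldTable:
    """Generic 2x2 table of counts (rows = groups, columns = outcomes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("empty fourfold table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self) -> Tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> Tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    def observed(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        """Theoretical frequencies T under independence: row x column / total."""
        r = np.array(self.row_margins, dtype=float)
        c = np.array(self.col_margins, dtype=float)
        return np.outer(r, c) / self.total

    @property
    def min_expected(self) -> float:
        return float(self.expected().min())


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test (Fisher carries no statistic)."""

    method: str
    statistic: Optional[float]
    p_value: float


def pearson_chi2(t: FourfoldTable) -> TestResult:
    """Pearson chi-square on a 2x2 table (1 df, no continuity correction)."""
    if 0 in t.row_margins or 0 in t.col_margins:
        raise ValueError("Pearson chi-square requires all margins > 0")
    stat, p, _dof, _exp = sps.chi2_contingency(t.observed(), correction=False)
    return TestResult("pearson", float(stat), float(p))


def yates_chi2(t: FourfoldTable) -> TestResult:
    """Yates continuity-corrected chi-square.

    Each term uses (|observed - expected| - 0.5)^2 / expected with the
    corrected deviation clamped at zero, so tables whose cells all sit
    within half a count of expectation score exactly 0.
    """
    if 0 in t.row_margins or 0 in t.col_margins:
        raise ValueError("Yates chi-square requires all margins > 0")
    obs = t.observed()
    exp = t.expected()
    dev = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float((dev**2 / exp).sum())
    return TestResult("yates", stat, float(sps.chi2.sf(stat, 1)))


def fisher_exact(t: FourfoldTable) -> TestResult:
    """Two-sided Fisher exact probability (sum of tables no more probable)."""
    _odds, p = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return TestResult("fisher", None, float(p))


def mcnemar(
    discordant_b: int,
    discordant_c: int,
    variant: str = "auto",
    exact_threshold: int = 25,
) -> TestResult:
    """McNemar test on paired discordant counts.

    ``variant='auto'`` uses the exact two-sided binomial when
    b + c < ``exact_threshold`` and the uncorrected chi-square
    (b - c)^2 / (b + c) otherwise; ``'exact'`` and ``'chi2'`` force a choice.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        return TestResult("mcnemar", 0.0, 1.0)
    if variant == "auto":
        variant = "exact" if (b + c) < exact_threshold else "chi2"
    table = np.array([[0, b], [c, 0]])
    if variant == "exact":
        res = _sm_mcnemar(table, exact=True)
        return TestResult("mcnemar", None, float(res.pvalue))
    if variant == "chi2":
        res = _sm_mcnemar(table, exact=False, correction=False)
        return TestResult("mcnemar", float(res.statistic), float(res.pvalue))
    raise ValueError(f"unknown McNemar variant: {variant!r}")


def select_test(t: FourfoldTable) -> str:
    """Select pearson / yates / fisher from sample size and expected counts.

    Fisher when n < 40 or the smallest theoretical frequency T < 1; the
    Yates correction when n >= 40 and T < 5; Pearson otherwise.
    """
    if t.total < 40 or t.min_expected < 1.0:
        return "fisher"
    if t.min_expected < 5.0:
        return "yates"
    return "pearson"


def run_selected_test(t: FourfoldTable) -> TestResult:
    """Apply the test chosen by :func:`select_test`."""
    method = select_test(t)
    if method == "fisher":
        return fisher_exact(t)
    if method == "yates":
        return yates_chi2(t)
    return pearson_chi2(t)


def _stratum_frame(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        sub = df
    else:
        DensityType(stratum)  # validate token
        sub = df[df["density_type"] == stratum]
    if len(sub) == 0:
        raise ValueError(f"empty stratum: {stratum!r}")
    return sub


def confusion(df: pd.DataFrame, system: str, stratum: str = "all") -> ContingencyTable:
    """Tabulate one system's screen labels against pathology on one stratum.

    ``df`` is a classified cohort frame with ``density_type``, ``pathology``
    and the system's ``*_screen`` column.
    """
    if system not in _SCREEN_COLUMNS:
        raise ValueError(f"unknown system: {system!r}")
    col = _SCREEN_COLUMNS[system]
    if col not in df.columns:
        raise ValueError(f"missing column {col!r}; classify the cohort first")
    if df["pathology"].isna().any():
        raise ValueError("every record needs a pathology truth for tabulation")
    sub = _stratum_frame(df, stratum)
    malignant = sub["pathology"] == "malignant"
    positive = sub[col] == ScreenLabel.POSITIVE.value
    return ContingencyTable(
        tp=int((malignant & positive).sum()),
        fn=int((malignant & ~positive).sum()),
        fp=int((~malignant & positive).sum()),
        tn=int((~malignant & ~positive).sum()),
    )


@dataclass(frozen=True)
class StratumComparison:
    """Both systems' tables, summaries and paired tests on one stratum."""

    stratum: str
    tables: Dict[str, ContingencyTable]
    summaries: Dict[str, DiagnosticSummary]
    sensitivity_test: TestResult
    specificity_test: TestResult
    agreement_test: TestResult


@dataclass(frozen=True)
class ComparisonResult:
    """Results object of :func:`compare_systems`.

    ``to_frame()`` gives the tabular report (one row per stratum x system,
    counts plus formatted rates); ``summary()`` renders it as text together
    with the paired-test results.
    """

    strata: Tuple[StratumComparison, ...]

    def __getitem__(self, stratum: str) -> StratumComparison:
        for s in self.strata:
            if s.stratum == stratum:
                return s
        raise KeyError(stratum)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            for system in ("lungrads", "pnigars"):
                ct = s.tables[system]
                summ = s.summaries[system]
                rows.append(
                    {
                        "stratum": s.stratum,
                        "system": system,
                        "tp": ct.tp,
                        "fn": ct.fn,
                        "fp": ct.fp,
                        "tn": ct.tn,
                        "sensitivity": summ.sensitivity.formatted(),
                        "specificity": summ.specificity.formatted(),
                        "agreement_rate": summ.agreement.formatted(),
                    }
                )
        return pd.DataFrame(rows)

    def tests_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.strata:
            for label, tr in (
                ("sensitivity", s.sensitivity_test),
                ("specificity", s.specificity_test),
                ("agreement_rate", s.agreement_test),
            ):
                rows.append(
                    {
                        "stratum": s.stratum,
                        "indicator": label,
                        "method": tr.method,
                        "statistic": tr.statistic,
                        "p_value": tr.p_value,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Diagnostic accuracy by stratum and system", ""]
        lines.append(self.to_frame().to_string(index=False))
        lines.append("")
        lines.append("Paired (McNemar) and agreement comparisons, Lung-RADS vs PNI-GARS")
        lines.append("")
        tests = self.tests_frame().copy()
        tests["statistic"] = tests["statistic"].map(
            lambda v: "-" if v is None or (isinstance(v, float) and math.isnan(v)) else f"{v:.2f}"
        )
        tests["p_value"] = tests["p_value"].map(lambda p: f"{p:.4g}")
        lines.append(tests.to_string(index=False))
        return "\n".join(lines)


def compare_systems(df: pd.DataFrame, mcnemar_variant: str = "auto") -> ComparisonResult:
    """Side-by-side diagnostic comparison of both systems on a classified cohort.

    Per stratum (SN, PSN, GGN, all): each system's contingency table and
    summary; McNemar tests on sensitivity (malignant pairs) and specificity
    (benign pairs) built from the per-nodule cross-classification; and a
    sample-size-selected test (Pearson / Yates / Fisher) on the agreement
    indicator.
    """
    for col in ("pni_screen", "lungrads_screen", "pathology", "density_type"):
        if col not in df.columns:
            raise ValueError(f"classified cohort is missing column {col!r}")

    results = []
    for stratum in STRATA:
        sub = _stratum_frame(df, stratum)
        tables = {sys: confusion(sub, sys, "all") for sys in ("lungrads", "pnigars")}
        summaries = {sys: diagnostic_summary(tables[sys]) for sys in tables}

        lung_pos = sub["lungrads_screen"] == ScreenLabel.POSITIVE.value
        pni_pos = sub["pni_screen"] == ScreenLabel.POSITIVE.value
        malignant = sub["pathology"] == "malignant"

        se_b = int((malignant & lung_pos & ~pni_pos).sum())
        se_c = int((malignant & ~lung_pos & pni_pos).sum())
        sp_b = int((~malignant & lung_pos & ~pni_pos).sum())
        sp_c = int((~malignant & ~lung_pos & pni_pos).sum())

        lung_agree = int((lung_pos == malignant).sum())
        pni_agree = int((pni_pos == malignant).sum())
        n = len(sub)
        agreement_table = FourfoldTable(lung_agree, n - lung_agree, pni_agree, n - pni_agree)

        results.append(
            StratumComparison(
                stratum=stratum,
                tables=tables,
                summaries=summaries,
                sensitivity_test=mcnemar(se_b, se_c, variant=mcnemar_variant),
                specificity_test=mcnemar(sp_b, sp_c, variant=mcnemar_variant),
                agreement_test=run_selected_test(agreement_table),
            )
        )
    return ComparisonResult(tuple(results))
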