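"""Validation of a composite mortality variable against a gold standard.

The composite and the gold standard each give a binary vital status per
patient, crossed into the 2x2 contingency table

    A  true positives   (dead in both)
    B  false positives  (dead in composite only)
    C  false negatives  (dead in gold only)
    D  true negatives   (dead in neither)

from which sensitivity A/(A+C), specificity D/(B+D), PPV A/(A+B) and
NPV D/(C+D) follow, each with a Wald 95% confidence interval.  Date
agreement is the fraction of composite death dates that match the gold
date within a window (0, ±15, ±30 days); composite deaths absent from
the gold standard count as disagreements.

:func:`reconstruct_contingency` inverts the published-report direction:
given three rounded metrics and the cohort size, an integer search
recovers the 2x2 table (and hence the unpublished fourth metric).  It
serves as an independent oracle whenever only rounded summary metrics
of a validation are available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContingencyTable",
    "Proportion",
    "ValidationReport",
    "PracticeSummary",
    "CoverageError",
    "contingency",
    "metrics",
    "date_agreement",
    "per_practice_sensitivity",
    "reconstruct_contingency",
    "validation_report",
    "report_table",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class CoverageError(ValueError):
    """Composite and gold tables do not cover the same cohort."""


@dataclass(frozen=True)
class ContingencyTable:
    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class Proportion:
    """A proportion with its Wald 95% CI; NaN throughout if undefined."""

    point: float
    lower: float
    upper: float
    denominator: int

    @classmethod
    def wald(cls, numerator: int, denominator: int) -> "Proportion":
        if denominator == 0:
            return cls(math.nan, math.nan, math.nan, 0)
        p = numerator / denominator
        half = Z95 * math.sqrt(p * (1.0 - p) / denominator)
        return cls(p, max(0.0, p - half), min(1.0, p + half), denominator)


@dataclass
class ValidationReport:
    """One benchmark row: all validation metrics for one dataset version."""

    label: str
    n: int
    table: ContingencyTable
    sensitivity: Proportion
    specificity: Proportion
    ppv: Proportion
    npv: Proportion
    date_agreement_exact: Proportion
    date_agreement_15: Proportion
    date_agreement_30: Proportion


@dataclass
class PracticeSummary:
    """Per-practice sensitivities plus the standard boxplot statistics."""

    sensitivities: pd.Series  # index practice_id
    median: float = math.nan
    q1: float = math.nan
    q3: float = math.nan
    whisker_low: float = math.nan
    whisker_high: float = math.nan
    outliers: list = field(default_factory=list)


def _death_flags(composite: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    comp_ids = set(composite["patient_id"])
    call_ids = set(calls["patient_id"])
    if comp_ids != call_ids:
        raise CoverageError(
            f"composite covers {len(comp_ids)} patients, gold calls cover "
            f"{len(call_ids)}; {len(comp_ids ^ call_ids)} differ")
    df = composite[["patient_id", "death_date"]].merge(
        calls[["patient_id", "status", "gold_death_date"]], on="patient_id")
    df["comp_dead"] = pd.to_datetime(df["death_date"]).notna()
    df["gold_dead"] = df["status"].eq("dead")
    return df


def contingency(composite: pd.DataFrame, calls: pd.DataFrame,
                ) -> ContingencyTable:
    """Cross composite death-date presence against gold vital status."""
    df = _death_flags(composite, calls)
    return ContingencyTable(
        A=int((df["comp_dead"] & df["gold_dead"]).sum()),
        B=int((df["comp_dead"] & ~df["gold_dead"]).sum()),
        C=int((~df["comp_dead"] & df["gold_dead"]).sum()),
        D=int((~df["comp_dead"] & ~df["gold_dead"]).sum()),
    )


def metrics(t: ContingencyTable) -> dict:
    """The four diagnostic metrics of a 2x2 table, as :class:`Proportion` s.

    A metric whose denominator is zero is reported as NaN (undefined),
    never as 0.
    """
    return {
        "sensitivity": Proportion.wald(t.A, t.A + t.C),
        "specificity": Proportion.wald(t.D, t.B + t.D),
        "ppv": Proportion.wald(t.A, t.A + t.B),
        "npv": Proportion.wald(t.D, t.C + t.D),
    }


def date_agreement(composite: pd.DataFrame, calls: pd.DataFrame,
                   window_days: int = 0) -> Proportion:
    """Fraction of composite death dates agreeing with the gold date.

    Denominator: patients with a composite death date (A+B).  Numerator:
    those whose gold death date exists and differs by at most
    ``window_days`` (inclusive).  Composite deaths with no gold death
    are disagreements by construction.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    df = _death_flags(composite, calls)
    df = df[df["comp_dead"]]
    delta = (pd.to_datetime(df["death_date"])
             - pd.to_datetime(df["gold_death_date"])).dt.days.abs()
    agree = df["gold_dead"] & (delta <= window_days)
    return Proportion.wald(int(agree.sum()), len(df))


def per_practice_sensitivity(composite: pd.DataFrame, calls: pd.DataFrame,
                             cohort: pd.DataFrame,
                             min_patients: int = 100) -> PracticeSummary:
    """Sensitivity stratified by practice, with boxplot statistics.

    Practices with fewer than ``min_patients`` cohort patients are
    excluded: tiny practices have so few deaths that their sensitivity
    is dominated by sampling noise.  Hinges are type-7 (linear
    interpolation) quartiles; whiskers reach the most extreme values
    within 1.5 IQR of the hinges, points beyond are outliers.
    """
    df = _death_flags(composite, calls).merge(
        cohort[["patient_id", "practice_id"]], on="patient_id")
    sizes = df.groupby("practice_id").size()
    keep = sizes[sizes >= min_patients].index
    df = df[df["practice_id"].isin(keep) & df["gold_dead"]]
    sens = df.groupby("practice_id")["comp_dead"].mean()
    if sens.empty:
        warnings.warn("no practice meets the size threshold; empty summary",
                      stacklevel=2)
        return PracticeSummary(sensitivities=sens)
    q1, med, q3 = np.percentile(sens, [25, 50, 75])
    iqr = q3 - q1
    inside = sens[(sens >= q1 - 1.5 * iqr) & (sens <= q3 + 1.5 * iqr)]
    outliers = sens[(sens < q1 - 1.5 * iqr) | (sens > q3 + 1.5 * iqr)]
    return PracticeSummary(
        sensitivities=sens, median=float(med), q1=float(q1), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=list(outliers.items()))


def _table_error(A: int, B: int, C: int, D: int, specificity, ppv, npv,
                 sensitivity) -> float:
    """Summed |recomputed - target| in pp over the constrained metrics.

    A target of NaN leaves that metric unconstrained; a constrained
    metric whose denominator is zero scores infinite (the table cannot
    reproduce a printed value for an undefined quantity).
    """
    err = 0.0
    for target, num, den in ((specificity, D, B + D), (ppv, A, A + B),
                             (npv, D, C + D), (sensitivity, A, A + C)):
        if math.isnan(target):
            continue
        if den == 0:
            return math.inf
        err += abs(100.0 * num / den - target)
    return err


def reconstruct_contingency(specificity: float, ppv: float, npv: float,
                            n: int, sensitivity: float = math.nan,
                            search_halfwidth: int = 4,
                            max_error_pp: float = 0.5) -> ContingencyTable:
    """Recover the 2x2 table behind rounded printed metrics.

    Inputs are percentages as printed (e.g. 97.06); pass NaN to leave a
    metric unconstrained.  Candidate integer tables with A+B+C+D = n
    are scored by the summed absolute deviation (percentage points) of
    their recomputed metrics from the constrained inputs; the minimiser
    is returned, ties broken by the smallest false-positive count B,
    then the smallest false-negative count C, then the largest A.  If
    no table comes within ``max_error_pp`` total deviation the inputs
    are declared infeasible.

    For small n (≤ 120) every table is enumerated.  For large n the
    search walks the true-negative count D and visits only the B and C
    counts within ``search_halfwidth`` of the values the printed
    specificity and NPV imply, which requires those two metrics to be
    constrained.
    """
    for name, v in (("specificity", specificity), ("ppv", ppv),
                    ("npv", npv), ("sensitivity", sensitivity)):
        if not math.isnan(v) and not 0.0 < v <= 100.0:
            raise ValueError(f"{name} must be in (0, 100] or NaN")

    def candidates():
        if n <= 120:
            for D in range(n + 1):
                for B in range(n - D + 1):
                    for C in range(n - D - B + 1):
                        yield n - B - C - D, B, C, D
            return
        if math.isnan(specificity) or math.isnan(npv):
            raise ValueError(
                "specificity and npv must be constrained for large n")
        s, q = specificity / 100.0, npv / 100.0
        w = search_halfwidth
        for D in range(n + 1):
            b_center = round(D * (1.0 - s) / s)
            c_center = round(D * (1.0 - q) / q)
            for B in range(max(0, b_center - w), b_center + w + 1):
                for C in range(max(0, c_center - w), c_center + w + 1):
                    A = n - B - C - D
                    if A >= 0:
                        yield A, B, C, D

    best_key, best_table = None, None
    for A, B, C, D in candidates():
        err = _table_error(A, B, C, D, specificity, ppv, npv, sensitivity)
        key = (err, B, C, -A)
        if best_key is None or key < best_key:
            best_key, best_table = key, (A, B, C, D)
    if best_table is None or best_key[0] > max_error_pp:
        raise ValueError(
            f"no contingency table with n={n} reproduces "
            f"({specificity}, {ppv}, {npv}) within {max_error_pp} pp")
    return ContingencyTable(*best_table)


def validation_report(label: str, composite: pd.DataFrame,
                      calls: pd.DataFrame) -> ValidationReport:
    """All validation metrics for one dataset version."""
    t = contingency(composite, calls)
    m = metrics(t)
    return ValidationReport(
        label=label, n=t.n, table=t,
        sensitivity=m["sensitivity"], specificity=m["specificity"],
        ppv=m["ppv"], npv=m["npv"],
        date_agreement_exact=date_agreement(composite, calls, 0),
        date_agreement_15=date_agreement(composite, calls, 15),
        date_agreement_30=date_agreement(composite, calls, 30),
    )


def report_table(reports) -> pd.DataFrame:
    """Stack validation reports into a benchmark table (one version per row).

    Column order follows the standard report layout: sensitivity,
    specificity, PPV, NPV, then exact / ±15-day / ±30-day date
    agreement, with Wald 95% CI bounds alongside each proportion.
    """
    rows = []
    for r in reports:
        row = {"version": r.label, "n": r.n,
               "A": r.table.A, "B": r.table.B, "C": r.table.C, "D": r.table.D}
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "date_agreement_exact", "date_agreement_15",
                     "date_agreement_30"):
            prop: Proportion = getattr(r, name)
            row[name] = prop.point
            row[f"{name}_lo"] = prop.lower
            row[f"{name}_hi"] = prop.upper
        rows.append(row)
    return pd.DataFrame(rows)
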