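"""Amalgamation of linked death assertions into a composite mortality variable.

One patient may carry death dates from several sources (structured EHR,
commercial CDD1, public SSDI).  The resolution rule:

* if two or more sources assert the same date, that date is used
  (``two_or_more_agree``);
* if the dates conflict, the hierarchy SSDI > CDD1 > EHR decides,
  SSDI having proven most reliable against the gold standard;
* a single assertion stands on its own (``single_source``).

Composite dates earlier than the patient's advanced-diagnosis date are
known to be wrong and are removed (``removed_implausible``).  The
chart-abstraction source (ABS) never competes in conflict resolution:
it only fills residual gaps for patients with no composite date and no
recent activity (``abs_fill``).

:func:`build_dataset_versions` emits the five benchmark versions in
development order: EHR only, SSDI only, EHR+CDD1, EHR+CDD1+SSDI, and
the final EHR+CDD1+SSDI+ABS composite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HIERARCHY",
    "VERSION_LABELS",
    "DatasetVersion",
    "resolve_death_date",
    "resolve_assertions",
    "plausibility_filter",
    "abs_fill",
    "build_dataset_versions",
]

HIERARCHY = ("SSDI", "CDD1", "EHR")

VERSION_LABELS = ("EHR_only", "SSDI_only", "EHR_CDD1", "EHR_CDD1_SSDI",
                  "EHR_CDD1_SSDI_ABS")

_VERSION_SOURCES = {
    "EHR_only": ("EHR",),
    "SSDI_only": ("SSDI",),
    "EHR_CDD1": ("EHR", "CDD1"),
    "EHR_CDD1_SSDI": ("EHR", "CDD1", "SSDI"),
    "EHR_CDD1_SSDI_ABS": ("EHR", "CDD1", "SSDI"),  # ABS enters via gap fill
}


@dataclass
class DatasetVersion:
    label: str
    composite: pd.DataFrame  # patient_id, death_date, contributing_sources, resolution


def resolve_death_date(assertions: dict,
                       hierarchy=HIERARCHY) -> tuple:
    """Resolve one patient's assertions ``{source: date}`` to a single date.

    Returns ``(date or None, resolution)``.  Agreement of any two
    sources outranks the hierarchy; among tied agreeing dates (possible
    only with more than three sources) the one backed by the
    highest-ranked source wins.
    """
    dates = {s: pd.Timestamp(d) for s, d in assertions.items()
             if d is not None and not pd.isna(d)}
    if not dates:
        return None, None
    if len(dates) == 1:
        return next(iter(dates.values())), "single_source"
    counts = pd.Series(list(dates.values())).value_counts()
    agreeing = counts[counts >= 2]
    if len(agreeing):
        if len(agreeing) == 1:
            return agreeing.index[0], "two_or_more_agree"
        # defensive tie-break for >3 sources: hierarchy decides
        for src in hierarchy:
            if src in dates and dates[src] in agreeing.index:
                return dates[src], "two_or_more_agree"
        return sorted(agreeing.index)[0], "two_or_more_agree"
    for src in hierarchy:
        if src in dates:
            return dates[src], f"hierarchy_{src}"
    # sources outside the hierarchy only: earliest date, deterministic
    return sorted(dates.values())[0], "single_source"


def resolve_assertions(cohort: pd.DataFrame, assertions: pd.DataFrame,
                       hierarchy=HIERARCHY) -> pd.DataFrame:
    """Resolve a linked assertion table into a full-cohort composite.

    ``assertions`` columns: ``patient_id, source_id, death_date``.
    Duplicate assertions from the same source keep the first occurrence.
    The output has one row per cohort patient (NaT date when no source
    asserted a death), columns ``patient_id, death_date,
    contributing_sources, resolution``.
    """
    a = assertions.copy()
    a["death_date"] = pd.to_datetime(a["death_date"])
    a = a.drop_duplicates(["patient_id", "source_id"], keep="first")

    rows = {}
    for pid, grp in a.groupby("patient_id", sort=False):
        asserted = dict(zip(grp["source_id"], grp["death_date"]))
        date, resolution = resolve_death_date(asserted, hierarchy)
        if date is None:
            continue
        contributing = ",".join(
            s for s in ("SSDI", "CDD1", "EHR", "ABS")
            if s in asserted and asserted[s] == date)
        rows[pid] = (date, contributing, resolution)

    out = cohort[["patient_id"]].copy()
    out["death_date"] = out["patient_id"].map(
        lambda p: rows.get(p, (pd.NaT,))[0])
    out["death_date"] = pd.to_datetime(out["death_date"])
    out["contributing_sources"] = out["patient_id"].map(
        lambda p: rows[p][1] if p in rows else "")
    out["resolution"] = out["patient_id"].map(
        lambda p: rows[p][2] if p in rows else pd.NA)
    return out


def plausibility_filter(composite: pd.DataFrame,
                        cohort: pd.DataFrame) -> pd.DataFrame:
    """Remove composite death dates known to be incorrect.

    A death date strictly before the patient's advanced-diagnosis date
    is cleared and flagged ``removed_implausible``; dates on or after
    the diagnosis date pass unchanged.
    """
    out = composite.merge(
        cohort[["patient_id", "advanced_diagnosis_date"]], on="patient_id")
    bad = out["death_date"].notna() & (
        out["death_date"] < pd.to_datetime(out["advanced_diagnosis_date"]))
    out.loc[bad, "death_date"] = pd.NaT
    out.loc[bad, "contributing_sources"] = ""
    out.loc[bad, "resolution"] = "removed_implausible"
    return out.drop(columns="advanced_diagnosis_date")


def abs_fill(composite: pd.DataFrame, abs_assertions: pd.DataFrame,
             cohort: pd.DataFrame, recency_days: int = 60,
             reference_date=None) -> pd.DataFrame:
    """Fill residual gaps from the chart-abstraction source.

    Only patients with no composite death date whose last activity is
    more than ``recency_days`` before ``reference_date`` (default: the
    latest activity in the cohort, i.e. the study cutoff) are eligible;
    recently active patients are presumed alive and never filled.
    Patients who already carry a composite date ignore ABS entirely.
    """
    if reference_date is None:
        reference_date = pd.Timestamp(cohort["last_activity_date"].max())
    reference_date = pd.Timestamp(reference_date)

    abs_dates = (abs_assertions.assign(
        death_date=lambda d: pd.to_datetime(d["death_date"]))
        .drop_duplicates("patient_id", keep="first")
        .set_index("patient_id")["death_date"])

    out = composite.merge(
        cohort[["patient_id", "last_activity_date"]], on="patient_id")
    inactive = pd.to_datetime(out["last_activity_date"]) < (
        reference_date - pd.Timedelta(days=recency_days))
    gap = out["death_date"].isna() & inactive
    fill = out["patient_id"].map(abs_dates)
    use = gap & fill.notna()
    out.loc[use, "death_date"] = fill[use]
    out.loc[use, "contributing_sources"] = "ABS"
    out.loc[use, "resolution"] = "abs_fill"
    return out.drop(columns="last_activity_date")


def build_dataset_versions(cohort: pd.DataFrame, linked_sources: dict,
                           recency_days: int = 60,
                           reference_date=None) -> list[DatasetVersion]:
    """Build the five benchmark composites in development order.

    ``linked_sources`` maps source_id to its linked assertion table
    (``patient_id, source_id, death_date``).  Each version uses exactly
    its labelled source subset, resolved and plausibility-filtered; the
    final version additionally gap-fills from ABS (filled dates are
    themselves subject to the plausibility rule).
    """
    empty = pd.DataFrame(columns=["patient_id", "source_id", "death_date"])
    versions = []
    for label in VERSION_LABELS:
        subset = [linked_sources.get(s, empty) for s in _VERSION_SOURCES[label]]
        merged = pd.concat(subset, ignore_index=True) if subset else empty
        comp = resolve_assertions(cohort, merged)
        comp = plausibility_filter(comp, cohort)
        if label == "EHR_CDD1_SSDI_ABS":
            comp = abs_fill(comp, linked_sources.get("ABS", empty), cohort,
                            recency_days=recency_days,
                            reference_date=reference_date)
            comp = plausibility_filter(comp, cohort)
        versions.append(DatasetVersion(label=label, composite=comp))
    return versions
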