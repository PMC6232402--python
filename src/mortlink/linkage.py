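"""Deterministic record linkage and gold-standard vital-status classification.

External mortality sources arrive without a shared key; records are
matched to cohort patients on the identifier fields a death index
actually carries — first and last name, birth date, state of residence —
through a fixed cascade of passes of decreasing strictness:

1. ``exact``        last name, first name, birth date all equal;
2. ``name_dob``     last name and birth date equal, first name within
                    Levenshtein distance 1 (a single typo);
3. ``name_state``   last and first name and state equal, birth date off
                    by a day/month field swap.

The first pass with exactly one candidate wins.  A pass in which two or
more patients tie makes the record unmatched outright: misattributing a
death to the wrong patient is worse than missing one, so ambiguity is
never broken by guessing.

Gold-standard (death-index) matches additionally carry a match-quality
class; :func:`classify_gold_matches` converts them into per-patient
vital-status calls with the conservative defaults of the validation
design: only ``exact`` and ``probable`` matches count as dead, while
``likely_false``, ``unclassifiable``, and the absence of any record all
leave the patient alive.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "MatcherConfig",
    "SchemaError",
    "DataError",
    "match_records",
    "classify_gold_matches",
    "match_class_fractions",
]

_PASS_SCORE = {"exact": 3, "name_dob": 2, "name_state": 1}

# precedence when one patient attracts several gold records
_QUALITY_RANK = {"exact": 0, "probable": 1, "likely_false": 2,
                 "unclassifiable": 3}


class SchemaError(ValueError):
    """An input table is missing a required column."""


class DataError(ValueError):
    """An input table violates a content invariant."""


@dataclass(frozen=True)
class MatcherConfig:
    max_first_name_edit_distance: int = 1


def _require(df: pd.DataFrame, columns, table: str) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{table} table is missing column {col!r}")


def _norm(s: pd.Series) -> pd.Series:
    return s.astype(str).str.strip().str.casefold()


def _swap_day_month(ts: pd.Timestamp):
    if pd.isna(ts) or ts.day > 12:
        return pd.NaT
    return ts.replace(day=ts.month, month=ts.day)


def _resolve(cands: pd.DataFrame, pass_name: str, matched: dict,
             terminal: set) -> None:
    """Fold candidate pairs into per-record outcomes for one pass."""
    for rid, grp in cands.groupby("record_id", sort=False):
        pids = grp["patient_id"].unique()
        if len(pids) == 1:
            matched[rid] = (pids[0], pass_name)
        else:  # ambiguous: never guess between tied patients
            terminal.add(rid)


def match_records(cohort: pd.DataFrame, source_records: pd.DataFrame,
                  config: MatcherConfig | None = None) -> pd.DataFrame:
    """Link source records to cohort patients.

    Returns one row per input record: ``record_id, patient_id``
    (NA when unmatched), ``match_pass`` (NA when unmatched), ``score``.
    """
    config = config or MatcherConfig()
    _require(cohort, ["patient_id", "first_name", "last_name",
                      "birth_date", "state"], "cohort")
    _require(source_records, ["record_id", "first_name", "last_name",
                              "birth_date", "state"], "source")

    pts = cohort[["patient_id"]].copy()
    pts["first"] = _norm(cohort["first_name"])
    pts["last"] = _norm(cohort["last_name"])
    pts["dob"] = pd.to_datetime(cohort["birth_date"])
    pts["state"] = _norm(cohort["state"])

    recs = source_records[["record_id"]].copy()
    recs["first"] = _norm(source_records["first_name"])
    recs["last"] = _norm(source_records["last_name"])
    recs["dob"] = pd.to_datetime(source_records["birth_date"])
    recs["state"] = _norm(source_records["state"])

    matched: dict[str, tuple] = {}
    terminal: set[str] = set()

    def pending():
        done = set(matched) | terminal
        return recs[~recs["record_id"].isin(done)]

    # pass 1: exact on (last, first, dob)
    cands = pending().merge(pts, on=["last", "first", "dob"], how="inner")
    _resolve(cands, "exact", matched, terminal)

    # pass 2: (last, dob) blocking, first name within edit distance 1
    cands = pending().merge(pts, on=["last", "dob"], how="inner",
                            suffixes=("_rec", "_pat"))
    if len(cands):
        k = config.max_first_name_edit_distance
        keep = [
            edlib.align(a, b, k=k)["editDistance"] != -1
            for a, b in zip(cands["first_rec"], cands["first_pat"])
        ]
        _resolve(cands[np.asarray(keep, bool)], "name_dob", matched, terminal)

    # pass 3: (last, first, state) blocking, dob off by a day/month swap
    rem = pending().copy()
    rem["dob_swapped"] = rem["dob"].map(_swap_day_month)
    rem = rem[rem["dob_swapped"].notna()]
    cands = rem.merge(pts, on=["last", "first", "state"], how="inner",
                      suffixes=("_rec", "_pat"))
    if len(cands):
        cands = cands[cands["dob_swapped"] == cands["dob_pat"]]
        _resolve(cands, "name_state", matched, terminal)

    out = source_records[["record_id"]].copy()
    out["patient_id"] = out["record_id"].map(
        lambda r: matched.get(r, (pd.NA, None))[0])
    out["match_pass"] = out["record_id"].map(
        lambda r: matched.get(r, (None, pd.NA))[1])
    out["score"] = out["match_pass"].map(_PASS_SCORE).astype("Int64")
    return out


def link_source(cohort: pd.DataFrame, source_records: pd.DataFrame,
                config: MatcherConfig | None = None) -> pd.DataFrame:
    """Match a source table and return its linked death assertions.

    Convenience wrapper: runs :func:`match_records` and joins the
    matched patient_id back onto the assertions, dropping unmatched
    records.  Output columns: ``patient_id, source_id, death_date,
    record_id, match_pass``.
    """
    m = match_records(cohort, source_records, config)
    joined = source_records.merge(m[m["patient_id"].notna()], on="record_id")
    return joined[["patient_id", "source_id", "death_date",
                   "record_id", "match_pass"]]


def classify_gold_matches(cohort: pd.DataFrame, gold_records: pd.DataFrame,
                          matches: pd.DataFrame) -> pd.DataFrame:
    """Turn matched gold records into one vital-status call per patient.

    Every cohort patient receives exactly one row: ``patient_id,
    status`` (dead/alive), ``reason`` (no_gold_record, exact_match,
    probable_match, likely_false_match, unclassifiable), and
    ``gold_death_date`` (NaT unless dead).  Patients without any
    matched gold record, and patients whose only records are
    likely-false or unclassifiable matches, are conservatively alive.
    """
    _require(cohort, ["patient_id"], "cohort")
    _require(gold_records, ["record_id", "death_date", "match_quality"],
             "gold")
    _require(matches, ["record_id", "patient_id"], "matches")

    linked = gold_records.merge(
        matches[matches["patient_id"].notna()][["record_id", "patient_id"]],
        on="record_id")
    has_date = pd.to_datetime(linked["death_date"]).notna()
    if (has_date & linked["match_quality"].isna()).any():
        bad = linked.loc[has_date & linked["match_quality"].isna(),
                         "record_id"].tolist()
        raise DataError(
            f"gold death records without match_quality: {bad[:5]}")
    unknown = set(linked["match_quality"].dropna()) - set(_QUALITY_RANK)
    if unknown:
        raise DataError(f"unknown gold match_quality values: {sorted(unknown)}")

    linked = linked[has_date].copy()
    linked["rank"] = linked["match_quality"].map(_QUALITY_RANK)
    best = (linked.sort_values(["rank", "record_id"])
            .drop_duplicates("patient_id", keep="first"))

    calls = cohort[["patient_id"]].copy()
    calls = calls.merge(best[["patient_id", "match_quality", "death_date"]],
                        on="patient_id", how="left")
    reason_map = {"exact": "exact_match", "probable": "probable_match",
                  "likely_false": "likely_false_match",
                  "unclassifiable": "unclassifiable"}
    calls["reason"] = calls["match_quality"].map(reason_map).fillna(
        "no_gold_record")
    dead = calls["reason"].isin(["exact_match", "probable_match"])
    calls["status"] = np.where(dead, "dead", "alive")
    calls["gold_death_date"] = pd.to_datetime(
        calls["death_date"]).where(dead, pd.NaT)
    return calls[["patient_id", "status", "reason", "gold_death_date"]]


def match_class_fractions(calls: pd.DataFrame) -> pd.Series:
    """Cohort fractions of each classification reason (audit logging)."""
    return calls["reason"].value_counts(normalize=True).sort_index()
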