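"""Cohort preparation: complete-case filtering, outcome-stratified splitting,
and minority-class oversampling.

The participant table is a pandas DataFrame with one row per trial
participant: a unique ``id``, treatment ``arm`` ("treated"/"control"), an
``event`` indicator, follow-up ``time`` in years, and baseline covariate
columns (continuous or categorical, possibly missing).  Missing covariates
are handled by complete-case exclusion only — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SplitResult",
    "validate_participant_table",
    "read_participant_table",
    "complete_case_filter",
    "stratified_split",
    "oversample_minority",
    "binary_outcome_label",
    "event_rate_by_arm",
]


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    n_excluded: int = 0


def validate_participant_table(table: pd.DataFrame) -> None:
    for col in ("id", "arm", "event", "time"):
        if col not in table.columns:
            raise ValueError(f"participant table lacks required column {col!r}")
    if table["id"].duplicated().any():
        raise ValueError("participant ids must be unique")
    time = table["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("time must be finite and > 0 for every row")
    if not set(pd.unique(table["event"])) <= {0, 1}:
        raise ValueError("event must be coded 0/1")


def read_participant_table(path) -> pd.DataFrame:
    """Read a comma-separated participant table (header row; empty field or
    'NA' encodes a missing value) and validate its invariants."""
    table = pd.read_csv(path, na_values=["NA", ""])
    validate_participant_table(table)
    return table


def complete_case_filter(
    table: pd.DataFrame, required_covariates: list[str]
) -> tuple[pd.DataFrame, int]:
    """Drop rows missing any required covariate; also returns the count dropped."""
    missing_cols = [c for c in required_covariates if c not in table.columns]
    if missing_cols:
        raise KeyError(f"required covariates absent from table: {missing_cols}")
    keep = table[required_covariates].notna().all(axis=1)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError("complete-case filter excluded every row")
    return out, int(len(table) - len(out))


def stratified_split(
    table: pd.DataFrame, test_fraction: float, seed: int
) -> SplitResult:
    """Outcome-stratified random split.

    Sampling is performed independently within the event=1 and event=0
    strata so the halves retain a near-identical outcome ratio.  Per-stratum
    test counts are round(stratum size x test_fraction), round-half-to-even.
    Deterministic given the seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = table["event"].value_counts()
    if counts.get(0, 0) == 0 or counts.get(1, 0) == 0:
        raise ValueError("both outcome classes must be present to stratify")
    rng = np.random.default_rng(seed)
    test_parts, train_parts = [], []
    for value in (0, 1):
        stratum = table.index[table["event"] == value].to_numpy()
        n_test = round(len(stratum) * test_fraction)
        picked = rng.permutation(stratum)[:n_test]
        mask = np.isin(stratum, picked)
        test_parts.append(stratum[mask])
        train_parts.append(stratum[~mask])
    test_idx = np.concatenate(test_parts)
    train_idx = np.concatenate(train_parts)
    return SplitResult(
        train=table.loc[np.sort(train_idx)].reset_index(drop=True),
        test=table.loc[np.sort(test_idx)].reset_index(drop=True),
    )


def oversample_minority(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Random oversampling with replacement of event rows until the classes
    balance.

    Every original row is retained; added rows are duplicates of event rows,
    keeping the original id plus a ``replicate`` counter so bootstrap
    bookkeeping stays auditable.  If the event class is not the minority the
    table is returned unchanged (aside from the replicate column).
    """
    n_event = int((table["event"] == 1).sum())
    n_other = int((table["event"] == 0).sum())
    if n_event == 0:
        raise ValueError("cannot oversample: no event rows present")
    out = table.copy()
    out["replicate"] = 0
    if n_event >= n_other:
        return out.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    event_rows = out[out["event"] == 1]
    picks = rng.integers(0, n_event, size=n_other - n_event)
    dup = event_rows.iloc[picks].copy()
    dup["replicate"] = dup.groupby("id").cumcount().to_numpy() + 1
    return pd.concat([out, dup], ignore_index=True)


def binary_outcome_label(table: pd.DataFrame) -> np.ndarray:
    """Classification label: the event indicator, with censoring ignored
    (a row censored before the horizon is labelled 0 by design — the
    classifiers model only whether the event was observed)."""
    if "event" not in table.columns:
        raise ValueError("table lacks an event column")
    return table["event"].to_numpy(dtype=int)


def event_rate_by_arm(table: pd.DataFrame) -> pd.Series:
    """Fraction of participants with an observed event, per arm."""
    return table.groupby("arm")["event"].mean()
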