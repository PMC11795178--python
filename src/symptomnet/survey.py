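"""Reading, validation, exclusion and scoring of PHQ-9/GAD-7 questionnaire tables.

The pipeline's unit of input is a per-respondent table with sixteen ordinal
items — nine Patient Health Questionnaire (PHQ-9) depression items labelled
``P1``–``P9`` and seven Generalized Anxiety Disorder (GAD-7) items labelled
``G1``–``G7`` — each scored 0 ("not at all") to 3 ("nearly every day"), plus a
group label (``school`` / ``vacation``) and coded demographics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHQ_ITEMS: tuple[str, ...] = tuple(f"P{i}" for i in range(1, 10))
GAD_ITEMS: tuple[str, ...] = tuple(f"G{i}" for i in range(1, 8))
ITEMS: tuple[str, ...] = PHQ_ITEMS + GAD_ITEMS

#: Cluster membership of each symptom node.
CLUSTER_OF: dict[str, str] = {**{p: "depression" for p in PHQ_ITEMS},
                              **{g: "anxiety" for g in GAD_ITEMS}}

#: Short symptom names conventionally used for the sixteen items.
ITEM_NAMES: dict[str, str] = {
    "P1": "Anhedonia", "P2": "Sad Mood", "P3": "Sleep", "P4": "Energy",
    "P5": "Appetite", "P6": "Guilty", "P7": "Concentration", "P8": "Motor",
    "P9": "Suicide", "G1": "Nervous", "G2": "Control Worry", "G3": "Worry A Lot",
    "G4": "Relax", "G5": "Restless", "G6": "Irritable", "G7": "Afraid",
}

DEMOGRAPHICS: tuple[str, ...] = (
    "gender", "age", "residence", "only_child",
    "father_education", "mother_education", "income",
)

GROUPS: tuple[str, str] = ("school", "vacation")

VALID_CODES = frozenset({0, 1, 2, 3})

# Severity bands shared by both screeners; the PHQ-9 maximum is 27, the
# GAD-7 maximum 21, and "probable diagnosis" is a total of 10 or more.
_BAND_EDGES = (4, 9, 14)
_BANDS = ("none", "mild", "moderate", "severe")
CLINICAL_CUTOFF = 10


class DegenerateScaleError(ValueError):
    """Raised when a scale has zero total-score variance."""


def _item_matrix(table: pd.DataFrame, items: Sequence[str] = ITEMS) -> pd.DataFrame:
    missing = [c for c in items if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks item columns: {missing}")
    return table[list(items)]


def apply_exclusion(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop incomplete or obviously erroneous rows.

    A row is excluded when any of the sixteen items is blank or outside the
    valid 0–3 code range, or when its ``respondent_id`` duplicates an earlier
    row (the later occurrence is dropped). Retained rows keep their original
    order. Returns ``(retained, n_excluded)``.
    """
    if len(table) == 0:
        raise ValueError("cannot apply exclusion to an empty table")
    items = _item_matrix(table)
    vals = items.to_numpy(dtype="float64", na_value=np.nan)
    ok = np.isfinite(vals) & np.isin(vals, (0.0, 1.0, 2.0, 3.0))
    keep = ok.all(axis=1)
    if "respondent_id" in table.columns:
        keep &= ~table["respondent_id"].duplicated(keep="first").to_numpy()
    retained = table.loc[keep].copy()
    retained[list(ITEMS)] = retained[list(ITEMS)].astype("int64")
    return retained, int((~keep).sum())


def _band(total: int) -> str:
    for edge, name in zip(_BAND_EDGES, _BANDS):
        if total <= edge:
            return name
    return _BANDS[-1]


@dataclass(frozen=True)
class ScoredRow:
    phq9_total: int
    gad7_total: int
    depression_band: str
    anxiety_band: str
    probable_depression: bool
    probable_anxiety: bool


def score_respondent(items: Sequence[int]) -> ScoredRow:
    """Score one respondent's sixteen item responses.

    ``items`` follows the canonical order ``P1..P9, G1..G7``. All responses
    must be present and in {0,1,2,3}; scoring happens after exclusion.
    """
    vals = list(items)
    if len(vals) != 16:
        raise ValueError(f"expected 16 item responses, got {len(vals)}")
    if any((v is None) or (isinstance(v, float) and math.isnan(v)) or int(v) not in VALID_CODES
           for v in vals):
        raise ValueError("missing or out-of-range item response; run exclusion first")
    phq = int(sum(vals[:9]))
    gad = int(sum(vals[9:]))
    return ScoredRow(
        phq9_total=phq, gad7_total=gad,
        depression_band=_band(phq), anxiety_band=_band(gad),
        probable_depression=phq >= CLINICAL_CUTOFF,
        probable_anxiety=gad >= CLINICAL_CUTOFF,
    )


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring of a post-exclusion table.

    Returns a DataFrame with totals, severity bands and probable-diagnosis
    flags, carrying over ``respondent_id`` and ``group`` when present.
    """
    items = _item_matrix(table).to_numpy(dtype="int64")
    if not np.isin(items, (0, 1, 2, 3)).all():
        raise ValueError("table contains invalid item codes; run exclusion first")
    phq = items[:, :9].sum(axis=1)
    gad = items[:, 9:].sum(axis=1)
    band = np.vectorize(_band)
    out = pd.DataFrame({
        "phq9_total": phq,
        "gad7_total": gad,
        "depression_band": band(phq),
        "anxiety_band": band(gad),
        "probable_depression": phq >= CLINICAL_CUTOFF,
        "probable_anxiety": gad >= CLINICAL_CUTOFF,
    }, index=table.index)
    for col in ("respondent_id", "group"):
        if col in table.columns:
            out.insert(0, col, table[col])
    return out


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum of item variances / total variance).

    Variances use the unbiased (n-1) denominator. Raises
    :class:`DegenerateScaleError` when the total score has zero variance.
    """
    x = np.asarray(item_matrix, dtype="float64")
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n >= 2 and k >= 2")
    if np.isnan(x).any():
        raise ValueError("item matrix contains missing entries")
    k = x.shape[1]
    item_vars = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateScaleError("total score has zero variance")
    return k / (k - 1) * (1.0 - item_vars.sum() / total_var)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, matching conventional survey reporting."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def prevalence_summary(scored: pd.DataFrame, group: str) -> dict:
    """Band counts and percentages for one group of scored respondents.

    Percentages use the group size as denominator and are reported to one
    decimal (half-up). ``at_least_mild`` counts respondents in the mild,
    moderate or severe band.
    """
    if len(scored) == 0:
        raise ValueError("scored table is empty")
    if "group" in scored.columns:
        if group not in set(scored["group"]):
            raise ValueError(f"unknown group label: {group!r}")
        sub = scored[scored["group"] == group]
    else:
        if group not in GROUPS:
            raise ValueError(f"unknown group label: {group!r}")
        sub = scored
    n = len(sub)
    summary: dict = {"group": group, "n": n}
    for scale, band_col, flag_col in (
        ("depression", "depression_band", "probable_depression"),
        ("anxiety", "anxiety_band", "probable_anxiety"),
    ):
        bands = {}
        for name in _BANDS:
            count = int((sub[band_col] == name).sum())
            bands[name] = {"count": count, "percent": round_half_up(100.0 * count / n)}
        at_least_mild = n - bands["none"]["count"]
        probable = int(sub[flag_col].sum())
        summary[scale] = {
            "bands": bands,
            "at_least_mild": {"count": at_least_mild,
                              "percent": round_half_up(100.0 * at_least_mild / n)},
            "probable": {"count": probable,
                         "percent": round_half_up(100.0 * probable / n)},
        }
    return summary


def read_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited questionnaire table, addressing item columns by label.

    ``column_map`` optionally renames file columns to the canonical labels
    (e.g. ``{"phq_1": "P1"}``); items are never addressed by position.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in (*ITEMS, "group") if c not in df.columns]
    if missing:
        raise ValueError(f"input table lacks required columns: {missing}")
    for c in ITEMS:
        df[c] = pd.array(df[c], dtype="Int64")
    return df


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
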