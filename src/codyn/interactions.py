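"""Monoculture-referenced interaction index and coculture outcome classes.

For each coculture and each growth parameter, the interaction index is the
signed relative deviation of the coculture from the mean of its two
monocultures:

    Id = (co - (m1 + m2)/2) / ((m1 + m2)/2)

Each coculture is classified into one of four outcomes by a t-test ladder:

* **A** — no significant difference from the monoculture average
  (no perceived interaction);
* **B** — overyielding: significantly above the larger monoculture;
* **C** — underyielding: significantly below the smaller monoculture;
* **D** — significantly different from the average but within the
  monoculture range.

Welch (unequal-variance) t-tests are used throughout: two-sided for the
A-gate, one-sided for the B/C gates (over/underyielding is directional).
The replicate set for "the monoculture average" pairs monoculture
replicates in order, ((m1_i + m2_i)/2), preserving replicate count and
variance scale.  For latency the biological sign is inverted: a longer lag
is a negative interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError

log = logging.getLogger(__name__)

PARAMETERS = ("auc", "r", "max_od", "latency")
#: parameters where a larger value means better growth (latency is opposite)
_HIGHER_IS_MORE = {"auc": 1.0, "r": 1.0, "max_od": 1.0, "latency": -1.0}

__all__ = [
    "PARAMETERS",
    "InteractionRecord",
    "interaction_index",
    "classify_coculture",
    "effect_direction",
    "analyze_all",
    "outcome_summary",
]


@dataclass(frozen=True)
class InteractionRecord:
    """Index, outcome class and p-values for one coculture x one parameter."""

    parameter: str
    strain_1: str
    strain_2: str
    species_1: str
    species_2: str
    index: float
    outcome: str
    p_avg: float
    p_max: float
    p_min: float
    effect_direction: str
    n_co: int
    n_m1: int
    n_m2: int


def interaction_index(co_mean: float, m1_mean: float, m2_mean: float) -> float:
    """Signed relative deviation of the coculture from the monoculture mean."""
    ref = 0.5 * (m1_mean + m2_mean)
    if ref == 0 or not np.isfinite(ref):
        raise AnalysisError("zero or non-finite monoculture average: interaction index undefined")
    return float((co_mean - ref) / ref)


def classify_coculture(co_reps, m1_reps, m2_reps, alpha: float = 0.05):
    """Outcome class plus the three gate p-values.

    Returns ``(outcome, p_avg, p_max, p_min)``.  ``p_max``/``p_min`` are the
    one-sided p-values against the larger/smaller monoculture regardless of
    which gate decided the class.
    """
    co = np.asarray(co_reps, dtype=float)
    m1 = np.asarray(m1_reps, dtype=float)
    m2 = np.asarray(m2_reps, dtype=float)
    if min(len(co), len(m1), len(m2)) < 2:
        raise AnalysisError("need at least 2 replicates in each group to classify")
    k = min(len(m1), len(m2))
    avg = 0.5 * (m1[:k] + m2[:k])

    p_avg = float(stats.ttest_ind(co, avg, equal_var=False).pvalue)
    hi, lo = (m1, m2) if m1.mean() >= m2.mean() else (m2, m1)
    p_max = float(stats.ttest_ind(co, hi, equal_var=False, alternative="greater").pvalue)
    p_min = float(stats.ttest_ind(co, lo, equal_var=False, alternative="less").pvalue)

    if not np.isfinite(p_avg):
        # identical constant groups: no evidence of any difference
        p_avg = 1.0
    if p_avg >= alpha:
        outcome = "A"
    elif np.isfinite(p_max) and p_max < alpha:
        outcome = "B"
    elif np.isfinite(p_min) and p_min < alpha:
        outcome = "C"
    else:
        outcome = "D"
    return outcome, p_avg, p_max, p_min


def effect_direction(parameter: str, index: float, outcome: str) -> str:
    """Biological direction of the interaction.

    Case A is neutral by definition.  Otherwise the sign of the index
    decides, inverted for latency (a longer lag is a negative interaction).
    """
    if parameter not in PARAMETERS:
        raise AnalysisError(f"unknown parameter {parameter!r}")
    if outcome == "A" or index == 0:
        return "neutral"
    signed = index * _HIGHER_IS_MORE[parameter]
    return "positive" if signed > 0 else "negative"


def analyze_all(params_df: pd.DataFrame, alpha: float = 0.05,
                parameters=PARAMETERS, bh_correct: bool = False) -> list[InteractionRecord]:
    """Classify every coculture for every growth parameter.

    ``params_df`` is the per-replicate kinetics table joined to the layout:
    columns ``kind, strain_a, strain_b, species_a, species_b`` plus one
    column per parameter.  Cocultures with missing values (failed fits)
    in any group are skipped with a log entry.  With ``bh_correct`` the
    A-gate p-values are Benjamini-Hochberg adjusted per parameter before
    classification (off by default).
    """
    mono: dict[str, pd.DataFrame] = {}
    for strain, grp in params_df[params_df["kind"] == "monoculture"].groupby("strain_a"):
        mono[strain] = grp.sort_values("replicate")
    species_of = {}
    for _, row in params_df.iterrows():
        species_of[row["strain_a"]] = row["species_a"]
        species_of[row["strain_b"]] = row["species_b"]

    records: list[InteractionRecord] = []
    co_df = params_df[params_df["kind"] == "coculture"]
    grouped = sorted(co_df.groupby(["strain_a", "strain_b"]),
                     key=lambda kv: tuple(sorted(kv[0])))
    for (sa, sb), grp in grouped:
        s1, s2 = sorted((sa, sb))
        if sa not in mono or sb not in mono:
            log.warning("coculture %s-%s skipped: missing monoculture reference", s1, s2)
            continue
        for parameter in parameters:
            co = grp.sort_values("replicate")[parameter].to_numpy(dtype=float)
            m1 = mono[s1][parameter].to_numpy(dtype=float)
            m2 = mono[s2][parameter].to_numpy(dtype=float)
            co, m1, m2 = co[~np.isnan(co)], m1[~np.isnan(m1)], m2[~np.isnan(m2)]
            if min(len(co), len(m1), len(m2)) < 2:
                log.warning("pair %s-%s, %s skipped: missing replicate values", s1, s2, parameter)
                continue
            try:
                idx = interaction_index(co.mean(), m1.mean(), m2.mean())
            except AnalysisError:
                log.warning("pair %s-%s, %s skipped: undefined index", s1, s2, parameter)
                continue
            outcome, p_avg, p_max, p_min = classify_coculture(co, m1, m2, alpha)
            records.append(InteractionRecord(
                parameter=parameter, strain_1=s1, strain_2=s2,
                species_1=str(species_of.get(s1, "")), species_2=str(species_of.get(s2, "")),
                index=idx, outcome=outcome, p_avg=p_avg, p_max=p_max, p_min=p_min,
                effect_direction=effect_direction(parameter, idx, outcome),
                n_co=len(co), n_m1=len(m1), n_m2=len(m2),
            ))
    if bh_correct:
        records = _bh_reclassify(records, alpha)
    return records


def _bh_reclassify(records: list[InteractionRecord], alpha: float) -> list[InteractionRecord]:
    from statsmodels.stats.multitest import multipletests
    from dataclasses import replace

    out = []
    by_param: dict[str, list[InteractionRecord]] = {}
    for rec in records:
        by_param.setdefault(rec.parameter, []).append(rec)
    for parameter, recs in by_param.items():
        adj = multipletests([r.p_avg for r in recs], alpha=alpha, method="fdr_bh")[1]
        for rec, p in zip(recs, adj):
            outcome = rec.outcome
            if p >= alpha:
                outcome = "A"
            out.append(replace(rec, p_avg=float(p), outcome=outcome,
                               effect_direction=effect_direction(rec.parameter, rec.index, outcome)))
    return out


def records_to_frame(records: list[InteractionRecord]) -> pd.DataFrame:
    cols = ["parameter", "strain_1", "strain_2", "species_1", "species_2", "index",
            "outcome", "p_avg", "p_max", "p_min", "effect_direction", "n_co", "n_m1", "n_m2"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def outcome_summary(records: list[InteractionRecord]) -> pd.DataFrame:
    """Per-parameter counts and percentages over the outcome classes."""
    df = records_to_frame(records)
    rows = []
    for parameter in PARAMETERS:
        sub = df[df["parameter"] == parameter]
        n = len(sub)
        for outcome in "ABCD":
            cnt = int((sub["outcome"] == outcome).sum())
            rows.append({"parameter": parameter, "outcome": outcome, "count": cnt,
                         "percent": 100.0 * cnt / n if n else float("nan"), "n_total": n})
    return pd.DataFrame(rows)
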