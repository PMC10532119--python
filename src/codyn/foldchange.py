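"""Cytometry relative abundances and T0 -> T24 fold changes.

A strain's fold change is its relative abundance (gate fraction of total
events) at 24 h divided by its relative abundance at inoculation.  In a
two-member coculture the per-replicate fold changes are algebraically
coupled: f_A s_A0 + f_B s_B0 = 1 where s_0 are the T0 shares.  A one-sample
t-test against 1 flags significant composition shifts; the test runs on the
raw fold-change scale by default (a log-scale option exists).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .io_plate import CytometrySample, PlateLayout

log = logging.getLogger(__name__)

__all__ = [
    "FoldChangeRecord",
    "relative_abundance",
    "fold_change",
    "test_fold_changes",
    "fold_change_table",
]


@dataclass(frozen=True)
class FoldChangeRecord:
    """Replicate fold changes of one focal strain against one partner."""

    focal: str
    partner: str
    fold_changes: tuple[float, ...]
    mean: float
    sd: float
    p_value: float
    n: int

    def significant(self, alpha: float = 0.05) -> bool:
        return np.isfinite(self.p_value) and self.p_value < alpha


def relative_abundance(sample: CytometrySample) -> dict[str, float]:
    """Gate fractions of total events (sum to 1)."""
    total = sample.total_events
    if total <= 0:
        raise AnalysisError(f"sample {sample.culture_id!r}: zero total events")
    return {gate: n / total for gate, n in sample.counts.items()}


def fold_change(t0: dict[str, float], t24: dict[str, float], strain: str) -> float:
    """T24 share over T0 share for one strain; requires a non-zero T0 share."""
    if strain not in t0 or strain not in t24:
        raise AnalysisError(f"strain {strain!r} missing from abundance mapping")
    if t0[strain] <= 0:
        raise AnalysisError(f"strain {strain!r}: zero T0 share, fold change undefined")
    return float(t24[strain] / t0[strain])


def test_fold_changes(fcs, alpha: float = 0.05, scale: str = "raw"):
    """One-sample two-sided t-test of replicate fold changes against 1.

    Returns ``(mean, sd, p)`` on the raw scale; with ``scale='log'`` the
    test runs on log fold changes against 0 (mean/sd still reported raw).
    With fewer than 2 replicates the test is skipped (p = NaN).
    """
    fcs = np.asarray(fcs, dtype=float)
    if np.any(fcs <= 0):
        raise AnalysisError("fold changes must be positive")
    mean = float(fcs.mean())
    sd = float(fcs.std(ddof=1)) if len(fcs) > 1 else float("nan")
    if len(fcs) < 2:
        return mean, sd, float("nan")
    if scale == "log":
        p = float(stats.ttest_1samp(np.log(fcs), 0.0).pvalue)
    elif scale == "raw":
        p = float(stats.ttest_1samp(fcs, 1.0).pvalue)
    else:
        raise AnalysisError(f"unknown fold-change scale {scale!r}")
    if not np.isfinite(p):
        # zero-variance replicates: no evidence against 1 unless shifted
        p = 0.0 if not math.isclose(mean, 1.0) else 1.0
    return mean, sd, p


def fold_change_table(samples: list[CytometrySample], layout: PlateLayout,
                      alpha: float = 0.05, scale: str = "raw"):
    """Per-replicate fold changes for every strain-in-pair, plus records.

    Returns ``(per_replicate_df, records)`` where records aggregate the
    replicates of each ordered (focal, partner) combination.
    """
    by_key = {(s.culture_id, s.timepoint): s for s in samples}
    rows = []
    for desc in layout:
        t0 = by_key.get((desc.culture_id, "T0"))
        t24 = by_key.get((desc.culture_id, "T24"))
        if t0 is None or t24 is None:
            continue
        a0, a24 = relative_abundance(t0), relative_abundance(t24)
        if desc.kind == "monoculture":
            # monoculture gates are clone labels (tagged/untagged), not
            # strain ids; the WT-vs-tag control is analyzed separately
            continue
        for focal, partner in ((desc.strain_a, desc.strain_b), (desc.strain_b, desc.strain_a)):
            try:
                fc = fold_change(a0, a24, focal)
            except AnalysisError:
                log.warning("well %s: fold change undefined for %s", desc.culture_id, focal)
                continue
            rows.append({"culture_id": desc.culture_id, "kind": desc.kind, "focal": focal,
                         "partner": partner, "replicate": desc.replicate, "fc": fc})
    per_rep = pd.DataFrame(rows, columns=["culture_id", "kind", "focal", "partner", "replicate", "fc"])
    records = []
    if len(per_rep):
        for (focal, partner), grp in per_rep.groupby(["focal", "partner"], sort=True):
            fcs = grp.sort_values("replicate")["fc"].to_numpy()
            mean, sd, p = test_fold_changes(fcs, alpha=alpha, scale=scale)
            records.append(FoldChangeRecord(focal=str(focal), partner=str(partner),
                                            fold_changes=tuple(float(f) for f in fcs),
                                            mean=mean, sd=sd, p_value=p, n=len(fcs)))
    return per_rep, records
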