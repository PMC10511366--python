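"""Scan-rescan agreement analysis for bronchial parameters.

Participants with a total-lung-volume (TLV) difference above 15% between the
two scans are excluded (inspiration mismatch); for each bronchial parameter
and airway generation the squared Pearson correlation (R^2), the Bland-Altman
mean difference (MD, scan2 - scan1), the limits of agreement
(LoA = 1.96 * SD of the differences, reported as +/- LoA around MD), and LoA
as a percentage of the mean are computed across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .measure import ScanSummary

__all__ = [
    "Participant",
    "PairedCohort",
    "tlv_exclusion",
    "r_squared",
    "bland_altman",
    "agreement_report",
    "plot_bland_altman",
]


@dataclass
class Participant:
    participant_id: str
    scan1: ScanSummary
    scan2: ScanSummary
    days_between: float = 90.0


@dataclass
class PairedCohort:
    participants: list[Participant]

    def __len__(self) -> int:
        return len(self.participants)


def tlv_exclusion(cohort: PairedCohort, threshold: float = 0.15) -> PairedCohort:
    """Drop participants whose TLV differs by more than ``threshold`` between scans.

    The relative difference uses the mean of the two TLVs as denominator:
    ``|TLV2 - TLV1| / ((TLV1 + TLV2) / 2)``.
    """
    kept = []
    for p in cohort.participants:
        t1, t2 = p.scan1.tlv_l, p.scan2.tlv_l
        if t1 is None or t2 is None or t1 <= 0 or t2 <= 0:
            raise ValueError(f"participant {p.participant_id}: TLV must be positive in both scans")
        rel = abs(t2 - t1) / ((t1 + t2) / 2.0)
        if rel <= threshold:
            kept.append(p)
    return PairedCohort(participants=kept)


def r_squared(x, y) -> float:
    """Squared Pearson correlation of paired values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: R^2 undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Bland-Altman agreement of scan-1 values ``x`` and scan-2 values ``y``.

    Returns ``(MD, LoA, LoA_percent)`` with ``d = y - x``, ``MD = mean(d)``,
    ``LoA = 1.96 * sample SD of d`` and ``LoA_percent = 100 * LoA / mean of
    the pairwise means (x + y) / 2``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = y - x
    md = float(d.mean())
    loa = float(1.96 * d.std(ddof=1))
    denom = float(((x + y) / 2.0).mean())
    loa_pct = 100.0 * loa / denom if denom != 0 else float("nan")
    return md, loa, loa_pct


def _paired_values(cohort: PairedCohort, parameter: str, generation: int | None):
    """Per-participant values for one report row, with pairwise deletion."""
    xs, ys = [], []
    for p in cohort.participants:
        if parameter == "Pi10":
            v1, v2 = p.scan1.pi10_mm, p.scan2.pi10_mm
        else:
            source = "mean_la_by_generation" if parameter == "LA" else "mean_wap_by_generation"
            v1 = getattr(p.scan1, source).get(generation)
            v2 = getattr(p.scan2, source).get(generation)
        if v1 is not None and v2 is not None:
            xs.append(v1)
            ys.append(v2)
    return np.asarray(xs), np.asarray(ys)


def agreement_report(cohort: PairedCohort, min_n: int = 3) -> pd.DataFrame:
    """Agreement table: one row per (parameter, generation) plus a Pi10 row.

    Rows with fewer than ``min_n`` contributing participants are omitted
    (reported absent, not zero); rows with zero variance report R^2 as NaN.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    gens = sorted(
        {
            g
            for p in cohort.participants
            for g in set(p.scan1.mean_la_by_generation) & set(p.scan2.mean_la_by_generation)
        }
    )
    for parameter in ("LA", "WAP"):
        for g in gens:
            x, y = _paired_values(cohort, parameter, g)
            if len(x) < min_n:
                continue
            md, loa, loa_pct = bland_altman(x, y)
            try:
                r2 = r_squared(x, y)
            except ValueError:
                r2 = float("nan")
            rows.append(
                {
                    "parameter": parameter,
                    "generation": g,
                    "n": len(x),
                    "r2": r2,
                    "md": md,
                    "loa": loa,
                    "loa_pct": loa_pct,
                }
            )
    x, y = _paired_values(cohort, "Pi10", None)
    if len(x) >= min_n:
        md, loa, loa_pct = bland_altman(x, y)
        try:
            r2 = r_squared(x, y)
        except ValueError:
            r2 = float("nan")
        rows.append(
            {
                "parameter": "Pi10",
                "generation": "overall",
                "n": len(x),
                "r2": r2,
                "md": md,
                "loa": loa,
                "loa_pct": loa_pct,
            }
        )
    return pd.DataFrame(rows, columns=["parameter", "generation", "n", "r2", "md", "loa", "loa_pct"])


def plot_bland_altman(x, y, ax=None, label: str | None = None):
    """Basic Bland-Altman scatter with MD and MD +/- LoA reference lines."""
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    md, loa, _ = bland_altman(x, y)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((x + y) / 2.0, y - x, s=12, alpha=0.7)
    ax.axhline(md, color="k", lw=1)
    ax.axhline(md + loa, color="k", lw=1, ls="--")
    ax.axhline(md - loa, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of scans")
    ax.set_ylabel("scan2 - scan1")
    if label:
        ax.set_title(label)
    return ax
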