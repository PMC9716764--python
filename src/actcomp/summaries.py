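"""Descriptive outputs: compensation prevalence and cohort descriptives.

Percentages are rounded half-up to one decimal everywhere (a printed
percentage like 14.2 recomputes exactly as 100*75/528 under this rule).
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .compensation import (
    ELIGIBLE_NEGATIVE,
    ELIGIBLE_POSITIVE,
    NEGATIVE,
    NONE,
    POSITIVE,
    TIE,
    CompensationLabel,
)
from .errors import DataError


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from the lower value (0.05 -> 0.1), not banker's."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Exact-rational percentage, rounded half-up."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * numerator) / Decimal(denominator)).quantize(q, ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class PrevalenceReport:
    """Counts and percentages of compensation labels over a set of units."""

    n_units: int
    n_positive: int
    n_negative: int
    n_none: int
    n_eligible_positive: int
    n_eligible_negative: int
    n_ties: int
    pct_positive: float
    pct_negative: float
    pct_any: float
    pct_positive_among_eligible: float
    pct_negative_among_eligible: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def prevalence(labels: list[CompensationLabel]) -> PrevalenceReport:
    """Tally labels into a :class:`PrevalenceReport` (order-independent)."""
    if not labels:
        raise DataError("prevalence of an empty label set is undefined")
    n = len(labels)
    n_pos = sum(1 for lb in labels if lb.label == POSITIVE)
    n_neg = sum(1 for lb in labels if lb.label == NEGATIVE)
    n_none = sum(1 for lb in labels if lb.label == NONE)
    n_ep = sum(1 for lb in labels if lb.eligibility == ELIGIBLE_POSITIVE)
    n_en = sum(1 for lb in labels if lb.eligibility == ELIGIBLE_NEGATIVE)
    n_tie = sum(1 for lb in labels if lb.eligibility == TIE)
    assert n_pos + n_neg + n_none == n and n_ep + n_en + n_tie == n
    return PrevalenceReport(
        n_units=n,
        n_positive=n_pos,
        n_negative=n_neg,
        n_none=n_none,
        n_eligible_positive=n_ep,
        n_eligible_negative=n_en,
        n_ties=n_tie,
        pct_positive=_pct(n_pos, n),
        pct_negative=_pct(n_neg, n),
        pct_any=_pct(n_pos + n_neg, n),
        pct_positive_among_eligible=_pct(n_pos, n_ep),
        pct_negative_among_eligible=_pct(n_neg, n_en),
    )


def labels_from_counts(
    n_positive: int,
    n_negative: int,
    n_none_eligible_positive: int,
    n_none_eligible_negative: int = 0,
    n_ties: int = 0,
    analysis: str = "observation",
) -> list[CompensationLabel]:
    """Expand printed label tallies into concrete labels for auditing.

    Positive labels are eligible-positive and negative labels
    eligible-negative by construction; 'none' labels are split by eligibility
    as given.
    """
    out: list[CompensationLabel] = []
    blocks = [
        (n_positive, ELIGIBLE_POSITIVE, POSITIVE),
        (n_negative, ELIGIBLE_NEGATIVE, NEGATIVE),
        (n_none_eligible_positive, ELIGIBLE_POSITIVE, NONE),
        (n_none_eligible_negative, ELIGIBLE_NEGATIVE, NONE),
        (n_ties, TIE, NONE),
    ]
    i = 0
    for count, eligibility, label in blocks:
        for _ in range(count):
            out.append(
                CompensationLabel(
                    unit_id=f"u{i}",
                    analysis=analysis,
                    participant_id=f"u{i}",
                    date=None,
                    eligibility=eligibility,
                    label=label,
                    delta=float("nan"),
                    threshold=float("nan"),
                )
            )
            i += 1
    return out


def descriptives(
    exposures: pd.DataFrame, participants: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Cohort mean (SD) table of participant covariates and segment minutes.

    Minutes are first averaged per girl across her valid days of each segment
    type, then summarised across girls with the sample SD (n-1).  A single
    contributing girl yields SD 0 with ``degenerate=True``.
    """
    rows = []
    if participants is not None:
        for col, name in (("age", "Age (years)"), ("bmi", "Body mass index (kg.m-2)")):
            if col in participants.columns:
                rows.append(_stat_row(name, participants[col].to_numpy(dtype=float)))
    if not exposures.empty:
        valid = exposures[exposures["valid"]]
        for segment in ("morning", "afternoon", "weekend_day"):
            seg = valid[valid["segment"] == segment]
            if seg.empty:
                continue
            for cat in ("st", "lpa", "mvpa"):
                per_girl = seg.groupby("participant_id")[f"{cat}_minutes"].mean()
                rows.append(
                    _stat_row(
                        f"{cat.upper()} {segment} (min)", per_girl.to_numpy(dtype=float)
                    )
                )
    return pd.DataFrame(rows, columns=["variable", "mean", "sd", "n", "degenerate"])


def _stat_row(name: str, values: np.ndarray) -> dict:
    n = values.size
    mean = float(values.mean()) if n else float("nan")
    degenerate = n < 2
    sd = 0.0 if degenerate else float(np.std(values, ddof=1))
    return {
        "variable": name,
        "mean": round_half_up(mean, 1),
        "sd": round_half_up(sd, 1),
        "n": n,
        "degenerate": degenerate,
    }


def plot_prevalence(report: PrevalenceReport, path) -> None:
    """Simple positive/negative/none bar chart of a prevalence report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shares = [
        100.0 * report.n_positive / report.n_units,
        100.0 * report.n_negative / report.n_units,
        100.0 * report.n_none / report.n_units,
    ]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(["positive", "negative", "none"], shares, color=["#2a9d8f", "#e76f51", "#8d99ae"])
    ax.set_ylabel("% of units")
    ax.set_ylim(0, 100)
    for x, y in enumerate(shares):
        ax.text(x, y + 2, f"{y:.1f}", ha="center", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
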