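"""Reduce batches of departure replicates to decision variables.

Three variables summarize each replicate: the number of joiners (the
departed count including the initiator, 0..N), the departure latency of
the first joiner ΔT_{1,2}, and the duration of joining ΔT_{1,N} (counted
only when all N individuals departed).  Each is averaged over all
replicates and, when a central individual is designated, conditionally on
whether the movement was initiated by the central individual C or by a
non-central individual c; the absolute C-vs-c difference of each variable
quantifies how much leadership the central position confers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulation import DepartureRecord

__all__ = ["ClassSummary", "BatchSummary", "summarize", "rank_latency_profile"]

#: replicate classes: any initiator, C-initiated, c-initiated, and (among
#: c-initiated replicates with a joiner) whether C was the first joiner
CLASSES = (
    "all",
    "central_init",
    "noncentral_init",
    "central_first_joiner",
    "noncentral_first_joiner",
)

VARIABLES = ("joiners", "first_latency", "duration")


@dataclass(frozen=True)
class ClassSummary:
    """Means of the three decision variables within one replicate class."""

    n: int  # replicates in the class
    n_with_joiner: int  # replicates with at least one joiner
    n_complete: int  # replicates where all N departed
    mean_joiners: float | None
    mean_first_latency: float | None
    mean_duration: float | None


@dataclass(frozen=True)
class BatchSummary:
    """Batch-level decision variables, split by initiator class."""

    classes: dict[str, ClassSummary]
    diffs: dict[str, float | None]
    rank_latency: np.ndarray
    central: str | None
    n_replicates: int
    n_void: int
    n_truncated: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, cs in self.classes.items():
            rows.append(
                {
                    "class": name,
                    "n": cs.n,
                    "n_with_joiner": cs.n_with_joiner,
                    "n_complete": cs.n_complete,
                    "mean_joiners": cs.mean_joiners,
                    "mean_first_latency": cs.mean_first_latency,
                    "mean_duration": cs.mean_duration,
                }
            )
        return pd.DataFrame(rows)


def _class_summary(records: list[DepartureRecord]) -> ClassSummary:
    joiners = [rec.n_departed for rec in records]
    latencies = [
        rec.first_joiner_latency for rec in records if rec.first_joiner_latency is not None
    ]
    durations = [rec.duration for rec in records if rec.duration is not None]
    return ClassSummary(
        n=len(records),
        n_with_joiner=len(latencies),
        n_complete=len(durations),
        mean_joiners=float(np.mean(joiners)) if joiners else None,
        mean_first_latency=float(np.mean(latencies)) if latencies else None,
        mean_duration=float(np.mean(durations)) if durations else None,
    )


def summarize(
    records: list[DepartureRecord], central: str | None = None
) -> BatchSummary:
    """Class-conditional means of the three decision variables.

    Void replicates (no initiation before the hard time cap) are excluded
    from every mean and reported in ``n_void``.  When ``central`` is unset
    only the ``all`` class is produced.  The first-joiner classes condition
    on non-centrally-initiated replicates with at least one joiner,
    according to whether the central individual joined first.
    """
    if not records:
        raise ValueError("cannot summarize an empty batch")
    live = [rec for rec in records if not rec.void]
    n_void = len(records) - len(live)
    n_truncated = sum(rec.truncated for rec in live)
    classes = {"all": _class_summary(live)}
    if central is not None and live:
        c_init = [rec for rec in live if rec.initiator == central]
        nc_init = [rec for rec in live if rec.initiator != central]
        classes["central_init"] = _class_summary(c_init)
        classes["noncentral_init"] = _class_summary(nc_init)
        followed = [rec for rec in nc_init if rec.n_departed >= 2]
        classes["central_first_joiner"] = _class_summary(
            [rec for rec in followed if rec.first_joiner == central]
        )
        classes["noncentral_first_joiner"] = _class_summary(
            [rec for rec in followed if rec.first_joiner != central]
        )
    diffs: dict[str, float | None] = {}
    for var in VARIABLES:
        attr = f"mean_{var}" if var != "joiners" else "mean_joiners"
        a = getattr(classes.get("central_init"), attr, None) if central else None
        b = getattr(classes.get("noncentral_init"), attr, None) if central else None
        diffs[var] = abs(a - b) if a is not None and b is not None else None
    n_total = live[0].n_total if live else 0
    return BatchSummary(
        classes=classes,
        diffs=diffs,
        rank_latency=rank_latency_profile(records, central=central),
        central=central,
        n_replicates=len(live),
        n_void=n_void,
        n_truncated=n_truncated,
    )


def rank_latency_profile(
    records: list[DepartureRecord],
    condition: str = "all",
    central: str | None = None,
) -> np.ndarray:
    """Mean inter-departure latency ΔT_{j-1,j} at each rank j = 2..N.

    ``condition`` restricts the batch to ``central``- or
    ``noncentral``-initiated replicates.  The initiator's own latency
    (rank 1) is excluded; ranks never reached in any replicate are NaN.
    """
    if not records:
        raise ValueError("cannot profile an empty batch")
    if condition not in ("all", "central", "noncentral"):
        raise ValueError(f"unknown condition {condition!r}")
    live = [rec for rec in records if not rec.void]
    if condition == "central":
        live = [rec for rec in live if rec.initiator == central]
    elif condition == "noncentral":
        live = [rec for rec in live if rec.initiator != central]
    n_total = max((rec.n_total for rec in records), default=0)
    sums = np.zeros(n_total - 1)
    counts = np.zeros(n_total - 1, dtype=int)
    for rec in live:
        for k, gap in enumerate(rec.gaps()):  # k=0 is rank 2
            sums[k] += gap
            counts[k] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile
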