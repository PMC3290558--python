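"""Stochastic departure model: mimetic joining on a weighted social network.

All ``N`` agents start in a resting area.  Time advances in 1-second
steps; each second, every resting agent draws a uniform number and leaves
for the foraging area when the draw falls below its current per-second
departure probability.  Before anyone has moved, that probability is the
intrinsic rate ``lam`` (a nutrient-need term, identical for all agents),
so the collective initiation probability is ``psi_01 = N * lam`` per
second.  Once agents are moving, a resting agent ``i`` is amplified by
the affiliation it has toward the ``j`` agents already moving,
``S = sum_k r(i, k)`` over moving ``k`` — the mimetic (allelomimetic)
process.  Three kernel variants are implemented:

* ``K1`` : ``psi_i = lam + M * S`` (the literal mimetic term);
* ``K2`` : ``psi_i = lam + M * (N - j) * S`` (amplified by the number
  still resting);
* ``K3`` : ``psi_i = lam + M * j * (N - j) * S`` (amplified by movers and
  resters alike, the parabolic-rate variant).

``K1`` is the default construction; the calibrated reference kernel used
by the reproduction driver is chosen by
:func:`collmove.reproduce.calibrate_kernel` (see ``docs/methods.md``).
A replicate ends when every agent has departed or when ``stop_window``
seconds (default 300) pass without a departure after the last one; the
window does not run before initiation, which is instead guarded by a hard
``max_time`` cap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .networks import NetworkError, SocialNetwork

__all__ = [
    "SimulationConfig",
    "DepartureRecord",
    "KERNELS",
    "initiation_probability",
    "joining_probability",
    "run_replicate",
    "event_driven_replicate",
    "run_batch",
    "write_batch",
    "read_batch",
]

logger = logging.getLogger(__name__)

KERNELS = ("K1", "K2", "K3")

#: probabilities are clamped strictly below 1 so waiting times stay finite
_P_MAX = 1.0 - 1e-12

#: seconds of uniform draws evaluated per vectorized block
_BLOCK = 256


@dataclass(frozen=True)
class SimulationConfig:
    """Run configuration for the departure model.

    Parameters
    ----------
    lam
        Intrinsic per-individual departure probability per second.
    M
        Mimetic coefficient per unit affiliation per second.
    kernel
        Mimetic kernel variant, one of ``K1``, ``K2``, ``K3``.
    stop_window
        Seconds without a departure (after the first one) that end a
        replicate.
    max_time
        Hard cap on simulated seconds, guarding against unbounded waits.
    replicates
        Number of replicates in a batch.
    seed
        Base seed; each replicate runs on an independent substream.
    """

    lam: float = 0.00007
    M: float = 0.002
    kernel: str = "K1"
    stop_window: int = 300
    max_time: int = 1_000_000
    replicates: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"lam={self.lam} must be in (0, 1)")
        if self.M < 0.0:
            raise ValueError(f"M={self.M} must be nonnegative")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel={self.kernel!r} must be one of {KERNELS}")
        if self.stop_window <= 0:
            raise ValueError("stop_window must be positive")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DepartureRecord:
    """One replicate: ordered departures with integer-second timestamps.

    ``events[0]`` is the initiator; ``n_departed`` counts all departed
    individuals *including* the initiator (0..N scale); ``void`` replicates
    saw no initiation before ``max_time`` and carry no events; ``truncated``
    replicates hit ``max_time`` mid-movement.
    """

    events: tuple[tuple[str, int], ...]
    n_total: int
    void: bool = False
    truncated: bool = False
    replicate: int | None = None

    @property
    def initiator(self) -> str | None:
        return self.events[0][0] if self.events else None

    @property
    def n_departed(self) -> int:
        return len(self.events)

    @property
    def complete(self) -> bool:
        return self.n_departed == self.n_total

    @property
    def initiation_time(self) -> int | None:
        """Latency of the initiator, ΔT_01."""
        return self.events[0][1] if self.events else None

    @property
    def first_joiner(self) -> str | None:
        return self.events[1][0] if self.n_departed >= 2 else None

    @property
    def first_joiner_latency(self) -> int | None:
        """ΔT_{1,2}: seconds between initiator and first joiner."""
        if self.n_departed < 2:
            return None
        return self.events[1][1] - self.events[0][1]

    @property
    def duration(self) -> int | None:
        """ΔT_{1,N}: initiator-to-last-joiner span, complete replicates only."""
        if not self.complete or self.void:
            return None
        return self.events[-1][1] - self.events[0][1]

    def gaps(self) -> list[int]:
        """Inter-departure latencies ΔT_{j-1,j} for ranks j = 2..n_departed."""
        times = [t for _, t in self.events]
        return [b - a for a, b in zip(times, times[1:])]


def initiation_probability(config: SimulationConfig, n: int) -> float:
    """Collective per-second initiation probability psi_01 = n * lam."""
    if n < 1:
        raise ValueError("group size must be at least 1")
    return n * config.lam


def _kernel_factor(kernel: str, j: int, n: int) -> float:
    if kernel == "K1":
        return 1.0
    if kernel == "K2":
        return float(n - j)
    if kernel == "K3":
        return float(j * (n - j))
    raise ValueError(f"unknown kernel {kernel!r}")


def _psi_vector(
    net: SocialNetwork,
    moving_mask: np.ndarray,
    resting_idx: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Per-second departure probabilities for the resting agents."""
    j = int(moving_mask.sum())
    if j == 0:
        psi = np.full(resting_idx.size, config.lam)
    else:
        s = net.weights[np.ix_(resting_idx, np.flatnonzero(moving_mask))].sum(axis=1)
        psi = config.lam + config.M * _kernel_factor(config.kernel, j, net.n) * s
    return np.minimum(psi, _P_MAX)


def joining_probability(
    net: SocialNetwork,
    moving: Iterable[str],
    i: str,
    config: SimulationConfig,
) -> float:
    """Per-second probability that resting agent ``i`` joins the movement."""
    moving = set(moving)
    if i in moving:
        raise NetworkError(f"{i!r} is already moving")
    moving_mask = np.zeros(net.n, dtype=bool)
    for lab in moving:
        moving_mask[net.index(lab)] = True
    psi = _psi_vector(net, moving_mask, np.array([net.index(i)]), config)
    return float(psi[0])


def _scan_for_departure(
    rng: np.random.Generator, psi: np.ndarray, window: int
) -> tuple[int | None, np.ndarray | None]:
    """First second within ``window`` at which any agent's draw beats psi.

    Every resting agent draws one uniform per second; seconds are
    evaluated in vectorized blocks.  Returns ``(gap, mask)`` with ``gap``
    the 1-based offset of the departure second and ``mask`` the agents
    departing that second, or ``(None, None)`` if the window elapses.
    """
    done = 0
    while done < window:
        m = min(_BLOCK, window - done)
        hits = rng.random((m, psi.size)) < psi
        rows = hits.any(axis=1)
        if rows.any():
            r0 = int(np.argmax(rows))
            return done + r0 + 1, hits[r0]
        done += m
    return None, None


def _record_departures(
    net: SocialNetwork,
    rng: np.random.Generator,
    events: list[tuple[str, int]],
    resting_idx: np.ndarray,
    mask: np.ndarray,
    t: int,
) -> np.ndarray:
    """Append this second's departures (rank order randomized on ties)."""
    departers = resting_idx[mask]
    if departers.size > 1:
        departers = rng.permutation(departers)
    for idx in departers:
        events.append((net.labels[int(idx)], t))
    return resting_idx[~mask]


def run_replicate(
    net: SocialNetwork, config: SimulationConfig, rng: np.random.Generator
) -> DepartureRecord:
    """One replicate of the per-second Bernoulli departure process."""
    n = net.n
    moving_mask = np.zeros(n, dtype=bool)
    resting_idx = np.arange(n)
    events: list[tuple[str, int]] = []
    t = 0
    truncated = False
    while resting_idx.size:
        psi = _psi_vector(net, moving_mask, resting_idx, config)
        window = config.max_time - t if not events else min(
            config.stop_window, config.max_time - t
        )
        if window <= 0:
            truncated = True
            break
        gap, mask = _scan_for_departure(rng, psi, window)
        if gap is None:
            if events and window < config.stop_window:
                truncated = True  # max_time cut the stop window short
            break
        t += gap
        resting_idx = _record_departures(net, rng, events, resting_idx, mask, t)
        moving_mask = np.ones(n, dtype=bool)
        moving_mask[resting_idx] = False
    return DepartureRecord(
        events=tuple(events),
        n_total=n,
        void=not events,
        truncated=truncated,
    )


def event_driven_replicate(
    net: SocialNetwork, config: SimulationConfig, rng: np.random.Generator
) -> DepartureRecord:
    """Replicate sampled by geometric waiting times (verification oracle).

    Instead of drawing one uniform per agent per second, each resting
    agent's waiting time is sampled directly from the geometric
    distribution with its current probability; ties across agents
    reproduce simultaneous departures.  By memorylessness this is
    distributionally identical to :func:`run_replicate`.
    """
    n = net.n
    moving_mask = np.zeros(n, dtype=bool)
    resting_idx = np.arange(n)
    events: list[tuple[str, int]] = []
    t = 0
    truncated = False
    while resting_idx.size:
        psi = _psi_vector(net, moving_mask, resting_idx, config)
        window = config.max_time - t if not events else min(
            config.stop_window, config.max_time - t
        )
        if window <= 0:
            truncated = True
            break
        u = rng.random(resting_idx.size)
        waits = np.ceil(np.log1p(-u) / np.log1p(-psi)).astype(np.int64)
        waits = np.maximum(waits, 1)
        gap = int(waits.min())
        if gap > window:
            if events and window < config.stop_window:
                truncated = True
            break
        t += gap
        resting_idx = _record_departures(
            net, rng, events, resting_idx, waits == gap, t
        )
        moving_mask = np.ones(n, dtype=bool)
        moving_mask[resting_idx] = False
    return DepartureRecord(
        events=tuple(events),
        n_total=n,
        void=not events,
        truncated=truncated,
    )


def run_batch(
    net: SocialNetwork,
    config: SimulationConfig,
    replicate_fn=run_replicate,
) -> list[DepartureRecord]:
    """Run ``config.replicates`` independent replicates.

    Replicate ``r`` draws from the ``r``-th child of
    ``SeedSequence(config.seed)``, so results are bit-reproducible and
    independent of execution order.
    """
    logger.info(
        "batch: n=%d lam=%g M=%g kernel=%s stop_window=%d replicates=%d seed=%d",
        net.n, config.lam, config.M, config.kernel,
        config.stop_window, config.replicates, config.seed,
    )
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    records = []
    for r, child in enumerate(children):
        rec = replicate_fn(net, config, np.random.default_rng(child))
        records.append(replace(rec, replicate=r))
    n_void = sum(rec.void for rec in records)
    n_trunc = sum(rec.truncated for rec in records)
    if n_void or n_trunc:
        logger.warning("batch: %d void and %d truncated replicates", n_void, n_trunc)
    return records


# ---------------------------------------------------------------------------
# batch I/O: one row per replicate plus a long-format event sidecar
# ---------------------------------------------------------------------------


def batch_frame(records: Sequence[DepartureRecord]) -> pd.DataFrame:
    """Per-replicate summary table (one row per replicate)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "replicate": rec.replicate,
                "initiator": rec.initiator,
                "n_departed": rec.n_departed,
                "dt01": rec.initiation_time,
                "dt12": rec.first_joiner_latency,
                "dt1N": rec.duration,
                "void": rec.void,
                "truncated": rec.truncated,
            }
        )
    return pd.DataFrame(rows)


def write_batch(records: Sequence[DepartureRecord], path: str | Path) -> None:
    """Write replicate table to ``path`` and events to ``<path>.events``."""
    path = Path(path)
    batch_frame(records).to_csv(path, sep="\t", index=False)
    rows = [
        {"replicate": rec.replicate, "rank": k + 1, "individual": lab, "time": t}
        for rec in records
        for k, (lab, t) in enumerate(rec.events)
    ]
    pd.DataFrame(rows, columns=["replicate", "rank", "individual", "time"]).to_csv(
        path.with_suffix(path.suffix + ".events"), sep="\t", index=False
    )


def read_batch(path: str | Path, n_total: int) -> list[DepartureRecord]:
    """Rebuild records from the replicate table and its event sidecar."""
    path = Path(path)
    main = pd.read_csv(path, sep="\t")
    ev = pd.read_csv(path.with_suffix(path.suffix + ".events"), sep="\t")
    by_rep = {
        rep: [(str(r.individual), int(r.time)) for r in grp.sort_values("rank").itertuples()]
        for rep, grp in ev.groupby("replicate")
    }
    records = []
    for row in main.itertuples(index=False):
        events = tuple(by_rep.get(row.replicate, []))
        records.append(
            DepartureRecord(
                events=events,
                n_total=n_total,
                void=bool(row.void),
                truncated=bool(row.truncated),
                replicate=int(row.replicate),
            )
        )
    return records
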