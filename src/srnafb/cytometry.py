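"""Flow-cytometry-style summary statistics and event-table I/O.

Per-cell fluorescence from gated bacterial populations is close to
log-normal, so the two condition-level statistics reported are the
geometric mean and the log-normal coefficient of variation
``sqrt(exp(sigma^2) - 1)`` with ``sigma^2`` the unbiased variance of the
natural-log fluorescence.  Event tables are plain CSV (one row per gated
cell), the text stand-in for FCS-extracted raw reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuits import InducerInput

__all__ = [
    "EventSample",
    "DoseResponseTable",
    "geometric_mean",
    "lognormal_cov",
    "summarize_experiment",
    "events_to_csv",
    "events_from_csv",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ("condition_id", "u1", "u2", "u3", "replicate", "geo_mean", "cov")


def _as_positive_events(events: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(events, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("events must be a non-empty 1-D array")
    bad = np.nonzero(~(arr > 0) | ~np.isfinite(arr))[0]
    if bad.size:
        i = int(bad[0])
        raise ValueError(f"event at index {i} is not positive: {arr[i]!r}")
    return arr


def geometric_mean(events: Sequence[float] | np.ndarray) -> float:
    """Exponential of the mean natural-log fluorescence."""
    arr = _as_positive_events(events)
    return float(np.exp(np.mean(np.log(arr))))


def lognormal_cov(events: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation under a log-normal model.

    With ``sigma^2`` the unbiased (n-1) sample variance of the log
    events, returns ``sqrt(exp(sigma^2) - 1)`` -- the population CoV of a
    log-normal with that log-variance.  Requires at least two events.
    """
    arr = _as_positive_events(events)
    if arr.size < 2:
        raise ValueError("CoV requires at least two events")
    var = float(np.var(np.log(arr), ddof=1))
    return math.sqrt(math.expm1(var))


@dataclass(frozen=True)
class EventSample:
    """One replicate of one condition: per-cell fluorescence values [a.u.]."""

    condition_id: str
    replicate: int
    events: np.ndarray

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        object.__setattr__(self, "events", _as_positive_events(self.events))

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass(frozen=True)
class DoseResponseTable:
    """Per-condition, per-replicate geometric means and CoVs.

    Backed by a tidy DataFrame with columns ``condition_id, u1, u2, u3,
    replicate, geo_mean, cov`` (one row per condition x replicate).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"dose-response table missing columns {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("dose-response table is empty")
        if (self.data["geo_mean"] <= 0).any():
            raise ValueError("geometric means must be > 0")
        if (self.data["cov"].dropna() < 0).any():
            raise ValueError("CoV must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def conditions(self) -> pd.DataFrame:
        return (self.data[["condition_id", "u1", "u2", "u3"]]
                .drop_duplicates("condition_id").reset_index(drop=True))

    def condition_stats(self) -> pd.DataFrame:
        """Across-replicate mean and standard deviation of the geometric
        means, plus the replicate count, per condition."""
        g = self.data.groupby("condition_id", sort=False)
        stats = g.agg(u1=("u1", "first"), u2=("u2", "first"), u3=("u3", "first"),
                      geo_mean_mean=("geo_mean", "mean"),
                      geo_mean_sd=("geo_mean", "std"),
                      cov_mean=("cov", "mean"),
                      n_replicates=("replicate", "nunique"))
        return stats.reset_index()

    def to_csv(self, path: str) -> None:
        self.data.to_csv(path, index=False, float_format="%.15g",
                         columns=list(TABLE_COLUMNS))

    @classmethod
    def from_csv(cls, path: str) -> "DoseResponseTable":
        return cls(pd.read_csv(path))


def summarize_experiment(samples: Iterable[EventSample],
                         conditions: Mapping[str, InducerInput],
                         ) -> DoseResponseTable:
    """Reduce per-cell event samples to a dose-response table.

    ``conditions`` maps condition ids to their inducer levels.  Condition
    ids listed without any events are dropped with a warning; a replicate
    with a single event gets ``cov = NaN``.
    """
    rows = []
    seen: set[str] = set()
    for sample in samples:
        cid = sample.condition_id
        if cid not in conditions:
            raise KeyError(f"no inducer metadata for condition {cid!r}")
        u = conditions[cid]
        u1, u2, u3 = u.constants()
        cov = lognormal_cov(sample.events) if sample.n_events >= 2 else float("nan")
        rows.append({"condition_id": cid, "u1": u1, "u2": u2, "u3": u3,
                     "replicate": sample.replicate,
                     "geo_mean": geometric_mean(sample.events), "cov": cov})
        seen.add(cid)
    for cid in conditions:
        if cid not in seen:
            logger.warning("condition %r has no events and was dropped", cid)
    if not rows:
        raise ValueError("no events in any condition")
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    return DoseResponseTable(df)


def events_to_csv(samples: Iterable[EventSample], path: str) -> None:
    """Write one row per gated cell: ``condition_id, replicate, fluorescence``."""
    frames = [pd.DataFrame({"condition_id": s.condition_id,
                            "replicate": s.replicate,
                            "fluorescence": s.events})
              for s in samples]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def events_from_csv(path: str) -> list[EventSample]:
    df = pd.read_csv(path)
    samples = []
    for (cid, rep), grp in df.groupby(["condition_id", "replicate"], sort=False):
        samples.append(EventSample(condition_id=str(cid), replicate=int(rep),
                                   events=grp["fluorescence"].to_numpy()))
    return samples
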