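"""Build-up functions and per-trial percept classification.

The build-up of stream segregation is the rise, over the first seconds of a
sequence, in the probability of hearing the sounds as separate streams.  It
is estimated here by time-binned averaging of the binary percept indicator
across N simulated trials.  A per-trial classifier reduces each percept
trace to a single segregated/integrated label by majority vote inside a
decision window (for the delay-detection task: around the delayed event),
which is what the ideal observer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .competition import PerceptTrace

__all__ = ["BuildupFunction", "buildup_function", "classify_trial", "decision_window"]

DEFAULT_BIN_WIDTH = 0.1


@dataclass(frozen=True)
class BuildupFunction:
    """Time-binned proportion of segregated percept across trials."""

    bin_centers: np.ndarray
    proportion_segregated: np.ndarray
    n_trials: int
    bin_width: float

    def __post_init__(self) -> None:
        p = self.proportion_segregated
        if len(p) != len(self.bin_centers):
            raise ValueError("bin_centers and proportions must have equal length")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("proportions must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def mean_over(self, t_start: float, t_stop: float) -> float:
        """Mean proportion over bins whose centers fall in [t_start, t_stop)."""
        sel = (self.bin_centers >= t_start) & (self.bin_centers < t_stop)
        if not sel.any():
            raise ValueError("no bins in the requested interval")
        return float(self.proportion_segregated[sel].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_s": self.bin_centers,
                "proportion_segregated": self.proportion_segregated,
                "n_trials": self.n_trials,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None, **kwargs):
        """Convenience line plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_centers, self.proportion_segregated, **kwargs)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("proportion segregated")
        ax.set_ylim(0, 1)
        return ax


def _trace_matrix(traces: Sequence[PerceptTrace]) -> tuple[np.ndarray, np.ndarray]:
    if not traces:
        raise ValueError("need at least one percept trace")
    t = traces[0].t
    for tr in traces[1:]:
        if len(tr.t) != len(t) or not np.allclose(tr.t, t):
            raise ValueError("all traces must share the same time grid")
    return t, np.vstack([tr.segregated for tr in traces])


def buildup_function(
    traces: Sequence[PerceptTrace],
    bin_width: float = DEFAULT_BIN_WIDTH,
    t_start: float = 0.0,
) -> BuildupFunction:
    """Time-binned proportion of segregation across trials.

    Each bin's value is the mean of the segregated indicator over all trials
    and all samples falling inside the bin.  Samples before ``t_start``
    (e.g. pre-stimulus silence) are excluded.
    """
    t, seg = _trace_matrix(traces)
    dt = t[1] - t[0] if len(t) > 1 else bin_width
    if bin_width < dt - 1e-12:
        raise ValueError("bin_width must be >= the trace sampling interval")
    keep = t >= t_start
    t, seg = t[keep], seg[:, keep]
    idx = np.floor((t - t_start) / bin_width + 1e-9).astype(int)
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=seg.sum(axis=0), minlength=n_bins)
    prop = sums / (counts * seg.shape[0])
    centers = t_start + (np.arange(n_bins) + 0.5) * bin_width
    return BuildupFunction(
        bin_centers=centers,
        proportion_segregated=prop,
        n_trials=seg.shape[0],
        bin_width=bin_width,
    )


def classify_trial(trace: PerceptTrace, window_start: float, window_end: float) -> int:
    """Label a trial segregated (1) iff the majority of samples in
    ``[window_start, window_end)`` are segregated; exact 50/50 splits count
    as segregated."""
    sel = (trace.t >= window_start) & (trace.t < window_end)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("decision window contains no samples")
    return int(trace.segregated[sel].sum() * 2 >= n)


def decision_window(timeline, margin: float | None = None) -> tuple[float, float]:
    """Default decision window for the delay-detection task.

    Spans the last (delayed) B event plus/minus one inter-onset interval —
    the portion of the sequence where the temporal delay must be detected —
    clipped to the sequence span.
    """
    target = timeline.last_event("B")
    if margin is None:
        margin = timeline.spec.ioi if timeline.spec is not None else target.duration
    start = max(0.0, target.onset - margin)
    end = min(timeline.total_duration, target.offset + margin)
    return start, end
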