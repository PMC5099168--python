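"""Population statistics: firing rate, sparseness, pairwise coherence, and
representation distance.

* Sparseness S in [0, 1]: 1 when a single cell carries all activity, 0 when
  activity is uniform (Rolls-Tovee lifetime sparseness, sign-flipped so
  sparser responses score higher).
* Coherence c >= 0: observed spike coincidences in 2 ms bins compared with
  rate-matched homogeneous-Poisson surrogates, linearly rectified and
  averaged over sampled cell pairs.
* Distance D in [0, 1] (for non-negative activity): one minus the cosine of
  the angle between two population activity vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeRaster",
    "MetricsRecord",
    "sparseness",
    "coherence",
    "distance",
    "mean_rate",
]


@dataclass
class SpikeRaster:
    """Spike times per unit over one recording window.

    ``events`` holds one strictly increasing array of spike times (ms) per
    unit; ``bin_width`` is the analysis bin used by the coherence measure.
    """

    events: list[np.ndarray]
    duration: float
    bin_width: float = 2.0

    def __post_init__(self) -> None:
        self.events = [np.asarray(e, dtype=float) for e in self.events]
        for i, e in enumerate(self.events):
            if e.size and (e.min() < 0 or e.max() > self.duration):
                raise ValueError(f"unit {i}: spike times outside [0, duration]")
            if e.size > 1 and np.any(np.diff(e) <= 0):
                raise ValueError(f"unit {i}: spike times must be strictly increasing")

    @property
    def n_units(self) -> int:
        return len(self.events)

    @classmethod
    def from_spike_matrix(
        cls, fired: np.ndarray, dt: float, bin_width: float = 2.0
    ) -> "SpikeRaster":
        """Build from a (n_steps, n_units) 0/1 matrix sampled every ``dt`` ms.
        A spike in step k is stamped at the step's midpoint."""
        fired = np.asarray(fired)
        n_steps = fired.shape[0]
        times = (np.arange(n_steps) + 0.5) * dt
        events = [times[fired[:, j] > 0] for j in range(fired.shape[1])]
        return cls(events=events, duration=n_steps * dt, bin_width=bin_width)

    def binned(self) -> np.ndarray:
        """Binary spike indicator per (bin, unit) at ``bin_width`` resolution."""
        k = int(np.ceil(self.duration / self.bin_width))
        out = np.zeros((k, self.n_units), dtype=bool)
        for j, e in enumerate(self.events):
            if e.size:
                idx = np.minimum((e / self.bin_width).astype(int), k - 1)
                out[idx, j] = True
        return out

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        unit = np.concatenate([np.full(e.size, j) for j, e in enumerate(self.events)]) \
            if any(e.size for e in self.events) else np.array([], dtype=int)
        t = np.concatenate([e for e in self.events]) if self.events else np.array([])
        pd.DataFrame({"unit_id": unit.astype(int), "spike_time_ms": t}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, n_units: int, duration: float) -> "SpikeRaster":
        import pandas as pd

        df = pd.read_csv(path)
        events = [
            np.sort(df.loc[df["unit_id"] == j, "spike_time_ms"].to_numpy())
            for j in range(n_units)
        ]
        return cls(events=events, duration=duration)


@dataclass
class MetricsRecord:
    """Derived statistics of one presentation window."""

    mean_rate: dict[str, float] = field(default_factory=dict)
    sparseness: dict[str, float] = field(default_factory=dict)
    coherence: dict[str, float] = field(default_factory=dict)
    distance: float | None = None
    M_mean: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean_rate": self.mean_rate,
            "sparseness": self.sparseness,
            "coherence": self.coherence,
            "distance": self.distance,
            "M_mean": self.M_mean,
            **self.extra,
        }


def sparseness(R: np.ndarray) -> float:
    """Population sparseness of a non-negative rate vector.

    ``S = [1 - (mean(R)^2 / mean(R^2))] / (1 - 1/N)``: 1 when exactly one
    cell is active, 0 when all cells share the same rate.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 1 or R.size < 2:
        raise ValueError("R must be a vector of at least two rates")
    if np.any(R < 0):
        raise ValueError("rates must be non-negative")
    sum_sq = float(np.mean(R) ** 2)
    sq_sum = float(np.mean(R**2))
    if sq_sum == 0:
        raise ValueError("sparseness undefined for an all-zero rate vector")
    n = R.size
    return (1.0 - sum_sq / sq_sum) / (1.0 - 1.0 / n)


def coherence(
    raster: SpikeRaster,
    n_pairs: int = 500,
    rng: int | np.random.Generator | None = None,
    pairs: np.ndarray | None = None,
) -> float:
    """Mean pairwise coherence against rate-matched Poisson surrogates.

    For each sampled pair (i, j): bin both trains at ``raster.bin_width``,
    count coincident bins, and compare with the coincidences of one draw of
    independent surrogate trains with the same per-unit rates:
    ``c_ij = max(0, 1 - surrogate/observed)``.  Pairs with no observed
    coincidences contribute 0.  Returns the average over pairs.
    """
    if raster.n_units < 2:
        raise ValueError("need at least two units")
    if all(e.size == 0 for e in raster.events):
        raise ValueError("empty raster")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = raster.binned()  # (K, n)
    k = x.shape[0]
    if pairs is None:
        n = raster.n_units
        i = rng.integers(0, n, size=2 * n_pairs)
        j = rng.integers(0, n, size=2 * n_pairs)
        keep = i != j
        pairs = np.stack([i[keep][:n_pairs], j[keep][:n_pairs]], axis=1)
    # per-unit probability of a spike in a bin, for the surrogate trains
    p = x.mean(axis=0)
    c_vals = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        observed = int(np.sum(x[:, i] & x[:, j]))
        if observed == 0:
            c_vals[idx] = 0.0
            continue
        si = rng.random(k) < p[i]
        sj = rng.random(k) < p[j]
        surrogate = int(np.sum(si & sj))
        c_vals[idx] = max(0.0, 1.0 - surrogate / observed)
    return float(np.mean(c_vals))


def distance(O1: np.ndarray, O2: np.ndarray) -> float:
    """Representation distance: one minus the normalised dot product."""
    O1 = np.asarray(O1, dtype=float)
    O2 = np.asarray(O2, dtype=float)
    if O1.shape != O2.shape:
        raise ValueError("activity vectors must have the same shape")
    n1, n2 = np.linalg.norm(O1), np.linalg.norm(O2)
    if n1 == 0 or n2 == 0:
        raise ValueError("distance undefined for a zero-norm activity vector")
    return float(1.0 - float(O1 @ O2) / (n1 * n2))


def mean_rate(
    raster: SpikeRaster, window: tuple[float, float] | None = None
) -> tuple[np.ndarray, float]:
    """Firing rate in Hz per unit over ``window`` (ms), and the group mean."""
    if window is None:
        window = (0.0, raster.duration)
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= raster.duration):
        raise ValueError("window must be a non-empty interval within the recording")
    span_s = (t1 - t0) / 1000.0
    counts = np.array([np.sum((e >= t0) & (e < t1)) for e in raster.events], dtype=float)
    rates = counts / span_s
    return rates, float(np.mean(rates))
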