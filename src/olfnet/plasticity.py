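"""ACh-gated Hebbian plasticity on the pyramidal association fibers.

Recurrent Pyr->Pyr weights grow when a presynaptic spike (through a slow
NMDA-receptor glutamate-binding trace, delayed by the axonal conduction
time) coincides with postsynaptic suprathreshold depolarisation, scaled by
the cholinergic modulation level M and a soft saturation factor
(1 - w/w_max):

    dw_ij/dt = M * (1 - w_ij/w_max) * i_post_i * b_glu_j(t - t_delay) / tau_pp

With M = 0 (full recall mode) the weights are frozen; with M = 1 learning
proceeds at full rate.  Weights live in [0, w_max] with a structurally zero
diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

__all__ = [
    "WeightMatrix",
    "GluTrace",
    "init_weights",
    "glu_trace_update",
    "hebbian_step",
    "normalized_weights",
    "weight_entropy",
    "save_weights",
    "load_weights",
]


@dataclass
class WeightMatrix:
    """Pyr x Pyr association-fiber weights (rows = postsynaptic)."""

    w: np.ndarray
    w_max: float = 0.4
    tau_pp: float = 40000.0
    t_delay: float = 1.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        self.w = w

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy(), self.w_max, self.tau_pp, self.t_delay)


@dataclass
class GluTrace:
    """Per-presynaptic-unit NMDA glutamate-binding trace.

    The default ("product") kinetics follow the literal product of two
    decaying exponentials, b(t) = exp(-t/tau_fall) * exp(-t/tau_rise), which
    restarts at 1 on each presynaptic spike and decays with effective time
    constant (1/tau_fall + 1/tau_rise)^-1.  The alternative "difference"
    mode uses the conventional difference of exponentials with a genuine
    rise phase.
    """

    b: np.ndarray
    tau_fall: float = 100.0
    tau_rise: float = 10.0
    mode: str = "product"
    # second state variable, used by the "difference" mode only
    b_rise: np.ndarray | None = None

    @classmethod
    def zeros(cls, n: int, tau_fall: float = 100.0, tau_rise: float = 10.0,
              mode: str = "product") -> "GluTrace":
        if mode not in ("product", "difference"):
            raise ValueError(f"unknown trace mode {mode!r}")
        return cls(
            b=np.zeros(n), tau_fall=tau_fall, tau_rise=tau_rise, mode=mode,
            b_rise=np.zeros(n) if mode == "difference" else None,
        )

    @property
    def effective_tau(self) -> float:
        """Decay constant of the product form."""
        return 1.0 / (1.0 / self.tau_fall + 1.0 / self.tau_rise)

    def copy(self) -> "GluTrace":
        return GluTrace(
            self.b.copy(), self.tau_fall, self.tau_rise, self.mode,
            None if self.b_rise is None else self.b_rise.copy(),
        )


def init_weights(
    n: int,
    seed: int | np.random.Generator,
    w_max: float = 0.4,
    w_init_max: float = 0.04,
    tau_pp: float = 40000.0,
    t_delay: float = 1.0,
) -> WeightMatrix:
    """Uniform random initial weights on [0, w_init_max] (~10% of w_max),
    zero diagonal, deterministic under the seed."""
    if n < 2:
        raise ValueError("need at least two units")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.uniform(0.0, w_init_max, size=(n, n))
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, w_max=w_max, tau_pp=tau_pp, t_delay=t_delay)


def glu_trace_update(trace: GluTrace, pre_fired: np.ndarray, dt: float) -> GluTrace:
    """Advance the trace one step; units whose delayed presynaptic spike
    arrives this step restart at the t=0 value (most recent spike wins)."""
    spiked = np.asarray(pre_fired, dtype=bool)
    out = trace.copy()
    if trace.mode == "product":
        decay = np.exp(-dt / trace.effective_tau)
        out.b = np.where(spiked, 1.0, trace.b * decay)
    else:
        # difference of exponentials: two state variables, both bumped on a spike
        df = np.exp(-dt / trace.tau_fall)
        dr = np.exp(-dt / trace.tau_rise)
        out.b = trace.b * df + spiked
        out.b_rise = trace.b_rise * dr + spiked
    return out


def trace_value(trace: GluTrace) -> np.ndarray:
    """Current trace value entering the Hebbian product."""
    if trace.mode == "product":
        return trace.b
    return trace.b - trace.b_rise


def hebbian_step(
    W: WeightMatrix,
    M: float,
    post_depol: np.ndarray,
    trace: GluTrace,
    dt: float,
) -> WeightMatrix:
    """One Euler step of the gated Hebbian rule.

    ``post_depol`` is the rectified suprathreshold depolarisation of each
    postsynaptic unit (max(v - theta_min, 0), mV); ``trace`` carries the
    delayed presynaptic NMDA signal.  Weight change is the outer product of
    the two, gated by M and the soft saturation factor, and clipped to
    [0, w_max].
    """
    post = np.asarray(post_depol, dtype=float)
    if np.any(post < 0):
        raise ValueError("post_depol must be rectified (>= 0)")
    out = W.copy()
    if M == 0.0:
        return out
    pre = trace_value(trace)
    dw = (dt * M / W.tau_pp) * (1.0 - W.w / W.w_max) * np.outer(post, pre)
    out.w = np.clip(W.w + dw, 0.0, W.w_max)
    np.fill_diagonal(out.w, 0.0)
    return out


def normalized_weights(W: WeightMatrix | np.ndarray) -> np.ndarray:
    """Weights normalised to unit total mass, W' = W / sum(W)."""
    w = W.w if isinstance(W, WeightMatrix) else np.asarray(W, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero weight matrix")
    return w / total


def weight_entropy(W: WeightMatrix | np.ndarray) -> float:
    """Shannon entropy (nats) of the normalised weight distribution; falls
    as learning concentrates mass on the trained pattern's connections."""
    p = normalized_weights(W).ravel()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def save_weights(W: WeightMatrix, path: str | Path, **metadata) -> None:
    """Dense binary container (.npz) with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, w=W.w)
    meta = dict(w_max=W.w_max, tau_pp=W.tau_pp, t_delay=W.t_delay, **metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_weights(path: str | Path) -> WeightMatrix:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    w = np.load(path)["w"]
    meta_path = path.with_suffix(".json")
    kwargs = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kwargs = {k: meta[k] for k in ("w_max", "tau_pp", "t_delay") if k in meta}
    return WeightMatrix(w, **kwargs)
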