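"""Single-unit dynamics shared by every cell group in the circuit.

All populations are leaky integrators (``tau dv/dt + v = V_ext``) with a
piecewise power-law output nonlinearity ``F(v)``.  Graded groups (sensory
neurons, periglomerular cells) transmit ``F(v)`` continuously; spiking groups
use ``F(v)`` as a per-step firing probability, reset to a hyperpolarised
potential after a spike, and sit out a refractory period.  Pyramidal cells
additionally carry a slow after-hyperpolarisation (AHC) conductance that
raises their effective threshold when cholinergic tone is low.

Everything here is vectorised over the units of one population; the network
module composes these primitives into the full circuit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationSpec",
    "PopulationState",
    "KernelParams",
    "output_activation",
    "conductance_kernel",
    "kernel_peak_time",
    "synaptic_drive",
    "integrate_step",
    "spike_draw",
    "adaptation_step",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of one homogeneous cell group.

    Parameters
    ----------
    name : str
        Group label (``"Pyr"``, ``"Mi_soma"``, ...).
    n : int
        Number of units in the group.
    spiking : bool
        Spiking (probabilistic, refractory) vs graded (rate) output.
    tau : float
        Membrane time constant in ms.
    beta : float
        Exponent of the output nonlinearity (>= 1).
    theta_min, theta_max : float
        Output threshold and saturation potentials in mV.  A negative
        ``theta_min`` makes the group spontaneously active at rest.
    v_hyper : float
        Post-spike reset potential in mV.
    t_refrac : float
        Absolute refractory period in ms.
    ahc_amplitude : float
        Increment of the spike-frequency-adaptation variable per spike step
        (0 disables adaptation).
    ahc_tau : float
        Adaptation decay time constant in ms.
    ahc_E : float
        Reversal potential of the adaptation conductance in mV.
    """

    name: str
    n: int
    spiking: bool
    tau: float
    beta: float
    theta_min: float
    theta_max: float
    v_hyper: float = -10.0
    t_refrac: float = 2.0
    ahc_amplitude: float = 0.0
    ahc_tau: float = 100.0
    ahc_E: float = -15.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.name}: population size must be >= 1")
        if self.theta_max <= self.theta_min:
            raise ValueError(f"{self.name}: theta_max must exceed theta_min")
        if self.tau <= 0:
            raise ValueError(f"{self.name}: tau must be positive")
        if self.t_refrac < 0:
            raise ValueError(f"{self.name}: t_refrac must be >= 0")
        if self.beta < 1:
            raise ValueError(f"{self.name}: beta must be >= 1")

    @property
    def has_adaptation(self) -> bool:
        return self.ahc_amplitude != 0.0


@dataclass
class PopulationState:
    """Evolving per-unit state of one group (membrane, refractoriness, AHC)."""

    v: np.ndarray
    refrac_remaining: np.ndarray
    fired: np.ndarray
    ahc: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "PopulationState":
        return cls(
            v=np.zeros(n),
            refrac_remaining=np.zeros(n),
            fired=np.zeros(n),
            ahc=np.zeros(n),
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.v.copy(),
            self.refrac_remaining.copy(),
            self.fired.copy(),
            self.ahc.copy(),
        )


@dataclass(frozen=True)
class KernelParams:
    """Difference-of-exponentials conductance kernel.

    ``g(t) = g_max * (exp(-t/tau_decay) - exp(-t/tau_rise))`` — zero at the
    spike time, a single interior maximum, decaying back to zero.  ``g_max``
    is dimensionless; the product ``w * g * (E_N - v)`` is taken directly in
    mV.
    """

    g_max: float
    tau_rise: float
    tau_decay: float
    E_N: float

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= 0:
            raise ValueError("kernel time constants must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")


def output_activation(v: np.ndarray | float, spec: PopulationSpec) -> np.ndarray | float:
    """Output nonlinearity F(v): 0 below threshold, 1 at saturation,
    ``((v - theta_min)/(theta_max - theta_min))**beta`` in between.

    For graded groups this is the transmitted rate; for spiking groups the
    per-step firing probability.
    """
    x = (np.asarray(v, dtype=float) - spec.theta_min) / (spec.theta_max - spec.theta_min)
    out = np.clip(x, 0.0, 1.0) ** spec.beta
    if np.isscalar(v):
        return float(out)
    return out


def conductance_kernel(t_elapsed: np.ndarray | float, k: KernelParams) -> np.ndarray | float:
    """Kernel value at ``t_elapsed`` ms after a presynaptic spike."""
    t = np.asarray(t_elapsed, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_elapsed must be >= 0")
    g = k.g_max * (np.exp(-t / k.tau_decay) - np.exp(-t / k.tau_rise))
    if np.isscalar(t_elapsed):
        return float(g)
    return g


def kernel_peak_time(k: KernelParams) -> float:
    """Time of the kernel maximum: where the two exponentials' slopes cancel."""
    tr, td = k.tau_rise, k.tau_decay
    return tr * td / (td - tr) * np.log(td / tr)


def synaptic_drive(
    w: np.ndarray | float,
    g: np.ndarray | float,
    E_N: float,
    v_post: np.ndarray | float,
) -> np.ndarray | float:
    """Voltage contribution of one synapse: ``w * g * (E_N - v_post)`` (mV)."""
    return w * g * (E_N - v_post)


def integrate_step(
    state: PopulationState,
    v_ext: np.ndarray,
    dt: float,
    spec: PopulationSpec,
) -> PopulationState:
    """One forward-Euler membrane step: ``v += (dt/tau) * (v_ext - v)``.

    Refractory units do not integrate: they hold ``v_hyper``.  The
    refractory clock itself is advanced by :func:`spike_draw`, after the
    eligibility check, so a unit firing at step k stays silent for exactly
    ``t_refrac`` and may fire again at step k + t_refrac/dt + 1.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v_ext = np.asarray(v_ext, dtype=float)
    if v_ext.shape != state.v.shape:
        raise ValueError(
            f"{spec.name}: v_ext shape {v_ext.shape} != state shape {state.v.shape}"
        )
    refractory = state.refrac_remaining > 0
    v = np.where(
        refractory,
        spec.v_hyper,
        state.v + (dt / spec.tau) * (v_ext - state.v),
    )
    return PopulationState(v=v, refrac_remaining=state.refrac_remaining,
                           fired=state.fired, ahc=state.ahc)


def spike_draw(
    activation: np.ndarray,
    state: PopulationState,
    rng: np.random.Generator,
    spec: PopulationSpec,
    dt: float = 0.5,
) -> PopulationState:
    """Bernoulli spike draw at probability ``activation`` for non-refractory
    units; firing units reset to ``v_hyper`` and start their refractory
    clock, while refractory units count down by ``dt``.
    """
    if not spec.spiking:
        raise ValueError(f"{spec.name} is a graded group; spike_draw does not apply")
    activation = np.asarray(activation, dtype=float)
    eligible = state.refrac_remaining <= 0
    fired = (rng.random(spec.n) < activation) & eligible
    v = np.where(fired, spec.v_hyper, state.v)
    refrac = np.where(fired, spec.t_refrac,
                      np.maximum(state.refrac_remaining - dt, 0.0))
    return PopulationState(
        v=v, refrac_remaining=refrac, fired=fired.astype(float), ahc=state.ahc
    )


def adaptation_step(
    state: PopulationState,
    dt: float,
    spec: PopulationSpec,
    ahc_amplitude: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the adaptation variable and return its voltage contribution.

    ``ahc += (dt/ahc_tau) * (A * X - ahc)`` where ``X`` is 1 in the step
    after the unit fired.  The contribution to the external drive is
    conductance-like, ``ahc * (ahc_E - v)``, with a hyperpolarising reversal
    potential.  ``ahc_amplitude`` may override the group's value (cholinergic
    modulation scales it towards zero).

    Returns ``(new_ahc, v_contribution)``.
    """
    amp = spec.ahc_amplitude if ahc_amplitude is None else ahc_amplitude
    x = state.fired  # 1 in the time step after a spike
    ahc = state.ahc + (dt / spec.ahc_tau) * (amp * x - state.ahc)
    contribution = ahc * (spec.ahc_E - state.v)
    return ahc, contribution
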