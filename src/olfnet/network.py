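"""The full circuit: olfactory bulb, piriform cortex, and HDB.

Ten coupled populations of 100 units each (the mitral cell contributes an
apical and a somatic compartment) wired by thirteen projections:

    OSN -> PG, OSN -> Mi(apical), PG -> Mi(apical)         (glomerular, 1:1)
    Mi(soma) <-> Gr, Mi(soma) -> Ff, Mi(soma) -> Pyr        (bulb <-> cortex)
    Ff -> Pyr, Pyr -> Fb, Fb -> Pyr, Pyr -> Pyr (plastic)   (cortex)
    Pyr -> Gb, Gb -> Ac                                     (HDB loop)

Within a time step the populations advance in anatomical feed-forward
order; synaptic events take effect on the following step, so the update is
order-independent except for the electrical coupling of the two mitral
compartments (the apical potential drives the soma within the same step).

Cholinergic modulation closes the loop: Ac firing is filtered into the
activation trace A, mapped to the modulation level M, and M linearly
rescales the ACh-sensitive parameters on every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np

from .core import (
    KernelParams,
    PopulationSpec,
    PopulationState,
    adaptation_step,
    integrate_step,
    output_activation,
    spike_draw,
)
from .neuromodulation import (
    ModulatedParamTable,
    ModulationState,
    ach_modulation,
    interpolate_params,
    update_activation,
)
from ._kernels import plasticity_kernel, step_kernel
from .odors import OdorPattern
from .params import GRADED_GROUPS, default_config
from .plasticity import (
    GluTrace,
    WeightMatrix,
    glu_trace_update,
    hebbian_step,
    init_weights,
    trace_value,
)

__all__ = [
    "ConnectionSpec",
    "OlfactoryNetwork",
    "build_network",
    "step_network",
    "osn_transduce",
]

#: population update order within a step (anatomical feed-forward order)
UPDATE_ORDER = (
    "OSN", "PG", "Mi_apical", "Mi_soma", "Gr", "Ff", "Pyr", "Fb", "Gb", "Ac",
)


@dataclass
class ConnectionSpec:
    """One directed projection with its incidence mask and kernel state."""

    label: str
    source: str
    target: str
    mask: np.ndarray          # (n_target, n_source) float 0/1
    kernel: KernelParams
    plastic: bool = False
    normalize: bool = False   # drive normalised by the recurrent divisor
    graded: bool = False      # continuous (rate) transmission from the source
    identity: bool = False    # one-to-one glomerular wiring (mask is eye)
    _decay_d: float = 0.0     # cached per-step decay factors, set at build
    _decay_r: float = 0.0

    # kernel state: difference-of-exponentials superposition for spiking
    # sources, a two-pole low-pass of the source rate for graded sources
    z_decay: np.ndarray | None = None
    z_rise: np.ndarray | None = None

    def reset_state(self) -> None:
        n_src = self.mask.shape[1]
        self.z_decay = np.zeros(n_src)
        self.z_rise = np.zeros(n_src)

    def advance(self, dt: float, source_output: np.ndarray) -> None:
        """Fold the previous step's source output into the kernel state."""
        k = self.kernel
        if self.graded:
            # unit-DC-gain two-pole low-pass of the continuous rate
            self.z_rise += (dt / k.tau_rise) * (source_output - self.z_rise)
            self.z_decay += (dt / k.tau_decay) * (self.z_rise - self.z_decay)
        else:
            self.z_decay = (self.z_decay + source_output) * np.exp(-dt / k.tau_decay)
            self.z_rise = (self.z_rise + source_output) * np.exp(-dt / k.tau_rise)

    def conductance_per_source(self) -> np.ndarray:
        """Unit-amplitude kernel value per presynaptic unit (g_max applied
        by the caller, which may modulate it)."""
        if self.graded:
            return self.z_decay
        return self.z_decay - self.z_rise


class OlfactoryNetwork:
    """The assembled circuit with its evolving state.

    Build with :func:`build_network` (or ``OlfactoryNetwork(config, seed)``);
    advance with :meth:`step`; convenience runners :meth:`run` and
    :meth:`odor_signature` handle recording and state hygiene.
    """

    def __init__(self, config: dict[str, Any] | None = None, seed: int = 0):
        self.config = config if config is not None else default_config()
        self.seed = int(seed)
        sim = self.config["simulation"]
        self.dt = float(sim["dt"])
        self.n_units = int(sim["n_units"])
        self.osn_gain = float(sim["osn_gain"])

        ss = np.random.SeedSequence(self.seed)
        build_ss, run_ss = ss.spawn(2)
        build_rng = np.random.default_rng(build_ss)
        self.rng = np.random.default_rng(run_ss)

        self.specs: dict[str, PopulationSpec] = {}
        for name, row in self.config["populations"].items():
            self.specs[name] = PopulationSpec(name=name, n=self.n_units, **row)

        self.connections: list[ConnectionSpec] = []
        for label, row in self.config["synapses"].items():
            self.connections.append(self._build_connection(label, row, build_rng))

        pcfg = self.config["plasticity"]
        self.W = init_weights(
            self.n_units,
            build_rng,
            w_max=float(pcfg["w_max"]),
            w_init_max=float(pcfg["w_init_max"]),
            tau_pp=float(pcfg["tau_pp"]),
            t_delay=float(pcfg["t_delay"]),
        )
        self._delay_steps = max(1, int(round(self.W.t_delay / self.dt)))
        self._recurrent_divisor = float(pcfg.get("recurrent_divisor", self.n_units))
        self._learning_threshold = float(pcfg.get("learning_threshold", 0.0))
        self._trace_cfg = dict(
            tau_fall=float(pcfg["tau_nmda_fall"]),
            tau_rise=float(pcfg["tau_nmda_rise"]),
            mode=str(pcfg["trace_mode"]),
        )

        self.mod_table = ModulatedParamTable.from_config(self.config["modulated"])
        self._neuro_cfg = self.config["neuromodulation"]

        # runtime switches
        self.plasticity_enabled = True
        self.modulation_enabled = True
        self.clamp_M: float | None = None
        self.lesions: set[str] = set()

        self._build_packed()
        self.reset_state()

    # ------------------------------------------------------------------ build

    def _build_connection(
        self, label: str, row: dict[str, Any], rng: np.random.Generator
    ) -> ConnectionSpec:
        source, target = row["source"], row["target"]
        if source not in self.config["populations"]:
            raise ValueError(f"{label}: unknown source group {source}")
        if target not in self.config["populations"]:
            raise ValueError(f"{label}: unknown target group {target}")
        n = self.n_units
        kind = row.get("mask", "density")
        if kind == "identity":
            mask = np.eye(n)
        elif kind == "full_no_self":
            mask = 1.0 - np.eye(n)
        elif kind == "density":
            density = float(row["density"])
            if not 0.0 < density <= 1.0:
                raise ValueError(f"{label}: density must lie in (0, 1]")
            k = int(round(density * n))
            mask = np.zeros((n, n))
            for i in range(n):
                mask[i, rng.choice(n, size=k, replace=False)] = 1.0
        else:
            raise ValueError(f"{label}: unknown mask kind {kind!r}")
        kernel = KernelParams(
            g_max=float(row["g_max"]),
            tau_rise=float(row["tau_rise"]),
            tau_decay=float(row["tau_decay"]),
            E_N=float(row["E_N"]),
        )
        conn = ConnectionSpec(
            label=label,
            source=source,
            target=target,
            mask=mask,
            kernel=kernel,
            plastic=bool(row.get("plastic", False)),
            normalize=bool(row.get("normalize", False)),
            graded=source in GRADED_GROUPS,
            identity=(kind == "identity"),
        )
        conn._decay_d = float(np.exp(-self.dt / kernel.tau_decay))
        conn._decay_r = float(np.exp(-self.dt / kernel.tau_rise))
        conn.reset_state()
        return conn

    def _build_packed(self) -> None:
        """Pack populations and projections into contiguous arrays for the
        compiled step kernel."""
        names = list(UPDATE_ORDER)
        if set(names) != set(self.specs):
            raise ValueError("population set must match the circuit layout")
        self._pop_names = names
        self._pop_index = {name: i for i, name in enumerate(names)}
        P, N = len(names), self.n_units
        self._tau_m = np.array([self.specs[g].tau for g in names])
        self._beta = np.array([self.specs[g].beta for g in names])
        self._tmin_base = np.array([self.specs[g].theta_min for g in names])
        self._tmax_base = np.array([self.specs[g].theta_max for g in names])
        self._vhyper = np.array([self.specs[g].v_hyper for g in names])
        self._trefrac = np.array([self.specs[g].t_refrac for g in names])
        self._spiking = np.array([self.specs[g].spiking for g in names])
        C = len(self.connections)
        # presynaptic index lists per target row (padded to the widest row)
        kmax = max(int(c.mask.sum(axis=1).max()) for c in self.connections)
        self._idx = np.zeros((C, N, kmax), dtype=np.int64)
        self._kcount = np.zeros(C, dtype=np.int64)
        for ci, c in enumerate(self.connections):
            counts = c.mask.sum(axis=1).astype(int)
            if c.plastic or c.identity:
                self._kcount[ci] = 0 if c.plastic else 1
                continue
            if len(set(counts)) != 1:
                raise ValueError(f"{c.label}: rows must have equal in-degree")
            kc = counts[0]
            self._kcount[ci] = kc
            for i in range(N):
                self._idx[ci, i, :kc] = np.flatnonzero(c.mask[i])
        self._g_base = np.array([c.kernel.g_max for c in self.connections])
        self._e_n = np.array([c.kernel.E_N for c in self.connections])
        self._dec_d = np.array([c._decay_d for c in self.connections])
        self._dec_r = np.array([c._decay_r for c in self.connections])
        self._tau_d = np.array([c.kernel.tau_decay for c in self.connections])
        self._tau_r = np.array([c.kernel.tau_rise for c in self.connections])
        self._graded = np.array([c.graded for c in self.connections])
        self._plastic = np.array([c.plastic for c in self.connections])
        self._identity = np.array([c.identity for c in self.connections])
        self._src = np.array([self._pop_index[c.source] for c in self.connections])
        self._tgt = np.array([self._pop_index[c.target] for c in self.connections])
        self._conn_index = {c.label: i for i, c in enumerate(self.connections)}
        # modulated-parameter table resolved against the packed layout:
        # (kind, index, without, with) with kind 0=theta_min, 1=theta_max,
        # 2=synaptic g_max, 3=pyramidal adaptation amplitude
        self._mod_entries: list[tuple[int, int, float, float]] = []
        for target, param, w0, w1 in self.mod_table.entries:
            if target in self._pop_index and param == "theta_min":
                self._mod_entries.append((0, self._pop_index[target], w0, w1))
            elif target in self._pop_index and param == "theta_max":
                self._mod_entries.append((1, self._pop_index[target], w0, w1))
            elif target in self._conn_index and param == "g_max":
                self._mod_entries.append((2, self._conn_index[target], w0, w1))
            elif target == "Pyr" and param == "ahc_amplitude":
                self._mod_entries.append((3, 0, w0, w1))
            else:
                raise ValueError(f"cannot modulate {param!r} of {target!r}")

    # ------------------------------------------------------------------ state

    def reset_state(self) -> None:
        """Reset membranes, conductances, adaptation, traces and the
        cholinergic filter to rest.  Weights persist."""
        P, N = len(self._pop_names), self.n_units
        self._v = np.zeros((P, N))
        self._refrac = np.zeros((P, N))
        self._fired = np.zeros((P, N))
        self._outputs_arr = np.zeros((P, N))
        self._ahc = np.zeros(N)
        self.states = {}
        for name, p in self._pop_index.items():
            self.states[name] = PopulationState(
                v=self._v[p],
                refrac_remaining=self._refrac[p],
                fired=self._fired[p],
                ahc=self._ahc if name == "Pyr" else np.zeros(N),
            )
        self._zd = np.zeros((len(self.connections), N))
        self._zr = np.zeros((len(self.connections), N))
        for i, conn in enumerate(self.connections):
            conn.z_decay = self._zd[i]
            conn.z_rise = self._zr[i]
        self.glu = GluTrace.zeros(self.n_units, **self._trace_cfg)
        self._pyr_delay = [np.zeros(self.n_units) for _ in range(self._delay_steps)]
        # shadow depolarisation for the learning rule: the pyramidal membrane
        # equation integrated without spike resets, so the Hebbian
        # postsynaptic term reflects the drive a cell receives rather than
        # its post-spike hyperpolarisation
        self._pyr_depol = np.zeros(self.n_units)
        self.mod = ModulationState.from_config(self._neuro_cfg)
        self._outputs = {name: self._outputs_arr[p] for name, p in self._pop_index.items()}
        # preallocated step buffers
        self._delay_buf = np.zeros(self.n_units)
        self._pyr_drive = np.zeros(self.n_units)
        self._zero_drive = np.zeros(self.n_units)
        self._last_odor = None
        self._last_drive = None
        self._glu_decay = float(np.exp(-self.dt / self.glu.effective_tau))

    def reseed_run(self, seed: int) -> None:
        """Replace the run-time random stream (masks/weights untouched)."""
        self.rng = np.random.default_rng(seed)

    # ------------------------------------------------------------------- step

    def effective_params(self, M: float):
        """Effective per-group specs and per-synapse g_max at modulation M
        (inspection helper; the step loop applies the same interpolation)."""
        overrides = interpolate_params(M, self.mod_table)
        spec_over: dict[str, dict[str, float]] = {}
        g_over: dict[str, float] = {}
        for (target, param), value in overrides.items():
            if target in self.specs:
                spec_over.setdefault(target, {})[param] = value
            else:
                g_over[target] = value
        eff_specs = dict(self.specs)
        for name, kv in spec_over.items():
            eff_specs[name] = replace(self.specs[name], **kv)
        return eff_specs, g_over

    def step(
        self,
        odor: OdorPattern | None = None,
        clamp: dict[str, np.ndarray] | None = None,
    ) -> dict[str, np.ndarray]:
        """Advance the whole circuit by one Euler step.

        ``odor`` drives the sensory layer (``None`` = no stimulus);
        ``clamp`` optionally forces the firing state of named groups (used
        by the loop-polarity diagnostics).  Returns this step's firing
        state per group (views of internal buffers; copy to keep).

        The heavy lifting happens in the compiled kernel
        (:func:`olfnet._kernels.step_kernel`), an inline equivalent of
        composing core.integrate_step / output_activation / spike_draw /
        adaptation_step per population in anatomical order.
        """
        dt = self.dt
        M = self.mod.M if self.clamp_M is None else self.clamp_M
        if not self.modulation_enabled:
            M = 0.0

        # effective values of the ACh-modulated parameters (linear in M)
        tmin = self._tmin_base.copy()
        tmax = self._tmax_base.copy()
        g_eff = self._g_base.copy()
        spec_pyr = self.specs["Pyr"]
        ahc_amp = spec_pyr.ahc_amplitude
        for kind, idx, w0, w1 in self._mod_entries:
            value = w0 + M * (w1 - w0)
            if kind == 0:
                tmin[idx] = value
            elif kind == 1:
                tmax[idx] = value
            elif kind == 2:
                g_eff[idx] = value
            else:
                ahc_amp = value

        lesioned = np.zeros(len(self.connections), dtype=bool)
        for label in self.lesions:
            lesioned[self._conn_index[label]] = True

        if odor is None:
            osn_drive = self._zero_drive
        elif odor is self._last_odor:
            osn_drive = self._last_drive
        else:
            osn_drive = odor.affinities * self.osn_gain
            self._last_odor = odor
            self._last_drive = osn_drive

        randoms = self.rng.random(self._v.shape)
        step_kernel(
            self._idx, self._kcount, g_eff, self._e_n, self._dec_d, self._dec_r,
            self._tau_d, self._tau_r, self._graded, self._plastic,
            self._identity, lesioned, self._src, self._tgt,
            self._zd, self._zr, self.W.w, self._recurrent_divisor,
            self._v, self._refrac, self._fired, self._outputs_arr,
            self._tau_m, self._beta, tmin, tmax, self._vhyper,
            self._trefrac, self._spiking, randoms,
            self._pop_index["Pyr"], self._pop_index["Mi_apical"],
            self._pop_index["Mi_soma"], self._ahc, ahc_amp,
            spec_pyr.ahc_tau, spec_pyr.ahc_E,
            osn_drive, self._pop_index["OSN"], dt, dt / 0.5, self._pyr_drive,
        )
        pyr_drive = self._pyr_drive

        fired = {name: self._fired[p] for name, p in self._pop_index.items()}
        if clamp is not None:
            for name, forced in clamp.items():
                p = self._pop_index[name]
                on = np.asarray(forced, dtype=float) > 0
                self._fired[p] = on.astype(float)
                fired[name] = self._fired[p]
                self.states[name].fired = self._fired[p]
                self._v[p][on] = self._vhyper[p]
                self._refrac[p][on] = self._trefrac[p]
                self._outputs_arr[p] = self._fired[p]

        # 4. recurrent plasticity: delayed presynaptic NMDA trace x current
        #    postsynaptic suprathreshold depolarisation, gated by M
        delayed_pre = self._pyr_delay.pop(0)
        np.copyto(self._delay_buf, fired["Pyr"])
        self._pyr_delay.append(self._delay_buf)
        self._delay_buf = delayed_pre  # recycle
        if self.glu.mode == "product":
            spiked = delayed_pre > 0
            self.glu.b *= self._glu_decay
            self.glu.b[spiked] = 1.0
            pre_vals = self.glu.b
        else:
            self.glu = glu_trace_update(self.glu, delayed_pre, dt)
            pre_vals = trace_value(self.glu)
        self._pyr_depol += (dt / spec_pyr.tau) * (pyr_drive - self._pyr_depol)
        if self.plasticity_enabled and M > 0.0:
            i_post = np.clip(
                self._pyr_depol - spec_pyr.theta_min - self._learning_threshold,
                0.0,
                spec_pyr.theta_max - spec_pyr.theta_min,
            )
            plasticity_kernel(
                self.W.w, self.W.w_max, dt * M / self.W.tau_pp, i_post, pre_vals
            )

        # 5. cholinergic loop: filter Ac firing into A, map to M
        mod = self.mod
        drive = mod.gain * float(fired["Ac"].mean())
        mod.A += (dt / mod.tau_ach) * (drive - mod.A)
        ab = mod.A ** mod.beta_ach
        mod.M = ab / (ab + mod.Y_half ** mod.beta_ach)

        return fired

    # ---------------------------------------------------------------- running

    def run(
        self,
        odor: OdorPattern | None,
        duration_ms: float,
        record: tuple[str, ...] = ("Pyr", "Mi_soma", "Ac", "Gb"),
        reset: bool = False,
    ) -> "SessionRecord":
        """Simulate ``duration_ms`` with a fixed stimulus, recording spikes
        of the named groups and the modulation trace."""
        if reset:
            self.reset_state()
        n_steps = int(round(duration_ms / self.dt))
        spikes = {g: np.zeros((n_steps, self.n_units), dtype=np.uint8) for g in record}
        m_trace = np.empty(n_steps)
        a_trace = np.empty(n_steps)
        for t in range(n_steps):
            fired = self.step(odor=odor)
            for g in record:
                spikes[g][t] = fired[g]
            m_trace[t] = self.mod.M
            a_trace[t] = self.mod.A
        return SessionRecord(
            spikes=spikes, m_trace=m_trace, a_trace=a_trace,
            dt=self.dt, duration_ms=duration_ms,
        )

    def odor_signature(
        self, odor: OdorPattern, duration_ms: float = 1000.0, plastic: bool = False
    ) -> np.ndarray:
        """Time-averaged pyramidal firing rate vector (Hz) evoked by an odor
        on the resting circuit; plasticity is off by default so probing does
        not train the network.  State is reset before and after."""
        saved_flag = self.plasticity_enabled
        self.plasticity_enabled = plastic
        try:
            rec = self.run(odor, duration_ms, record=("Pyr",), reset=True)
        finally:
            self.plasticity_enabled = saved_flag
            self.reset_state()
        return rec.rates("Pyr")

    # ----------------------------------------------------------------- export

    def export(self, path: str | Path) -> None:
        """Masks + weights in an .npz container with a JSON config sidecar."""
        path = Path(path)
        arrays = {f"mask_{c.label}": c.mask for c in self.connections}
        arrays["weights"] = self.W.w
        np.savez_compressed(path, **arrays)
        sidecar = {"seed": self.seed, "config": self.config}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class SessionRecord:
    """Spike matrices, modulation trace, and timing of one simulated window."""

    spikes: dict[str, np.ndarray]
    m_trace: np.ndarray
    a_trace: np.ndarray
    dt: float
    duration_ms: float

    def rates(self, group: str) -> np.ndarray:
        """Per-unit firing rate in Hz."""
        counts = self.spikes[group].sum(axis=0)
        return counts / (self.duration_ms / 1000.0)

    def mean_rate(self, group: str) -> float:
        return float(np.mean(self.rates(group)))

    def mean_m(self) -> float:
        return float(np.mean(self.m_trace))


def build_network(config: dict[str, Any] | None = None, seed: int = 0) -> OlfactoryNetwork:
    """Construct the default nine-group circuit, reproducibly from a seed."""
    return OlfactoryNetwork(config=config, seed=seed)


def step_network(
    net: OlfactoryNetwork,
    odor: OdorPattern | None = None,
    clamp: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Advance ``net`` one time step (thin functional wrapper)."""
    return net.step(odor=odor, clamp=clamp)


def osn_transduce(odor: OdorPattern, spec: PopulationSpec) -> np.ndarray:
    """Sensory transduction: affinity a in [0, 1] becomes the OSN input
    voltage a * theta_max, so a unit holding affinity 1 settles at the
    saturation potential and transmits activation 1."""
    if odor.affinities.size != spec.n:
        raise ValueError("odor must supply one affinity per sensory unit")
    return odor.affinities * spec.theta_max
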