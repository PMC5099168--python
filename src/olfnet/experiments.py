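"""Reproducible experiment protocols: training, novelty switch, distance
sweep, and novel-odor onset dynamics.

All protocols share the session convention of the underlying study: an odor
presentation lasts 1 s (2000 Euler steps at dt = 0.5 ms); between sessions
the dynamic state (membranes, conductances, adaptation, the cholinergic
filter) is reset while the recurrent weights persist.  A network is "in
learning mode" when cholinergic modulation is high and pyramidal output low,
and "in recall mode" when modulation is low and pyramidal output high; the
classifier thresholds each probe against the midpoints of the naive and
trained-odor reference statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .metrics import SpikeRaster, coherence, distance, sparseness
from .network import OlfactoryNetwork, SessionRecord, build_network
from .odors import OdorPattern, generate_odor, morph_odor

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "run_session",
    "run_training_protocol",
    "run_novelty_switch",
    "run_distance_sweep",
    "run_novelty_onset",
    "classify_mode",
]


@dataclass
class ExperimentConfig:
    """Protocol-level settings (network parameters live in ``config``)."""

    seed: int = 0
    session_ms: float = 1000.0
    n_sessions: int = 9
    n_repeats: int = 100
    sweep_fractions: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.45, 0.6, 0.8, 1.0)
    equilibrate_ms: float = 200.0
    coherence_pairs: int = 200
    config: dict[str, Any] | None = None  # network config overrides (None = defaults)

    def __post_init__(self) -> None:
        if self.session_ms <= 0 or self.n_sessions < 1:
            raise ValueError("session length must be positive and n_sessions >= 1")


@dataclass
class SessionSummary:
    """Statistics of one 1 s presentation."""

    label: str
    m_mean: float
    rates: dict[str, float]
    sparseness: dict[str, float]
    coherence: dict[str, float]
    m_trace: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "m_mean": self.m_mean,
            "rates": self.rates,
            "sparseness": self.sparseness,
            "coherence": self.coherence,
        }


@dataclass
class RunResult:
    """Per-session summaries plus protocol-level outputs."""

    sessions: list[SessionSummary]
    mode: str | None = None
    weights_sum: float | None = None
    extra: dict = field(default_factory=dict)

    def session_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sessions):
            row = {"session": i + 1, "label": s.label, "M": s.m_mean}
            row.update({f"rate_{g}": v for g, v in s.rates.items()})
            row.update({f"sparseness_{g}": v for g, v in s.sparseness.items()})
            row.update({f"coherence_{g}": v for g, v in s.coherence.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_session(
    rec: SessionRecord,
    label: str,
    coherence_pairs: int = 0,
    coherence_groups: tuple[str, ...] = ("Pyr", "Mi_soma"),
    rng: np.random.Generator | None = None,
    keep_trace: bool = False,
) -> SessionSummary:
    """Rates, sparseness and (optionally) coherence for a recorded session."""
    rates = {g: rec.mean_rate(g) for g in rec.spikes}
    spars = {}
    for g in rec.spikes:
        r = rec.rates(g)
        spars[g] = sparseness(r) if r.sum() > 0 else 0.0
    coh = {}
    if coherence_pairs > 0:
        rng = rng if rng is not None else np.random.default_rng(0)
        for g in coherence_groups:
            if g not in rec.spikes or rec.spikes[g].sum() == 0:
                continue
            raster = SpikeRaster.from_spike_matrix(rec.spikes[g], rec.dt)
            coh[g] = coherence(raster, n_pairs=coherence_pairs, rng=rng)
    return SessionSummary(
        label=label,
        m_mean=rec.mean_m(),
        rates=rates,
        sparseness=spars,
        coherence=coh,
        m_trace=rec.m_trace if keep_trace else None,
    )


def run_session(
    net: OlfactoryNetwork,
    odor: OdorPattern | None,
    cfg: ExperimentConfig,
    label: str = "",
    coherence_pairs: int = 0,
    rng: np.random.Generator | None = None,
    keep_trace: bool = False,
) -> SessionSummary:
    """One presentation: reset dynamic state, run for ``session_ms``,
    summarise.  Weights carry whatever plasticity produced."""
    rec = net.run(odor, cfg.session_ms, reset=True)
    return summarize_session(
        rec, label, coherence_pairs=coherence_pairs, rng=rng, keep_trace=keep_trace
    )


def classify_mode(
    m_probe: float,
    rate_probe: float,
    m_naive: float,
    rate_naive: float,
    m_recall: float,
    rate_recall: float,
) -> str:
    """Learning/recall dichotomy by midpoint thresholds.

    Recall requires modulation below the midpoint of the naive and
    trained-odor reference levels *and* pyramidal rate above the
    corresponding midpoint; anything else is learning.
    """
    m_mid = 0.5 * (m_naive + m_recall)
    r_mid = 0.5 * (rate_naive + rate_recall)
    if m_probe < m_mid and rate_probe > r_mid:
        return "recall"
    return "learning"


def run_training_protocol(
    cfg: ExperimentConfig,
    coherence_pairs: int | None = None,
) -> RunResult:
    """Train one odor for ``n_sessions`` 1 s sessions, then probe with the
    trained odor and with a novel (full-morph) odor."""
    n_pairs = cfg.coherence_pairs if coherence_pairs is None else coherence_pairs
    net = build_network(cfg.config, seed=cfg.seed)
    odor_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    stat_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    odor1 = generate_odor(odor_rng, id="odor1")
    odor2 = morph_odor(odor1, 1.0, rng=odor_rng, id="odor2")

    sessions = []
    for k in range(cfg.n_sessions):
        sessions.append(
            run_session(net, odor1, cfg, label=f"train{k + 1}",
                        coherence_pairs=n_pairs, rng=stat_rng)
        )
    w_trained = net.W.copy()

    probe_trained = run_session(net, odor1, cfg, label="probe_trained",
                                coherence_pairs=n_pairs, rng=stat_rng)
    net.W = w_trained.copy()  # probes are independent 10th sessions
    probe_novel = run_session(net, odor2, cfg, label="probe_novel",
                              coherence_pairs=n_pairs, rng=stat_rng)
    net.W = w_trained

    sessions.extend([probe_trained, probe_novel])
    return RunResult(
        sessions=sessions,
        weights_sum=float(net.W.w.sum()),
        extra={"net": net, "odor1": odor1, "odor2": odor2},
    )


def run_novelty_switch(
    cfg: ExperimentConfig,
    net: OlfactoryNetwork,
    trained_odor: OdorPattern,
    probe_odor: OdorPattern,
    naive_reference: tuple[float, float],
    recall_reference: tuple[float, float],
) -> RunResult:
    """Present ``probe_odor`` to a trained network for one session and
    classify the resulting state as learning or recall.

    ``naive_reference`` and ``recall_reference`` are (mean M, mean Pyr rate)
    of the untrained-network/novel-odor and trained-network/trained-odor
    conditions used as classifier anchors.
    """
    w0 = net.W.copy()
    probe = run_session(net, probe_odor, cfg, label="probe", keep_trace=True)
    net.W = w0
    mode = classify_mode(
        probe.m_mean,
        probe.rates["Pyr"],
        *naive_reference,
        *recall_reference,
    )
    return RunResult(sessions=[probe], mode=mode)


def run_distance_sweep(
    cfg: ExperimentConfig,
    coherence_pairs: int | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Train/probe repeats across probe distances; the core experiment.

    For each repeat: build a fresh network (new seed), train a fresh random
    odor for ``n_sessions``, then probe once per morph fraction with the
    trained weights restored before every probe (independent 10th sessions).
    Per probe the realised input distance, mean modulation, pyramidal rate,
    sparseness, coherence, and the learning/recall label are recorded.

    Returns a tidy DataFrame with one row per (repeat, fraction).
    """
    n_pairs = cfg.coherence_pairs if coherence_pairs is None else coherence_pairs
    rows = []
    for r in range(cfg.n_repeats):
        seed_r = int(np.random.SeedSequence([cfg.seed, 7, r]).generate_state(1)[0] % (2**31))
        rep_cfg = ExperimentConfig(
            seed=seed_r,
            session_ms=cfg.session_ms,
            n_sessions=cfg.n_sessions,
            n_repeats=1,
            sweep_fractions=cfg.sweep_fractions,
            coherence_pairs=n_pairs,
            config=cfg.config,
        )
        net = build_network(rep_cfg.config, seed=seed_r)
        odor_rng = np.random.default_rng(np.random.SeedSequence([seed_r, 1]))
        stat_rng = np.random.default_rng(np.random.SeedSequence([seed_r, 2]))
        odor1 = generate_odor(odor_rng, id=f"rep{r}_odor1")

        naive = run_session(net, odor1, rep_cfg, label="naive")
        m_naive, rate_naive = naive.m_mean, naive.rates["Pyr"]
        for _ in range(cfg.n_sessions - 1):
            run_session(net, odor1, rep_cfg, label="train")
        w_trained = net.W.copy()

        recall_ref = None
        for f in cfg.sweep_fractions:
            net.W = w_trained.copy()
            probe = morph_odor(odor1, f, rng=odor_rng)
            d_in = distance(odor1.affinities, probe.affinities) if f > 0 else 0.0
            s = run_session(net, probe, rep_cfg, label=f"probe_f{f:.2f}",
                            coherence_pairs=n_pairs, rng=stat_rng)
            if f == 0.0:
                recall_ref = (s.m_mean, s.rates["Pyr"])
            ref = recall_ref if recall_ref is not None else (s.m_mean, s.rates["Pyr"])
            mode = classify_mode(
                s.m_mean, s.rates["Pyr"], m_naive, rate_naive, *ref
            )
            rows.append(
                {
                    "repeat": r,
                    "fraction": f,
                    "distance": d_in,
                    "M": s.m_mean,
                    "rate_Pyr": s.rates["Pyr"],
                    "sparseness_Pyr": s.sparseness["Pyr"],
                    "coherence_Pyr": s.coherence.get("Pyr", np.nan),
                    "mode": mode,
                }
            )
        net.W = w_trained
        if progress:
            print(f"repeat {r + 1}/{cfg.n_repeats} done")
    return pd.DataFrame(rows)


def sweep_summary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction averages of the sweep table, plus the learning share."""
    grouped = sweep.groupby("fraction")
    out = grouped[["distance", "M", "rate_Pyr", "sparseness_Pyr", "coherence_Pyr"]].mean()
    out["learning_share"] = grouped["mode"].apply(lambda s: float(np.mean(s == "learning")))
    return out.reset_index()


def switch_distance(sweep: pd.DataFrame) -> float:
    """Smallest mean probe distance at which the majority of repeats are in
    learning mode."""
    summary = sweep_summary(sweep).sort_values("distance")
    learning = summary[summary["learning_share"] >= 0.5]
    if learning.empty:
        raise ValueError("no distance bin reaches majority learning mode")
    return float(learning["distance"].iloc[0])


def run_novelty_onset(
    cfg: ExperimentConfig,
    duration_ms: float = 1000.0,
) -> dict[str, Any]:
    """Novel odor onto an untrained, equilibrated network: the modulation
    trace around odor onset, averaged over repeats.

    Returns the trial-averaged M trace (from odor onset), its standard
    error, the onset-window mean (first 50 ms), and two latency measures of
    the onset dip: ``dip_latency_ms`` -- the time of the trough of the
    averaged trace within the first 200 ms, i.e. when the onset transient of
    pyramidal activity maximally suppresses modulation -- and
    ``first_detectable_ms`` -- the earliest time the averaged trace falls
    more than two standard errors below its onset value.
    """
    traces = []
    for r in range(cfg.n_repeats):
        seed_r = int(np.random.SeedSequence([cfg.seed, 11, r]).generate_state(1)[0] % (2**31))
        net = build_network(cfg.config, seed=seed_r)
        odor = generate_odor(np.random.default_rng(np.random.SeedSequence([seed_r, 1])))
        net.run(None, cfg.equilibrate_ms, record=(), reset=True)
        rec = net.run(odor, duration_ms, record=("Pyr",))
        traces.append(rec.m_trace)
        dt = rec.dt
    traces = np.stack(traces)
    mean = traces.mean(axis=0)
    se = traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
    t = (np.arange(mean.size) + 1) * dt
    onset_mask = t <= 50.0
    m_onset_window = float(mean[onset_mask].mean())
    m0 = mean[0]
    below = mean < (m0 - 2.0 * se)
    first_detectable = float(t[np.argmax(below)]) if below.any() else float("nan")
    window = t <= 200.0
    dip_latency = float(t[np.argmin(mean[window])])
    return {
        "t_ms": t,
        "m_mean": mean,
        "m_se": se,
        "m_onset": m_onset_window,
        "dip_latency_ms": dip_latency,
        "first_detectable_ms": first_detectable,
    }
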