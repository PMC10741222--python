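"""Feedback actuators: helicopter altitude dynamics, attention-proportional
distraction scheduling, and the closed-loop session orchestrator.

Helicopter update per step of duration dt, with nfb the normalized
feedback in [0, 1] and speed a constant 10 m/s::

    h' = clip(h + nfb*speed*dt - 0.5*speed*dt, h_min, h_max)

so nfb = 0.5 is the exact hover equilibrium.

Distractions occur inside 30 s blocks (the first block of each task is
distraction-free). The target inter-onset interval is ``min_interval /
max(nfb, eps)``: a fully focused child (nfb = 1) gets one distraction
every 3 s, an unfocused child the floor of one per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .engine import (CalibrationBounds, EngineConfig, TBRSample, calibrate,
                     normalize, stream_tbr)

__all__ = [
    "HelicopterState",
    "DistractionEvent",
    "BlockPlan",
    "DISTRACTION_CATALOGUE",
    "helicopter_step",
    "schedule_distractions",
    "SessionPlan",
    "SessionLog",
    "run_closed_loop",
]


@dataclass(frozen=True)
class HelicopterState:
    h: float = 0.0
    h_min: float = 0.0
    h_max: float = 2.4   # whiteboard height (m)
    speed: float = 10.0  # m/s

    def __post_init__(self):
        if not (self.h_min <= self.h <= self.h_max):
            raise ValueError("h outside clamp bounds")


def helicopter_step(state: HelicopterState, nfb: float, dt: float) -> HelicopterState:
    """One discrete update of the altitude dynamics."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0.0 <= nfb <= 1.0:
        raise ValueError("nfb must be in [0, 1]")
    vd = nfb * state.speed * dt
    gd = -0.5 * state.speed * dt
    h = min(max(state.h + vd + gd, state.h_min), state.h_max)
    return replace(state, h=h)


# kind -> (modality, default duration s); durations capped by the scheduler
DISTRACTION_CATALOGUE: dict[str, tuple[str, float]] = {
    "mistress_walk": ("audiovisual", 2.5),
    "mistress_cough": ("audiovisual", 1.0),
    "mistress_yawn": ("audiovisual", 1.5),
    "mistress_speak": ("audiovisual", 2.5),
    "headmaster_enter_exit": ("audiovisual", 2.5),
    "headmaster_walk": ("audiovisual", 2.5),
    "headmaster_cough": ("audiovisual", 1.0),
    "headmaster_yawn": ("audiovisual", 1.5),
    "headmaster_speak": ("audiovisual", 2.5),
    "kid_raise_hand": ("visual", 1.5),
    "kid_speak": ("audiovisual", 2.0),
    "phone_vibrate": ("audiovisual", 1.5),
    "bell_ring": ("audio", 2.0),
    "insects_fly": ("audiovisual", 2.5),
}


@dataclass(frozen=True)
class DistractionEvent:
    onset: float
    duration: float
    kind: str
    modality: str


@dataclass(frozen=True)
class BlockPlan:
    block_len_s: float = 30.0
    first_block_distraction_free: bool = True
    min_events_per_block: int = 1
    min_interval_s: float = 3.0

    def __post_init__(self):
        if min(self.block_len_s, self.min_interval_s) <= 0 or self.min_events_per_block < 1:
            raise ValueError("BlockPlan fields must be positive")


def schedule_distractions(n_blocks: int, nfb_at, plan: BlockPlan = BlockPlan(),
                          catalogue: dict | None = None, seed: int = 0,
                          t0: float = 0.0) -> list[DistractionEvent]:
    """Schedule events over ``n_blocks`` consecutive blocks starting at ``t0``.

    ``nfb_at(t)`` maps an absolute time to the instantaneous normalized
    feedback value. Only one distraction occurs at a time; consecutive
    onsets are at least ``min_interval_s`` apart; every distraction block
    gets at least one event; kinds are drawn uniformly with ``seed``.
    """
    catalogue = DISTRACTION_CATALOGUE if catalogue is None else catalogue
    if not catalogue:
        raise ValueError("catalogue must be non-empty")
    kinds = sorted(catalogue)
    rng = np.random.default_rng(seed)
    eps = plan.min_interval_s / plan.block_len_s  # nfb floor -> 1 event/block
    events: list[DistractionEvent] = []
    for b in range(n_blocks):
        start = t0 + b * plan.block_len_s
        end = start + plan.block_len_s
        if b == 0 and plan.first_block_distraction_free:
            continue
        t = start
        block_events = []
        while t < end - 1e-9:
            kind = kinds[rng.integers(len(kinds))]
            modality, dur = catalogue[kind]
            interval = plan.min_interval_s / max(float(nfb_at(t)), eps)
            dur = min(dur, plan.min_interval_s, end - t)
            block_events.append(DistractionEvent(t, dur, kind, modality))
            t += interval
        if not block_events:  # floor: at least one per distraction block
            kind = kinds[rng.integers(len(kinds))]
            modality, dur = catalogue[kind]
            block_events.append(DistractionEvent(start, min(dur, plan.min_interval_s,
                                                            plan.block_len_s), kind, modality))
        events.extend(block_events[:])
    return events


# ---------------------------------------------------------------------------
# closed loop

@dataclass(frozen=True)
class SessionPlan:
    calib_phase_s: float = 20.0   # x4: relax, focus, relax, focus
    run_s: float = 180.0          # helicopter run length
    n_runs: int = 2
    hop_dt: float = 1.0           # helicopter/engine update step
    block: BlockPlan = field(default_factory=BlockPlan)
    relax_level: float = 0.15     # latent attention during relax calibration
    focus_level: float = 0.85


@dataclass
class SessionLog:
    bounds: CalibrationBounds | None
    tbr: list[TBRSample]
    helicopter: list[tuple[float, float]]          # (t, h)
    distractions: list[DistractionEvent]
    runs: list[tuple[float, float]]                # (start, stop) of each run
    mean_altitude: float
    mean_tbr_raw: float


def run_closed_loop(agent_mean: float, plan: SessionPlan = SessionPlan(),
                    engine_config: EngineConfig = EngineConfig(),
                    bounds: CalibrationBounds | None = None,
                    ch_names: list[str] | None = None,
                    seed: int = 0, agent_volatility: float = 0.05) -> SessionLog:
    """Simulate one full session against a synthetic child.

    The child is an attention process with stationary mean ``agent_mean``.
    Calibration (relax/focus phases at fixed latent levels) precedes the
    helicopter runs unless ``bounds`` is supplied. Returns a complete log
    with shared timestamps.
    """
    from .synth import (AttentionParams, AttentionTrace, SynthEEGParams,
                        simulate_attention_trace, synthesize_eeg)

    if ch_names is None:
        ch_names = ["Fz", "Cz", "Pz", "T7", "ECG"]
    rate = 10.0
    calib_total = 4 * plan.calib_phase_s if bounds is None else 0.0
    run_total = plan.n_runs * plan.run_s
    total = calib_total + run_total
    if run_total == 0:
        return SessionLog(bounds, [], [], [], [], float("nan"), float("nan"))

    # latent attention: fixed relax/focus levels during calibration, then
    # the agent's own stationary process during runs
    rng = np.random.default_rng(seed)
    segs = []
    if calib_total:
        for i in range(4):
            level = plan.relax_level if i % 2 == 0 else plan.focus_level
            p = AttentionParams(target=level, volatility=0.03)
            segs.append(simulate_attention_trace(plan.calib_phase_s, rate, p,
                                                 seed=int(rng.integers(2**31))).values)
    p = AttentionParams(target=agent_mean, volatility=agent_volatility)
    segs.append(simulate_attention_trace(run_total, rate, p,
                                         seed=int(rng.integers(2**31))).values)
    trace = AttentionTrace(np.concatenate(segs), rate, seed)

    rec = synthesize_eeg(trace, ch_names, sfreq=500.0,
                         params=SynthEEGParams(blink_amp=0.0),
                         seed=int(rng.integers(2**31)))

    if bounds is None:
        calib_samples = stream_tbr(rec, engine_config, t_stop=calib_total)
        bounds = calibrate(calib_samples)

    all_tbr: list[TBRSample] = []
    helicopter: list[tuple[float, float]] = []
    distractions: list[DistractionEvent] = []
    runs = []
    for r in range(plan.n_runs):
        r_start = calib_total + r * plan.run_s
        r_stop = r_start + plan.run_s
        runs.append((r_start, r_stop))
        samples = stream_tbr(rec, engine_config, bounds=bounds,
                             t_start=r_start, t_stop=r_stop)
        all_tbr.extend(samples)
        state = HelicopterState()
        nfb_by_t = {round(s.t, 6): s.feedback for s in samples}
        last_nfb = 0.5
        t = r_start + plan.hop_dt
        while t <= r_stop + 1e-9:
            last_nfb = nfb_by_t.get(round(t, 6), last_nfb)
            state = helicopter_step(state, last_nfb, plan.hop_dt)
            helicopter.append((t, state.h))
            t += plan.hop_dt

        def nfb_at(tt, samples=samples):
            best = 0.5
            for s in samples:
                if s.t <= tt:
                    best = s.feedback
                else:
                    break
            return best

        n_blocks = int(plan.run_s // plan.block.block_len_s)
        distractions.extend(schedule_distractions(
            n_blocks, nfb_at, plan.block, seed=seed * 1000 + r, t0=r_start))

    alts = np.array([h for _, h in helicopter])
    raws = np.array([s.tbr_raw for s in all_tbr if np.isfinite(s.tbr_raw)])
    return SessionLog(bounds, all_tbr, helicopter, distractions, runs,
                      float(alts.mean()) if len(alts) else float("nan"),
                      float(raws.mean()) if len(raws) else float("nan"))
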