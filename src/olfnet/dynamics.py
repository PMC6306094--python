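"""Stochastic firing-rate dynamics of the olfactory network.

Every population follows the same rate equation

    tau dx/dt = -x + s(x_tilde) [+ noise],

where ``x_tilde`` is the signed, weighted input drive and ``s`` is a
shared bounded saturating nonlinearity.  Octopamine multiplies
excitatory drive by ``(1 + a * M_O)`` and inhibitory drive by
``(1 - gamma_inh * a * M_O)`` through diagonal, population-specific
neuromodulator channels (zero for PNs, KCs and ENs).  Additive noise of
intensity ``epsilon`` enters the four antennal-lobe populations (RN,
LN, PN, QN) only; Kenyon cells and the readout neuron are noise-free,
so their trajectories are deterministic functions of the AL trajectory.

Integration is Euler-Maruyama with post-step clipping at zero;
:func:`check_convergence` compares the noise-free path against a
4th-order Runge-Kutta reference integrating the identical right-hand
side on an aligned finer grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .connectome import Moth, MothTemplate
from .stimuli import StimulusSchedule
from . import plasticity as _plasticity

__all__ = [
    "MothState",
    "DynamicsConfig",
    "SimResult",
    "sigmoid",
    "drift",
    "step_em",
    "simulate",
    "check_convergence",
]

POPULATIONS = ("RN", "LN", "PN", "QN", "KC", "EN")
NOISY = ("RN", "LN", "PN", "QN")           # AL populations receive SDE noise


@dataclass
class MothState:
    """Instantaneous firing rates of all six populations, spikes/s."""

    uR: np.ndarray   # receptor neurons (nG,)
    uL: np.ndarray   # lateral neurons (nG,)
    P: np.ndarray    # projection neurons (nG,)
    Q: np.ndarray    # inhibitory projection neurons (nQN,)
    K: np.ndarray    # Kenyon cells (nKC,)
    E: np.ndarray    # extrinsic readout neurons (nEN,)

    @classmethod
    def zeros(cls, moth: Moth) -> "MothState":
        t = moth.template
        return cls(np.zeros(t.n_glomeruli), np.zeros(t.n_glomeruli),
                   np.zeros(t.n_glomeruli), np.zeros(t.n_qn),
                   np.zeros(t.n_kc), np.zeros(t.n_en))

    def as_dict(self) -> dict:
        return {"RN": self.uR, "LN": self.uL, "PN": self.P,
                "QN": self.Q, "KC": self.K, "EN": self.E}


@dataclass
class DynamicsConfig:
    """Shared dynamics parameters (one decay constant, one sigmoid,
    one noise intensity for the whole network)."""

    tau: float = 0.5
    noise: float = 3.0
    sigmoid_slope: float = 1.0
    sigmoid_max: float = 180.0
    gamma_inh: float = 0.3
    lh_inhibition: float = 30.0     # constant global damping on KCs
    dt: float = 0.010
    response_tail: float = 0.3      # window extension past pulse offset, s

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.noise < 0 or self.lh_inhibition < 0:
            raise ValueError("noise and lh_inhibition must be nonnegative")

    @classmethod
    def from_template(cls, template: MothTemplate, **overrides) -> "DynamicsConfig":
        kw = dict(tau=template.tau, noise=template.noise,
                  sigmoid_slope=template.sigmoid_slope,
                  sigmoid_max=template.sigmoid_max,
                  gamma_inh=template.gamma_inh,
                  lh_inhibition=template.lh_inhibition, dt=template.dt)
        kw.update(overrides)
        return cls(**kw)


def sigmoid(x: np.ndarray, slope: float, fmax: float) -> np.ndarray:
    """Bounded saturating rate function: 0 for x <= 0, ceiling ``fmax``.

    ``fmax * tanh(slope * x / fmax)`` on the positive half-line; slope
    at the origin equals ``slope``, output lies in [0, fmax).
    """
    return fmax * np.tanh(slope * np.maximum(x, 0.0) / fmax)


def drift(state: MothState, moth: Moth, odor_drive: np.ndarray,
          octo_amp: float, config: DynamicsConfig,
          weights: dict | None = None) -> MothState:
    """Deterministic part dx/dt of the rate equations for all populations.

    ``odor_drive`` is the instantaneous per-glomerulus RN stimulation
    (spikes/s); ``octo_amp`` the octopamine amplitude a(t);
    ``weights`` optionally supplies the current plastic matrices
    (``M_PK``, ``M_QK``, ``M_KE``) in place of the moth's naive ones.
    """
    t = moth.template
    if state.K.shape[0] != t.n_kc or state.uR.shape[0] != t.n_glomeruli:
        raise ValueError("state dimensions do not match moth template")
    M_PK = moth.M_PK if weights is None else weights["M_PK"]
    M_QK = moth.M_QK if weights is None else weights["M_QK"]
    M_KE = moth.M_KE if weights is None else weights["M_KE"]
    a = float(octo_amp)
    g = config.gamma_inh
    slope, fmax, tau = config.sigmoid_slope, config.sigmoid_max, config.tau

    uL = state.uL
    inh_L = moth.M_LL @ uL
    inh_R = moth.M_LR @ uL
    inh_P = moth.M_LP @ uL

    R_t = ((1.0 + a * moth.M_OR) * (moth.rn_spont + odor_drive)
           - np.maximum(1.0 - g * a * moth.M_OR, 0.0) * inh_R)
    L_t = ((1.0 + a * moth.M_OL) * (moth.M_RL * state.uR)
           - np.maximum(1.0 - g * a * moth.M_OL, 0.0) * inh_L)
    P_t = ((1.0 + a * moth.M_OP) * (moth.M_RP * state.uR)
           - np.maximum(1.0 - g * a * moth.M_OP, 0.0) * inh_P)
    Q_t = moth.M_RQ @ state.uR - moth.M_LQ @ uL
    K_t = M_PK @ state.P - M_QK @ state.Q - config.lh_inhibition
    E_t = M_KE @ state.K

    return MothState(
        uR=(-state.uR + sigmoid(R_t, slope, fmax)) / tau,
        uL=(-state.uL + sigmoid(L_t, slope, fmax)) / tau,
        P=(-state.P + sigmoid(P_t, slope, fmax)) / tau,
        Q=(-state.Q + sigmoid(Q_t, slope, fmax)) / tau,
        K=(-state.K + sigmoid(K_t, slope, fmax)) / tau,
        E=(-state.E + sigmoid(E_t, slope, fmax)) / tau,
    )


def step_em(state: MothState, deriv: MothState, dt: float, eps: float,
            rng: np.random.Generator | None) -> MothState:
    """One Euler-Maruyama step, x + dt*f + eps*sqrt(dt)*N(0,1), clipped at 0.

    Noise enters the AL populations only; with ``eps == 0`` this is
    forward Euler.  KC/EN coordinates are always noise-free.
    """
    nG, nQN = state.uR.size, state.Q.size
    if eps > 0.0 and rng is not None:
        z = rng.standard_normal(3 * nG + nQN) * (eps * np.sqrt(dt))
        nR, nL, nP, nQ = (z[:nG], z[nG:2 * nG], z[2 * nG:3 * nG],
                          z[3 * nG:])
    else:
        nR = nL = nP = nQ = 0.0
    clip = lambda x: np.maximum(x, 0.0)
    return MothState(
        uR=clip(state.uR + dt * deriv.uR + nR),
        uL=clip(state.uL + dt * deriv.uL + nL),
        P=clip(state.P + dt * deriv.P + nP),
        Q=clip(state.Q + dt * deriv.Q + nQ),
        K=clip(state.K + dt * deriv.K),
        E=clip(state.E + dt * deriv.E),
    )


@dataclass
class SimResult:
    """Timecourses, per-pulse responses and plastic-weight snapshots."""

    time: np.ndarray                      # recorded time axis, s
    rates: dict                           # population -> (n_rec, n) float32
    pulse_responses: dict                 # "KC"/"EN" -> (n_pulses, n)
    pulse_odor: np.ndarray                # (n_pulses,) odor id per pulse
    pulse_phase: np.ndarray               # (n_pulses,) phase label per pulse
    weights_initial: dict
    weights_final: dict
    snapshots: dict = field(default_factory=dict)  # phase -> weight dict
    seed: int = 0
    schedule: StimulusSchedule | None = None

    def responses(self, population: str, odor: int, phase: str) -> np.ndarray:
        """Per-pulse mean responses for one odor in one schedule phase."""
        sel = (self.pulse_odor == odor) & (self.pulse_phase == phase)
        return self.pulse_responses[population][sel]


def simulate(moth: Moth, schedule: StimulusSchedule,
             config: DynamicsConfig | None = None, seed: int = 0,
             plastic: bool = True, record: tuple = ("PN", "EN"),
             record_stride: int = 1) -> SimResult:
    """Integrate the full network over a stimulus schedule.

    Deterministic given ``seed``.  Plastic weights start from the
    moth's naive matrices and, when ``plastic`` is true, grow by the
    octopamine-gated Hebbian rule wherever the schedule gate is open;
    the moth object itself is never mutated.  ``record`` selects which
    populations keep full timecourses (per-pulse mean responses of KCs
    and the EN are always accumulated).
    """
    if config is None:
        config = DynamicsConfig.from_template(moth.template)
    if abs(schedule.dt - config.dt) > 1e-12:
        raise ValueError(
            f"schedule dt {schedule.dt} differs from config dt {config.dt}")
    t = moth.template
    n_steps = schedule.n_steps
    dt, eps = config.dt, config.noise
    rng = np.random.default_rng(seed)

    drive = (schedule.glomerular_drive() if schedule.odor_maps
             else np.zeros((n_steps, t.n_glomeruli)))
    octo = schedule.octopamine
    gate = schedule.gate if plastic else np.zeros(n_steps, dtype=np.uint8)

    weights = moth.plastic_weights()
    weights_initial = {k: v.copy() for k, v in weights.items()}
    gammas = {"M_PK": t.gamma_pk, "M_QK": t.gamma_qk, "M_KE": t.gamma_ke}

    # per-pulse response windows: pulse + tail, mean rate accumulators
    n_pulses = len(schedule.pulses)
    window_of = np.full(n_steps, -1, dtype=np.int64)
    for j, p in enumerate(schedule.pulses):
        i0 = int(round(p.onset / dt))
        i1 = min(int(round((p.onset + p.duration + config.response_tail) / dt)),
                 n_steps)
        window_of[i0:i1] = j
    acc_K = np.zeros((n_pulses, t.n_kc))
    acc_E = np.zeros((n_pulses, t.n_en))
    acc_n = np.zeros(n_pulses, dtype=np.int64)

    rec_idx = np.arange(0, n_steps, record_stride)
    sizes = {"RN": t.n_glomeruli, "LN": t.n_glomeruli, "PN": t.n_glomeruli,
             "QN": t.n_qn, "KC": t.n_kc, "EN": t.n_en}
    rec = {pop: np.empty((rec_idx.size, sizes[pop]), dtype=np.float32)
           for pop in record}

    # snapshot plastic weights at the end of each named phase
    snap_at = {}
    for name, (_, t1) in schedule.phase_bounds.items():
        snap_at[min(int(round(t1 / dt)), n_steps) - 1] = name
    snapshots = {}

    # --- fused integration loop (same update as drift + step_em) ---
    nG, nQN = t.n_glomeruli, t.n_qn
    slope, fmax = config.sigmoid_slope, config.sigmoid_max
    g_inh, L0, tau = config.gamma_inh, config.lh_inhibition, config.tau
    a_dt = dt / tau
    sq = eps * np.sqrt(dt)
    spont = moth.rn_spont
    uR = np.zeros(nG); uL = np.zeros(nG); P = np.zeros(nG)
    Q = np.zeros(nQN); K = np.zeros(t.n_kc); E = np.zeros(t.n_en)

    def _s(x):
        return fmax * np.tanh(slope * np.maximum(x, 0.0) / fmax)

    r = 0
    for i in range(n_steps):
        a = octo[i]
        inh_R = moth.M_LR @ uL
        inh_L = moth.M_LL @ uL
        inh_P = moth.M_LP @ uL
        if a > 0.0:
            R_t = ((1.0 + a * moth.M_OR) * (spont + drive[i])
                   - np.maximum(1.0 - g_inh * a * moth.M_OR, 0.0) * inh_R)
            L_t = ((1.0 + a * moth.M_OL) * (moth.M_RL * uR)
                   - np.maximum(1.0 - g_inh * a * moth.M_OL, 0.0) * inh_L)
            P_t = ((1.0 + a * moth.M_OP) * (moth.M_RP * uR)
                   - np.maximum(1.0 - g_inh * a * moth.M_OP, 0.0) * inh_P)
        else:
            R_t = spont + drive[i] - inh_R
            L_t = moth.M_RL * uR - inh_L
            P_t = moth.M_RP * uR - inh_P
        Q_t = moth.M_RQ @ uR - moth.M_LQ @ uL
        K_t = weights["M_PK"] @ P - weights["M_QK"] @ Q - L0
        E_t = weights["M_KE"] @ K

        if eps > 0.0:
            z = rng.standard_normal(3 * nG + nQN) * sq
            uR = np.maximum(uR + a_dt * (_s(R_t) - uR) + z[:nG], 0.0)
            uL = np.maximum(uL + a_dt * (_s(L_t) - uL) + z[nG:2 * nG], 0.0)
            P = np.maximum(P + a_dt * (_s(P_t) - P) + z[2 * nG:3 * nG], 0.0)
            Q = np.maximum(Q + a_dt * (_s(Q_t) - Q) + z[3 * nG:], 0.0)
        else:
            uR += a_dt * (_s(R_t) - uR)
            uL += a_dt * (_s(L_t) - uL)
            P += a_dt * (_s(P_t) - P)
            Q += a_dt * (_s(Q_t) - Q)
        K += a_dt * (_s(K_t) - K)
        E += a_dt * (_s(E_t) - E)

        if gate[i]:
            _plasticity.hebbian_step(
                weights, moth.pk_mask, MothState(uR, uL, P, Q, K, E),
                gammas, dt)
        w = window_of[i]
        if w >= 0:
            acc_K[w] += K
            acc_E[w] += E
            acc_n[w] += 1
        if i % record_stride == 0:
            if record:
                sd = {"RN": uR, "LN": uL, "PN": P, "QN": Q, "KC": K, "EN": E}
                for pop in record:
                    rec[pop][r] = sd[pop]
            r += 1
        if i in snap_at:
            snapshots[snap_at[i]] = {k: v.copy() for k, v in weights.items()}
        if i % 500 == 499 and not np.isfinite(uR).all():
            raise RuntimeError(
                f"nonfinite firing rates at t={i * dt:.2f} s; "
                "check noise intensity and weight scales")

    for pop in ("RN", "LN", "PN", "QN", "KC", "EN"):
        if pop in rec and not np.isfinite(rec[pop]).all():
            raise RuntimeError(f"nonfinite {pop} rates recorded")

    denom = np.maximum(acc_n, 1)[:, None]
    return SimResult(
        time=rec_idx * dt,
        rates=rec,
        pulse_responses={"KC": acc_K / denom, "EN": acc_E / denom},
        pulse_odor=np.array([p.odor_id for p in schedule.pulses]),
        pulse_phase=np.array([p.phase for p in schedule.pulses]),
        weights_initial=weights_initial,
        weights_final=weights,
        snapshots=snapshots,
        seed=int(seed),
        schedule=schedule,
    )


def check_convergence(moth: Moth, schedule: StimulusSchedule,
                      config: DynamicsConfig | None = None,
                      substeps: int = 6) -> tuple:
    """Max |Euler-Maruyama - RK4| discrepancy of the noise-free system.

    Both integrators see the identical right-hand side: the stimulus
    channels sampled on the schedule grid, held constant over each
    timestep (the discrete schedule *is* the system input, so the
    comparison isolates integrator error from signal-sampling error).
    The reference is classic 4th-order Runge-Kutta with ``substeps``
    sub-intervals per hold interval, aligned with the input so the
    right-hand side is smooth within every RK step.

    Returns ``(max_discrepancy, peak_rate)`` in spikes/s, the maximum
    taken over every neuron and recorded timestep.
    """
    if config is None:
        config = DynamicsConfig.from_template(moth.template)
    config = dataclasses.replace(config, noise=0.0)
    t = moth.template
    em = simulate(moth, schedule, config, seed=0, plastic=False,
                  record=POPULATIONS)
    em_flat = np.concatenate([em.rates[p].astype(float) for p in POPULATIONS],
                             axis=1)

    drive = (schedule.glomerular_drive() if schedule.odor_maps
             else np.zeros((schedule.n_steps, t.n_glomeruli)))
    sizes = [t.n_glomeruli] * 3 + [t.n_qn, t.n_kc, t.n_en]
    splits = np.cumsum(sizes)[:-1]

    def fun(y, dv, oc):
        d = drift(MothState(*np.split(y, splits)), moth, dv, oc, config)
        return np.concatenate([d.uR, d.uL, d.P, d.Q, d.K, d.E])

    y = np.zeros(sum(sizes))
    h = schedule.dt / substeps
    err, peak = 0.0, 0.0
    for i in range(schedule.n_steps):
        dv, oc = drive[i], schedule.octopamine[i]
        for _ in range(substeps):
            k1 = fun(y, dv, oc)
            k2 = fun(y + 0.5 * h * k1, dv, oc)
            k3 = fun(y + 0.5 * h * k2, dv, oc)
            k4 = fun(y + h * k3, dv, oc)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        err = max(err, float(np.abs(em_flat[i] - y).max()))
        peak = max(peak, float(y.max()))
    return err, peak
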