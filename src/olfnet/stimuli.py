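"""Odor maps and time-resolved stimulus schedules.

Odor pulses and octopamine episodes are raised-cosine (Hamming) windows
on the simulation clock; the smooth edges keep the rate ODEs non-stiff
at a 10 ms timestep.  A :class:`StimulusSchedule` carries, on a common
grid: per-odor stimulus envelopes, the octopamine amplitude, and the
Hebbian training gate ``o(t)`` which is 1 only during training episodes
(octopamine delivered *and* plasticity enabled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import MothConfigError, MothTemplate, _clipped_normal

__all__ = [
    "OdorMap",
    "Pulse",
    "StimulusSchedule",
    "ScheduleError",
    "make_odor_maps",
    "hamming_pulse",
    "build_schedule",
    "build_learning_schedule",
]


class ScheduleError(ValueError):
    """Raised for degenerate or inconsistent schedule requests."""


@dataclass
class OdorMap:
    """Projection of one odor onto the glomerular array.

    ``weights`` is a length-nG vector of nonnegative RN stimulation
    gains, zero off-target.
    """

    odor_id: int
    glomeruli: np.ndarray      # indices of hit glomeruli
    weights: np.ndarray        # (nG,) peak RN drive, spikes/s


@dataclass
class Pulse:
    odor_id: int
    onset: float
    duration: float
    phase: str                 # e.g. "baseline", "train", "post"


def make_odor_maps(n_odors: int, n_glomeruli: int, hits_per_odor: int,
                   rng: np.random.Generator, strength: float = 30.0,
                   cv: float = 0.3) -> list[OdorMap]:
    """Independent uniform draws of ``hits_per_odor`` glomeruli per odor.

    Stimulation weights on the hit glomeruli follow the same
    proportional-variance Gaussian scheme as connection weights.
    """
    if hits_per_odor > n_glomeruli:
        raise MothConfigError("hits_per_odor cannot exceed n_glomeruli")
    maps = []
    for k in range(n_odors):
        hit = rng.choice(n_glomeruli, size=hits_per_odor, replace=False)
        w = np.zeros(n_glomeruli)
        w[hit] = _clipped_normal(rng, strength, cv, hits_per_odor)
        maps.append(OdorMap(odor_id=k, glomeruli=np.sort(hit), weights=w))
    return maps


def odor_maps_for(template: MothTemplate, n_odors: int,
                  rng: np.random.Generator) -> list[OdorMap]:
    """Odor maps with hit count and strength taken from a template."""
    return make_odor_maps(n_odors, template.n_glomeruli,
                          template.hits_per_odor, rng,
                          strength=template.odor_strength,
                          cv=template.weight_cv)


def hamming_pulse(onset: float, duration: float, dt: float):
    """Raised-cosine pulse envelope, peak amplitude 1.

    Returns ``(start_index, envelope)`` where ``envelope`` samples the
    Hamming window ``0.54 - 0.46 cos(2 pi n / (N-1))`` (edge value 0.08
    of peak) on the grid; zero outside the window is implied.
    """
    if duration < 2 * dt:
        raise ScheduleError(
            f"pulse duration {duration} s is degenerate at dt={dt} s "
            "(need duration >= 2*dt)")
    start = int(round(onset / dt))
    n = int(round(duration / dt)) + 1
    env = np.hamming(n)
    return start, env / env.max()


@dataclass
class StimulusSchedule:
    """Stimulus channels sampled on the simulation grid."""

    dt: float
    n_steps: int
    n_odors: int
    odor_env: np.ndarray = None        # (n_steps, n_odors) in [0, 1]
    octopamine: np.ndarray = None      # (n_steps,) amplitude >= 0
    gate: np.ndarray = None            # (n_steps,) Hebbian gate in {0, 1}
    pulses: list = field(default_factory=list)
    phase_bounds: dict = field(default_factory=dict)   # name -> (t0, t1)
    odor_maps: list = field(default_factory=list)      # optional OdorMap list

    def __post_init__(self):
        if self.odor_env is None:
            self.odor_env = np.zeros((self.n_steps, self.n_odors))
        if self.octopamine is None:
            self.octopamine = np.zeros(self.n_steps)
        if self.gate is None:
            self.gate = np.zeros(self.n_steps, dtype=np.uint8)

    @property
    def duration(self) -> float:
        return self.n_steps * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def add_odor_pulse(self, odor_id: int, onset: float, duration: float,
                       phase: str = "") -> None:
        """Add one Hamming odor pulse; overlapping odor pulses are an error."""
        if onset < 0 or onset + duration > self.duration + 1e-9:
            raise ScheduleError(
                f"pulse [{onset}, {onset + duration}] s outside schedule "
                f"of duration {self.duration} s")
        for p in self.pulses:
            if onset < p.onset + p.duration and p.onset < onset + duration:
                raise ScheduleError(
                    f"odor pulse at {onset} s overlaps pulse at {p.onset} s")
        start, env = hamming_pulse(onset, duration, self.dt)
        stop = min(start + env.size, self.n_steps)
        self.odor_env[start:stop, odor_id] = np.maximum(
            self.odor_env[start:stop, odor_id], env[:stop - start])
        self.pulses.append(Pulse(odor_id, onset, duration, phase))

    def add_octopamine(self, onset: float, duration: float,
                       amplitude: float = 1.0, training: bool = False) -> None:
        """Add one Hamming octopamine episode; opens the gate iff training."""
        start, env = hamming_pulse(onset, duration, self.dt)
        stop = min(start + env.size, self.n_steps)
        self.octopamine[start:stop] = np.maximum(
            self.octopamine[start:stop], amplitude * env[:stop - start])
        if training:
            self.gate[start:stop] = 1

    def glomerular_drive(self) -> np.ndarray:
        """(n_steps, nG) RN odor drive: envelopes times odor-map weights."""
        if not self.odor_maps:
            raise ScheduleError("schedule has no odor maps attached")
        W = np.stack([m.weights for m in self.odor_maps])   # (n_odors, nG)
        return self.odor_env @ W


def build_schedule(phases: list[dict], dt: float, n_odors: int,
                   odor_maps: list[OdorMap] | None = None,
                   pulse_duration: float = 0.2, gap: float = 4.0,
                   octo_amplitude: float = 1.0) -> StimulusSchedule:
    """Assemble a schedule from an ordered list of phase descriptions.

    Each phase is a dict with a ``kind`` key:

    - ``{"kind": "quiet", "duration": s}``
    - ``{"kind": "odor_series", "odors": [ids], "stimulations": n}`` —
      for each odor in turn, ``n`` Hamming pulses separated by ``gap``
    - ``{"kind": "octopamine", "duration": s}`` — control octopamine,
      Hebbian gate closed
    - ``{"kind": "training", "odor": id, "stimulations": n}`` — odor
      pulses under one octopamine episode spanning the block, with the
      Hebbian gate open

    An empty phase list yields an all-zero schedule of minimal length.
    """
    # first pass: total duration
    t = 0.0
    spans = []
    for ph in phases:
        kind = ph["kind"]
        if kind == "quiet":
            d = ph["duration"]
        elif kind == "odor_series":
            d = len(ph["odors"]) * ph["stimulations"] * (pulse_duration + gap)
        elif kind == "octopamine":
            d = ph["duration"] + gap
        elif kind == "training":
            d = ph["stimulations"] * (pulse_duration + gap)
        else:
            raise ScheduleError(f"unknown phase kind {kind!r}")
        spans.append((t, t + d))
        t += d
    n_steps = max(int(round(t / dt)), 2)
    sched = StimulusSchedule(dt=dt, n_steps=n_steps, n_odors=n_odors,
                             odor_maps=list(odor_maps or []))

    for ph, (t0, t1) in zip(phases, spans):
        kind = ph["kind"]
        name = ph.get("name", kind)
        sched.phase_bounds[name] = (t0, t1)
        cursor = t0
        if kind == "quiet":
            continue
        if kind == "odor_series":
            for odor in ph["odors"]:
                for _ in range(ph["stimulations"]):
                    sched.add_odor_pulse(odor, cursor, pulse_duration,
                                         phase=name)
                    cursor += pulse_duration + gap
        elif kind == "octopamine":
            sched.add_octopamine(cursor, ph["duration"],
                                 amplitude=octo_amplitude, training=False)
        elif kind == "training":
            # one octopamine episode spanning the whole block: the AL
            # settles into its octopamine-elevated balance before the
            # stimulations arrive, which keeps the KC set recruited
            # during training odor-specific
            span = ph["stimulations"] * (pulse_duration + gap)
            sched.add_octopamine(t0, span, amplitude=octo_amplitude,
                                 training=True)
            for _ in range(ph["stimulations"]):
                sched.add_odor_pulse(ph["odor"], cursor, pulse_duration,
                                     phase=name)
                cursor += pulse_duration + gap
    return sched


def build_learning_schedule(n_odors: int, trained_odor: int, n_sessions: int,
                            dt: float, odor_maps: list[OdorMap] | None = None,
                            baseline_stims: int = 16, post_stims: int = 16,
                            stims_per_session: int = 5,
                            pulse_duration: float = 0.2, gap: float = 4.0,
                            quiet: float = 5.0,
                            control_octo_duration: float = 10.0,
                            octo_amplitude: float = 1.0) -> StimulusSchedule:
    """Canonical learning-experiment event sequence.

    Quiet baseline; a series of stimulations per odor (naive response);
    a control-octopamine period without odor or training; training on
    one odor (sessions of 5 stimulations under octopamine with the
    Hebbian gate open); quiet; post-training stimulations per odor
    without octopamine.
    """
    phases = [
        {"kind": "quiet", "duration": quiet, "name": "settle"},
        {"kind": "odor_series", "odors": list(range(n_odors)),
         "stimulations": baseline_stims, "name": "baseline"},
        {"kind": "octopamine", "duration": control_octo_duration,
         "name": "control_octopamine"},
        {"kind": "training", "odor": trained_odor,
         "stimulations": n_sessions * stims_per_session, "name": "train"},
        {"kind": "quiet", "duration": quiet, "name": "rest"},
        {"kind": "odor_series", "odors": list(range(n_odors)),
         "stimulations": post_stims, "name": "post"},
    ]
    if n_sessions == 0:
        phases[3] = {"kind": "quiet", "duration": gap, "name": "train"}
    return build_schedule(phases, dt=dt, n_odors=n_odors,
                          odor_maps=odor_maps, pulse_duration=pulse_duration,
                          gap=gap, octo_amplitude=octo_amplitude)
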