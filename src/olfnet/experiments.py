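"""Experiment protocols: the learning battery and the sparsity sweep.

The learning battery runs the canonical conditioning sequence (naive
stimulations, control octopamine, training sessions, post-training
stimulations) for every {trained odor, session count, noise
realization} triple on one moth, and aggregates percent changes in EN
odor response.  Realizations vary only the SDE noise stream; the moth,
its odor maps, and the schedule are held fixed, and every run starts
from the naive plastic weights.

The sparsity sweep varies the lateral-horn inhibition on the Kenyon
cells and records, per level, the percent of KCs active during odor,
the EN response signal-to-noise ratio, and the learning focus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import Moth, MothTemplate, generate_moth
from .dynamics import DynamicsConfig, simulate
from .measures import anova_training_effect, en_snr, kc_stats, learning_focus
from .stimuli import OdorMap, build_learning_schedule, odor_maps_for

__all__ = [
    "LearningProtocol",
    "SparsityProtocol",
    "ExperimentSummary",
    "SparsitySweepResult",
    "run_learning_battery",
    "run_sparsity_sweep",
]


@dataclass
class LearningProtocol:
    """Learning-battery design; defaults give 4 x 4 x 11 = 176 runs."""

    n_odors: int = 4
    baseline_stims: int = 16
    session_counts: tuple = (1, 2, 3, 4)
    stims_per_session: int = 5
    post_stims: int = 16
    n_realizations: int = 11
    pulse_duration: float = 0.2
    gap: float = 4.0
    quiet: float = 5.0
    control_octo_duration: float = 10.0
    octo_amplitude: float = 1.0

    @property
    def n_runs(self) -> int:
        return self.n_odors * len(self.session_counts) * self.n_realizations

    def runs(self):
        """Enumerate (trained_odor, n_sessions, realization) triples."""
        for odor in range(self.n_odors):
            for sessions in self.session_counts:
                for r in range(self.n_realizations):
                    yield odor, sessions, r


@dataclass
class SparsityProtocol:
    """MB-sparsity sweep design: one trained odor, one control."""

    lh_levels: tuple = (16.0, 22.0, 28.0, 36.0, 48.0, 70.0)
    training_stims: int = 15
    baseline_stims: int = 5
    post_stims: int = 5
    n_realizations: int = 3
    pulse_duration: float = 0.2
    gap: float = 4.0
    quiet: float = 5.0
    octo_amplitude: float = 1.0

    def __post_init__(self):
        lv = np.asarray(self.lh_levels, dtype=float)
        if lv.size < 3 or not (np.diff(lv) > 0).all():
            raise ValueError("lh_levels must be >= 3 strictly increasing values")


@dataclass
class ExperimentSummary:
    """Aggregated learning-battery output."""

    runs: pd.DataFrame            # one row per (run, odor) response record
    summary: pd.DataFrame         # mean/std percent change per (trained, sessions, odor)
    anova_p: float
    naive_response: np.ndarray    # per-odor mean naive EN response

    @property
    def naive_spread(self) -> float:
        """Largest-to-smallest ratio of naive EN odor responses."""
        return float(self.naive_response.max() / self.naive_response.min())


def _run_seed(base_seed: int, index: int) -> int:
    # independent, order-invariant per-run streams
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def find_even_moth(template: MothTemplate, n_odors: int, seed: int,
                   max_spread: float = 3.0, max_tries: int = 10,
                   config: DynamicsConfig | None = None):
    """Generate a moth whose naive EN odor responses are within ``max_spread``.

    Moths with highly uneven naive responses learn robustly too, but
    percent-change comparisons across odors become scale-confounded, so
    batteries are run on roughly-even moths.  Tries successive derived
    seeds, probing each candidate with a short baseline-only schedule,
    and returns ``(moth, odor_maps, spread)`` for the first acceptable
    candidate.
    """
    if config is None:
        config = DynamicsConfig.from_template(template)
    best = None
    for k in range(max_tries):
        moth = generate_moth(template, _run_seed(seed, 3 * k))
        maps = odor_maps_for(template, n_odors,
                             np.random.default_rng(_run_seed(seed, 3 * k + 1)))
        sched = build_learning_schedule(n_odors, 0, 0, dt=config.dt,
                                        odor_maps=maps, baseline_stims=3,
                                        post_stims=2)
        res = simulate(moth, sched, config, seed=_run_seed(seed, 3 * k + 2),
                       record=())
        naive = np.array([res.responses("EN", o, "baseline").mean()
                          for o in range(n_odors)])
        if naive.min() <= 0:
            continue
        spread = float(naive.max() / naive.min())
        if spread <= max_spread:
            return moth, maps, spread
        if best is None or spread < best[2]:
            best = (moth, maps, spread)
    if best is None:
        raise RuntimeError("no candidate moth produced positive naive "
                           "responses to every odor")
    return best


def run_learning_battery(moth: Moth, odor_maps: list[OdorMap],
                         protocol: LearningProtocol, seed: int,
                         config: DynamicsConfig | None = None
                         ) -> ExperimentSummary:
    """Execute the full battery on one moth; deterministic given seed.

    Per-run seeds are derived by counter from ``seed``, so results do
    not depend on execution order.  Returns per-run records, a
    mean +/- std table per {trained odor, sessions}, and the one-way
    ANOVA p-value for trained-vs-control percent changes.
    """
    if len(odor_maps) < protocol.n_odors:
        raise ValueError("not enough odor maps for the protocol")
    if config is None:
        config = DynamicsConfig.from_template(moth.template)
    t = moth.template
    records = []
    for idx, (trained, sessions, real) in enumerate(protocol.runs()):
        sched = build_learning_schedule(
            protocol.n_odors, trained, sessions, dt=config.dt,
            odor_maps=odor_maps[:protocol.n_odors],
            baseline_stims=protocol.baseline_stims,
            post_stims=protocol.post_stims,
            stims_per_session=protocol.stims_per_session,
            pulse_duration=protocol.pulse_duration, gap=protocol.gap,
            quiet=protocol.quiet,
            control_octo_duration=protocol.control_octo_duration,
            octo_amplitude=protocol.octo_amplitude)
        res = simulate(moth, sched, config, seed=_run_seed(seed, idx),
                       record=())
        for odor in range(protocol.n_odors):
            naive = res.responses("EN", odor, "baseline").mean()
            post = res.responses("EN", odor, "post").mean()
            pct = 100.0 * (post - naive) / naive if naive > 0 else np.nan
            records.append({
                "trained_odor": trained, "sessions": sessions,
                "realization": real, "odor": odor,
                "role": "trained" if odor == trained else "control",
                "naive": naive, "post": post, "pct_change": pct,
            })
    runs = pd.DataFrame.from_records(records)

    summary = (runs.groupby(["trained_odor", "sessions", "role", "odor"])
               ["pct_change"].agg(["mean", "std"]).reset_index())
    p = anova_training_effect(
        runs.loc[runs.role == "trained", "pct_change"].to_numpy(),
        runs.loc[runs.role == "control", "pct_change"].to_numpy())
    naive_by_odor = runs.groupby("odor")["naive"].mean().to_numpy()
    return ExperimentSummary(runs=runs, summary=summary, anova_p=p,
                             naive_response=naive_by_odor)


@dataclass
class SparsitySweepResult:
    """Per-level sparsity/SNR/focus table plus cubic trend fits."""

    table: pd.DataFrame           # level, pct_active, snr, focus
    snr_fit: np.ndarray           # cubic polynomial coefficients vs pct_active
    focus_fit: np.ndarray


def run_sparsity_sweep(template: MothTemplate, protocol: SparsityProtocol,
                       seed: int) -> SparsitySweepResult:
    """Sweep lateral-horn inhibition and measure the SNR/focus trade-off.

    One moth and one odor pair (trained + control) are generated from
    ``seed`` — selected so the two naive EN responses are roughly even,
    as the focus ratio compares raw post-training responses — and
    reused at every inhibition level; realizations vary the noise
    stream.  Per level the result reports the mean percent of KCs
    responding to odor (naive), the naive EN response SNR, and the
    post-training learning focus.
    """
    moth, odor_maps, _ = find_even_moth(template, 2, seed, max_spread=1.5)
    sessions = int(np.ceil(protocol.training_stims / 5))
    rows = []
    for li, level in enumerate(protocol.lh_levels):
        config = DynamicsConfig.from_template(template, lh_inhibition=level)
        sched = build_learning_schedule(
            2, 0, sessions, dt=config.dt, odor_maps=odor_maps,
            baseline_stims=protocol.baseline_stims,
            post_stims=protocol.post_stims,
            stims_per_session=min(protocol.training_stims, 5),
            pulse_duration=protocol.pulse_duration, gap=protocol.gap,
            quiet=protocol.quiet,
            octo_amplitude=protocol.octo_amplitude)
        pct_active, snrs, focus = [], {0: [], 1: []}, []
        for r in range(protocol.n_realizations):
            res = simulate(moth, sched, config, record=(),
                           seed=_run_seed(seed, li * 1000 + r))
            for o in (0, 1):
                resp_k = res.responses("KC", o, "baseline")
                pct_active.append(kc_stats(resp_k).percent_active)
                snrs[o].append(res.responses("EN", o, "baseline"))
            focus.append(learning_focus(res.responses("EN", 0, "post"),
                                        res.responses("EN", 1, "post")))
        snr = np.nanmean([en_snr(np.concatenate(snrs[o])) for o in (0, 1)])
        rows.append({"lh_inhibition": level,
                     "pct_active": float(np.mean(pct_active)),
                     "snr": float(snr),
                     "focus": float(np.mean(focus))})
    table = pd.DataFrame(rows)
    ok = np.isfinite(table.snr) & np.isfinite(table.focus)
    deg = min(3, max(1, int(ok.sum()) - 1))
    snr_fit = np.polyfit(table.pct_active[ok], table.snr[ok], deg)
    focus_fit = np.polyfit(table.pct_active[ok], table.focus[ok], deg)
    return SparsitySweepResult(table=table, snr_fit=snr_fit,
                               focus_fit=focus_fit)
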