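"""Firing-rate statistics and figures of merit.

The central quantity is the Mahalanobis-style activity measure

    M(t) = (F(t) - mu_bar_S(t)) / sigma_S(t),

the distance of the raw rate F from a smoothed estimate of the mean
spontaneous rate, in units of the locally-windowed spontaneous
standard deviation.  It normalizes away the up-to-40x spread in raw
spontaneous rates between neurons, so downstream responses can be
compared on a common scale.  Neurons with spontaneous rate below
1 spike/s are excluded (the Gaussian noise-envelope assumption fails
there).

Also here: KC sparsity/consistency statistics, the EN response
signal-to-noise ratio mu(f)/sigma(f), the learning focus
mu(f_T)/mu(f_C) comparing trained and control odors post-training, and
the one-way ANOVA for the differential effect of training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FRStats",
    "KCStats",
    "fr_measure",
    "classify_response",
    "kc_stats",
    "window_response",
    "response_summary",
    "en_snr",
    "learning_focus",
    "anova_training_effect",
]

EXCLUSION_RATE = 1.0        # spikes/s; neurons quieter than this are ignored
HEATMAP_THRESHOLD = 2.5     # |M| envelope for excited/inhibited display
STRONG_THRESHOLD = 2.0      # |M| cut for "strong" response statistics


@dataclass
class FRStats:
    """Per-neuron spontaneous-rate statistics and the M(t) measure."""

    F: np.ndarray               # raw rate series, spikes/s
    spontaneous_mask: np.ndarray
    mu_s: np.ndarray            # moving average of spontaneous rate (full grid)
    mu_bar: np.ndarray          # smoothed (quadratic) fit of mu_s (full grid)
    sigma_s: np.ndarray         # windowed spontaneous std (full grid)
    M: np.ndarray               # activity measure; NaN if excluded
    excluded: bool


def fr_measure(F: np.ndarray, spontaneous_mask: np.ndarray, dt: float,
               window: float = 10.0) -> FRStats:
    """Compute M(t) for one neuron's rate series.

    ``spontaneous_mask`` marks the no-odor segments used to estimate
    the spontaneous statistics.  ``mu_s`` is a centered moving average
    of the spontaneous samples, ``mu_bar`` a quadratic fit of ``mu_s``
    over time (tracking slow drifts, e.g. under octopamine), and
    ``sigma_s(t)`` the standard deviation of the spontaneous residuals
    within a moving window of length ``window`` centered on ``t``.
    """
    F = np.asarray(F, dtype=float)
    mask = np.asarray(spontaneous_mask, dtype=bool)
    if F.ndim != 1 or mask.shape != F.shape:
        raise ValueError("F and spontaneous_mask must be equal-length 1-D")
    if not mask.any():
        raise ValueError("spontaneous mask selects no samples")
    t = np.arange(F.size) * dt
    t_s, S = t[mask], F[mask]

    if S.mean() < EXCLUSION_RATE:
        nan = np.full_like(F, np.nan)
        return FRStats(F, mask, nan, nan, nan, nan, excluded=True)

    w = max(int(round(window / dt)), 1)
    mu_s_sp = (pd.Series(S).rolling(w, center=True, min_periods=1)
               .mean().to_numpy())
    mu_s = np.interp(t, t_s, mu_s_sp)

    coef = np.polyfit(t_s, mu_s_sp, deg=2)
    mu_bar = np.polyval(coef, t)

    resid = S - np.polyval(coef, t_s)
    # windowed std of residuals via cumulative sums over the sorted
    # spontaneous sample times
    lo = np.searchsorted(t_s, t - window / 2.0)
    hi = np.searchsorted(t_s, t + window / 2.0)
    c1 = np.concatenate([[0.0], np.cumsum(resid)])
    c2 = np.concatenate([[0.0], np.cumsum(resid ** 2)])
    n = np.maximum(hi - lo, 1)
    m1 = (c1[hi] - c1[lo]) / n
    var = np.maximum((c2[hi] - c2[lo]) / n - m1 ** 2, 0.0)
    sigma = np.sqrt(var)
    # a (near-)constant spontaneous segment has no noise scale beyond
    # fit round-off; unit sigma keeps M finite (and zero wherever F
    # tracks mu_bar)
    tol = 1e-8 * max(1.0, float(np.abs(S).max()))
    fallback = resid.std() if resid.std() > tol else 1.0
    sigma[(hi - lo) < 2] = fallback
    sigma[sigma <= tol] = fallback

    M = (F - mu_bar) / sigma
    return FRStats(F, mask, mu_s, mu_bar, sigma, M, excluded=False)


def classify_response(M, threshold: float = HEATMAP_THRESHOLD) -> np.ndarray:
    """Label M values as ``excited``/``inhibited``/``within`` the envelope."""
    M = np.asarray(M, dtype=float)
    return np.select([M > threshold, M < -threshold], ["excited", "inhibited"],
                     default="within")


@dataclass
class KCStats:
    """Sparsity and trial-to-trial consistency of KC odor responses."""

    consistency: np.ndarray       # per KC, % of pulses with response >= cut
    levels: np.ndarray            # consistency levels, %
    percent_at_level: np.ndarray  # % of KCs responding at >= each level
    percent_active: float         # % of KCs responding to at least one pulse

    def percent_responding(self, level: float) -> float:
        """% of KCs with response consistency at or above ``level`` %."""
        return float(np.mean(self.consistency >= level) * 100.0)


def kc_stats(responses: np.ndarray, threshold: float = EXCLUSION_RATE,
             levels: np.ndarray | None = None) -> KCStats:
    """KC activation statistics over repeated pulses of one odor.

    ``responses`` is (n_pulses, n_kc): per-pulse mean rates.  A KC
    "responds" to a pulse when its windowed rate reaches ``threshold``
    (1 spike/s by default, matching the active/silent display cut).
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if responses.shape[0] < 2:
        raise ValueError("need at least 2 pulses to assess consistency")
    hits = responses >= threshold
    consistency = hits.mean(axis=0) * 100.0
    if levels is None:
        levels = np.arange(10.0, 101.0, 10.0)
    pct = np.array([(consistency >= lv).mean() * 100.0 for lv in levels])
    return KCStats(consistency=consistency, levels=np.asarray(levels),
                   percent_at_level=pct,
                   percent_active=float((consistency > 0).mean() * 100.0))


def window_response(series: np.ndarray, dt: float, onset: float,
                    duration: float, tail: float = 0.3) -> float:
    """Mean rate in a pulse window extended by ``tail`` seconds."""
    i0 = int(round(onset / dt))
    i1 = min(int(round((onset + duration + tail) / dt)), len(series))
    if i1 <= i0:
        raise ValueError("response window is empty")
    return float(np.mean(series[i0:i1]))


def response_summary(rates: np.ndarray, dt: float, schedule,
                     window: float = 10.0) -> pd.DataFrame:
    """Per-neuron response statistics over a simulated schedule.

    ``rates`` is ``(n_steps, n_neurons)`` on the schedule grid.  One
    row per neuron with the five summary columns: mean spontaneous
    rate ``mu_s``; noisiness ``sigma_over_mu``; strongest odor-window
    excursion in spontaneous-sigma units (M), without and with
    octopamine; and the mean spontaneous-rate shift under octopamine,
    also in sigma units.  Excluded (sub-1 spike/s) neurons carry NaNs.
    """
    n_steps = rates.shape[0]
    t = np.arange(n_steps) * dt
    in_pulse = np.zeros(n_steps, dtype=bool)
    for p in schedule.pulses:
        i0 = int(round(p.onset / dt))
        i1 = min(int(round((p.onset + p.duration + 0.3) / dt)), n_steps)
        in_pulse[i0:i1] = True
    octo_on = schedule.octopamine[:n_steps] > 0
    spont = ~in_pulse & ~octo_on          # no odor, no octopamine
    odor_plain = in_pulse & ~octo_on
    odor_octo = in_pulse & octo_on
    octo_only = ~in_pulse & octo_on

    def seg_med(M, mask):
        if not mask.any():
            return np.nan
        m = M[mask]
        # signed value of the strongest excursion (Mahalanobis units)
        return float(m[np.nanargmax(np.abs(m))])

    rows = []
    for j in range(rates.shape[1]):
        st = fr_measure(rates[:, j].astype(float), spont, dt, window=window)
        if st.excluded:
            rows.append({"neuron": j, "mu_s": np.nan, "sigma_over_mu": np.nan,
                         "odor_response": np.nan, "odor_response_octo": np.nan,
                         "octo_shift": np.nan, "excluded": True})
            continue
        mu = float(rates[spont, j].mean())
        sig = float(np.median(st.sigma_s[spont]))
        octo_shift = (float(np.nanmean(st.M[octo_only]))
                      if octo_only.any() else np.nan)
        rows.append({"neuron": j, "mu_s": mu,
                     "sigma_over_mu": sig / mu if mu > 0 else np.nan,
                     "odor_response": seg_med(st.M, odor_plain),
                     "odor_response_octo": seg_med(st.M, odor_octo),
                     "octo_shift": octo_shift, "excluded": False})
    return pd.DataFrame(rows)


def en_snr(f: np.ndarray) -> float:
    """Signal-to-noise ratio mu(f)/sigma(f) of per-pulse EN responses.

    Returns NaN when the responses have zero spread (SNR undefined).
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise ValueError("need at least 2 responses for an SNR")
    s = f.std(ddof=1)
    if s == 0.0:
        return float("nan")
    return float(f.mean() / s)


def learning_focus(f_trained: np.ndarray, f_control: np.ndarray) -> float:
    """mu(f_T)/mu(f_C): post-training EN gain concentration on the
    trained odor.  Returns +inf when the control mean is zero."""
    mu_t = float(np.mean(f_trained))
    mu_c = float(np.mean(f_control))
    if mu_c == 0.0:
        return float("inf")
    return mu_t / mu_c


def anova_training_effect(trained: np.ndarray,
                          control: np.ndarray) -> float:
    """One-way ANOVA p-value, trained vs control percent changes.

    Groups are post-training percent changes in EN response across
    noise realizations; a small p indicates training affected the
    reinforced odor differentially.
    """
    trained = np.asarray(trained, dtype=float)
    control = np.asarray(control, dtype=float)
    if trained.size < 2 or control.size < 2:
        raise ValueError("need at least 2 realizations per group")
    pooled = np.concatenate([trained, control])
    if np.allclose(pooled.var(), 0.0):
        raise ValueError("degenerate variance: all percent changes equal")
    return float(stats.f_oneway(trained, control).pvalue)
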