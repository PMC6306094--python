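"""Moth generation: connection matrices and spontaneous rates.

A :class:`MothTemplate` is a declarative parameter set describing the
statistics of one species-typical moth olfactory network: the antennal
lobe (AL, ~60 glomeruli with receptor, lateral and projection neurons),
the mushroom body (MB, ~2000 Kenyon cells), a small population of
inhibitory projection neurons (QNs), and a single extrinsic readout
neuron (EN).  :func:`generate_moth` samples one realization — a
:class:`Moth` — holding every connection matrix and the receptor-neuron
spontaneous rates.

Connection weights are drawn from Gaussians whose standard deviation is
proportional to the class mean (``sigma = weight_cv * mu``), clipped at
zero so that all matrices are nonnegative; signs are carried by the
dynamics equations, not the matrices.  AL-internal inhibitory matrices
are built in two stages so that weights correlate both within a
glomerulus (shared glomerular arborization factor) and within a target
type (shared class mean).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MothTemplate",
    "Moth",
    "MothConfigError",
    "generate_moth",
    "make_glomerular_matrix",
    "apply_gaba_sensitivity",
    "draw_rn_spontaneous",
]


class MothConfigError(ValueError):
    """Raised when a template field is structurally invalid."""


@dataclass
class MothTemplate:
    """Generative parameter set for a moth olfactory network.

    Connection means ``mu_*`` are named source-to-target, e.g. ``mu_lp``
    is the mean lateral-neuron -> projection-neuron inhibitory weight.
    The lateral-inhibition means default to the calibrated
    LN->RN : LN->LN : LN->PN ratio of 6:2:1.
    """

    # --- network sizes ---
    n_glomeruli: int = 60
    n_pn_per_glomerulus: int = 1  # one modeled PN signal per glomerulus
    n_kc: int = 2000
    n_qn: int = 15
    n_en: int = 1
    kc_degree: int = 10           # glomeruli sampled per Kenyon cell
    qn_degree: int = 20           # glomeruli pooled per QN (~nG/3)

    # --- connection-weight means (spikes/s gain units) ---
    mu_rp: float = 1.0            # RN -> PN (diagonal)
    mu_rl: float = 0.5            # RN -> LN (diagonal)
    mu_lr: float = 0.030          # LN -> RN   } 6
    mu_ll: float = 0.010          # LN -> LN   } 2
    mu_lp: float = 0.005          # LN -> PN   } 1
    mu_rq: float = 0.05           # RN -> QN (pooled)
    mu_lq: float = 0.005          # LN -> QN (pooled, PN-like)
    mu_pk: float = 0.50           # PN -> KC
    mu_qk: float = 0.15           # QN -> KC
    mu_ke: float = 0.02           # KC -> EN (uniform at generation)

    # --- variance scaling ---
    weight_cv: float = 0.3        # sigma_c = weight_cv * mu_c for all classes
    gaba_cv: float = 0.3          # per-glomerulus GABA-sensitivity spread (LN->PN only)

    # --- octopamine weight means (diagonal channels; not plastic) ---
    mu_octo_rn: float = 0.6
    mu_octo_ln: float = 0.4
    mu_octo_pn: float = 0.0       # PNs receive no direct octopamine drive

    # --- RN spontaneous rates: bias + Gamma(shape, rate), spikes/s ---
    rn_spont_shape: float = 1.5
    rn_spont_rate: float = 0.3
    rn_spont_bias: float = 0.5

    # --- shared dynamics parameters ---
    tau: float = 0.5             # decay constant, s
    noise: float = 3.0            # SDE noise intensity epsilon (AL populations)
    sigmoid_slope: float = 1.0
    sigmoid_max: float = 180.0    # firing-rate ceiling, spikes/s
    gamma_inh: float = 0.3        # octopamine scaling on inhibitory terms
    lh_inhibition: float = 30.0   # constant lateral-horn damping on KCs
    dt: float = 0.010             # integration timestep, s

    # --- Hebbian growth rates (per spike^2 per s) ---
    gamma_pk: float = 5.0e-6
    gamma_qk: float = 8.0e-6
    gamma_ke: float = 1.0e-6

    # --- odor input statistics ---
    odor_strength: float = 800.0   # mean peak RN drive on a hit glomerulus, spikes/s
    hits_per_odor: int = 20

    def validate(self) -> None:
        """Raise :class:`MothConfigError` naming the first offending field."""
        for name in ("n_glomeruli", "n_pn_per_glomerulus", "n_kc", "n_qn",
                     "n_en", "kc_degree", "qn_degree", "hits_per_odor"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise MothConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if self.kc_degree > self.n_glomeruli:
            raise MothConfigError("kc_degree cannot exceed n_glomeruli")
        if self.qn_degree > self.n_glomeruli:
            raise MothConfigError("qn_degree cannot exceed n_glomeruli")
        if self.hits_per_odor > self.n_glomeruli:
            raise MothConfigError("hits_per_odor cannot exceed n_glomeruli")
        for name in ("mu_rp", "mu_rl", "mu_lr", "mu_ll", "mu_lp", "mu_rq",
                     "mu_lq", "mu_pk", "mu_qk", "mu_ke", "mu_octo_rn",
                     "mu_octo_ln", "mu_octo_pn", "weight_cv", "gaba_cv",
                     "noise", "gamma_inh", "lh_inhibition", "gamma_pk",
                     "gamma_qk", "gamma_ke", "odor_strength",
                     "rn_spont_bias"):
            if getattr(self, name) < 0:
                raise MothConfigError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        for name in ("tau", "dt", "sigmoid_slope", "sigmoid_max",
                     "rn_spont_shape", "rn_spont_rate"):
            if getattr(self, name) <= 0:
                raise MothConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MothTemplate":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise MothConfigError(f"unknown template fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Moth:
    """One sampled network realization.

    Matrices are oriented ``[target, source]`` so that the drive onto a
    population is ``M @ rates``.  Diagonal matrices (RN->PN, RN->LN and
    the octopamine channels) are stored as length-``n_glomeruli``
    vectors of their diagonals.
    """

    template: MothTemplate
    seed: int
    M_LG: np.ndarray          # glomerulus->glomerulus LN arborization (nG, nG)
    M_LR: np.ndarray          # LN -> RN inhibition (nG, nG), zero diagonal
    M_LL: np.ndarray          # LN -> LN inhibition (nG, nG), zero diagonal
    M_LP: np.ndarray          # LN -> PN inhibition (nG, nG), zero diagonal
    M_RP: np.ndarray          # RN -> PN gain, diagonal as (nG,)
    M_RL: np.ndarray          # RN -> LN gain, diagonal as (nG,)
    M_RQ: np.ndarray          # RN -> QN pooled excitation (nQN, nG)
    M_LQ: np.ndarray          # LN -> QN pooled inhibition (nQN, nG)
    M_PK: np.ndarray          # PN -> KC excitation (nKC, nG), sparse rows
    M_QK: np.ndarray          # QN -> KC inhibition (nKC, nQN)
    M_KE: np.ndarray          # KC -> EN excitation (nEN, nKC), uniform at start
    M_OR: np.ndarray          # octopamine -> RN, diagonal as (nG,)
    M_OL: np.ndarray          # octopamine -> LN, diagonal as (nG,)
    M_OP: np.ndarray          # octopamine -> PN, diagonal as (nG,)
    rn_spont: np.ndarray      # RN spontaneous rates (nG,), spikes/s
    pk_mask: np.ndarray = field(default=None)  # structural PN->KC connectivity (bool)

    def plastic_weights(self) -> dict:
        """Fresh copies of the three plastic matrices (naive state)."""
        return {"M_PK": self.M_PK.copy(),
                "M_QK": self.M_QK.copy(),
                "M_KE": self.M_KE.copy()}


def _clipped_normal(rng: np.random.Generator, mean: float, cv: float,
                    shape) -> np.ndarray:
    """Gaussian with std proportional to the mean, clipped at zero."""
    if mean == 0.0:
        return np.zeros(shape)
    return np.clip(rng.normal(mean, cv * mean, size=shape), 0.0, None)


def make_glomerular_matrix(template: MothTemplate,
                           rng: np.random.Generator) -> np.ndarray:
    """Glomerulus-to-glomerulus LN arborization strengths.

    Unit mean, zero diagonal (a glomerulus does not inhibit itself).
    Shared by all type-specific lateral-inhibition matrices, which makes
    weights onto different neuron types within a glomerulus correlated.
    """
    nG = template.n_glomeruli
    if nG < 2:
        raise MothConfigError("n_glomeruli must be >= 2 for lateral inhibition")
    M = _clipped_normal(rng, 1.0, template.weight_cv, (nG, nG))
    np.fill_diagonal(M, 0.0)
    return M


def apply_gaba_sensitivity(M_LP: np.ndarray, rng: np.random.Generator,
                           factor: float) -> np.ndarray:
    """Rescale each target glomerulus's LN->PN weights by a sensitivity draw.

    Models per-glomerulus sensitivity to GABA; mean sensitivity is 1 so
    the expected weights are unchanged.  Applies to LN->PN(QN)
    connections only; the caller must not route LN->RN or LN->LN
    matrices through here.
    """
    if factor < 0:
        raise MothConfigError(f"gaba_cv must be >= 0, got {factor!r}")
    sens = _clipped_normal(rng, 1.0, factor, M_LP.shape[0])
    return M_LP * sens[:, None]


def draw_rn_spontaneous(template: MothTemplate,
                        rng: np.random.Generator) -> np.ndarray:
    """RN spontaneous firing rates: bias + Gamma(shape, rate) per glomerulus."""
    g = rng.gamma(template.rn_spont_shape, 1.0 / template.rn_spont_rate,
                  size=template.n_glomeruli)
    return template.rn_spont_bias + g


def _lateral_matrix(M_LG: np.ndarray, c_type: float, cv: float,
                    rng: np.random.Generator) -> np.ndarray:
    # type-specific mean times the shared glomerular factor, with an
    # independent per-entry perturbation; diagonal stays exactly zero
    M = c_type * M_LG * _clipped_normal(rng, 1.0, cv, M_LG.shape)
    np.fill_diagonal(M, 0.0)
    return M


def _row_subset_mask(rng: np.random.Generator, n_rows: int, n_cols: int,
                     degree: int) -> np.ndarray:
    """Boolean mask with exactly ``degree`` True entries per row, uniform."""
    order = rng.random((n_rows, n_cols)).argsort(axis=1)
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    np.put_along_axis(mask, order[:, :degree], True, axis=1)
    return mask


def generate_moth(template: MothTemplate, seed: int) -> Moth:
    """Sample one moth realization; pure function of (template, seed)."""
    template.validate()
    rng = np.random.default_rng(seed)
    nG, nKC, nQN, nEN = (template.n_glomeruli, template.n_kc,
                         template.n_qn, template.n_en)
    cv = template.weight_cv

    M_LG = make_glomerular_matrix(template, rng)
    M_LR = _lateral_matrix(M_LG, template.mu_lr, cv, rng)
    M_LL = _lateral_matrix(M_LG, template.mu_ll, cv, rng)
    M_LP = apply_gaba_sensitivity(
        _lateral_matrix(M_LG, template.mu_lp, cv, rng), rng, template.gaba_cv)

    M_RP = _clipped_normal(rng, template.mu_rp, cv, nG)
    M_RL = _clipped_normal(rng, template.mu_rl, cv, nG)

    qn_mask = _row_subset_mask(rng, nQN, nG, template.qn_degree)
    M_RQ = _clipped_normal(rng, template.mu_rq, cv, (nQN, nG)) * qn_mask
    M_LQ = _clipped_normal(rng, template.mu_lq, cv, (nQN, nG)) * qn_mask

    pk_mask = _row_subset_mask(rng, nKC, nG, template.kc_degree)
    M_PK = _clipped_normal(rng, template.mu_pk, cv, (nKC, nG)) * pk_mask
    M_QK = _clipped_normal(rng, template.mu_qk, cv, (nKC, nQN))
    # all KC->EN weights equal at the start of training
    M_KE = np.full((nEN, nKC), template.mu_ke)

    M_OR = _clipped_normal(rng, template.mu_octo_rn, cv, nG)
    M_OL = _clipped_normal(rng, template.mu_octo_ln, cv, nG)
    M_OP = _clipped_normal(rng, template.mu_octo_pn, cv, nG)

    rn_spont = draw_rn_spontaneous(template, rng)

    return Moth(template=template, seed=int(seed), M_LG=M_LG, M_LR=M_LR,
                M_LL=M_LL, M_LP=M_LP, M_RP=M_RP, M_RL=M_RL, M_RQ=M_RQ,
                M_LQ=M_LQ, M_PK=M_PK, M_QK=M_QK, M_KE=M_KE, M_OR=M_OR,
                M_OL=M_OL, M_OP=M_OP, rn_spont=rn_spont, pk_mask=pk_mask)
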