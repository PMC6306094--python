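"""Fixture generation, configuration parsing and serialization.

Templates round-trip through flat YAML; moths are archived as NumPy
``.npz`` files with JSON metadata; simulation timecourses are written
both as tidy long-format CSV (``time_s, population, index, rate_sps``)
and as compact array archives.  All randomness flows from explicit
seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import Moth, MothConfigError, MothTemplate
from .dynamics import POPULATIONS, SimResult

__all__ = [
    "make_default_template",
    "template_hash",
    "save_template",
    "load_template",
    "save_moth",
    "load_moth",
    "write_timecourses",
    "read_timecourses",
    "RunManifest",
]


def make_default_template() -> MothTemplate:
    """The documented default moth template (model defaults).

    60 glomeruli, 2000 Kenyon cells, 15 QNs, one EN; lateral-inhibition
    means in the 6:2:1 RN:LN:PN ratio; no direct octopamine drive onto
    PNs; 10 ms timestep.
    """
    return MothTemplate()


def template_hash(template: MothTemplate) -> str:
    """Stable short hash of the full parameter set."""
    blob = json.dumps(template.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_template(template: MothTemplate, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(template.to_dict(), fh, sort_keys=True)


def load_template(path) -> MothTemplate:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise MothConfigError(f"template file {path} is not a flat mapping")
    return MothTemplate.from_dict(d)


_MOTH_ARRAYS = ("M_LG", "M_LR", "M_LL", "M_LP", "M_RP", "M_RL", "M_RQ",
                "M_LQ", "M_PK", "M_QK", "M_KE", "M_OR", "M_OL", "M_OP",
                "rn_spont", "pk_mask")


def save_moth(moth: Moth, path) -> None:
    """Archive every matrix plus seed and template metadata."""
    arrays = {name: getattr(moth, name) for name in _MOTH_ARRAYS}
    meta = json.dumps({"seed": moth.seed,
                       "template": moth.template.to_dict(),
                       "template_hash": template_hash(moth.template)})
    np.savez_compressed(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **arrays)


def load_moth(path) -> Moth:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        arrays = {name: z[name] for name in _MOTH_ARRAYS}
    template = MothTemplate.from_dict(meta["template"])
    return Moth(template=template, seed=meta["seed"], **arrays)


def write_timecourses(result: SimResult, path) -> None:
    """Tidy long-format CSV: time_s, population, index, rate_sps."""
    frames = []
    for pop, arr in result.rates.items():
        n_t, n = arr.shape
        frames.append(pd.DataFrame({
            "time_s": np.repeat(result.time, n),
            "population": pop,
            "index": np.tile(np.arange(n), n_t),
            "rate_sps": arr.ravel(),
        }))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["time_s", "population", "index",
                                     "rate_sps"]))
    df.to_csv(path, index=False)


def read_timecourses(path) -> dict:
    """Read a tidy timecourse table back into per-population arrays.

    Returns ``{"time": t, "rates": {population: (n_t, n) array}}``.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface parser diagnostics with context
        raise ValueError(f"malformed timecourse file {path}: {exc}") from exc
    required = {"time_s", "population", "index", "rate_sps"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"timecourse file {path} missing columns "
            f"{sorted(required - set(df.columns))}")
    unknown = set(df.population.unique()) - set(POPULATIONS)
    if unknown:
        raise ValueError(f"unknown population labels {sorted(unknown)}")
    rates = {}
    time = None
    for pop, grp in df.groupby("population", sort=False):
        piv = grp.pivot(index="time_s", columns="index", values="rate_sps")
        rates[pop] = piv.to_numpy()
        time = piv.index.to_numpy()
    return {"time": time if time is not None else np.array([]),
            "rates": rates}


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-exactly."""

    template_hash: str
    seeds: dict
    version: str
    phase_bounds: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
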