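"""Flat run configuration with validated defaults and a provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model import ValidationError

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Every knob the pipeline exposes, with the package-wide defaults."""

    # model structure
    degradation_pathway: str = "four_step"
    ikk_kinetics: str = "hill"
    a20_feedback: str = "dual_site"
    # solver
    rtol: float = 1e-8
    atol: float = 1e-10
    # equilibration
    eq_tol: float = 1e-9
    eq_t_max: float = 1e5
    # normalization reference times (min)
    nfkb_ref_time: float = 20.0
    ikk_ref_time: float = 5.0
    # driven-input tail: constant level beyond the last knot, as a fraction
    # of the 5-min peak
    tail_fraction: float = 0.05
    # assumed peak active-IKK concentration when scaling normalized IKK
    # data into a µM drive
    ikk_scale_uM: float = 0.03
    # synthetic data
    n_experiments_nfkb: int = 5
    n_replicates_nfkb: int = 3
    n_experiments_ikk: int = 3
    n_replicates_ikk: int = 1
    noise_base_sd: float = 0.05
    noise_prop_sd: float = 0.05
    # estimation
    n_starts: int = 50
    objective: str = "sse"
    # seeds and output
    seed: int = 1
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.eq_tol <= 0:
            raise ValidationError("solver tolerances must be positive")
        if self.objective not in ("sse", "chi2F"):
            raise ValidationError(f"unknown objective {self.objective!r}")
        if self.n_starts < 1:
            raise ValidationError("n_starts must be ≥ 1")
        if not 0 <= self.tail_fraction <= 1:
            raise ValidationError("tail_fraction must lie in [0, 1]")

    def hash(self) -> str:
        """Short digest embedded in outputs for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
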