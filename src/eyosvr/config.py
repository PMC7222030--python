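"""Run configuration: YAML-backed, strictly validated, reproducible.

A ``RunConfig`` collects every stage's parameters under one master seed.
Unknown keys are rejected rather than ignored, and the resolved
configuration is written next to every output so any table can be
regenerated from the run log alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .cv_engine import CVConfig
from .datatypes import MODALITIES
from .errors import ConfigurationError
from .synthetic_data import CohortSpec

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything the pipeline needs, in one frozen object.

    The nested-CV ensemble defaults to the reduced 2x10x2x10 = 400-model
    design; the full 10^4-model bookkeeping is a configuration away
    (``cv: {n_outer_perms: 10, n_inner_perms: 10}``).
    """

    seed: int = 0
    modalities: str = "AFGC"
    sweep_subsets: Optional[tuple[str, ...]] = None  # None = all 15
    enrichment_strategies: tuple[str, ...] = ("G", "AG", "AGC", "AFGC")
    windows: tuple[int, ...] = (1, 2, 3, 4)
    fractions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40)
    alpha: float = 0.05
    power: float = 0.8
    reference_group_adad: str = "NC"
    reference_group_sporadic: str = "CN"
    scaler_ddof: int = 1
    r2_kind: str = "partial"
    fit_mixed: bool = True
    adad: dict = field(default_factory=dict)      # CohortSpec overrides
    sporadic: dict = field(default_factory=dict)  # CohortSpec overrides
    cv: dict = field(default_factory=lambda: {"n_outer_perms": 2, "n_inner_perms": 2})

    def __post_init__(self) -> None:
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ConfigurationError(f"unknown modalities {sorted(bad)}")
        # fail fast on unknown nested keys
        for attr, cls in (("adad", CohortSpec), ("sporadic", CohortSpec)):
            allowed = {f.name for f in dataclasses.fields(cls)}
            unknown = set(getattr(self, attr)) - allowed
            if unknown:
                raise ConfigurationError(f"unknown {attr} spec keys: {sorted(unknown)}")
        allowed_cv = {f.name for f in dataclasses.fields(CVConfig)}
        unknown = set(self.cv) - allowed_cv
        if unknown:
            raise ConfigurationError(f"unknown cv keys: {sorted(unknown)}")

    # -- derived stage configs --------------------------------------------
    def adad_spec(self) -> CohortSpec:
        return CohortSpec.adad_default(seed=self.seed, **self.adad)

    def sporadic_spec(self) -> CohortSpec:
        return CohortSpec.sporadic_default(seed=self.seed + 1, **self.sporadic)

    def cv_config(self, seed_offset: int = 0) -> CVConfig:
        kw = dict(self.cv)
        kw.setdefault("seed", self.seed + 2 + seed_offset)
        return CVConfig(**kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("sweep_subsets", "enrichment_strategies", "windows", "fractions"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """Load a RunConfig from YAML (all keys optional), rejecting unknowns."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for key in ("sweep_subsets", "enrichment_strategies"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    for key in ("windows",):
        if key in data:
            data[key] = tuple(int(v) for v in data[key])
    if "fractions" in data:
        data["fractions"] = tuple(float(v) for v in data["fractions"])
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
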