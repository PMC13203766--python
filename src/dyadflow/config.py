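"""Run configuration for end-to-end pipeline runs.

A :class:`RunConfig` captures everything a run needs — input location or
simulation spec, sampling rate, scale grid, estimator parameters,
exclusion thresholds and the master seed — and round-trips losslessly
through YAML so a run can be reproduced from its logged config.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .infotheory import EntropyParams, ScaleGrid
from .simulate import CohortSpec, EffectMap, SimConfig

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "dyadflow_out"
    rr_dir: str | None = None  # read RR CSVs from here instead of simulating
    fs: float = 20.0
    n_dyads: int = 10
    duration: float = 600.0
    seed: int = 0
    min_run_s: float = 10.0
    max_low_fraction: float = 0.05
    taus: tuple[float, ...] | None = None  # None -> ScaleGrid.default(fs)
    summary_interval: tuple[float, float] = (0.5, 2.5)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    cohort: CohortSpec | None = None

    def scale_grid(self) -> ScaleGrid:
        if self.taus is None:
            return ScaleGrid.default(self.fs)
        return ScaleGrid(tuple(self.taus), tuple(self.summary_interval))

    def cohort_spec(self) -> CohortSpec:
        if self.cohort is not None:
            return self.cohort
        return CohortSpec(
            n_dyads=self.n_dyads,
            sim=SimConfig(duration=self.duration),
            seed=self.seed,
        )

    # -- YAML round-trip ----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if raw.get("entropy") is not None:
            raw["entropy"] = EntropyParams(**raw["entropy"])
        else:
            raw.pop("entropy", None)
        if raw.get("cohort") is not None:
            c = dict(raw["cohort"])
            if c.get("effects") is not None:
                c["effects"] = EffectMap(**c["effects"])
            if c.get("sim") is not None:
                s = dict(c["sim"])
                for k in ("maternal_oscillators", "fetal_oscillators"):
                    if k in s:
                        s[k] = tuple(tuple(o) for o in s[k])
                c["sim"] = SimConfig(**s)
            raw["cohort"] = CohortSpec(**c)
        if raw.get("taus") is not None:
            raw["taus"] = tuple(raw["taus"])
        if raw.get("summary_interval") is not None:
            raw["summary_interval"] = tuple(raw["summary_interval"])
        return cls(**raw)


def _plain(obj):
    """Convert tuples to lists recursively for clean YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
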