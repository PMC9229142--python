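"""YAML run configuration: schema declaration, model settings, seeds, paths.

A configuration file looks like::

    schema:
      entries:
        - {name: age, kind: continuous, model_order: 1}
        - {name: year, kind: categorical, levels: ["1985", "1986"],
           model_order: 2, is_year: true}
        - {name: stage, kind: categorical,
           levels: [Localized, Regional, Distant], model_order: 3}
    covariate_settings: {z_df: 4, interactions: true}
    model_spec:
      baseline_df: 5
      categorical_effects: [stage]
      continuous_effects: {age: 3}
      winsor: {age: [2, 98]}
      interactions: [[age, stage]]
      tde: {age: 3, stage: 3}
    seed: 1
    n: 9064
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .covariates import CovariateSettings
from .data import CovariateSchema
from .fpm import ModelSpec

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    schema: CovariateSchema | None
    covariate_settings: CovariateSettings
    model_spec: ModelSpec | None
    seed: int
    n: int | None
    missing_label: str

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            schema=CovariateSchema.from_dict(d["schema"]) if "schema" in d else None,
            covariate_settings=CovariateSettings.from_dict(d.get("covariate_settings", {})),
            model_spec=ModelSpec.from_dict(d["model_spec"]) if "model_spec" in d else None,
            seed=int(d.get("seed", 0)),
            n=int(d["n"]) if "n" in d else None,
            missing_label=str(d.get("missing_label", "Missing")),
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})
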