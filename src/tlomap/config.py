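"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ParameterError

NORMALIZATION_MODES = ("regression_residual", "size_factor_log")


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study's whole-volume run.

    ``n_variable_genes`` and ``n_clusters`` default to the values used
    for the densest biopsy (2000 variable genes, 4 spatial clusters);
    infiltrate-only reruns cut the tree at ``n_infiltrate_clusters``.
    """

    min_genes: int = 200
    n_variable_genes: int = 2000
    n_clusters: int = 4
    n_infiltrate_clusters: int = 2
    de_p_threshold: float = 0.001
    de_logratio_threshold: float = 0.5
    density_percentile: float = 70.0
    rng_seed: int = 0
    normalization_mode: str = "regression_residual"

    def __post_init__(self) -> None:
        if self.min_genes < 0:
            raise ParameterError("min_genes must be non-negative")
        if self.n_variable_genes <= 0 or self.n_clusters <= 0 or self.n_infiltrate_clusters <= 0:
            raise ParameterError("counts in RunConfig must be positive")
        if not 0.0 < self.de_p_threshold < 1.0:
            raise ParameterError("de_p_threshold must be a probability")
        if not 0.0 <= self.density_percentile <= 100.0:
            raise ParameterError("density_percentile must be in [0, 100]")
        if self.normalization_mode not in NORMALIZATION_MODES:
            raise ParameterError(
                f"normalization_mode must be one of {NORMALIZATION_MODES}"
            )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    return RunConfig(**{k: v for k, v in raw.items() if k in known})
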