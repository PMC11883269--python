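"""Model parameter containers and configuration loading.

All default values live in :mod:`meristemsim.data` (``defaults.yaml``) so that
the calibrated baseline is version-controlled rather than buried in code.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

VERSIONS = ("threshold", "mutual")
NOISE_MODELS = ("multiplicative", "additive", "demographic")


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments violating its contract."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the five-lineage stochastic competition model.

    Attributes
    ----------
    n_lineages:
        Number of competing lineages (founder marginal cells).
    r:
        Baseline division rate of outer (marginal) cells, per hour.
    gamma:
        Factor in (0, 1] reducing the inner-cell division rate to ``gamma*r``.
    sigma:
        Noise strength (>= 0) multiplying the Wiener increments.
    K_hill:
        Half-saturation constant of the Hill-type inhibition term, in cells.
    m_hill:
        Hill exponent (> 0).
    alpha:
        Lead margin, in marginal cells, that one lineage must hold over all
        others before inhibition switches on (threshold version only).
    version:
        ``"threshold"`` (leading-lineage rule) or ``"mutual"`` (all lineages
        inhibit one another continuously).
    t_end:
        Simulation horizon in hours.
    dt:
        Euler-Maruyama step in hours.
    noise_model:
        Diffusion coupling g(X): ``"multiplicative"`` (g = X, default),
        ``"additive"`` (g = 1) or ``"demographic"`` (g = sqrt(X)).
    """

    n_lineages: int = 5
    r: float = 0.05
    gamma: float = 0.5
    sigma: float = 0.05
    K_hill: float = 5.0
    m_hill: float = 4.0
    alpha: float = 1.0
    version: str = "threshold"
    t_end: float = 120.0
    dt: float = 0.05
    noise_model: str = "multiplicative"

    def __post_init__(self) -> None:
        if self.n_lineages < 2:
            raise InvalidInputError("n_lineages must be >= 2")
        if not self.r > 0:
            raise InvalidInputError("r must be > 0")
        if not (0 < self.gamma <= 1):
            raise InvalidInputError("gamma must lie in (0, 1]")
        if self.sigma < 0:
            raise InvalidInputError("sigma must be >= 0")
        if not self.K_hill > 0:
            raise InvalidInputError("K_hill must be > 0")
        if not self.m_hill > 0:
            raise InvalidInputError("m_hill must be > 0")
        if self.alpha < 0:
            raise InvalidInputError("alpha must be >= 0")
        if self.version not in VERSIONS:
            raise InvalidInputError(f"version must be one of {VERSIONS}")
        if not self.dt > 0:
            raise InvalidInputError("dt must be > 0")
        if self.t_end < self.dt:
            raise InvalidInputError("t_end must be >= dt")
        if self.noise_model not in NOISE_MODELS:
            raise InvalidInputError(f"noise_model must be one of {NOISE_MODELS}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidInputError(
                f"unknown model parameter(s): {sorted(unknown)}"
            )
        return cls(**mapping)


def _default_mapping() -> dict[str, Any]:
    ref = importlib.resources.files("meristemsim") / "data" / "defaults.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def default_params(version: str = "threshold") -> ModelParams:
    """Calibrated baseline parameters for the requested model version."""
    cfg = _default_mapping()
    common = dict(cfg["model"])
    overrides = cfg.get("version_overrides", {}).get(version, {})
    common.update(overrides)
    common["version"] = version
    return ModelParams.from_dict(common)


def load_params(path: str | Path) -> ModelParams:
    """Read a YAML/JSON config file holding ModelParams fields.

    Unknown keys are rejected so that typos fail loudly.
    """
    with open(path, "r", encoding="utf-8") as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise InvalidInputError(f"config file {path} does not hold a mapping")
    return ModelParams.from_dict(mapping)


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)
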