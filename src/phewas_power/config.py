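"""Declarative run configuration for grid simulations.

A single YAML (or JSON — YAML is a superset) file lists the grid axes; the
cartesian product of the axes forms the simulation grid.  Binary grids take
``cases`` and ``ratios`` axes, quantitative grids take ``sample_sizes``.
Unknown keys are rejected by name, and a parsed config serialises back to an
equivalent document (parse -> serialize -> parse identity).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from itertools import product

import yaml

from .power import SimDesign

__all__ = ["RunConfig", "parse_config", "DEFAULT_BINARY_GRID", "DEFAULT_QUANT_GRID"]

#: Default grid axes for binary-trait simulation surfaces.
DEFAULT_BINARY_GRID = {
    "cases": [10, 20, 50, 100, 200, 500, 1000],
    "ratios": [1, 2, 4],
    "maf": [0.01, 0.05, 0.10, 0.25],
    "penetrance": [0.10, 0.15, 0.20, 0.25, 0.30],
}

#: Default grid axes for quantitative-trait surfaces (n from 10 to 25000).
DEFAULT_QUANT_GRID = {
    "sample_sizes": [10, 50, 100, 500, 1000, 5000, 10000, 25000],
    "maf": [0.01, 0.05, 0.10, 0.25],
    "penetrance": [0.10, 0.15, 0.20, 0.25, 0.30],
}

_KEYS = {
    "trait", "cases", "ratios", "sample_sizes", "maf", "penetrance", "baseline",
    "replicates", "family_level", "alpha", "master_seed", "workers", "output",
}


def _require_list(cfg: dict, key: str, numeric_range=None) -> list:
    if key not in cfg:
        raise ValueError(f"config is missing required axis '{key}'")
    values = cfg[key]
    if not isinstance(values, (list, tuple)) or len(values) == 0:
        raise ValueError(f"axis '{key}' must be a non-empty list")
    if numeric_range is not None:
        lo, hi = numeric_range
        for v in values:
            if not (lo <= v <= hi):
                raise ValueError(f"axis '{key}' value {v} outside [{lo}, {hi}]")
    return list(values)


@dataclass(frozen=True)
class RunConfig:
    """Validated grid configuration for a power run."""

    trait: str
    maf: list = field(default_factory=list)
    penetrance: list = field(default_factory=list)
    cases: list | None = None
    ratios: list | None = None
    sample_sizes: list | None = None
    baseline: float = 0.1
    replicates: int = 1000
    family_level: float | None = None
    alpha: float | None = None
    master_seed: int = 0
    workers: int = 1
    output: str | None = None

    def build_grid(self) -> list[SimDesign]:
        """Cartesian product of the axes, in deterministic axis order."""
        designs = []
        if self.trait == "binary":
            for n_cases, ratio, maf, pen in product(
                self.cases, self.ratios, self.maf, self.penetrance
            ):
                designs.append(
                    SimDesign(
                        trait="binary", maf=maf, penetrance=pen, baseline=self.baseline,
                        n_cases=int(n_cases), ratio=ratio, replicates=self.replicates,
                        alpha=self.alpha, family_level=self.family_level,
                    )
                )
        else:
            for n, maf, pen in product(self.sample_sizes, self.maf, self.penetrance):
                designs.append(
                    SimDesign(
                        trait="quantitative", maf=maf, penetrance=pen,
                        baseline=self.baseline, n=int(n), replicates=self.replicates,
                        alpha=self.alpha, family_level=self.family_level,
                    )
                )
        return designs

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of the config content, for output provenance."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _validate(cfg: dict) -> RunConfig:
    unknown = set(cfg) - _KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    trait = cfg.get("trait")
    if trait not in ("binary", "quantitative"):
        raise ValueError(f"'trait' must be 'binary' or 'quantitative', got {trait!r}")
    maf = _require_list(cfg, "maf", (1e-9, 0.5))
    pen = _require_list(cfg, "penetrance", (0.0, 1.0))
    baseline = cfg.get("baseline", 0.1)
    if not (0.0 < baseline <= 1.0):
        raise ValueError(f"'baseline' must lie in (0, 1], got {baseline}")
    for p in pen:
        if p < baseline:
            raise ValueError(f"'penetrance' value {p} below baseline {baseline}")
    kwargs: dict = {}
    if trait == "binary":
        kwargs["cases"] = [int(v) for v in _require_list(cfg, "cases", (1, 10**8))]
        kwargs["ratios"] = _require_list(cfg, "ratios", (1, 10**6))
        if "sample_sizes" in cfg:
            raise ValueError("'sample_sizes' is a quantitative-trait axis; binary grids use 'cases' and 'ratios'")
    else:
        kwargs["sample_sizes"] = [int(v) for v in _require_list(cfg, "sample_sizes", (2, 10**9))]
        for k in ("cases", "ratios"):
            if k in cfg:
                raise ValueError(f"'{k}' is a binary-trait axis; quantitative grids use 'sample_sizes'")
    replicates = int(cfg.get("replicates", 1000))
    if replicates < 1:
        raise ValueError(f"'replicates' must be >= 1, got {replicates}")
    family_level = cfg.get("family_level")
    if family_level is not None and not (0.0 < family_level < 1.0):
        raise ValueError(f"'family_level' must lie in (0, 1), got {family_level}")
    alpha = cfg.get("alpha")
    if alpha is not None and not (0.0 < alpha < 1.0):
        raise ValueError(f"'alpha' must lie in (0, 1), got {alpha}")
    workers = int(cfg.get("workers", 1))
    if workers < 1:
        raise ValueError(f"'workers' must be >= 1, got {workers}")
    return RunConfig(
        trait=trait, maf=maf, penetrance=pen, baseline=baseline,
        replicates=replicates, family_level=family_level, alpha=alpha,
        master_seed=int(cfg.get("master_seed", 0)), workers=workers,
        output=cfg.get("output"), **kwargs,
    )


def parse_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping at top level")
    return _validate(cfg)


def parse_config_dict(cfg: dict) -> RunConfig:
    """Validate an already-loaded configuration mapping."""
    return _validate(dict(cfg))
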