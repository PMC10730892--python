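"""Pipeline configuration: paths, karyotypes, comparisons and thresholds.

All analysis thresholds default to the published values (raw-count filter
mean > 5, padj < 0.1, |r| > 0.95 with p < 0.05, 10 kb co-location window,
0.1 ratio bins, 10% landmark tolerance, histogram cap 3.0) and every value is
validated before any computation and echoed into the run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imbalance import KaryotypeSpec
from .simulate import default_karyotypes


class ConfigError(ValueError):
    """Raised when a pipeline configuration fails validation."""


@dataclass
class Thresholds:
    min_mean: float = 5.0
    padj: float = 0.1
    r: float = 0.95
    p: float = 0.05
    window: int = 10_000
    bin_width: float = 0.1
    rel_tol: float = 0.10
    cap: float = 3.0

    def validate(self) -> None:
        for name in ("padj", "r", "p"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"threshold {name}={v} outside (0, 1]")
        if self.min_mean < 0:
            raise ConfigError("min_mean must be >= 0")
        if self.window < 0:
            raise ConfigError("window must be >= 0")
        if not (0 < self.bin_width <= self.cap):
            raise ConfigError("need 0 < bin_width <= cap")
        if self.rel_tol <= 0:
            raise ConfigError("rel_tol must be > 0")


@dataclass
class PipelineConfig:
    paths: dict[str, str] = field(default_factory=dict)
    karyotypes: list[KaryotypeSpec] = field(default_factory=default_karyotypes)
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [("2LF", "CF"), ("2LM", "CM"), ("XXX", "CF")]
    )
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()
        names = {k.genotype for k in self.karyotypes}
        for case, control in self.comparisons:
            if case not in names or control not in names:
                raise ConfigError(
                    f"comparison ({case}, {control}) references unknown genotype"
                )

    def karyotype(self, genotype: str) -> KaryotypeSpec:
        for k in self.karyotypes:
            if k.genotype == genotype:
                return k
        raise ConfigError(f"unknown genotype {genotype}")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config; None yields the validated defaults."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    karyotypes = [
        KaryotypeSpec(name, dict(spec["doses"]), spec.get("control", ""))
        for name, spec in raw.get("karyotypes", {}).items()
    ] or default_karyotypes()
    cfg = PipelineConfig(
        paths=dict(raw.get("paths", {})),
        karyotypes=karyotypes,
        comparisons=[tuple(c) for c in raw.get("comparisons", [])]
        or [("2LF", "CF"), ("2LM", "CM"), ("XXX", "CF")],
        thresholds=Thresholds(**raw.get("thresholds", {})),
        seed=int(raw.get("seed", 0)),
        simulation=dict(raw.get("simulation", {})),
    )
    cfg.validate()
    return cfg


def dump_config(cfg: PipelineConfig) -> dict:
    """Plain-dict form of the config, for provenance echoing into reports."""
    return {
        "paths": dict(cfg.paths),
        "karyotypes": {
            k.genotype: {"doses": dict(k.doses), "control": k.control_genotype}
            for k in cfg.karyotypes
        },
        "comparisons": [list(c) for c in cfg.comparisons],
        "thresholds": vars(cfg.thresholds).copy(),
        "seed": cfg.seed,
    }
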