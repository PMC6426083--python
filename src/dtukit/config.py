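"""Run configuration: every threshold and seed, recorded verbatim in outputs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunables of a DTU run.

    alpha
        Significance level applied to BH-adjusted p-values.
    dprop_threshold
        Minimum absolute isoform-proportion difference (effect size) for a
        call; significant results below it are rejected.
    abundance_threshold
        Minimum mean count per condition for a transcript to count as
        detected.  0 disables pre-filtering (the benchmark setting); the
        routine-use default of 5 suppresses noise-driven ratios.
    qrep_threshold / rrep_threshold
        Quantification / inter-replicate reproducibility fractions a
        provisional call must *exceed* to survive filtering.
    n_quant_draws
        Bootstrap-iteration draws for quantification reproducibility.
    """

    alpha: float = 0.05
    dprop_threshold: float = 0.2
    abundance_threshold: float = 5.0
    qrep_threshold: float = 0.95
    rrep_threshold: float = 0.85
    n_quant_draws: int = 100
    seed: int = 0
    samples_a: list[str] = field(default_factory=list)
    samples_b: list[str] = field(default_factory=list)
    annotation: str | None = None
    gtf: str | None = None
    output_dir: str = "dtu_out"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.dprop_threshold <= 1:
            raise ValueError("dprop_threshold must be in [0, 1]")
        if self.abundance_threshold < 0:
            raise ValueError("abundance_threshold must be non-negative")
        for name in ("qrep_threshold", "rrep_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_quant_draws < 1:
            raise ValueError("n_quant_draws must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        loaded.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**loaded)
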