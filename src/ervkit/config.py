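"""Pipeline configuration with validated, literature-fixed defaults."""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Mapping


class ConfigError(ValueError):
    """One or more configuration problems (all reported together)."""


@dataclass
class PipelineConfig:
    """Thresholds and rates for the full pipeline.

    Defaults marked (fixed) are the published analysis constants; changing
    them is supported but flagged in report headers by the CLI.
    """

    min_peak_reads: int = 30  # (fixed) minimum unique reads per TSS peak
    tss_distance_bp: int = 1000  # (fixed) < 1 kb => TSS category
    promoter_upstream: int = 250  # (fixed)
    promoter_downstream: int = 50  # (fixed)
    barcode_max_mismatch: int = 2  # (fixed)
    trim_length: int = 11  # (fixed) non-genomic read prefix
    cpm_expression_threshold: float = 1.0  # (fixed) strictly greater than
    hervh_flank_bp: int = 10_000  # (fixed)
    top_n: int = 200  # (fixed) group size for divergence comparisons
    motif_p_threshold: float = 0.01  # (fixed)
    motif_q_threshold: float = 0.01  # (fixed)
    evolution_rate: float = 1.28e-8  # (fixed) substitutions/site/year
    pseudocount: float = 0.5
    merge_window: int = 20
    gap_tolerance: int = 100
    n_perm: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        errors = _validate_fields(self)
        if errors:
            raise ConfigError("; ".join(errors))


_POSITIVE = {
    "min_peak_reads", "tss_distance_bp", "promoter_upstream", "promoter_downstream",
    "trim_length", "cpm_expression_threshold", "hervh_flank_bp", "top_n",
    "motif_p_threshold", "motif_q_threshold", "evolution_rate", "pseudocount",
    "merge_window", "gap_tolerance", "n_perm",
}
_NON_NEGATIVE = {"barcode_max_mismatch", "seed"}


def _validate_fields(cfg: PipelineConfig) -> list[str]:
    errors = []
    for f in fields(cfg):
        value = getattr(cfg, f.name)
        if not isinstance(value, (int, float)):
            errors.append(f"{f.name}: expected a number, got {type(value).__name__}")
            continue
        if f.name in _POSITIVE and value <= 0:
            errors.append(f"{f.name}: must be > 0, got {value}")
        if f.name in _NON_NEGATIVE and value < 0:
            errors.append(f"{f.name}: must be >= 0, got {value}")
    if cfg.n_perm < 100:
        errors.append(f"n_perm: must be >= 100, got {cfg.n_perm}")
    return errors


def validate_config(raw: Mapping[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a mapping, rejecting unknown keys.

    All type/range violations are collected and reported together.
    """
    known = {f.name for f in fields(PipelineConfig)}
    errors = [f"unknown configuration key: {k!r}" for k in raw if k not in known]
    if errors:
        raise ConfigError("; ".join(errors))
    try:
        return PipelineConfig(**raw)
    except ConfigError:
        raise
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
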