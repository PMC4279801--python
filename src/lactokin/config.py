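"""Analysis-wide thresholds, collected in one validated object.

Every fixed constant of the analysis lives here so that no stage
hard-codes a cut-off: the 5% FDR and |log2FC| > 1 selection rule, the
30% missing-value filter, the background-threshold multiplier, the
consensus-clustering parameters (5 runs, 60% co-occurrence), the dual
basal-expression filter (|log2 ratio| >= 4, reads > 100), the 800-bp
mutation window, the Bradford-to-Lowry correction range (3.5-5x) and
the 0.90 gC/gC carbon-balance floor.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisThresholds", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised for an unparseable or out-of-range configuration."""


@dataclass(frozen=True)
class AnalysisThresholds:
    fdr_cutoff: float = 0.05          # probability
    lfc_cutoff: float = 1.0           # log2 ratio
    missing_fraction_max: float = 0.30
    background_sd_mult: float = 2.0
    kmeans_runs: int = 5
    cooccurrence_threshold: float = 0.60
    basal_logratio_min: float = 4.0   # log2 ratio
    basal_reads_min: float = 100.0    # average read count
    mutation_window: int = 800        # bp
    bradford_factor_low: float = 3.5
    bradford_factor_high: float = 5.0
    carbon_balance_min: float = 0.90  # gC produced / gC consumed
    funcat_main_min: int = 10         # "more than ten genes"
    funcat_bold_margin: int = 2       # genes
    lowess_span: float = 0.3          # fraction of probes per local fit

    def __post_init__(self) -> None:
        for name in ("fdr_cutoff", "missing_fraction_max",
                     "cooccurrence_threshold", "lowess_span"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("kmeans_runs", "mutation_window", "funcat_main_min",
                     "funcat_bold_margin"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        for name in ("lfc_cutoff", "background_sd_mult", "basal_logratio_min",
                     "basal_reads_min", "bradford_factor_low",
                     "bradford_factor_high", "carbon_balance_min"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and >= 0, got {v!r}")
        if not self.bradford_factor_low < self.bradford_factor_high:
            raise ConfigError(
                "bradford_factor_low must be < bradford_factor_high "
                f"({self.bradford_factor_low} vs {self.bradford_factor_high})"
            )


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(AnalysisThresholds)}
_INT_FIELDS = {f.name for f in dataclasses.fields(AnalysisThresholds)
               if f.type == "int"}


def load_config(path: str | Path) -> AnalysisThresholds:
    """Read a flat key: value document; absent keys take the defaults.

    Unknown keys, non-numeric values and out-of-range values raise
    :class:`ConfigError` naming the offending key.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must be a flat key: value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key not in _FIELD_TYPES:
            raise ConfigError(f"unknown configuration key {key!r}")
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"key {key!r}: expected a number, got {value!r}")
        if key in _INT_FIELDS:
            if int(value) != value:
                raise ConfigError(f"key {key!r}: expected an integer, got {value!r}")
            value = int(value)
        else:
            value = float(value)
        kwargs[key] = value
    return AnalysisThresholds(**kwargs)


def save_config(cfg: AnalysisThresholds, path: str | Path) -> None:
    """Serialize to the same flat document ``load_config`` reads.

    A copy is written into every output directory for provenance; the
    round trip reproduces an equal object.
    """
    data = dataclasses.asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
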