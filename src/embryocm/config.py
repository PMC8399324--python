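"""Run configuration: every numeric gate of the pipeline in one place.

The defaults encode the screening rules the pipeline implements: a 0.8
consistency criterion, a 0.25 missing-value cap for random-forest
imputation, a two-fold change gate, volcano significance at p < 0.05 with
tendencies up to 0.10, a 0.700 ROC-AUC gate relaxed to 0.850 for very
small blocks, 70% single-biomarker and 80% combined-coverage thresholds,
and a Bonferroni family level of 0.10 for the whole-dataset models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Developmental stage ordering at the start (0 h) and end (24 h) of the
#: 24 h single-culture step: morula < early blastocyst < blastocyst <
#: expanding blastocyst < fully expanded blastocyst.
STAGE0H_LEVELS = ("M", "EB", "B")
STAGE24H_LEVELS = ("ExB", "FEB")
STAGE_ORDER = {"M": 0, "EB": 1, "B": 2, "ExB": 3, "FEB": 4}

ENDPOINTS = ("D40", "D62", "Birth")

#: Stage-constraint whitelist used by the block enumeration: singletons,
#: the EB+B union, and "free" at 0 h; singletons and "free" at 24 h.
DEFAULT_STAGE0H_SUBSETS = (
    frozenset({"M"}),
    frozenset({"EB"}),
    frozenset({"B"}),
    frozenset({"EB", "B"}),
    None,
)
DEFAULT_STAGE24H_SUBSETS = (
    frozenset({"ExB"}),
    frozenset({"FEB"}),
    None,
)


@dataclass
class RunConfig:
    """All pipeline thresholds, paths and the master seed."""

    # preprocessing
    consistency_threshold: float = 0.8
    max_missing_fraction: float = 0.25
    impute_estimators: int = 25
    impute_max_iter: int = 3

    # block screen
    min_class: int = 3
    fold_change_gate: float = 2.0       # |FCh| >= 2, i.e. |log2 FCh| >= 1
    level1_alpha: float = 0.05
    level1_tendency: float = 0.10
    auc_gate: float = 0.700
    small_n_total: int = 12
    small_n_auc: float = 0.850
    small_n_p: float = 0.15

    # annotation
    precursor_ppm: float = 10.0
    ms2_ppm: float = 5.0
    min_ms2_ions: int = 3

    # coverage
    min_predicted: float = 70.0
    combined_gate: float = 80.0

    # endpoint reporting
    bonferroni_levels: tuple[float, float] = (0.05, 0.10)

    seed: int = 0
    stage0h_subsets: Sequence[frozenset | None] = DEFAULT_STAGE0H_SUBSETS
    stage24h_subsets: Sequence[frozenset | None] = DEFAULT_STAGE24H_SUBSETS

    def __post_init__(self) -> None:
        if not 0 < self.consistency_threshold <= 1:
            raise ValueError("consistency_threshold must lie in (0, 1]")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must lie in [0, 1]")
        if self.fold_change_gate < 1:
            raise ValueError("fold_change_gate must be >= 1")
        for p in (self.level1_alpha, self.level1_tendency, self.small_n_p):
            if not 0 < p < 1:
                raise ValueError(f"significance level {p} outside (0, 1)")
        if not 0.5 <= self.auc_gate <= 1:
            raise ValueError("auc_gate must lie in [0.5, 1]")
        if self.min_class < 1:
            raise ValueError("min_class must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage0h_subsets" in raw:
            raw["stage0h_subsets"] = tuple(
                None if s is None else frozenset(s) for s in raw["stage0h_subsets"]
            )
        if "stage24h_subsets" in raw:
            raw["stage24h_subsets"] = tuple(
                None if s is None else frozenset(s) for s in raw["stage24h_subsets"]
            )
        if "bonferroni_levels" in raw:
            raw["bonferroni_levels"] = tuple(raw["bonferroni_levels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage0h_subsets"] = [None if s is None else sorted(s) for s in self.stage0h_subsets]
        d["stage24h_subsets"] = [None if s is None else sorted(s) for s in self.stage24h_subsets]
        d["bonferroni_levels"] = list(self.bonferroni_levels)
        return d

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
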