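"""Run configuration with the study's canonical defaults.

Defaults mirror the reference protocol: 100 GSN replicates, five-fold
cross-validation, 100 similarity permutations, term sizes strictly between
20 and 2000 genes, ±2 kb TSS windows in 20 bp bins.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from lncgo.io_normalize import ACTIVE_MARKS, REPRESSIVE_MARKS


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    master_seed: int = 17
    n_gsn: int = 100
    k_folds: int = 5
    n_perm: int = 100
    min_term_genes: int = 20   # exclusive lower bound (keep n > 20)
    max_term_genes: int = 2000  # exclusive upper bound (keep n < 2000)
    propagation: str = "full"  # or "one_level"
    cv_auc: str = "pooled"     # or "mean"
    strictness: str = "strict"  # or "lenient" for missing entities
    zscore_ddof: int = 1
    perm_smoothing: bool = False
    tss_window: int = 2000
    tss_bin_width: int = 20
    min_confidence: float = 0.0
    active_marks: tuple[str, ...] = tuple(sorted(ACTIVE_MARKS))
    repressive_marks: tuple[str, ...] = tuple(sorted(REPRESSIVE_MARKS))

    def __post_init__(self) -> None:
        if self.propagation not in ("full", "one_level"):
            raise ConfigError(f"bad propagation {self.propagation!r}")
        if self.cv_auc not in ("pooled", "mean"):
            raise ConfigError(f"bad cv_auc {self.cv_auc!r}")
        if self.strictness not in ("strict", "lenient"):
            raise ConfigError(f"bad strictness {self.strictness!r}")
        if self.min_term_genes >= self.max_term_genes:
            raise ConfigError("min_term_genes must be < max_term_genes")
        if not 0 <= self.min_confidence <= 1:
            raise ConfigError("min_confidence must be in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = json.loads(text)
        for key in ("active_marks", "repressive_marks"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
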