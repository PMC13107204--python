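"""Run configuration: thresholds, seeding, and config-file round trip."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of the pipeline, with their default values.

    Defaults: genome-wide FDR 0.05; DEI log2 fold-change cut 1; colocalization
    PP.H4 cut 0.7; MAF floor 0.05; imputation R2 floor 0.3; cis window
    +/- 1,000,000 bp around the TSS; splice-junction-site width 2 bp; NMD
    distance 50 nt; 1,000 permutations; LD pruning with a 200-variant window,
    step 1, r2 0.1; 2-fold rule for cross-cell-type magnitude sharing.
    """

    seed: int = 0
    fdr_level: float = 0.05
    dei_log2fc: float = 1.0
    pph4_cut: float = 0.7
    maf_min: float = 0.05
    rsq_min: float = 0.3
    cis_window: int = 1_000_000
    sjs_width: int = 2
    nmd_distance: int = 50
    n_permutations: int = 1000
    ld_prune_window: int = 200
    ld_prune_step: int = 1
    ld_prune_r2: float = 0.1
    sharing_fold: float = 2.0
    min_cells_per_individual: int = 5
    min_expressed_frac: float = 0.2
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "fdr_level", "dei_log2fc", "pph4_cut", "maf_min", "rsq_min",
            "cis_window", "sjs_width", "nmd_distance", "n_permutations",
            "ld_prune_window", "ld_prune_step", "ld_prune_r2", "sharing_fold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def rng(self, *stream: object) -> np.random.Generator:
        """Independent generator for a named stream, derived from the run seed."""
        return np.random.default_rng(self.child_seed(*stream))

    def child_seed(self, *stream: object) -> int:
        h = hashlib.sha256(repr((self.seed,) + stream).encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
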