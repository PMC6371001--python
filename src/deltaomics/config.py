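"""Pipeline configuration: block files, analysis pairs, and stage parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Default analysis pairs: clinical against every other block, plus the
#: serum-metabolome / adipose-transcriptome pair.  Thresholds: |0.7| for the
#: lifestyle and metagenomic-species pairs, |0.75| for metabolomics and
#: transcriptome pairs.
DEFAULT_PAIRS = [
    ("clinical", "lifestyle", 0.70),
    ("clinical", "mgs", 0.70),
    ("clinical", "fecal_metab", 0.75),
    ("clinical", "urine_metab", 0.75),
    ("clinical", "serum_metab", 0.75),
    ("clinical", "transcriptome", 0.75),
    ("serum_metab", "transcriptome", 0.75),
]


@dataclass
class PipelineConfig:
    """All tunable parameters of the delta-integration pipeline.

    ``block_files`` maps block name -> {"baseline": path, "week6": path} or
    {"delta": path} when precomputed delta tables are supplied.
    ``block_classes`` maps block name -> block class (defaults to the name).
    """

    block_files: dict = field(default_factory=dict)
    block_classes: dict = field(default_factory=dict)
    pairs: list = field(default_factory=lambda: [list(p) for p in DEFAULT_PAIRS])

    # two-block PLS
    n_components: int = 2
    similarity_variates: str = "x"        # "x" or "mean"
    mgs_prevalence_min: int = 2

    # reduction
    reduction_fraction: float = 0.20
    reduction_mode: str = "variables"     # or "edges"
    anchors: list = field(default_factory=list)

    # spectral consensus
    eigvec_fraction: float = 0.14
    coord_threshold: float = 0.03
    quorum: int = 2
    engines: list = field(default_factory=lambda:
                          ["shrink_pcor", "mi_dpi", "pc_skeleton"])
    alpha: float = 0.05

    # contribution analysis
    targets: list = field(default_factory=lambda: ["revQUICKI", "HOMA2_B"])
    folds: int = 10
    seed: int = 0

    out_dir: str = "deltaomics_run"

    def __post_init__(self):
        if not 0 < self.reduction_fraction <= 1:
            raise ValueError("reduction_fraction must be in (0, 1]")
        if not 0 < self.eigvec_fraction <= 1:
            raise ValueError("eigvec_fraction must be in (0, 1]")
        if self.coord_threshold < 0:
            raise ValueError("coord_threshold must be >= 0")
        if not 1 <= self.quorum <= len(self.engines):
            raise ValueError("quorum must lie between 1 and len(engines)")
        if self.block_files:
            known = set(self.block_files)
            for a, b, _tau in self.pairs:
                for name in (a, b):
                    if name not in known:
                        raise ValueError(
                            f"analysis pair names unknown block {name!r}")

    def block_class(self, name: str) -> str:
        return self.block_classes.get(name, name)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("_comment", None)
        return cls(**raw)
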