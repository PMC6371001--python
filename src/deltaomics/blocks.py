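"""Omics block data model, table IO and delta computation.

A *block* is one data source (clinical chemistry, lifestyle diary, metagenomic
species, a metabolome compartment, or the adipose transcriptome) stored as a
subjects x features matrix.  Every downstream analysis consumes *delta* blocks:
the within-subject change between the end of the intervention and baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("deltaomics")

#: Recognised block classes, in the canonical pipeline order.
BLOCK_CLASSES = (
    "clinical",
    "lifestyle",
    "mgs",
    "fecal_metab",
    "urine_metab",
    "serum_metab",
    "transcriptome",
)


@dataclass
class OmicsBlock:
    """One omics data source as a subjects x features matrix.

    Parameters
    ----------
    name : str
        Block identifier (e.g. ``"serum_metab"``).
    block_class : str
        One of :data:`BLOCK_CLASSES`.
    subjects : list of str
        Ordered subject identifiers; no duplicates.
    features : list of str
        Ordered feature identifiers; no duplicates.
    values : ndarray of shape (n_subjects, n_features)
        Measurements; ``NaN`` marks missing values.
    annotations : dict, optional
        Free-text annotation per feature (e.g. ``{"f12": "glucose"}``).
    """

    name: str
    block_class: str
    subjects: list
    features: list
    values: np.ndarray
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.block_class not in BLOCK_CLASSES:
            raise ValueError(
                f"unknown block_class {self.block_class!r}; "
                f"expected one of {BLOCK_CLASSES}"
            )
        self.subjects = list(self.subjects)
        self.features = list(self.features)
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.subjects)
        if dup is not None:
            raise ValueError(f"duplicate subject identifier: {dup!r}")
        dup = _first_duplicate(self.features)
        if dup is not None:
            raise ValueError(f"duplicate feature identifier: {dup!r}")
        if self.values.shape != (len(self.subjects), len(self.features)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.features)} features"
            )

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.features)

    def subset_features(self, keep: Sequence[str]) -> "OmicsBlock":
        """Return a copy restricted to ``keep`` (block order preserved)."""
        keep = set(keep)
        idx = [j for j, f in enumerate(self.features) if f in keep]
        return replace(
            self,
            features=[self.features[j] for j in idx],
            values=self.values[:, idx],
            annotations={f: a for f, a in self.annotations.items()
                         if f in keep},
        )


@dataclass
class DeltaBlock(OmicsBlock):
    """An :class:`OmicsBlock` whose values are week6 - baseline changes.

    ``provenance`` records the two source tables (paths or block names);
    ``constant_features`` lists features whose delta has zero variance across
    subjects (flagged by :func:`compute_delta`, excluded from model fits).
    """

    provenance: tuple = ("", "")
    constant_features: list = field(default_factory=list)


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_block(path, block_class: str, name: str | None = None,
               cls=OmicsBlock) -> OmicsBlock:
    """Read a subjects x features table (TSV or CSV) into a block.

    First column holds subject identifiers, header row holds feature
    identifiers.  Non-numeric cells become missing values (NaN).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    dup = _first_duplicate(header)
    if dup is not None:              # pandas would mangle these silently
        raise ValueError(f"duplicate feature identifier {dup!r} in {path}")
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.empty:
        raise ValueError(f"empty table: {path}")
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise ValueError(f"duplicate subject identifier {dup!r} in {path}")
    def _parse(cell):
        try:
            return float(cell)       # correctly-rounded, lossless round trip
        except (TypeError, ValueError):
            return np.nan

    values = np.array([[_parse(c) for c in row]
                       for row in df.to_numpy()], dtype=float)
    block = cls(
        name=name or path.stem,
        block_class=block_class,
        subjects=[str(s) for s in df.index],
        features=[str(f) for f in df.columns],
        values=values,
    )
    logger.info("read block %s (%s): %d subjects x %d features from %s",
                block.name, block_class, *block.shape, path)
    return block


def write_block(block: OmicsBlock, path) -> Path:
    """Write a block as TSV/CSV (delimiter chosen from the extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    block.to_frame().to_csv(path, sep=_sep_for(path), index_label="subject")
    return path


# ---------------------------------------------------------------------------
# delta computation
# ---------------------------------------------------------------------------

def compute_delta(baseline: OmicsBlock, week6: OmicsBlock) -> DeltaBlock:
    """week6 - baseline changes on the common subjects.

    Subjects are aligned by identifier (never by row order); subject order
    follows the baseline table restricted to the intersection.  Features whose
    delta is constant across subjects are flagged in ``constant_features``.
    """
    if baseline.features != week6.features:
        diff = sorted(set(baseline.features) ^ set(week6.features))
        raise ValueError(f"feature lists differ; symmetric difference: {diff}")
    common = [s for s in baseline.subjects if s in set(week6.subjects)]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common subjects; need at least 3")
    b = baseline.to_frame().loc[common]
    w = week6.to_frame().loc[common]
    delta = w.to_numpy() - b.to_numpy()
    with np.errstate(invalid="ignore"):
        span = np.nanmax(delta, axis=0) - np.nanmin(delta, axis=0)
    constant = [f for f, s in zip(baseline.features, span)
                if not np.isnan(s) and s == 0.0]
    if constant:
        logger.warning("block %s: %d zero-variance delta features flagged",
                       baseline.name, len(constant))
    return DeltaBlock(
        name=baseline.name,
        block_class=baseline.block_class,
        subjects=common,
        features=list(baseline.features),
        values=delta,
        annotations=dict(baseline.annotations),
        provenance=(baseline.name + "@baseline", week6.name + "@week6"),
        constant_features=constant,
    )


# ---------------------------------------------------------------------------
# missing data policy
# ---------------------------------------------------------------------------

def clean_block(block: OmicsBlock, max_missing_frac: float = 0.2,
                drop_constant: bool = True) -> OmicsBlock:
    """Apply the pipeline's missing-data policy to a block.

    Features missing in more than ``max_missing_frac`` of subjects are dropped
    (with a warning); remaining missing values are median-imputed per feature.
    With ``drop_constant``, zero-variance features are removed as well (their
    correlations are undefined).  Median imputation is the robust choice at
    the small sample sizes this pipeline targets.
    """
    V = block.values
    miss = np.isnan(V).mean(axis=0)
    keep = miss <= max_missing_frac
    if not keep.all():
        dropped = [f for f, k in zip(block.features, keep) if not k]
        logger.warning("block %s: dropping %d features missing in >%.0f%% "
                       "of subjects: %s", block.name, len(dropped),
                       100 * max_missing_frac, dropped[:5])
    V = V[:, keep]
    feats = [f for f, k in zip(block.features, keep) if k]
    if np.isnan(V).any():
        med = np.nanmedian(V, axis=0)
        idx = np.where(np.isnan(V))
        V = V.copy()
        V[idx] = np.take(med, idx[1])
    if drop_constant and V.size:
        var = V.var(axis=0)
        nz = var > 0
        if not nz.all():
            dropped = [f for f, k in zip(feats, nz) if not k]
            logger.warning("block %s: dropping %d zero-variance features",
                           block.name, len(dropped))
        V = V[:, nz]
        feats = [f for f, k in zip(feats, nz) if k]
    out = replace(block, features=feats, values=V,
                  annotations={f: a for f, a in block.annotations.items()
                               if f in set(feats)})
    return out
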