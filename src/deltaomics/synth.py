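"""Synthetic multi-block study generator with planted latent structure.

The generator emulates the shape of a short calorie-restriction study: seven
delta blocks (clinical, lifestyle, metagenomic species, three metabolome
compartments, adipose transcriptome) observed on a small cohort.  One latent
per-subject factor ``s`` — the unobserved "insulin-sensitivity improvement" —
drives a small planted subset of features in every block:

* ten clinical IS surrogate markers load on ``s`` with alternating signs; the
  first (a revised-QUICKI-like primary index) is a nearly noiseless transform
  of ``s``, the rest carry measurement noise (the real indexes are mutually
  redundant functions of the same fasting measurements);
* two clinical anchor measurements (adipocyte diameter, NEFA) load on ``s``;
* each non-clinical block has ``n_planted`` features of the form
  ``effect * s + r + sigma * eps`` where ``r`` is a unit-variance Gaussian
  chain-graphical residual over the block's planted set;
* all remaining features are independent noise.

The recorded truth graph ``E*`` is the conditional-dependence structure this
model implies for the observables: the within-block chains, plus a star from
the primary index to every other feature that loads on ``s`` (conditioning on
the primary index — an almost exact proxy of ``s`` — removes every other
latent-induced pairwise dependence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import DeltaBlock

#: Block sizes matching the published study design (total 9,986 variables).
PAPER_DIMS = {
    "clinical": 45,
    "lifestyle": 63,          # 26 food groups + 34 nutrients + 3 activity indexes
    "mgs": 741,
    "fecal_metab": 835,
    "urine_metab": 562,
    "serum_metab": 180,
    "transcriptome": 7560,
}

#: Small block sizes for fast fixtures (same statistical structure).
MINI_DIMS = {
    "clinical": 16,
    "lifestyle": 12,
    "mgs": 20,
    "fecal_metab": 24,
    "urine_metab": 18,
    "serum_metab": 15,
    "transcriptome": 40,
}

DEFAULT_N_PLANTED = {
    "lifestyle": 4,
    "mgs": 5,
    "fecal_metab": 5,
    "urine_metab": 4,
    "serum_metab": 5,
    "transcriptome": 6,
}

#: The ten IS surrogate markers; the first is the near-noiseless primary index.
IS_MARKERS = (
    "revQUICKI", "HOMA2_IR", "QUICKI", "FIRI", "Disse",
    "insulin", "HOMA2_S", "glucose", "HOMA2_B", "ins_glu_ratio",
)
PRIMARY_MARKER = IS_MARKERS[0]
CLINICAL_ANCHORS = ("adipocyte_diameter", "NEFA")

#: Annotation flavour for planted serum features (exercises the
#: glucose-exclusion rule of the contribution stage).
_SERUM_NOTES = ("leucine (BCAA)", "valine (BCAA)", "glucose",
                "glucose signal", "acetylcarnitine")

_CHAIN_PARTIAL = 0.45          # neighbor partial correlation of the residual
_PRIMARY_NOISE_FACTOR = 0.1    # primary-index noise sd = 0.1 * sigma


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic study."""

    seed: int
    latent: np.ndarray                       # s, per subject
    loadings: dict                           # feature id -> a_j
    planted: dict = field(default_factory=dict)   # block -> [feature ids]
    edges: set = field(default_factory=set)       # E*, frozenset pairs
    sigma: float = 0.5
    noise_sd: float = 1.0
    dims: dict = field(default_factory=dict)
    is_markers: tuple = IS_MARKERS
    primary_marker: str = PRIMARY_MARKER
    anchors: tuple = ()
    delta_values: dict = field(default_factory=dict)  # block -> matrix

    def planted_features(self) -> list:
        out = []
        for block in self.planted:
            out.extend(self.planted[block])
        return out

    def marker_associated(self) -> list:
        """Features outside the clinical block that truly load on s."""
        return [f for block, feats in self.planted.items()
                if block != "clinical" for f in feats]


def _chain_residual_cov(k: int, w: float = _CHAIN_PARTIAL) -> np.ndarray:
    """Unit-variance covariance of a chain Gaussian graphical model on k nodes."""
    omega = np.eye(k)
    idx = np.arange(k - 1)
    omega[idx, idx + 1] = omega[idx + 1, idx] = -w
    evals = np.linalg.eigvalsh(omega)
    if evals.min() <= 0:          # chain with |w| < 0.5 is always PD
        raise ValueError("residual precision matrix not positive definite")
    cov = np.linalg.inv(omega)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def generate_study(dims=None, n_subjects: int = 27, n_planted=None,
                   effect: float = 1.0, sigma: float = 0.5,
                   noise_sd: float = 1.0, seed: int = 0,
                   sparsify_mgs: bool = False):
    """Generate one synthetic study as delta blocks plus ground truth.

    Returns ``(blocks, truth)`` where ``blocks`` is a list of
    :class:`~deltaomics.blocks.DeltaBlock` in canonical block order.
    Identical seeds give bit-identical output.
    """
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")
    dims = dict(PAPER_DIMS if dims is None else dims)
    if any(p <= 0 for p in dims.values()):
        raise ValueError("block dimensions must be positive")
    n_planted = dict(DEFAULT_N_PLANTED if n_planted is None else n_planted)
    for block, k in n_planted.items():
        if k > dims.get(block, 0):
            raise ValueError(
                f"n_planted={k} exceeds block {block!r} size {dims.get(block)}")
    if dims["clinical"] < len(IS_MARKERS) + len(CLINICAL_ANCHORS):
        raise ValueError("clinical block too small for markers + anchors")

    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n_subjects)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]

    loadings, planted, edges = {}, {}, set()
    blocks = []

    # --- clinical block -------------------------------------------------
    p_clin = dims["clinical"]
    marker_signs = np.array([(-1) ** i for i in range(len(IS_MARKERS))])
    feats = list(IS_MARKERS) + list(CLINICAL_ANCHORS) \
        + [f"clin_{j}" for j in range(len(IS_MARKERS) + len(CLINICAL_ANCHORS) + 1,
                                      p_clin + 1)]
    V = np.empty((n_subjects, p_clin))
    for i, (m, sg) in enumerate(zip(IS_MARKERS, marker_signs)):
        m_sd = _PRIMARY_NOISE_FACTOR * sigma if m == PRIMARY_MARKER else sigma
        V[:, i] = sg * effect * s + m_sd * rng.standard_normal(n_subjects)
        loadings[m] = sg * effect
    for i, (a_name, sg) in enumerate(zip(CLINICAL_ANCHORS, (-1, 1)),
                                     start=len(IS_MARKERS)):
        V[:, i] = sg * effect * s + sigma * rng.standard_normal(n_subjects)
        loadings[a_name] = sg * effect
    n_struct = len(IS_MARKERS) + len(CLINICAL_ANCHORS)
    V[:, n_struct:] = noise_sd * rng.standard_normal(
        (n_subjects, p_clin - n_struct))
    planted["clinical"] = feats[:n_struct]
    for f in planted["clinical"]:
        if f != PRIMARY_MARKER:
            edges.add(frozenset((PRIMARY_MARKER, f)))
    annotations = {m: "IS marker" for m in IS_MARKERS}
    blocks.append(DeltaBlock(name="clinical", block_class="clinical",
                             subjects=subjects, features=feats, values=V,
                             annotations=annotations,
                             provenance=("synthetic", f"seed={seed}")))

    # --- non-clinical blocks --------------------------------------------
    for block in ("lifestyle", "mgs", "fecal_metab", "urine_metab",
                  "serum_metab", "transcriptome"):
        p = dims[block]
        k = int(n_planted.get(block, 0))
        feats = [f"{block}_f{j + 1}" for j in range(p)]
        V = noise_sd * rng.standard_normal((n_subjects, p))
        idx = np.sort(rng.choice(p, size=k, replace=False)) if k else []
        names = [feats[j] for j in idx]
        if k >= 2:
            cov = _chain_residual_cov(k)
            resid = rng.standard_normal((n_subjects, k)) @ np.linalg.cholesky(cov).T
        else:
            resid = np.zeros((n_subjects, k))   # isolated node: no residual
        for c, j in enumerate(idx):
            V[:, j] = effect * s + resid[:, c] \
                + sigma * rng.standard_normal(n_subjects)
            loadings[feats[j]] = effect
        for a, b in zip(names[:-1], names[1:]):
            edges.add(frozenset((a, b)))        # within-block chain
        for f in names:
            edges.add(frozenset((PRIMARY_MARKER, f)))   # latent star
        planted[block] = names
        annotations = {}
        if block == "serum_metab":
            annotations = {f: note for f, note in zip(names, _SERUM_NOTES)}
        if block == "mgs" and sparsify_mgs:
            non_planted = np.setdiff1d(np.arange(p), idx)
            prevalence = rng.uniform(0.05, 1.0, size=non_planted.size)
            mask = rng.random((n_subjects, non_planted.size)) < prevalence
            V[:, non_planted] *= mask
        blocks.append(DeltaBlock(name=block, block_class=block,
                                 subjects=subjects, features=feats, values=V,
                                 annotations=annotations,
                                 provenance=("synthetic", f"seed={seed}")))

    if any(len(v) >= 2 for v in planted.values()) and not edges:
        raise AssertionError("planted dependence graph unexpectedly empty")

    truth = SyntheticTruth(
        seed=seed, latent=s, loadings=loadings, planted=planted, edges=edges,
        sigma=sigma, noise_sd=noise_sd, dims=dims,
        anchors=tuple(IS_MARKERS) + CLINICAL_ANCHORS,
        delta_values={b.name: b.values.copy() for b in blocks},
    )
    return blocks, truth


def generate_mini(seed: int = 0, n_subjects: int = 27, effect: float = 1.0,
                  sigma: float = 0.5, **kwargs):
    """Fast fixture: the seven-block study at small feature counts."""
    return generate_study(dims=MINI_DIMS, n_subjects=n_subjects,
                          effect=effect, sigma=sigma, seed=seed, **kwargs)


def generate_two_timepoints(seed: int = 0, **kwargs):
    """Two-time-point variant exercising explicit delta computation.

    Returns ``(baseline_blocks, week6_blocks, truth)`` with
    ``week6 = baseline + delta`` where the deltas are those of
    :func:`generate_study` (stored in ``truth.delta_values``).
    """
    from dataclasses import replace

    delta_blocks, truth = generate_study(seed=seed, **kwargs)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    baseline, week6 = [], []
    for blk in delta_blocks:
        base_levels = rng.normal(loc=rng.uniform(-2, 2, blk.n_features),
                                 scale=1.0,
                                 size=blk.values.shape)
        baseline.append(replace(blk, values=base_levels,
                                provenance=("synthetic", "baseline")))
        week6.append(replace(blk, values=base_levels + blk.values,
                             provenance=("synthetic", "week6")))
    return baseline, week6, truth
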