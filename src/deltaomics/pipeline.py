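"""End-to-end pipeline: delta -> paired stats -> PLS pairs -> reduction ->
spectral consensus -> contribution, with plain-file artifacts and a run
manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import DeltaBlock, clean_block, compute_delta, read_block
from .config import PipelineConfig
from .contrib import run_contribution
from .networks import export_network
from .pls import run_all_pairs
from .reduction import count_report, select_top_fraction
from .scs import run_scs
from .stats import delta_change_table

logger = logging.getLogger("deltaomics")


def setup_logging(out_dir=None, level=logging.INFO):
    """Structured log to stderr and, when a run directory is given, a file."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    logger.addHandler(sh)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(out_dir) / "deltaomics.log")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def load_blocks(config: PipelineConfig) -> list:
    """Read the configured blocks, computing deltas where two time points
    are supplied, and apply the missing-data policy."""
    blocks = []
    for name, files in config.block_files.items():
        cls = config.block_class(name)
        if "delta" in files:
            blk = read_block(files["delta"], cls, name=name, cls=DeltaBlock)
        else:
            base = read_block(files["baseline"], cls, name=name)
            week6 = read_block(files["week6"], cls, name=name)
            blk = compute_delta(base, week6)
        blocks.append(clean_block(blk))
    return blocks


def default_anchors(blocks) -> list:
    """IS markers plus adipocyte diameter and NEFA, where present."""
    anchors = []
    for b in blocks:
        if b.block_class != "clinical":
            continue
        for f in b.features:
            note = b.annotations.get(f, "").lower()
            if "is marker" in note or f in ("adipocyte_diameter", "NEFA"):
                anchors.append(f)
    return anchors


def reduced_matrix(blocks, reduced):
    """Assemble the reduced-set data matrix (subjects x kept variables)."""
    frames = {b.name: b.to_frame() for b in blocks}
    owner = {f: b.name for b in blocks for f in b.features}
    cols, ids, classes = [], [], {}
    class_of = {b.name: b.block_class for b in blocks}
    for f, cls, _sc, _src in reduced.members:
        blk = owner.get(f)
        if blk is None:
            logger.warning("reduced variable %s not found in any block", f)
            continue
        col = frames[blk][f]
        if col.std(ddof=0) == 0:
            logger.warning("reduced variable %s is constant; skipped", f)
            continue
        cols.append(col.to_numpy())
        ids.append(f)
        classes[f] = cls or class_of[blk]
    return np.column_stack(cols), ids, classes


def run_pipeline(config: PipelineConfig, blocks=None) -> dict:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns the run manifest (also written as ``manifest.json``).  ``blocks``
    may be supplied directly (e.g. from the synthetic generator) instead of
    reading the configured files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out)
    cfg_text = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "outputs": {},
    }

    def record(stage, paths):
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = [str(p) for p in paths]

    try:
        if blocks is None:
            blocks = load_blocks(config)
        record("delta", [])

        stats = pd.concat([delta_change_table(b) for b in blocks],
                          ignore_index=True)
        stats_path = out / "paired_stats.tsv"
        stats.to_csv(stats_path, sep="\t", index=False)
        record("stats", [stats_path])

        networks = run_all_pairs(blocks, config)
        net_paths, summary = [], []
        for net in networks:
            p = out / f"pls_{net.pair.replace(':', '_')}.graphml"
            export_network(net, p, "graphml")
            net_paths.append(p)
            summary.append((net.pair, net.threshold, net.n_edges,
                            len(net.nodes())))
        pd.DataFrame(summary, columns=["pair", "tau", "n_edges", "n_nodes"]) \
            .to_csv(out / "pls_summary.tsv", sep="\t", index=False)
        net_paths.append(out / "pls_summary.tsv")
        record("pls", net_paths)

        anchors = config.anchors or default_anchors(blocks)
        reduced = select_top_fraction(
            networks, config.reduction_fraction, anchors=anchors,
            mode=config.reduction_mode)
        red_path = out / "reduced_set.tsv"
        pd.DataFrame(reduced.members,
                     columns=["feature", "class", "score", "source"]) \
            .to_csv(red_path, sep="\t", index=False)
        record("reduce", [red_path])

        X, ids, classes = reduced_matrix(blocks, reduced)
        consensus = run_scs(
            X, variables=ids, node_classes=classes,
            eigvec_fraction=config.eigvec_fraction,
            coord_threshold=config.coord_threshold,
            quorum=config.quorum, engines=tuple(config.engines),
            alpha=config.alpha)
        cons_path = out / "consensus.graphml"
        export_network(consensus, cons_path, "graphml")
        export_network(consensus, out / "consensus.sif", "sif")
        record("scs", [cons_path, out / "consensus.sif"])

        try:
            reports = run_contribution(consensus, blocks,
                                       targets=config.targets,
                                       folds=config.folds, seed=config.seed)
        except ValueError as exc:
            logger.warning("contribution stage skipped: %s", exc)
            reports = []
        contrib_paths = []
        for rep in reports:
            p = out / f"contribution_{rep.target}.json"
            with open(p, "w") as fh:
                json.dump({"target": rep.target, "mse": rep.mse,
                           "shares": rep.shares,
                           "members": rep.class_members,
                           "excluded": rep.excluded}, fh, indent=2)
            pd.DataFrame(rep.pie_table(), columns=["class", "share"]) \
                .to_csv(out / f"contribution_{rep.target}.tsv",
                        sep="\t", index=False)
            contrib_paths.append(p)
        record("contrib", contrib_paths)

        book = count_report(blocks, networks, reduced)
        book_path = out / "bookkeeping.json"
        with open(book_path, "w") as fh:
            json.dump(book, fh, indent=2, sort_keys=True)
        record("bookkeeping", [book_path])
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        _write_manifest(out, manifest)
        raise
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict):
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    for stage, paths in manifest["outputs"].items():
        for p in paths:
            if not Path(p).exists():
                logger.warning("manifest: output %s of stage %s missing",
                               p, stage)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
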