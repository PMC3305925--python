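"""End-to-end pipeline: preprocessing -> structure correction ->
component selection -> external CV -> permutation test -> feature
selection -> network export, with a JSON run report."""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .association import correlation_network
from .datatypes import DataError, TraitVector, align_samples
from .feature_selection import score_features
from .io import (
    read_annotations,
    read_block,
    read_qmatrix,
    read_trait,
    write_edges_graphml,
    write_edges_tsv,
)
from .multiblock import fit_mbopls, select_components
from .preprocessing import (
    correct_population_structure,
    filter_missing,
    impute_missing,
    log2_transform,
    summarize_annotated_peaks,
    unit_variance_scale,
)
from .validation import permutation_test

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    block_paths: list
    trait_path: str
    trait_name: str
    out_dir: str
    q_path: str | None = None
    annotation_path: str | None = None
    log2: bool = False
    log2_offset: float = 0.0
    max_missing_fraction: float = 0.3
    summarize: bool = False
    summarize_threshold: float = 0.5
    max_orth_block: int = 3
    max_orth_top: int = 3
    n_folds: int = 7
    n_repeats: int = 10
    n_perm: int = 100
    n_boot: int = 100
    n_null: int = 100
    prior_h0: float = 0.95
    network_p_max: float = 0.001
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(report, name, fn):
    t0 = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:
        raise DataError(f"stage {name!r} failed: {exc}") from exc
    report["timings"][name] = round(time.perf_counter() - t0, 3)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by `config`; returns the report."""
    for p in list(config.block_paths) + [config.trait_path]:
        if not os.path.exists(p):
            raise DataError(f"input file not found: {p}")
    if config.q_path and not os.path.exists(config.q_path):
        raise DataError(f"input file not found: {config.q_path}")
    os.makedirs(config.out_dir, exist_ok=True)
    report = {"tool": "mbopls", "version": __version__,
              "config": asdict(config), "config_hash": config.config_hash(),
              "seed": config.seed, "timings": {}, "stages": {}}

    ann = read_annotations(config.annotation_path) if config.annotation_path else None
    trait = read_trait(config.trait_path, config.trait_name)
    blocks = [read_block(p, annotations=ann) for p in config.block_paths]

    def preprocess():
        out = []
        for blk in blocks:
            b = log2_transform(blk, config.log2_offset) if config.log2 else blk
            b = filter_missing(b, config.max_missing_fraction)
            b, _, _ = unit_variance_scale(b)
            out.append(b)
        return out

    scaled = _stage(report, "preprocess", preprocess)
    report["stages"]["preprocess"] = {
        "features_kept": [b.n_features for b in scaled]}

    if config.summarize:
        merged, provenance = _stage(
            report, "summarize",
            lambda: summarize_annotated_peaks(scaled, config.summarize_threshold))
        merged, _, _ = unit_variance_scale(merged)
        scaled = [merged]
        report["stages"]["summarize"] = {
            "merged_groups": {k: v for k, v in provenance.items()}}

    if config.q_path:
        q = read_qmatrix(config.q_path)
        trait = _stage(report, "structure_correction",
                       lambda: correct_population_structure(trait, q))
        report["stages"]["structure_correction"] = {"corrected": True}

    # align blocks and drop samples missing the trait
    obs = trait.observed_mask()
    kept_ids = [s for s, o in zip(trait.sample_ids, obs) if o]
    mats, fids = [], []
    for b in scaled:
        idx = align_samples(kept_ids, b.sample_ids, "blocks and trait")
        bb = b.with_values(b.values[idx])
        bb.sample_ids = list(kept_ids)
        mats.append(impute_missing(bb))
        fids.extend(b.feature_ids)
    y_raw = trait.values[obs]
    y_mean = float(y_raw.mean())
    y = y_raw - y_mean

    n_ob, n_ot, curves = _stage(
        report, "select_components",
        lambda: select_components(mats, y, config.max_orth_block,
                                  config.max_orth_top, config.n_folds,
                                  seed=config.seed))
    report["stages"]["select_components"] = {
        "n_orth_per_block": n_ob, "n_orth_top": n_ot,
        "cv_curves": {k: [[int(c), float(q2)] for c, q2 in v]
                      for k, v in curves.items()}}

    model = fit_mbopls(mats, y, n_ob, n_ot, trait_name=config.trait_name)
    model.y_mean = y_mean
    model.cv_meta = {"n_folds": config.n_folds, "seed": config.seed}
    model.save(os.path.join(config.out_dir, "model.json"))

    perm = _stage(
        report, "validation",
        lambda: permutation_test(mats, y, n_perm=config.n_perm,
                                 n_folds=config.n_folds,
                                 n_repeats=config.n_repeats,
                                 max_orth_block=config.max_orth_block,
                                 max_orth_top=config.max_orth_top,
                                 seed=config.seed))
    report["stages"]["validation"] = {
        "median_rcv2": perm.observed, "p_cv": perm.p_value, "n0": perm.n0,
        "n_perm": perm.n_perm, "rcv2_per_run": perm.observed_cv.rcv2_per_run.tolist()}
    med_idx = int(np.argsort(perm.observed_cv.rcv2_per_run)[
        len(perm.observed_cv.rcv2_per_run) // 2])
    with open(os.path.join(config.out_dir, "oof_predictions.tsv"), "w") as fh:
        fh.write("sample_id\ty_true\ty_pred_median_run\n")
        for s, yt, yp in zip(kept_ids, y_raw,
                             perm.observed_cv.predictions_per_run[med_idx]):
            fh.write(f"{s}\t{yt:.6g}\t{yp:.6g}\n")

    scores = _stage(
        report, "feature_selection",
        lambda: score_features(mats, y, n_ob, n_ot, feature_ids=fids,
                               n_boot=config.n_boot, n_null=config.n_null,
                               prior_h0=config.prior_h0, seed=config.seed))
    scores_path = os.path.join(config.out_dir, "feature_scores.tsv")
    scores.to_csv(scores_path, sep="\t", index=False)
    selected = scores.loc[scores["selected"], "feature_id"].tolist()
    report["stages"]["feature_selection"] = {
        "n_selected": len(selected), "selected": selected}

    X_all = np.concatenate([m.values for m in mats], axis=1)
    edges = _stage(
        report, "network",
        lambda: correlation_network(X_all, feature_ids=fids,
                                    selected_features=selected,
                                    p_max=config.network_p_max))
    write_edges_tsv(edges, os.path.join(config.out_dir, "network_edges.tsv"))
    try:
        write_edges_graphml(edges, os.path.join(config.out_dir, "network.graphml"))
    except DataError:
        pass
    report["stages"]["network"] = {"n_edges": len(edges)}

    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
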