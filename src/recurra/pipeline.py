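"""End-to-end pipeline: simulate/load -> UniFrac -> PCoA -> inference.

``run_pipeline`` wires the library modules into the dependency order
counts -> distance matrix -> ordination -> centroids -> group
comparisons -> binned likelihood model -> leave-one-out validation ->
resampling exercises (and optionally the sequencing-error experiment),
persisting every intermediate as TSV plus a JSON run manifest.  A single
global seed fans out to per-stage seeds by a fixed derivation so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    combination_tests,
    fit_binned_model,
    loocv,
    patient_distance_pools,
    single_biopsy_resampling,
    stability_through_time,
)
from .data_model import (
    CountTable,
    DistanceMatrix,
    PhyloTree,
    SampleMetadata,
    check_sample_alignment,
    load_count_table,
)
from .diversity import unifrac_matrix
from .group_inference import distance_pool, group_distance_summary
from .ordination import collapse_to_centroids, pcoa
from .seqsim import inflation_experiment
from .synth import (
    CohortSimConfig,
    simulate_cohort,
    simulate_reference_sequences,
    simulate_tree,
)

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "stage_seed", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "simulate", "unifrac", "pcoa", "centroids", "compare",
    "heatmap", "loocv", "resample", "combos",
)


def stage_seed(global_seed: int, stage: str) -> np.random.SeedSequence:
    """Fixed derivation of a per-stage seed from the global seed."""
    return np.random.SeedSequence([int(global_seed) % (2 ** 31), zlib.crc32(stage.encode())])


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the requested stages; returns the output directory.

    ``config`` is a dict (or path to a YAML file) with keys ``seed``,
    ``stages`` (subset of the defaults, plus optionally ``errsim``),
    optional input paths (``tree``, ``counts``, ``metadata``) when the
    simulate stage is not requested, and optional parameter blocks
    ``cohort`` (CohortSimConfig fields), ``resample`` and ``errsim``.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker = outdir / "FAILED"
    try:
        result = _run(dict(config), outdir)
    except Exception:
        marker.write_text("pipeline failed; see logs\n")
        raise
    if marker.exists():
        marker.unlink()
    return result


def _run(config: dict, outdir: Path) -> Path:
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {
        "command": "run_pipeline",
        "config": _jsonable(config),
        "seed": seed,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs": {},
        "stages": [],
    }

    tree = table = meta = None
    if "simulate" in stages:
        cohort_cfg = CohortSimConfig(**config.get("cohort", {}))
        rng_tree = np.random.default_rng(stage_seed(seed, "simulate-tree"))
        tree = simulate_tree(cohort_cfg.n_taxa, rng_tree)
        rng_cohort = np.random.default_rng(stage_seed(seed, "simulate-cohort"))
        table, meta = simulate_cohort(cohort_cfg, tree, rng_cohort)
        tree.write(outdir / "tree.nwk")
        table.to_tsv(outdir / "counts.tsv")
        meta.to_tsv(outdir / "meta.tsv")
        refs = simulate_reference_sequences(
            tree.leaf_names, config.get("ref_length", 150),
            np.random.default_rng(stage_seed(seed, "simulate-refs")),
        )
        refs.to_fasta(outdir / "refs.fasta")
        manifest["stages"].append({"stage": "simulate", "n_samples": len(table.sample_ids)})
        logger.info("simulate: %d samples, %d taxa", *table.shape)
    else:
        for key, loader in (("tree", PhyloTree.read), ("counts", load_count_table),
                            ("metadata", SampleMetadata.read)):
            if key not in config:
                raise ValueError(f"config missing input {key!r} for requested stages")
        tree = PhyloTree.read(config["tree"])
        table = load_count_table(config["counts"])
        meta = SampleMetadata.read(config["metadata"])
        for key in ("tree", "counts", "metadata"):
            manifest["inputs"][key] = _digest(Path(config[key]))
    table, meta = check_sample_alignment(
        table, meta, drop_unmatched=bool(config.get("drop_unmatched", False))
    )

    D = ordn = cents = None
    if "unifrac" in stages:
        D = unifrac_matrix(tree, table, normalized=bool(config.get("normalized", True)))
        D.to_tsv(outdir / "dist.tsv")
        manifest["stages"].append({"stage": "unifrac", "n_samples": len(D)})
    if "pcoa" in stages:
        if D is None:
            raise ValueError("stage 'pcoa' requires stage 'unifrac'")
        ordn = pcoa(D)
        ordn.to_tsv(outdir / "ord.tsv")
        manifest["stages"].append(
            {"stage": "pcoa", "n_axes": ordn.n_axes,
             "negative_eigenvalue_fraction": ordn.negative_fraction}
        )
    if "centroids" in stages:
        if ordn is None:
            raise ValueError("stage 'centroids' requires stage 'pcoa'")
        cents = collapse_to_centroids(ordn, meta)
        cents.to_tsv(outdir / "centroids.tsv")
        manifest["stages"].append({"stage": "centroids", "n_groups": len(cents.keys)})

    if "compare" in stages:
        if ordn is None:
            raise ValueError("stage 'compare' requires stage 'pcoa'")
        crohns_init = meta.select(cohort="crohns", timepoint=1)["sample_id"].tolist()
        ctrl_init = meta.select(cohort="control", timepoint=1)["sample_id"].tolist()
        pools = {
            "crohns_vs_crohns": distance_pool(
                crohns_init, crohns_init, "between-patient-centroids",
                ordn=ordn, meta=meta),
            "control_vs_control": distance_pool(
                ctrl_init, ctrl_init, "between-patient-centroids",
                ordn=ordn, meta=meta),
            "crohns_vs_control": distance_pool(
                crohns_init, ctrl_init, "between-patient-centroids",
                ordn=ordn, meta=meta),
        }
        comps = group_distance_summary(
            [
                ("crohns_vs_crohns|control_vs_control",
                 pools["crohns_vs_crohns"], pools["control_vs_control"]),
                ("crohns_vs_crohns|crohns_vs_control",
                 pools["crohns_vs_crohns"], pools["crohns_vs_control"]),
            ],
            reps=int(config.get("mc_reps", 1000)),
            seed=stage_seed(seed, "compare").generate_state(1)[0] % (2 ** 31),
        )
        pd.DataFrame([c.__dict__ for c in comps]).to_csv(
            outdir / "comparisons.tsv", sep="\t", index=False
        )
        manifest["stages"].append({"stage": "compare", "n_comparisons": len(comps)})

    pool_name = config.get("pool", "all-controls")
    pools_labels = None
    if {"heatmap", "loocv"} & set(stages):
        if D is None:
            raise ValueError("stages 'heatmap'/'loocv' require stage 'unifrac'")
        pools_labels = patient_distance_pools(D, meta, pool=pool_name)
    if "heatmap" in stages:
        per_pat, labels = pools_labels
        rem = np.concatenate([d for p, d in per_pat.items() if labels[p] == "remission"])
        rec = np.concatenate([d for p, d in per_pat.items() if labels[p] == "recurrence"])
        model = fit_binned_model(rem, rec, bin_width=float(config.get("bin_width", 0.1)))
        model.to_frame().to_csv(outdir / "heatmap.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": "heatmap", "n_bins": model.n_bins})
    if "loocv" in stages:
        per_pat, labels = pools_labels
        preds, summary = loocv(per_pat, labels,
                               bin_width=float(config.get("bin_width", 0.1)))
        pd.DataFrame(
            [
                {"patient_id": p.patient_id, "probability": p.probability,
                 "predicted": p.predicted, "true_label": p.true_label}
                for p in preds
            ]
        ).to_csv(outdir / "loocv.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": "loocv", **summary})

    if "resample" in stages:
        if D is None:
            raise ValueError("stage 'resample' requires stage 'unifrac'")
        per_pat, labels = patient_distance_pools(D, meta, pool="all-controls")
        df = meta.df
        biopsies = {
            p: df[(df["patient_id"] == p) & (df["timepoint"] == 1)]["sample_id"].tolist()
            for p in per_pat
        }
        ctrl_ids = df[df["cohort"] == "control"]["sample_id"].tolist()
        res = single_biopsy_resampling(
            D, biopsies, labels, ctrl_ids,
            reps=int(config.get("resample", {}).get("reps", 10000)),
            alpha=float(config.get("resample", {}).get("alpha", 0.05)),
            seed=np.random.default_rng(stage_seed(seed, "resample")),
        )
        (outdir / "resample.json").write_text(json.dumps(
            {k: v for k, v in res.items() if k != "p_values"}, indent=2))
        manifest["stages"].append(
            {"stage": "resample", "fraction_significant": res["fraction_significant"]}
        )
    if "combos" in stages:
        if ordn is None:
            raise ValueError("stage 'combos' requires stage 'pcoa'")
        per_pat, labels = patient_distance_pools(D, meta, pool="all-controls")
        df = meta.df
        ctrl_ids = [s for s in df[df["cohort"] == "control"]["sample_id"] if s in set(ordn.ids)]
        ctrl_centroid = ordn.coords_for(ctrl_ids).mean(axis=0)
        coords = {
            p: ordn.coords_for(
                df[(df["patient_id"] == p) & (df["timepoint"] == 1)]["sample_id"].tolist()
            )
            for p in per_pat
        }
        res = combination_tests(coords, ctrl_centroid, labels)
        (outdir / "combos.json").write_text(json.dumps(
            {k: v for k, v in res.items() if k != "p_values"}, indent=2))
        manifest["stages"].append(
            {"stage": "combos", "n_combinations": res["n_combinations"],
             "fraction_significant": res["fraction_significant"]}
        )

    if "errsim" in stages:
        err_cfg = config.get("errsim", {})
        refs = simulate_reference_sequences(
            [f"ref{i:03d}" for i in range(int(err_cfg.get("n_refs", 20)))],
            int(err_cfg.get("read_length", 100)),
            np.random.default_rng(stage_seed(seed, "errsim-refs")),
        )
        table_err = inflation_experiment(
            refs,
            read_length=int(err_cfg.get("read_length", 100)),
            depths=list(err_cfg.get("depths", [10000])),
            error_rates=list(err_cfg.get("error_rates", [0.0, 0.001, 0.005])),
            threshold=float(err_cfg.get("threshold", 0.97)),
            seed=int(stage_seed(seed, "errsim").generate_state(1)[0] % (2 ** 31)),
        )
        table_err.to_csv(outdir / "otu_inflation.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": "errsim", "n_cells": len(table_err)})

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), outdir)
    return outdir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
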