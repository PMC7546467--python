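"""End-to-end orchestration: simulate (or preprocess) -> multi-restart
clustering -> optional bulk refinement -> evaluation, with a manifest
recording versions, seeds and the config for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bulk import bulk_local_search
from .config import PipelineConfig
from .io import (
    load_matrix,
    read_bulk_tsv,
    save_matrix,
    write_bulk_tsv,
)
from .metrics import evaluate_result, v_measure, prevalence_mae
from .model import Hyperparams
from .selection import run_restarts, select_best
from .simulate import SyntheticConfig, simulate_dataset

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Stages whose outputs already exist are skipped unless ``force``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": [],
    }
    master = np.random.SeedSequence(config.seed)
    sim_seed, fit_seed, bulk_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in master.spawn(3)
    )

    dataset = None
    stage = "simulate" if config.simulate.enabled else "preprocess"
    try:
        if config.simulate.enabled:
            prefix = out / "synthetic"
            sim = config.simulate
            syn_cfg = SyntheticConfig(
                n_cells=sim.n_cells,
                n_loci=sim.n_loci,
                n_regions=sim.n_regions,
                n_clusters=sim.n_clusters,
                cluster_freqs=(
                    tuple(sim.cluster_freqs) if sim.cluster_freqs else None
                ),
                missing_prop=sim.missing_prop,
                cell_variability=sim.cell_variability,
                n_diff_regions=sim.n_diff_regions,
                error_rate=sim.error_rate,
                bulk_depth=sim.bulk_depth,
                seed=sim_seed,
            )
            dataset = simulate_dataset(syn_cfg)
            matrix = dataset.observed
            if force or not (out / "synthetic_matrix.tsv.gz").exists():
                save_matrix(matrix, prefix)
                pd.DataFrame(
                    {
                        "cell_id": matrix.cell_ids,
                        "true_label": dataset.true_labels + 1,
                    }
                ).to_csv(out / "true_labels.tsv", sep="\t", index=False)
                write_bulk_tsv(dataset.bulk, out / "bulk.tsv")
            manifest["stages"].append("simulate")
        else:
            matrix = load_matrix(str(out / "preprocessed"))
            manifest["stages"].append("preprocess")
    except Exception as exc:
        _write_manifest(out, manifest)
        raise StageError(stage, exc) from exc

    stage = "cluster"
    try:
        cl = config.cluster
        hyper = Hyperparams(
            alpha0=cl.alpha0,
            beta0=tuple(cl.beta0),
            gamma0=tuple(tuple(row) for row in cl.gamma0),
        )
        table = run_restarts(
            matrix,
            n_restarts=cl.n_restarts,
            kmax=cl.kmax,
            hyperparams=hyper,
            seed=fit_seed,
            tol=cl.tol,
            max_iters=cl.max_iters,
            shared_region=cl.shared_region,
        )
        selection = select_best(table, decrease_threshold=cl.decrease_threshold)
        table.df.to_csv(out / "runs.tsv", sep="\t", index=False)
        selection.dic_curve.to_csv(out / "dic_curve.tsv", sep="\t", index=False)
        best = selection.best_fit
        assign = pd.DataFrame(
            {"cell_id": matrix.cell_ids, "map_label": best.map_labels + 1}
        )
        for k in range(best.model.K):
            assign[f"prob_{k + 1}"] = best.resp[:, k]
        assign.to_csv(out / "assignments.tsv", sep="\t", index=False)
        with open(out / "scalars.json", "w") as fh:
            json.dump(
                {
                    "selected_clusters": selection.n_clusters,
                    "best_run_id": selection.best_run_id,
                    "elbo": best.elbo,
                    "dic": best.dic,
                    "n_iters": best.n_iters,
                    "converged": best.converged,
                },
                fh,
                indent=2,
            )
        manifest["stages"].append("cluster")
    except Exception as exc:
        _write_manifest(out, manifest)
        raise StageError(stage, exc) from exc

    labels = best.map_labels
    if config.bulk_refine.enabled:
        stage = "bulk_refine"
        try:
            br = config.bulk_refine
            if br.bulk_tsv:
                bulk = read_bulk_tsv(br.bulk_tsv)
            elif dataset is not None and dataset.bulk is not None:
                bulk = dataset.bulk
            else:
                raise ValueError("bulk refinement needs a bulk profile")
            refined = bulk_local_search(
                best,
                bulk,
                rng=bulk_seed,
                n_iterations=br.n_iterations,
                accept_worse_prob=br.accept_worse_prob,
                uncertain_threshold=br.uncertain_threshold,
                candidate_floor=br.candidate_floor,
            )
            labels = refined.labels
            pd.DataFrame(
                {"cell_id": matrix.cell_ids, "refined_label": labels + 1}
            ).to_csv(out / "refined_assignments.tsv", sep="\t", index=False)
            manifest["stages"].append("bulk_refine")
        except Exception as exc:
            _write_manifest(out, manifest)
            raise StageError(stage, exc) from exc

    if config.evaluate and dataset is not None:
        stage = "evaluate"
        try:
            report = evaluate_result(dataset, best)
            metrics = report.to_dict()
            if config.bulk_refine.enabled:
                h, c, v = v_measure(dataset.true_labels, labels)
                metrics["refined_v_measure"] = v
                metrics["refined_prevalence_mae"] = prevalence_mae(
                    dataset.true_labels, labels
                )
            with open(out / "metrics.json", "w") as fh:
                json.dump(metrics, fh, indent=2, default=float)
            report.coclustering.to_csv(out / "coclustering.tsv", sep="\t")
            manifest["stages"].append("evaluate")
        except Exception as exc:
            _write_manifest(out, manifest)
            raise StageError(stage, exc) from exc

    _write_manifest(out, manifest)
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
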