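"""End-to-end orchestration: build -> fingerprint -> embed -> cluster ->
characterize -> render, with per-stage persistence and a run manifest."""

from __future__ import annotations

import json
import logging
import os
import platform
import time

import numpy as np

from . import __version__
from .config import PipelineConfig
from .errors import RinStatesError
from .fingerprints import (fingerprint_matrix, normalize_fingerprints,
                           save_fingerprints_csv)
from .landscape import cluster_density, embed_nonlinear, pca_embed
from .rin import build_rins, export_contact_table
from .states import (MapColoring, cluster_populations, consensus_graph,
                     save_summary_json, save_weight_matrix_csv,
                     summarize_cluster)
from .traj_io import TrajectoryEnsemble
from .viz import render_landscape

log = logging.getLogger(__name__)

STAGES = ("build", "fingerprint", "embed", "cluster", "characterize", "render")


class PipelineResult(dict):
    """Dict of per-stage products with attribute access for the common ones."""

    @property
    def labels(self):
        return self["labels"]

    @property
    def embedding(self):
        return self["embedding"]

    @property
    def fingerprints(self):
        return self["fingerprints"]


def run_pipeline(config: PipelineConfig, ensemble: TrajectoryEnsemble,
                 write_outputs: bool = True) -> PipelineResult:
    """Run the full analysis on an in-memory ensemble.

    Every stage's outputs are persisted under ``config.output_dir`` (when
    ``write_outputs``), and a manifest records version, seed, parameters and
    completed stages. A stage failure aborts with the stage name while the
    manifest keeps the partial progress.
    """
    outdir = config.output_dir
    if write_outputs:
        os.makedirs(outdir, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "stages_completed": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    result = PipelineResult()

    def finish_stage(name: str) -> None:
        manifest["stages_completed"].append(name)
        if write_outputs:
            with open(os.path.join(outdir, "manifest.json"), "w") as fh:
                json.dump(manifest, fh, indent=2)

    stage = "build"
    try:
        graphs = build_rins(ensemble, cutoff=config.cutoff_nm,
                            residue_range=config.residue_subset)
        result["graphs"] = graphs
        if write_outputs:
            export_contact_table(graphs, os.path.join(outdir, "contacts.csv"))
        finish_stage(stage)

        stage = "fingerprint"
        fp = normalize_fingerprints(
            fingerprint_matrix(ensemble, graphs,
                               convention=config.closeness_convention))
        result["fingerprints"] = fp
        if write_outputs:
            save_fingerprints_csv(fp, os.path.join(outdir, "fingerprints.csv"))
        finish_stage(stage)

        stage = "embed"
        if config.embedding_method == "pca":
            emb = pca_embed(fp, k=config.embedding_k)
        else:
            params = {"k": config.embedding_k, **config.embedding_params}
            if config.embedding_method == "encodermap-like":
                params.setdefault("sigmoid_high", config.sigmoid_high)
                params.setdefault("sigmoid_low", config.sigmoid_low)
            emb = embed_nonlinear(fp, method=config.embedding_method,
                                  params=params, seed=config.seed)
        result["embedding"] = emb
        finish_stage(stage)

        stage = "cluster"
        labels = cluster_density(emb, min_cluster_size=config.min_cluster_size,
                                 min_samples=config.min_samples,
                                 selection=config.cluster_selection_method)
        result["labels"] = labels
        if write_outputs:
            _save_embedding_csv(ensemble, emb, labels,
                                os.path.join(outdir, "landscape.csv"))
        finish_stage(stage)

        stage = "characterize"
        pops = cluster_populations(labels)
        summaries = {}
        consensus = {}
        for c in labels.cluster_ids:
            summaries[c] = summarize_cluster(c, fp, labels, emb,
                                             config.n_representatives)
            consensus[c] = consensus_graph(graphs, labels, c)
            if write_outputs:
                save_summary_json(summaries[c],
                                  os.path.join(outdir, f"cluster_{c}.json"))
                save_weight_matrix_csv(consensus[c].weights,
                                       os.path.join(outdir, f"consensus_{c}.csv"))
        result["populations"] = pops
        result["summaries"] = summaries
        result["consensus"] = consensus
        finish_stage(stage)

        stage = "render"
        if write_outputs:
            density = MapColoring(kind="density", values=np.zeros(emb.n_frames))
            render_landscape(emb, density, outlines=labels,
                             path=os.path.join(outdir, "landscape_density.svg"),
                             bins=config.density_bins)
            clusters = MapColoring(kind="cluster_id",
                                   values=labels.labels.astype(float))
            render_landscape(emb, clusters,
                             path=os.path.join(outdir, "landscape_clusters.svg"))
        finish_stage(stage)
    except Exception as exc:
        raise RinStatesError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if write_outputs:
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    result["manifest"] = manifest
    log.info("pipeline complete: %d clusters, %.1f%% classified",
             len(result["labels"].cluster_ids),
             100.0 * (result["labels"].labels >= 0).mean())
    return result


def _save_embedding_csv(ensemble, emb, labels, path) -> None:
    with open(path, "w") as fh:
        cols = ",".join(f"c{i+1}" for i in range(emb.k))
        fh.write(f"trajectory,frame,{cols},cluster\n")
        for f, (tid, fi) in enumerate(ensemble.frame_ids):
            coords = ",".join(f"{x:.6f}" for x in emb.coords[f])
            fh.write(f"{tid},{fi},{coords},{labels.labels[f]}\n")
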