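"""End-to-end orchestration: validated YAML configs, staged runs, manifests.

A run proceeds simulate-or-load → quantify → topics → differential → motifs,
each stage toggleable, with every stochastic step seeded from the config.
All outputs are plain text (Matrix Market, TSV, BED, YAML, JSON); the run
manifest records a SHA-256 checksum per output so two runs from one config
can be compared bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from . import synthio
from .diffmark import PoissonDiffModel, call_dynamic, classify_fate_independent
from .motifact import MotifActivityModel, MotifDesign
from .quantify import CountMatrix, bins_above_background, filter_cells
from .synthio import SimConfig
from .topics import TopicModel, cluster_cells, correct_batch, impute_signal, latent_log_odds

_DEFAULTS = {
    "bin_width": 50_000,
    "tss_halfwidth": 5_000,
    "q_threshold_active": 1e-50,
    "q_threshold_h3k9me3": 1e-9,
    "z_threshold": 0.7,
    "knn_k": 10,
    "velocity_delta": 0.01,
    "min_cuts": 100,
    "n_topic": None,        # defaults to the simulated n_type
    "seed": 0,
    "mark": "H3K4me1",
}

_SIM_KEYS = {"n_region", "n_type", "n_cell_per_type", "depth_median", "depth_sigma",
             "frac_dynamic", "fold_spec", "batch_spec", "n_plate", "seed"}
_STAGE_NAMES = ["simulate", "quantify", "topics", "diff", "motifs"]


@dataclass
class PipelineConfig:
    """Validated run configuration with paper-default parameters filled in."""

    outdir: str
    counts_prefix: str | None = None        # load counts instead of simulating
    metadata_path: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGE_NAMES})
    params: dict = field(default_factory=lambda: dict(_DEFAULTS))
    sim: dict = field(default_factory=dict)


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config mapping; unknown keys are rejected by name."""
    raw = dict(raw or {})
    known_top = {"outdir", "counts_prefix", "metadata_path", "stages", "params", "sim"}
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "outdir" not in raw:
        raise ValueError("missing required config key: outdir")
    stages = {s: True for s in _STAGE_NAMES}
    for k, v in (raw.get("stages") or {}).items():
        if k not in stages:
            raise ValueError(f"unknown stage: {k!r}")
        stages[k] = bool(v)
    params = dict(_DEFAULTS)
    for k, v in (raw.get("params") or {}).items():
        if k not in params:
            raise ValueError(f"unknown parameter: {k!r}")
        params[k] = v
    sim = dict(raw.get("sim") or {})
    unknown_sim = set(sim) - _SIM_KEYS
    if unknown_sim:
        raise ValueError(f"unknown sim keys: {sorted(unknown_sim)}")
    for key in ("counts_prefix", "metadata_path"):
        path = raw.get(key)
        if path is not None:
            probe = f"{path}.mtx" if key == "counts_prefix" else path
            if not os.path.exists(probe):
                raise ValueError(f"config key {key}: path {probe} does not exist")
    return PipelineConfig(outdir=raw["outdir"], counts_prefix=raw.get("counts_prefix"),
                          metadata_path=raw.get("metadata_path"),
                          stages=stages, params=params, sim=sim)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    cio.ensure_dir(cfg.outdir)
    outputs: list[str] = []
    log: list[dict] = []
    seed = int(cfg.params["seed"])

    def _record(stage, files, **info):
        outputs.extend(files)
        log.append({"stage": stage, "files": [os.path.basename(f) for f in files], **info})

    mat: CountMatrix | None = None
    meta: pd.DataFrame | None = None
    truth = None

    if cfg.stages["simulate"] and cfg.counts_prefix is None:
        sim_kwargs = dict(cfg.sim)
        sim_kwargs.setdefault("seed", seed)
        sc = SimConfig(**sim_kwargs)
        truth = synthio.simulate_profiles(sc)
        mat, labels = synthio.simulate_cells(truth, sc)
        meta = pd.DataFrame({"celltype": labels, "plate": truth.cell_plates})
        prefix = os.path.join(cfg.outdir, "counts")
        files = cio.write_count_matrix(mat, prefix)
        meta_path = os.path.join(cfg.outdir, "cell_metadata.tsv")
        cio.write_cell_metadata(meta, meta_path)
        truth_path = os.path.join(cfg.outdir, "truth_dynamic.tsv")
        pd.DataFrame({"region": mat.regions.ids,
                      "dynamic": truth.dynamic_mask}).to_csv(truth_path, sep="\t", index=False)
        _record("simulate", files + [meta_path, truth_path],
                seed=sc.seed, n_cell=len(mat.cells), n_region=len(mat.regions))
    elif cfg.counts_prefix is not None:
        mat = cio.read_count_matrix(cfg.counts_prefix)
        if cfg.metadata_path:
            meta = cio.read_cell_metadata(cfg.metadata_path)
        _record("load", [], prefix=cfg.counts_prefix)
    if mat is None:
        raise RuntimeError("stage simulate disabled and no counts_prefix given")

    result: dict = {"config": {"params": cfg.params, "stages": cfg.stages, "sim": cfg.sim}}

    if cfg.stages["quantify"]:
        try:
            mat, qc = filter_cells(mat, min_cuts=int(cfg.params["min_cuts"]))
        except ValueError as err:
            raise RuntimeError(f"stage quantify failed: {err}") from err
        if meta is not None:
            meta = meta.loc[mat.cells]
        mask = bins_above_background(mat)
        mat_bg = mat.subset_regions(mask)
        qc_path = os.path.join(cfg.outdir, "qc_cells.tsv")
        qc.per_cell.to_csv(qc_path, sep="\t")
        mask_path = os.path.join(cfg.outdir, "bins_above_background.tsv")
        pd.DataFrame({"region": mat.regions.ids, "above_background": mask}).to_csv(
            mask_path, sep="\t", index=False)
        _record("quantify", [qc_path, mask_path],
                n_pass=qc.n_pass, n_bins_kept=int(mask.sum()))
    else:
        mat_bg = mat

    signal = None
    labels_for_diff = meta["celltype"] if meta is not None and "celltype" in meta else None
    cluster_labels = None
    if cfg.stages["topics"]:
        n_topic = cfg.params["n_topic"] or (len(set(labels_for_diff)) if labels_for_diff is not None else 10)
        try:
            fit = TopicModel(mat_bg, n_topic=int(n_topic)).fit(seed=seed)
        except ValueError as err:
            raise RuntimeError(f"stage topics failed: {err}") from err
        latent = latent_log_odds(fit)
        cluster_labels = cluster_cells(latent, k=int(n_topic), seed=seed)
        if meta is not None and "plate" in meta and meta["plate"].nunique() > 1:
            latent = correct_batch(latent, meta["plate"].to_numpy(), cluster_labels)
        signal = impute_signal(fit)
        theta_path = os.path.join(cfg.outdir, "doc_topic.tsv")
        pd.DataFrame(fit.doc_topic, index=fit.cells).to_csv(theta_path, sep="\t")
        clu_path = os.path.join(cfg.outdir, "clusters.tsv")
        pd.DataFrame({"cell": fit.cells, "cluster": cluster_labels}).to_csv(
            clu_path, sep="\t", index=False)
        _record("topics", [theta_path, clu_path], K=int(n_topic))
        result["cluster_labels"] = cluster_labels

    if cfg.stages["diff"]:
        if labels_for_diff is None:
            raise RuntimeError("stage diff needs cell-type labels in metadata")
        try:
            diff = PoissonDiffModel(mat_bg, labels_for_diff).fit()
        except ValueError as err:
            raise RuntimeError(f"stage diff failed: {err}") from err
        mark = str(cfg.params["mark"])
        thresholds = {"H3K4me1": cfg.params["q_threshold_active"],
                      "H3K4me3": cfg.params["q_threshold_active"],
                      "H3K27me3": cfg.params["q_threshold_active"],
                      "H3K9me3": cfg.params["q_threshold_h3k9me3"]}
        call_dynamic(diff, mark, thresholds)
        if diff.table["dynamic"].any():
            fate = classify_fate_independent(diff)
            fate_path = os.path.join(cfg.outdir, "fate_independence.tsv")
            fate.to_csv(fate_path, sep="\t", index=False)
        else:
            fate_path = None
        diff_path = os.path.join(cfg.outdir, "diff_regions.tsv")
        diff.table.join(diff.log2_fold.add_prefix("log2fc_")).to_csv(diff_path, sep="\t")
        _record("diff", [diff_path] + ([fate_path] if fate_path else []),
                n_dynamic=int(diff.table["dynamic"].sum()))
        result["diff"] = diff

    if cfg.stages["motifs"]:
        if signal is None:
            raise RuntimeError("stage motifs needs the topics stage")
        n_motif = 10
        rng = np.random.default_rng(seed + 1)
        N = rng.poisson(1.0, size=(signal.shape[0], n_motif)).astype(float)
        N[rng.integers(0, signal.shape[0], size=n_motif), np.arange(n_motif)] += 1
        design = MotifDesign(N=N, motif_names=[f"motif{m}" for m in range(n_motif)],
                             region_ids=signal.region_ids)
        act = MotifActivityModel(signal, design).fit(seed=seed,
                                                     z_threshold=float(cfg.params["z_threshold"]))
        act_path = os.path.join(cfg.outdir, "motif_activities.tsv")
        act.activities.to_csv(act_path, sep="\t")
        z_path = os.path.join(cfg.outdir, "motif_zscores.tsv")
        pd.DataFrame({"zscore": act.zscores, "significant": act.significant}).to_csv(
            z_path, sep="\t")
        _record("motifs", [act_path, z_path], lam=act.lam)

    manifest = {
        "outputs": {os.path.basename(f): _sha256(f) for f in outputs},
        "log": log,
        "seed": seed,
    }
    man_path = os.path.join(cfg.outdir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    result["manifest"] = manifest
    result["truth"] = truth
    result["count_matrix"] = mat_bg
    result["metadata"] = meta
    return result
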