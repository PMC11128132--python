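"""End-to-end orchestration: simulate/ingest -> normalize -> integrate ->
cluster -> score -> compare (-> DE -> ORA), from one config with one seed.

The global seed is expanded into independent per-stage seeds by hashing
``"{seed}:{stage}"`` with SHA-256 (mod 2^31), so each stochastic stage
(simulation, control-gene draws, random forest, Louvain) is reproducible in
isolation. Every written artifact gets a JSON sidecar with the stage
parameters, its seed and the SHA-256 checksum of the file; re-running an
identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import simdata
from .io_spatial import StudyDataset, read_study_manifest, write_visium
from .markers import MarkerPanel
from .prep_integrate import (
    embed_pca,
    integrate_rpca,
    log_normalize,
    scale_and_regress,
    select_integration_features,
)
from .scoring import aggregate_scores, compare_groups, score_signatures
from .segment import cluster_snn_louvain, label_regions, majority_vote_names
from .diffexpr import classify_degs, read_gmt, run_de, run_ora

logger = logging.getLogger("stquant.pipeline")

__all__ = ["PipelineConfig", "PipelineResult", "run_study", "run_pipeline", "stage_seed"]

KNOWN_KEYS = {
    "seed", "out_dir", "simulate", "study", "integrate", "cluster",
    "regions", "score", "compare", "de", "ora",
}


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    simulate: dict[str, Any] | None = None
    study: str | None = None  # manifest TSV path, alternative to simulate
    integrate: dict[str, Any] = field(default_factory=dict)
    cluster: dict[str, Any] = field(default_factory=dict)
    regions: dict[int, str] | str = "majority_vote"
    score: dict[str, Any] = field(default_factory=dict)
    compare: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] | None = None
    ora: dict[str, Any] | None = None

    @classmethod
    def from_mapping(cls, cfg: dict[str, Any]) -> "PipelineConfig":
        unknown = set(cfg) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        obj = cls(**cfg)
        obj.validate()
        return obj

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if self.simulate is None and self.study is None:
            raise ValueError("config needs either a 'simulate' block or a 'study' manifest")
        if self.study is not None and not Path(self.study).exists():
            raise ValueError(f"study manifest not found: {self.study}")
        panel = self.score.get("panel")
        if isinstance(panel, str) and panel != "truth" and not Path(panel).exists():
            raise ValueError(f"marker panel file not found: {panel}")
        if self.ora and not Path(self.ora.get("gmt", "")).exists():
            raise ValueError(f"GMT file not found: {self.ora.get('gmt')}")


@dataclass
class PipelineResult:
    study: StudyDataset
    truth: simdata.GroundTruth | None
    corrected: np.ndarray
    assignment: Any
    scores: pd.DataFrame
    table: Any  # SignatureTable
    comparison: Any  # GroupComparison
    de_result: Any = None
    ora_result: Any = None


def run_study(config: PipelineConfig) -> PipelineResult:
    """In-memory pipeline run (no files); the core of :func:`run_pipeline`."""
    seed = config.seed
    t0 = time.perf_counter()

    if config.simulate is not None:
        sim = dict(config.simulate)
        spec = sim.pop("spec", None)
        if spec is None:
            spec = simdata.default_brain_spec(**sim)
        study, truth = simdata.simulate_study(spec, seed=stage_seed(seed, "simulate"))
    else:
        study, truth = read_study_manifest(config.study), None
    logger.info("stage=ingest n_spots=%d n_genes=%d", study.n_spots, study.n_genes)

    icfg = dict(config.integrate)
    ref_groups = set(np.atleast_1d(icfg.pop("reference_groups", ["WT"])))
    n_features = min(icfg.pop("n_features", 2000), study.n_genes)
    features = select_integration_features(
        study, n=n_features, n_hvg=min(2000, study.n_genes)
    )
    non_ref = (~study.obs["group"].isin(ref_groups)).any()
    if non_ref and not study.obs["group"].isin(ref_groups).any():
        ref_groups = {study.obs["group"].iloc[0]}  # degenerate single-group study
    corrected, _anchors = integrate_rpca(
        study, reference_groups=ref_groups, features=features, **icfg
    )
    logger.info("stage=integrate n_features=%d dt=%.2fs", len(features), time.perf_counter() - t0)

    ccfg = dict(config.cluster)
    n_pcs = ccfg.pop("n_pcs", 30)
    totals = np.asarray(study.counts.sum(axis=1)).ravel()
    scaled = scale_and_regress(corrected, covariate=totals)
    emb = embed_pca(scaled, n_pcs=min(n_pcs, min(scaled.shape) - 1))
    labels = cluster_snn_louvain(emb, seed=stage_seed(seed, "cluster"), **ccfg)
    if config.regions == "majority_vote" and truth is not None:
        name_map = majority_vote_names(labels, truth.region.to_numpy())
    elif isinstance(config.regions, dict):
        name_map = {int(k): v for k, v in config.regions.items()}
    else:
        name_map = {}
    assignment = label_regions(
        labels, name_map, resolution=ccfg.get("resolution", 0.15)
    )
    logger.info("stage=cluster n_clusters=%d", assignment.n_clusters)

    scfg = dict(config.score)
    panel_src = scfg.pop("panel", "truth")
    if panel_src == "truth":
        if truth is None:
            raise ValueError("panel='truth' requires a simulated study")
        spec_obj = config.simulate.get("spec") if config.simulate else None
        if spec_obj is not None and spec_obj.signature_blocks:
            gene_sets = {
                f"{region}|{group}": list(genes_)
                for (region, group), (genes_, _t) in spec_obj.signature_blocks.items()
            }
        else:
            gene_sets = {"reactive_glia": simdata.reactive_glia_signature(
                spec_obj or simdata.default_brain_spec(**(config.simulate or {}))
            )}
    elif isinstance(panel_src, MarkerPanel):
        gene_sets = panel_src.gene_sets()
    else:
        gene_sets = MarkerPanel.read_json(panel_src).gene_sets()
    norm = log_normalize(study.counts, gene_ids=study.shared_genes)
    scores = score_signatures(
        norm, gene_sets, obs_index=study.obs.index,
        seed=stage_seed(seed, "score"), **scfg,
    )
    table = aggregate_scores(scores, assignment, study)

    mcfg = dict(config.compare)
    groups = mcfg.pop("groups", None)
    if groups is None:
        uniq = list(dict.fromkeys(study.obs["group"]))
        groups = uniq[-1:] + uniq[:1] if len(uniq) > 1 else uniq * 2
    comparison = compare_groups(table, groups[0], groups[1], **mcfg)
    logger.info("stage=compare n_tests=%d", len(comparison.rows))

    de_result = ora_result = None
    if config.de is not None:
        dcfg = dict(config.de)
        de_groups = dcfg.pop("groups", groups)
        de_result = run_de(
            study, assignment, dcfg.pop("region"), de_groups[0], de_groups[1], **dcfg
        )
        classify_degs(de_result)
    if config.ora is not None and de_result is not None:
        up, down = classify_degs(de_result)
        ora_result = run_ora(
            up + down, list(study.shared_genes), read_gmt(config.ora["gmt"])
        )
    return PipelineResult(
        study=study, truth=truth, corrected=corrected, assignment=assignment,
        scores=scores, table=table, comparison=comparison,
        de_result=de_result, ora_result=ora_result,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | dict | str) -> dict:
    """Run all stages and write artifacts + sidecars; returns the manifest."""
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_mapping(config)
    config.validate()
    out = Path(config.out_dir or "stquant_run")
    out.mkdir(parents=True, exist_ok=True)

    res = run_study(config)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def emit(stage: str, name: str, writer, params: dict) -> None:
        path = out / name
        writer(path)
        entry = {
            "file": name,
            "sha256": _sha256(path),
            "params": params,
            "seed": stage_seed(config.seed, stage),
        }
        (out / f"{name}.json").write_text(json.dumps(entry, indent=2, default=str))
        manifest["stages"][stage] = entry

    obs = res.study.obs
    emit(
        "cluster",
        "clusters.tsv",
        lambda p: res.assignment.to_frame(obs).to_csv(p, sep="\t", index=False),
        {"resolution": res.assignment.resolution, "n_clusters": res.assignment.n_clusters},
    )
    emit(
        "score",
        "scores.tsv",
        lambda p: res.scores.round(9).to_csv(p, sep="\t"),
        dict(config.score),
    )
    emit(
        "aggregate",
        "aggregates.tsv",
        lambda p: res.table.aggregates.round(9).to_csv(p, sep="\t", index=False),
        {},
    )
    emit(
        "compare",
        "comparisons.tsv",
        lambda p: res.comparison.rows.round(9).to_csv(p, sep="\t", index=False),
        dict(config.compare),
    )
    if res.de_result is not None:
        emit(
            "de",
            "de.tsv",
            lambda p: res.de_result.table.round(9).to_csv(p, sep="\t", index=False),
            dict(config.de or {}),
        )
    if res.ora_result is not None:
        emit(
            "ora",
            "ora.tsv",
            lambda p: res.ora_result.table.round(9).to_csv(p, sep="\t", index=False),
            dict(config.ora or {}),
        )
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_simulation(spec, seed: int, out_dir) -> Path:
    """Write one Visium tree per simulated slide plus truth tables and spec."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, truth = simdata.simulate_study(spec, seed=seed)
    rows = []
    for slide in study.slides:
        d = out / slide.slide_id
        write_visium(slide, d)
        rows.append(
            dict(slide_id=slide.slide_id, path=slide.slide_id,
                 mouse_id=slide.mouse_id, group=slide.group, plane=slide.plane)
        )
    pd.DataFrame(rows).to_csv(out / "study.tsv", sep="\t", index=False)
    truth.region.rename("region").to_frame().to_csv(out / "truth_regions.tsv", sep="\t")
    truth.effects.to_csv(out / "truth_effects.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(r, ",".join(g)) for r, g in truth.markers.items()],
        columns=["region", "genes"],
    ).to_csv(out / "truth_markers.tsv", sep="\t", index=False)
    def plain(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    spec_dict = {
        k: plain(v) for k, v in spec.__dict__.items() if not isinstance(v, dict)
    }
    (out / "spec.yaml").write_text(yaml.safe_dump(spec_dict))
    return out
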