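"""End-to-end reproducible pipeline: corpus -> topics -> novelty -> networks
-> co-mention -> trends -> synthetic cohort risk model, with a manifest of
configuration, seeds and output hashes."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import cohort as cohort_mod
from . import networks, novelty, topics, trends
from .corpus import (
    build_vocabulary,
    clean_corpus,
    read_corpus,
    write_clean,
    write_corpus,
)
from .simulate import CorpusSimConfig, generate_corpus

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Serialisable parameters for one pipeline run.

    ``corpus_csv`` reads an existing corpus; otherwise a synthetic corpus is
    generated with ``simulate`` overrides (fields of CorpusSimConfig).
    """

    corpus_csv: str | None = None
    simulate: dict = field(default_factory=dict)
    seed: int = 7
    k: int = 7
    noise_quantile: float = 0.03
    embed_dim: int = 16
    min_count: int = 2
    top_n_keywords: int = 10
    window: int = 5
    min_weight: int = 2
    resolution: float = 1.0
    horizon_start: int = 2026
    horizon_end: int = 2029
    cohort_n: int = 500
    cohort_seed: int = 11
    permutation_repeats: int = 10

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage, writing outputs and a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    manifest: dict = {
        "package": "litaxis",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
    }

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - report stage and cause
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(name)
        return deco

    state: dict = {}

    @stage("corpus")
    def _corpus():
        if config.corpus_csv:
            records = read_corpus(config.corpus_csv)
        else:
            sim = CorpusSimConfig(**{"seed": config.seed, **config.simulate})
            records, truth = generate_corpus(sim)
            gt_path = out / "ground_truth.json"
            gt_path.write_text(
                json.dumps(
                    {
                        "doc_topic_labels": truth.doc_topic_labels,
                        "planted_triad_docs": truth.planted_triad_docs,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            outputs["ground_truth"] = gt_path
        corpus_path = out / "corpus.csv"
        write_corpus(records, corpus_path)
        outputs["corpus"] = corpus_path
        state["records"] = records

    @stage("clean")
    def _clean():
        docs = clean_corpus(state["records"])
        vocab, docs = build_vocabulary(docs, min_count=config.min_count)
        state["docs"] = docs
        state["vocab"] = vocab
        path = out / "clean.csv"
        write_clean(docs, path)
        outputs["clean"] = path

    @stage("topics")
    def _topics():
        E = topics.embed_documents(
            state["docs"], dim=min(config.embed_dim, len(state["vocab"])),
            seed=config.seed,
        )
        assignment = topics.cluster_documents(
            E, K=config.k, noise_quantile=config.noise_quantile, seed=config.seed
        )
        summaries = topics.ctfidf_keywords(
            state["docs"], assignment, top_n=config.top_n_keywords
        )
        state["E"] = E
        state["assignment"] = assignment
        state["summaries"] = summaries
        path = out / "topics.json"
        path.write_text(
            json.dumps(
                {
                    "labels": {
                        d: int(l)
                        for d, l in zip(assignment.doc_ids, assignment.labels)
                    },
                    "K": assignment.K,
                    "summaries": [
                        {
                            "topic_id": s.topic_id,
                            "top_terms": [
                                {"term": t, "weight": w} for t, w in s.top_terms
                            ],
                        }
                        for s in summaries
                    ],
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["topics"] = path

    @stage("novelty")
    def _novelty():
        metrics = novelty.compute_topic_metrics(
            state["E"], state["assignment"], state["docs"]
        )
        state["metrics"] = metrics
        path = out / "topic_metrics.csv"
        metrics.to_csv(path, index=False)
        outputs["topic_metrics"] = path

    @stage("network")
    def _network():
        keywords = {t for s in state["summaries"] for t, _ in s.top_terms}
        g = networks.build_cooccurrence(
            state["docs"], keywords, window=config.window,
            min_weight=config.min_weight,
        )
        partition = networks.louvain_communities(
            g, seed=config.seed, resolution=config.resolution
        )
        edge_path = out / "cooccurrence_edges.tsv"
        networks.write_edge_list(g, edge_path)
        outputs["cooccurrence_edges"] = edge_path
        graphml_path = out / "cooccurrence.graphml"
        networks.write_graphml(g, graphml_path)
        outputs["cooccurrence_graphml"] = graphml_path
        part_path = out / "communities.json"
        part_path.write_text(
            json.dumps(
                {
                    "membership": {str(k): int(v) for k, v in partition.membership.items()},
                    "Q": partition.Q,
                    "resolution": partition.resolution,
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["communities"] = part_path

    @stage("comention")
    def _comention():
        m = networks.comention_matrix(state["docs"])
        pairs, triad = networks.top_axes(m)
        path = out / "comention.csv"
        m.scores.to_csv(path)
        outputs["comention"] = path
        axes_path = out / "comention_axes.json"
        axes_path.write_text(
            json.dumps(
                {
                    "normalisation": m.normalisation,
                    "top_pairs": [
                        {"pair": list(p), "score": s} for p, s in pairs
                    ],
                    "best_triad": {
                        "terms": list(triad.terms),
                        "min_pairwise": triad.min_pairwise,
                    },
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["comention_axes"] = axes_path

    @stage("trends")
    def _trends():
        summary = trends.trend_summary(
            state["assignment"], state["docs"],
            horizon_start=config.horizon_start, horizon_end=config.horizon_end,
        )
        metrics = state["metrics"]
        merged = summary.merge(
            metrics[["topic_id", "novelty_index"]], on="topic_id", how="inner"
        )
        if len(merged) >= 3:
            rho, p = trends.novelty_slope_correlation(
                merged["novelty_index"], merged["forecast_slope"]
            )
            manifest["novelty_slope_spearman"] = {"rho": rho, "p": p}
        path = out / "trend_summary.csv"
        summary.to_csv(path, index=False)
        outputs["trend_summary"] = path

    @stage("cohort")
    def _cohort():
        table = cohort_mod.simulate_cohort(
            cohort_mod.CohortConfig(
                n_subjects=config.cohort_n, seed=config.cohort_seed
            )
        )
        path = out / "cohort.csv"
        table.to_csv(path, index=False)
        outputs["cohort"] = path
        report = cohort_mod.risk_report(
            table, repeats=config.permutation_repeats, seed=config.cohort_seed
        )
        tn, fp, fn, tp = report.confusion
        risk_path = out / "risk_report.json"
        risk_path.write_text(
            json.dumps(
                {
                    "confusion": {"TN": tn, "FP": fp, "FN": fn, "TP": tp},
                    "auc": report.auc,
                    "importances": report.importances.to_dict(orient="records"),
                },
                indent=2,
                sort_keys=True,
            )
        )
        outputs["risk_report"] = risk_path

    config_blob = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(config_blob.encode()).hexdigest()
    manifest["outputs"] = {name: _sha256(p) for name, p in sorted(outputs.items())}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
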