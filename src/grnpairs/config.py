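"""Experiment orchestration: YAML config, stage pipeline, run manifest.

A single YAML file drives the whole pipeline; stages run in the order
simulate -> prepare -> train -> predict -> evaluate -> hubs, each stage
optional (e.g. omit ``simulate`` and point ``corpus`` at an existing image
directory).  Every artifact path and every seed lands in a run manifest,
and a rerun with the same config and seeds reproduces all deterministic
artifacts byte-for-byte (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dataset import (GenePairLabel, image_sets_from_corpus, load_corpus,
                      read_edge_tsv, sample_negatives, split_by_gene,
                      enumerate_instances, write_instance_index)
from .evaluation import evaluate, hit_ratio
from .inference import predict_links, write_predictions
from .model import ModelConfig, TrainConfig, PairClassifier
from .netanalysis import top_k_edges, extract_hubs, export_network, export_gene_list
from .simulate import SyntheticSpec, generate_corpus, write_corpus

__all__ = ["RunManifest", "run_experiment", "load_config", "validate_config"]

_STAGES = ("simulate", "prepare", "train", "predict", "evaluate", "hubs")

_SPEC_KEYS = {
    "n_tfs", "n_targets", "n_regions", "img_width", "img_height",
    "images_per_gene_per_orientation", "interaction_density", "noise_sd",
    "global_scale_range", "active_regions_per_gene", "seed",
}


@dataclass
class RunManifest:
    config_snapshot: dict
    config_hash: str
    seeds: dict[str, int]
    versions: dict[str, str]
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check before any compute; raises listing every offending key."""
    problems = []
    known = set(_STAGES) | {"corpus", "networks", "model", "seed", "out_dir"}
    for key in cfg:
        if key not in known:
            problems.append(f"unknown key {key!r}")
    if "simulate" not in cfg:
        corpus = cfg.get("corpus")
        if not corpus:
            problems.append("need either a 'simulate' section or a 'corpus' section")
        else:
            for k in ("image_dir", "manifest"):
                if k not in corpus:
                    problems.append(f"corpus.{k} missing")
                elif not Path(corpus[k]).exists():
                    problems.append(f"corpus.{k}: path {corpus[k]!r} does not exist")
            nets = cfg.get("networks", {})
            if "positives" not in nets:
                problems.append("networks.positives missing (required without simulate)")
    else:
        bad = set(cfg["simulate"]) - _SPEC_KEYS
        problems += [f"simulate.{k} is not a generator parameter" for k in sorted(bad)]
    if "out_dir" not in cfg:
        problems.append("out_dir missing")
    if problems:
        raise ValueError("config schema violation: " + "; ".join(problems))


def _seed_for(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_experiment(config_path, out_dir=None, verbose: bool = False) -> RunManifest:
    """Execute the configured pipeline end-to-end; returns the run manifest."""
    cfg = load_config(config_path)
    validate_config(cfg)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(cfg.get("seed", 0))
    seeds = {s: _seed_for(master_seed, s) for s in
             ("simulate", "negatives", "split", "init", "train")}
    snapshot = json.loads(json.dumps(cfg, default=str))
    manifest = RunManifest(
        config_snapshot=snapshot,
        config_hash=hashlib.sha256(
            json.dumps(snapshot, sort_keys=True).encode()).hexdigest()[:16],
        seeds=seeds,
        versions={"grnpairs": __version__, "numpy": np.__version__,
                  "python": platform.python_version()},
    )

    def stamp(stage):
        manifest.timestamps[stage] = datetime.now(timezone.utc).isoformat()

    # ---- simulate / corpus -------------------------------------------------
    medium_edges: set = set()
    if "simulate" in cfg:
        stamp("simulate")
        params = dict(cfg["simulate"])
        params.setdefault("seed", seeds["simulate"])
        for k in ("images_per_gene_per_orientation", "global_scale_range"):
            if k in params:
                params[k] = tuple(params[k])
        spec = SyntheticSpec(**params)
        corpus = generate_corpus(spec)
        corpus_dir = out / "corpus"
        write_corpus(corpus, corpus_dir)
        manifest.outputs["corpus"] = str(corpus_dir)
        image_sets = image_sets_from_corpus(corpus)
        positives = {(t, g) for t, g in corpus.truth_edges}
        medium_edges = set(corpus.medium_edges)
        tf_universe = sorted({t for t, _ in positives} | set(spec.tf_ids))
        gene_universe = sorted(spec.target_ids)
        input_h, input_w = spec.img_height, spec.img_width
    else:
        corpus_cfg = cfg["corpus"]
        image_sets = load_corpus(corpus_cfg["image_dir"], corpus_cfg["manifest"])
        manifest.input_checksums["manifest"] = _sha256(corpus_cfg["manifest"])
        positives = read_edge_tsv(cfg["networks"]["positives"])
        manifest.input_checksums["positives"] = _sha256(cfg["networks"]["positives"])
        if "exclusion" in cfg.get("networks", {}):
            medium_edges = read_edge_tsv(cfg["networks"]["exclusion"])
            manifest.input_checksums["exclusion"] = _sha256(cfg["networks"]["exclusion"])
        tf_universe = sorted({t for t, _ in positives})
        gene_universe = sorted(image_sets)
        some = next(iter(image_sets.values()))
        arr = next(iter(some.by_orientation.values()))[0]
        input_h, input_w = arr.shape

    # ---- prepare -----------------------------------------------------------
    prep = cfg.get("prepare", {})
    stamp("prepare")
    pos_pairs = [GenePairLabel(t, g, 1) for t, g in sorted(positives)]
    neg_pairs = sample_negatives(tf_universe, gene_universe, positives,
                                 medium_edges,
                                 float(prep.get("negative_ratio", 1.0)),
                                 seeds["negatives"])
    pairs = pos_pairs + neg_pairs
    plan = split_by_gene(pairs,
                         float(prep.get("train_frac", 0.8)),
                         float(prep.get("val_frac_of_train", 0.1)),
                         seeds["split"],
                         tolerance=float(prep.get("tolerance", 0.05)))
    report = plan.report()
    (out / "split_report.json").write_text(json.dumps(report, indent=1,
                                                      sort_keys=True))
    manifest.outputs["split_report"] = str(out / "split_report.json")

    def instances_for(pair_list):
        ins = []
        for p in pair_list:
            ins += enumerate_instances(p, image_sets[p.tf_id],
                                       image_sets[p.target_id])
        return ins

    tr_ins = instances_for(plan.train_pairs)
    va_ins = instances_for(plan.val_pairs)
    for name, ins in (("train", tr_ins), ("val", va_ins)):
        write_instance_index(ins, out / f"instances_{name}.tsv")
        manifest.outputs[f"instances_{name}"] = str(out / f"instances_{name}.tsv")

    # ---- train -------------------------------------------------------------
    model_cfg = ModelConfig(**cfg.get("model", {"backbone": "small_cnn",
                                                "in_channels": 1}))
    clf = PairClassifier(model_cfg, input_hw=(2 * input_h, input_w),
                         seed=seeds["init"])
    results = None
    if "train" in cfg:
        stamp("train")
        tcfg_kwargs = dict(cfg["train"])
        if "lr_decay_epochs" in tcfg_kwargs:
            tcfg_kwargs["lr_decay_epochs"] = tuple(tcfg_kwargs["lr_decay_epochs"])
        tcfg_kwargs.setdefault("seed", seeds["train"])
        tcfg = TrainConfig(**tcfg_kwargs)
        results = clf.fit(tr_ins, va_ins, image_sets, tcfg, verbose=verbose)
        results.save_history(out / "history.csv")
        clf.network.save(out / "model.npz")
        manifest.outputs["history"] = str(out / "history.csv")
        manifest.outputs["model"] = str(out / "model.npz")

    # ---- predict / evaluate / hubs ----------------------------------------
    predictions = None
    if "predict" in cfg or "evaluate" in cfg or "hubs" in cfg:
        stamp("predict")
        threshold = float(cfg.get("predict", {}).get("threshold", 0.5))
        predictions = predict_links(clf.network, plan.test_pairs, image_sets,
                                    threshold)
        write_predictions(predictions, out / "predictions.tsv")
        manifest.outputs["predictions"] = str(out / "predictions.tsv")

    if "evaluate" in cfg and predictions is not None:
        stamp("evaluate")
        labels = {p.key: p.label for p in pairs}
        rep = evaluate(predictions, labels,
                       float(cfg["evaluate"].get("top_fraction", 0.10)))
        (out / "eval_report.json").write_text(
            json.dumps(rep.to_dict(), indent=1, sort_keys=True))
        rep.histogram_frame().to_csv(out / "histogram.csv", index=False)
        manifest.outputs["eval_report"] = str(out / "eval_report.json")
        manifest.outputs["histogram"] = str(out / "histogram.csv")

    if "hubs" in cfg and predictions is not None:
        stamp("hubs")
        hcfg = cfg["hubs"]
        k = int(hcfg.get("k", 1000))
        net = top_k_edges(predictions, k)
        if net.edges:
            hubs = extract_hubs(net, int(hcfg.get("min_degree", 2)))
            (out / "hubs.json").write_text(json.dumps(
                {"hubs": hubs.hubs, "min_degree": hubs.min_degree,
                 "degree_distribution": hubs.degree_distribution}, indent=1))
            export_network(net, "TSV", out / "network_topk.tsv")
            export_network(net, "SIF", out / "network_topk.sif")
            export_gene_list(net, out / "network_genes.txt")
            manifest.outputs["hubs"] = str(out / "hubs.json")
            manifest.outputs["network"] = str(out / "network_topk.tsv")

    stamp("done")
    manifest.save(out / "manifest.json")
    return manifest
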