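"""End-to-end orchestration: simulate -> extract -> select -> bench -> cluster.

One global seed deterministically derives a per-stage seed, so re-running a
config reproduces every intermediate file byte-for-byte (timestamps live only
in the provenance record). Every stage writes its interface files into
``<output_dir>/<stage>/`` and registers them in ``manifest.json``.
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
import yaml

from . import __version__
from .bench import ClassifierSpec, run_benchmark, summary_table
from .cluster import jaccard_matrix, pcoa, upgma, write_newick
from .extract import (
    DEFAULT_MIN_REPEATS,
    FeatureMatrix,
    GroupLabels,
    build_feature_matrix,
    calls_to_tsv,
    classify_calls,
    detect_ssrs,
)
from .io import read_fasta, read_gff3_loci
from .select import gc_ssr_select, hybrid_select, lasso_select, select_k_best
from .simulate import ConfigError, SimulationConfig, simulate_feature_table, simulate_genomes

log = logging.getLogger("ssrtrace")

_STAGES = ("simulate", "extract", "select", "bench", "cluster")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "ssrtrace_out",
    "stages": {s: True for s in _STAGES},
    "paths": {"fasta_dir": None, "gff3": None, "labels": None, "matrix": None},
    "simulate": {
        "genome_mode": True,
        "group_names": ["MP", "FG", "PG", "CO"],
        "samples_per_group": [12, 14, 8, 4],
        "n_conserved_per_group": [6, 6, 0, 6],
        "n_noise_features": 200,
        "noise_presence_prob": 0.03,
        "heterogeneous_groups": ["PG"],
        "locus_length": 150,
    },
    "extraction": {
        "thresholds": {str(u): t for u, t in DEFAULT_MIN_REPEATS.items()},
        "coding_only": True,
        "drop_n": True,
        "interrupt_max_bp": 4,
        "compound_gap_bp": 10,
        "reference_sample": None,
    },
    "selection": {
        "cap": "auto",  # "auto" = natural size of the group-conserved panel
        "k1": 5000,
        "hybrid_iterations": 150,
        "hybrid_folds": 4,
        "hybrid_search_space": None,  # None = documented forest default
        "lasso_iterations": 25,
    },
    "bench": {
        "iterations": 100,
        "folds": 3,
        "replicates": 30,
        "k_max": 30,
        "classifiers": ["linear_svc", "random_forest", "gradient_boosting"],
        "search_spaces": None,  # per-kind override of the documented defaults
    },
    "cluster": {},
    "plots": False,
}


@dataclass
class PipelineConfig:
    data: dict[str, Any] = field(default_factory=lambda: _merge(_DEFAULTS, {}))

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31 derived from the global seed."""
        digest = hashlib.sha256(f"{self.data['seed']}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = {}
    unknown = set(override) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(path + k for k in unknown)}")
    for key, dv in defaults.items():
        ov = override.get(key, None)
        if isinstance(dv, dict) and key not in ("thresholds",):
            out[key] = _merge(dv, ov or {}, path=f"{path}{key}.")
        else:
            out[key] = dv if ov is None else ov
    return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse, default and validate a pipeline config; unknown keys are rejected."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    data = _merge(_DEFAULTS, raw)
    if not isinstance(data["seed"], int):
        raise ConfigError("seed: must be an integer")
    for stage, on in data["stages"].items():
        if not isinstance(on, bool):
            raise ConfigError(f"stages.{stage}: must be boolean")
    if data["stages"]["extract"] and not data["stages"]["simulate"]:
        for key in ("fasta_dir", "gff3", "labels"):
            p = data["paths"][key]
            if p is None or not Path(p).exists():
                raise ConfigError(f"paths.{key}: required (and must exist) for extract stage")
    return PipelineConfig(data)


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute enabled stages in order; returns a results bundle.

    The clustering stage runs on the best (selection, classifier)
    combination's optimal marker panel — highest mean weighted F1 at its best
    k, ties resolved toward fewer markers then lexicographic names.
    """
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    bundle: dict[str, Any] = {}
    t0 = time.time()
    events: list[dict] = []

    def emit(stage: str, name: str) -> Path:
        stage_dir = outdir / stage
        stage_dir.mkdir(exist_ok=True)
        p = stage_dir / name
        manifest.append(str(p.relative_to(outdir)))
        return p

    def record(stage: str, **info) -> None:
        events.append({"stage": stage, **info})

    matrix: FeatureMatrix | None = None
    labels: GroupLabels | None = None

    if config["stages"]["simulate"]:
        log.info("stage simulate: generating synthetic benchmark")
        sim_cfg_raw = dict(config["simulate"])
        sim = SimulationConfig(
            group_names=tuple(sim_cfg_raw["group_names"]),
            samples_per_group=tuple(sim_cfg_raw["samples_per_group"]),
            n_conserved_per_group=tuple(sim_cfg_raw["n_conserved_per_group"]),
            n_noise_features=sim_cfg_raw["n_noise_features"],
            noise_presence_prob=sim_cfg_raw["noise_presence_prob"],
            heterogeneous_groups=frozenset(sim_cfg_raw["heterogeneous_groups"]),
            genome_mode=sim_cfg_raw["genome_mode"],
            locus_length=sim_cfg_raw["locus_length"],
            seed=config.stage_seed("simulate"),
        )
        if sim.genome_mode:
            genomes = simulate_genomes(sim)
            paths = genomes.write(outdir / "simulate")
            for p in [*paths.values(), *(outdir / "simulate" / "samples").glob("*.fasta")]:
                manifest.append(str(Path(p).relative_to(outdir)))
            config.data["paths"]["fasta_dir"] = str(outdir / "simulate" / "samples")
            config.data["paths"]["gff3"] = str(paths["gff3"])
            config.data["paths"]["labels"] = str(paths["labels"])
            labels = genomes.labels
            bundle["truth"] = genomes.truth
            record("simulate", mode="genome", n_samples=len(genomes.samples),
                   genome_bp=len(genomes.reference))
        else:
            matrix, labels, truth = simulate_feature_table(sim)
            matrix.to_csv(emit("simulate", "matrix.csv"), labels)
            truth.to_json(emit("simulate", "truth.json"))
            bundle["truth"] = truth
            record("simulate", mode="table", n_samples=matrix.n_samples,
                   n_features=matrix.n_features)

    if config["stages"]["extract"]:
        log.info("stage extract: detecting SSRs and building the feature matrix")
        ext = config["extraction"]
        thresholds = {int(u): int(t) for u, t in ext["thresholds"].items()}
        fasta_dir = Path(config["paths"]["fasta_dir"])
        labels = GroupLabels.from_csv(config["paths"]["labels"])
        annotations = read_gff3_loci(config["paths"]["gff3"])
        calls_by_sample = {}
        for fa in sorted(fasta_dir.glob("*.fasta")):
            sample_id = fa.stem
            calls = []
            for seq_id, seq in read_fasta(fa).items():
                raw = detect_ssrs(seq, thresholds, sample_id=sample_id, seq_id=seq_id)
                calls.extend(
                    classify_calls(raw, ext["interrupt_max_bp"], ext["compound_gap_bp"])
                )
            calls_by_sample[sample_id] = calls
        matrix = build_feature_matrix(
            calls_by_sample,
            annotations,
            labels,
            coding_only=ext["coding_only"],
            drop_n=ext["drop_n"],
            exclude_reference_sample=ext["reference_sample"],
        )
        all_calls = [c for calls in calls_by_sample.values() for c in calls]
        calls_to_tsv(all_calls, emit("extract", "calls.tsv"))
        matrix.to_csv(emit("extract", "matrix.csv"), labels)
        record("extract", n_calls=len(all_calls), n_samples=matrix.n_samples,
               n_features=matrix.n_features)

    if matrix is None and config["paths"].get("matrix"):
        matrix, labels = FeatureMatrix.from_csv(config["paths"]["matrix"])
    bundle["matrix"], bundle["labels"] = matrix, labels

    selections = None
    if config["stages"]["select"]:
        if matrix is None:
            raise ConfigError("select stage needs a feature matrix (enable simulate/extract or set paths.matrix)")
        log.info("stage select: running the four selection strategies")
        sel_cfg = config["selection"]
        seed = config.stage_seed("select")
        gc = gc_ssr_select(matrix, labels)
        cap = len(gc.features) if sel_cfg["cap"] == "auto" else int(sel_cfg["cap"])
        cap = max(cap, 1)
        skb = select_k_best(matrix, labels, k=cap)
        smallest = min(len(labels.samples_of(g)) for g in labels.groups)
        folds = min(sel_cfg["hybrid_folds"], smallest)
        if folds < sel_cfg["hybrid_folds"]:
            log.info("reducing hybrid CV folds to %d (smallest class)", folds)
        hyb = hybrid_select(
            matrix, labels,
            k1=min(sel_cfg["k1"], matrix.n_features), k2=min(cap, matrix.n_features),
            search_iterations=sel_cfg["hybrid_iterations"],
            cv_folds=folds, seed=seed,
            search_space=sel_cfg["hybrid_search_space"],
        )
        las = lasso_select(
            matrix, labels, cap=cap,
            search_iterations=sel_cfg["lasso_iterations"], seed=seed,
        )
        selections = [gc, skb, hyb, las]
        for sel in selections:
            _write_json(emit("select", f"{sel.method}.json"), sel.to_json_dict())
            sel.to_feature_csv(emit("select", f"{sel.method}_features.csv"))
        bundle["selections"] = selections
        record("select", cap=cap, panel_sizes={s.method: len(s.features) for s in selections})

    results = None
    if config["stages"]["bench"]:
        if selections is None:
            raise ConfigError("bench stage requires the select stage")
        log.info("stage bench: evaluating selection x classifier combinations")
        bcfg = config["bench"]
        seed = config.stage_seed("bench")
        classifiers = [ClassifierSpec(kind=k, seed=seed) for k in bcfg["classifiers"]]
        smallest = min(len(labels.samples_of(g)) for g in labels.groups)
        tune_folds = min(bcfg["folds"], smallest)
        if tune_folds < bcfg["folds"]:
            log.info("reducing tuning CV folds to %d (smallest class)", tune_folds)
        results = run_benchmark(
            matrix, labels, [s for s in selections if s.features], classifiers,
            tune_iterations=bcfg["iterations"], tune_folds=tune_folds,
            replicates=bcfg["replicates"], k_max=bcfg["k_max"], base_seed=seed,
            search_spaces=bcfg["search_spaces"],
        )
        table = summary_table(results)
        table.to_csv(emit("bench", "summary.csv"), index=False)
        for (method, kind), res in results.items():
            if res is None:
                continue
            _write_json(
                emit("bench", f"{method}__{kind}.json"),
                {
                    "selection": method,
                    "classifier": kind,
                    "best_k": res.best_k,
                    "best_features": [str(k) for k in res.best_features],
                    "k_values": res.curve.k_values,
                    "means": {m: list(map(float, v)) for m, v in res.curve.means.items()},
                    "sds": {m: list(map(float, v)) for m, v in res.curve.sds.items()},
                    "mean_confusion": res.mean_confusion_matrix.tolist(),
                    "classes": res.curve.classes,
                    "hyperparameters": {k: _py(v) for k, v in res.spec.hyperparameters.items()},
                },
            )
        bundle["bench"] = results
        bundle["summary"] = table
        record("bench", n_combinations=len(results),
               failed=[list(k) for k, v in results.items() if v is None])

    if config["stages"]["cluster"]:
        if results is None:
            raise ConfigError("cluster stage requires the bench stage")
        log.info("stage cluster: Jaccard PCoA + UPGMA on the best combination")
        best_key, best_res = _best_combination(results)
        panel = matrix.restrict(best_res.best_features)
        d = jaccard_matrix(panel)
        d.to_csv(emit("cluster", "jaccard.csv"))
        ord_res = pcoa(d)
        import pandas as pd

        pd.DataFrame(
            ord_res.coordinates,
            index=pd.Index(ord_res.ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
        ).to_csv(emit("cluster", "pcoa_coordinates.csv"))
        sidecar = {
            "proportion_explained": ord_res.proportion_explained.tolist(),
            "eigenvalues": ord_res.eigenvalues.tolist(),
            "negative_eigenvalues": ord_res.negative_eigenvalues.tolist(),
            "ids": ord_res.ids,
            "combination": list(best_key),
        }
        _write_json(emit("cluster", "pcoa.json"), sidecar)
        tree = upgma(d)
        newick = write_newick(tree)
        emit("cluster", "upgma.nwk").write_text(
            "; edge length = (parent height - child height) / 2\n" + newick + "\n"
        )
        record("cluster", combination=list(best_key), n_markers=len(best_res.best_features))
        if config["plots"]:
            from . import plots

            plots.plot_pcoa(ord_res, labels.mapping, emit("cluster", "pcoa.png"))
            plots.plot_dendrogram(tree, emit("cluster", "upgma.png"))
            plots.plot_learning_curve(best_res.curve, emit("bench", "best_curve.png"))
            plots.plot_confusion(
                best_res.mean_confusion_matrix, best_res.curve.classes,
                emit("bench", "best_confusion.png"),
            )
        bundle["cluster"] = {"distance": d, "pcoa": ord_res, "tree": tree, "combination": best_key}

    (outdir / "events.jsonl").write_text(
        "".join(json.dumps(e, sort_keys=True, default=_py) + "\n" for e in events)
    )
    manifest.append("events.jsonl")
    _write_json(outdir / "manifest.json", {"files": sorted(manifest)})
    _write_json(
        outdir / "provenance.json",
        {
            "config_sha256": hashlib.sha256(config.to_yaml().encode()).hexdigest(),
            "seed": config["seed"],
            "version": __version__,
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    return bundle


def _py(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _best_combination(results):
    """Highest mean weighted F1 at best k; ties -> fewer markers, then name."""
    scored = []
    for key, res in results.items():
        if res is None:
            continue
        ki = res.curve.k_values.index(res.best_k)
        scored.append((-res.curve.means["weighted_f1"][ki], res.best_k, key, res))
    if not scored:
        raise RuntimeError("no successful benchmark combination")
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    _, _, key, res = scored[0]
    return key, res
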