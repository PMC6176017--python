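"""Orchestration: sample splitting, the surrogate-set evaluation protocol,
and the end-to-end pipeline with file artifacts and incremental re-runs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path
from typing import Sequence, TypeVar

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .backends import BACKENDS
from .consensus import ConsensusConfig, ConsensusModel, predict_consensus, train_consensus
from .enrichment import EnrichmentConfig
from .filtering import median_variance_filter
from .matrix import CategorizationConfig, CategorizedMatrix, ExpressionMatrix, ProbeSet, categorize
from .ontology import Ontology, read_gmt, write_gmt
from .psi import PSISummary, psi_from_predictions, y_scramble
from .reduction import ReductionConfig, reduce_features
from .selection import SelectionConfig, combine_sets, greedy_select, overlap_report
from .simulate import SimConfig, simulate_compendium

logger = logging.getLogger("httimpute")

MatrixT = TypeVar("MatrixT", ExpressionMatrix, CategorizedMatrix)


def split_samples(
    matrix: MatrixT, fraction: float, seed: int, stratify: bool = True
) -> tuple[MatrixT, MatrixT]:
    """Random disjoint train/holdout split of the samples.

    When sample metadata with a ``compound`` column is present and
    ``stratify`` is true, whole compounds are assigned to one side (a group
    split), so no compound appears in both train and holdout; the cut point
    is chosen to bring the train size as close as possible to the requested
    fraction.  Without metadata the split is plain random, with the train
    size rounded to the nearest integer.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    ids = matrix.sample_ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    meta = matrix.sample_meta
    if stratify and meta is not None and "compound" in meta.columns:
        compounds = list(pd.unique(meta["compound"]))
        order = rng.permutation(len(compounds))
        counts = meta["compound"].value_counts()
        cum = 0
        train_compounds: set[str] = set()
        for idx in order:
            comp = compounds[idx]
            new_cum = cum + int(counts[comp])
            if abs(new_cum - n_train) <= abs(cum - n_train):
                train_compounds.add(comp)
                cum = new_cum
            else:
                break
        if cum == 0 or cum == n:  # degenerate: fall back to plain random
            train_compounds = set()
        if train_compounds:
            train_ids = [s for s in ids if meta.loc[s, "compound"] in train_compounds]
            holdout_ids = [s for s in ids if s not in set(train_ids)]
            return matrix.subset_samples(train_ids), matrix.subset_samples(holdout_ids)
    perm = rng.permutation(n)
    train_pos = sorted(perm[:n_train])
    holdout_pos = sorted(perm[n_train:])
    train_ids = [ids[i] for i in train_pos]
    holdout_ids = [ids[i] for i in holdout_pos]
    return matrix.subset_samples(train_ids), matrix.subset_samples(holdout_ids)


def assemble_full_profile(
    surrogate_classes: CategorizedMatrix, predicted_targets: CategorizedMatrix
) -> CategorizedMatrix:
    """Stack measured surrogate classes over predicted target classes into a
    whole-genome profile (surrogate probes are measured by the platform)."""
    frame = pd.concat([surrogate_classes.classes, predicted_targets.classes])
    return CategorizedMatrix(frame, surrogate_classes.sample_meta)


def evaluate_surrogate_set(
    probe_list: ProbeSet,
    train: CategorizedMatrix,
    validation: CategorizedMatrix,
    ontology: Ontology,
    consensus_config: ConsensusConfig | None = None,
    enrichment_config: EnrichmentConfig | None = None,
) -> PSISummary:
    """Table-2-style protocol: train a consensus model with ``probe_list`` as
    predictors, predict the validation set, and score per-sample PSI of the
    predicted whole-genome profile against the actual one.

    Probes in the list but absent from the matrix are reported and dropped;
    the identical protocol applies to any supplied list, enabling
    side-by-side comparison of competing surrogate sets.
    """
    effective = sorted(probe_list.probes & set(train.probe_ids))
    dropped = sorted(probe_list.probes - set(train.probe_ids))
    if dropped:
        warnings.warn(
            f"{len(dropped)} probe(s) from {probe_list.name!r} absent from the "
            f"matrix were dropped (e.g. {dropped[:3]})"
        )
    if not effective:
        raise ValueError(f"no probe of {probe_list.name!r} is present in the matrix")
    surrogates = ProbeSet(probe_list.name, frozenset(effective))
    model = train_consensus(train, surrogates, consensus_config)
    val_surro = validation.subset_probes(model.surrogates)
    if model.targets:
        pred = predict_consensus(model, val_surro)
        predicted = assemble_full_profile(val_surro, pred.classes)
        actual = validation.subset_probes(model.surrogates + model.targets)
    else:
        predicted = val_surro
        actual = val_surro
    return psi_from_predictions(actual, predicted, ontology, enrichment_config)


@dataclasses.dataclass
class PipelineConfig:
    """Nested configuration of the end-to-end run."""

    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    categorization: CategorizationConfig = dataclasses.field(
        default_factory=CategorizationConfig
    )
    reduction: ReductionConfig = dataclasses.field(default_factory=ReductionConfig)
    reduction_k: int | None = None
    selection_step: int = 5
    selection_budget: int = 40
    selection_folds: int = 10
    selection_target_subsample: int | None = 200
    consensus_mode: str = "multioutput"
    enrichment: EnrichmentConfig = dataclasses.field(default_factory=EnrichmentConfig)
    train_fraction: float = 0.75
    ga_eval_fraction: float = 0.30
    n_scramble: int = 5
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if not 0 < self.ga_eval_fraction < 1:
            raise ValueError("ga_eval_fraction must lie in (0, 1)")

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            if "class_thresholds" in sim:
                sim["class_thresholds"] = CategorizationConfig(**sim["class_thresholds"])
            for key in ("dose_multipliers", "time_multipliers"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        if "categorization" in kwargs:
            kwargs["categorization"] = CategorizationConfig(**kwargs["categorization"])
        if "reduction" in kwargs:
            kwargs["reduction"] = ReductionConfig(**kwargs["reduction"])
        if "enrichment" in kwargs:
            kwargs["enrichment"] = EnrichmentConfig(**kwargs["enrichment"])
        return cls(**kwargs)


def _stage(manifest: dict, name: str, outputs: list[Path], func) -> None:
    if all(p.exists() for p in outputs) and name in manifest.get("stages", {}):
        logger.info("stage %s: outputs present, skipped", name)
        return
    t0 = time.perf_counter()
    try:
        func()
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    elapsed = time.perf_counter() - t0
    logger.info("stage %s: done in %.2fs", name, elapsed)
    manifest.setdefault("stages", {})[name] = {
        "outputs": [str(p) for p in outputs],
        "seconds": round(elapsed, 3),
    }


def run_all(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline: simulate -> categorize -> filter -> reduce
    -> greedy selection per backend -> combine -> train -> predict -> PSI ->
    Y-scramble.  Every artifact is written under ``outdir`` together with a
    manifest recording the config hash and per-stage wall time; stages whose
    outputs already exist for the same config hash are skipped.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.config_hash()
    manifest: dict = {"config_hash": cfg_hash, "config": config.to_dict(), "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            manifest = old
        else:
            logger.info("config hash changed; recomputing all stages")

    paths = {
        "matrix": out / "matrix.tsv",
        "meta": out / "sample_meta.tsv",
        "gmt": out / "ontology.gmt",
        "truth": out / "truth.json",
        "filtered": out / "filtered.tsv",
        "categorized": out / "categorized.tsv",
        "train_samples": out / "train_samples.txt",
        "holdout_samples": out / "holdout_samples.txt",
        "representatives": out / "representatives.txt",
        "distortion": out / "distortion.tsv",
        "combined": out / "combined.txt",
        "overlap": out / "overlap.tsv",
        "model": out / "model",
        "predicted": out / "predicted.tsv",
        "psi": out / "psi.tsv",
        "psi_summary": out / "psi_summary.json",
        "scramble": out / "scramble.json",
    }
    sel_paths = {b: out / f"selected_{b}.txt" for b in BACKENDS}
    trace_paths = {b: out / f"trace_{b}.tsv" for b in BACKENDS}

    def do_simulate() -> None:
        matrix, ontology, truth = simulate_compendium(config.sim)
        hio.write_expression_matrix(matrix, paths["matrix"])
        hio.write_sample_meta(matrix.sample_meta, paths["meta"])
        write_gmt(ontology, paths["gmt"])
        paths["truth"].write_text(
            json.dumps({"membership": truth.membership}, indent=1)
        )

    _stage(manifest, "simulate",
           [paths["matrix"], paths["meta"], paths["gmt"], paths["truth"]], do_simulate)

    def load_matrix() -> ExpressionMatrix:
        meta = hio.read_sample_meta(paths["meta"])
        return hio.read_expression_matrix(paths["matrix"], sample_meta=meta)

    def do_filter() -> None:
        hio.write_expression_matrix(median_variance_filter(load_matrix()), paths["filtered"])

    _stage(manifest, "filter", [paths["filtered"]], do_filter)

    def do_categorize() -> None:
        meta = hio.read_sample_meta(paths["meta"])
        filtered = hio.read_expression_matrix(paths["filtered"], sample_meta=meta)
        hio.write_categorized(categorize(filtered, config.categorization), paths["categorized"])

    _stage(manifest, "categorize", [paths["categorized"]], do_categorize)

    def do_split() -> None:
        meta = hio.read_sample_meta(paths["meta"])
        cat = hio.read_categorized(paths["categorized"], sample_meta=meta)
        train, holdout = split_samples(
            cat, config.train_fraction, config.seed, stratify=config.stratify
        )
        paths["train_samples"].write_text("\n".join(train.sample_ids) + "\n")
        paths["holdout_samples"].write_text("\n".join(holdout.sample_ids) + "\n")

    _stage(manifest, "split", [paths["train_samples"], paths["holdout_samples"]], do_split)

    def _train_samples() -> list[str]:
        return paths["train_samples"].read_text().split()

    def do_reduce() -> None:
        meta = hio.read_sample_meta(paths["meta"])
        filtered = hio.read_expression_matrix(paths["filtered"], sample_meta=meta)
        filtered = filtered.subset_samples(_train_samples())
        result = reduce_features(filtered, config.reduction, k=config.reduction_k)
        hio.write_ordered_probe_list(result.representatives, paths["representatives"])
        pd.DataFrame(result.distortion_curve, columns=["k", "distortion"]).to_csv(
            paths["distortion"], sep="\t", index=False
        )

    _stage(manifest, "reduce", [paths["representatives"], paths["distortion"]], do_reduce)

    def make_select(backend: str):
        def do_select() -> None:
            meta = hio.read_sample_meta(paths["meta"])
            cat = hio.read_categorized(paths["categorized"], sample_meta=meta)
            train = cat.subset_samples(_train_samples())
            pool = ProbeSet("representatives",
                            frozenset(hio.read_ordered_probe_list(paths["representatives"])))
            sel_cfg = SelectionConfig(
                step_size=config.selection_step,
                budget=config.selection_budget,
                n_folds=config.selection_folds,
                backend=backend,
                target_subsample=config.selection_target_subsample,
                candidate_pool=pool,
                random_seed=config.seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = greedy_select(train, sel_cfg)
            hio.write_ordered_probe_list(sel.selected, sel_paths[backend])
            pd.DataFrame(sel.error_trace, columns=["iteration", "cv_error"]).to_csv(
                trace_paths[backend], sep="\t", index=False
            )

        return do_select

    for backend in BACKENDS:
        _stage(manifest, f"select_{backend}",
               [sel_paths[backend], trace_paths[backend]], make_select(backend))

    def do_combine() -> None:
        sets = [
            ProbeSet(b, frozenset(hio.read_ordered_probe_list(sel_paths[b])))
            for b in BACKENDS
        ]
        combined = combine_sets(*sets)
        hio.write_probe_list(combined.probes, paths["combined"])
        overlap_report(sets).to_csv(paths["overlap"], sep="\t", index=False)

    _stage(manifest, "combine", [paths["combined"], paths["overlap"]], do_combine)

    def do_train() -> None:
        meta = hio.read_sample_meta(paths["meta"])
        cat = hio.read_categorized(paths["categorized"], sample_meta=meta)
        train = cat.subset_samples(_train_samples())
        combined = hio.read_probe_list(paths["combined"], name="combined")
        model = train_consensus(
            train, combined, ConsensusConfig(mode=config.consensus_mode, seed=config.seed)
        )
        model.save(paths["model"])

    _stage(manifest, "train", [paths["model"] / "manifest.json"], do_train)

    def _holdout(cat_path: Path) -> CategorizedMatrix:
        meta = hio.read_sample_meta(paths["meta"])
        cat = hio.read_categorized(cat_path, sample_meta=meta)
        return cat.subset_samples(paths["holdout_samples"].read_text().split())

    def do_predict() -> None:
        model = ConsensusModel.load(paths["model"])
        holdout = _holdout(paths["categorized"])
        pred = predict_consensus(model, holdout.subset_probes(model.surrogates))
        full = assemble_full_profile(holdout.subset_probes(model.surrogates), pred.classes)
        hio.write_categorized(full, paths["predicted"])

    _stage(manifest, "predict", [paths["predicted"]], do_predict)

    def do_psi() -> None:
        model = ConsensusModel.load(paths["model"])
        holdout = _holdout(paths["categorized"])
        meta = hio.read_sample_meta(paths["meta"])
        predicted = hio.read_categorized(paths["predicted"], sample_meta=meta)
        actual = holdout.subset_probes(model.surrogates + model.targets)
        ontology = read_gmt(paths["gmt"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = psi_from_predictions(actual, predicted, ontology, config.enrichment)
        summary.table.to_csv(paths["psi"], sep="\t")
        paths["psi_summary"].write_text(
            json.dumps(
                {"mean_psi": summary.mean_psi,
                 "n_samples": int(summary.table["psi"].notna().sum())},
                indent=1,
            )
        )

    _stage(manifest, "psi", [paths["psi"], paths["psi_summary"]], do_psi)

    def do_scramble() -> None:
        model = ConsensusModel.load(paths["model"])
        holdout = _holdout(paths["categorized"])
        ontology = read_gmt(paths["gmt"])
        result = y_scramble(
            holdout.subset_probes(model.surrogates + model.targets),
            model, ontology, config.enrichment,
            n_permutations=config.n_scramble, seed=config.seed,
        )
        paths["scramble"].write_text(
            json.dumps(
                {"null_means": result.null_means, "null_mean": result.null_mean,
                 "quantiles": result.quantiles},
                indent=1,
            )
        )

    _stage(manifest, "scramble", [paths["scramble"]], do_scramble)

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out
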