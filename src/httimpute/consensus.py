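"""Consensus prediction of ternary expression classes.

One model per target probe per backend is trained on the surrogate probes'
classes (per-target mode); a shared multi-output mode is provided for speed.
Predictions are combined by majority vote over the three backends, with a
three-way disagreement defaulting to "unchanged".
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .backends import BACKENDS, make_classifier, make_multioutput_model
from .matrix import UNCHANGED, CategorizedMatrix, ProbeSet


@dataclasses.dataclass
class ConsensusConfig:
    backends: tuple[str, ...] = BACKENDS
    mode: str = "per_target"  # or "multioutput"
    seed: int = 0
    backend_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [b for b in self.backends if b not in BACKENDS]
        if unknown:
            raise ValueError(f"unknown backend(s): {unknown}")
        if len(self.backends) != 3 or len(set(self.backends)) != 3:
            raise ValueError("consensus requires exactly the 3 distinct backends")
        if self.mode not in ("per_target", "multioutput"):
            raise ValueError("mode must be 'per_target' or 'multioutput'")


@dataclasses.dataclass
class ConsensusModel:
    surrogates: list[str]
    targets: list[str]
    config: ConsensusConfig
    #: per backend: either {target: fitted estimator} (per-target mode) or a
    #: single multi-output model over the non-constant targets.
    predictors: dict
    #: targets constant in training, mapped to their constant class.
    constant_targets: dict[str, int]
    #: non-constant targets, in the column order of the multi-output models.
    variable_targets: list[str]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "surrogates": self.surrogates,
            "targets": self.targets,
            "variable_targets": self.variable_targets,
            "constant_targets": self.constant_targets,
            "backends": list(self.config.backends),
            "mode": self.config.mode,
            "seed": self.config.seed,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
        joblib.dump(self.predictors, directory / "predictors.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ConsensusModel":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        predictors = joblib.load(directory / "predictors.joblib")
        cfg = ConsensusConfig(
            backends=tuple(manifest["backends"]),
            mode=manifest["mode"],
            seed=manifest["seed"],
        )
        return cls(
            surrogates=manifest["surrogates"],
            targets=manifest["targets"],
            config=cfg,
            predictors=predictors,
            constant_targets={k: int(v) for k, v in manifest["constant_targets"].items()},
            variable_targets=manifest["variable_targets"],
        )


@dataclasses.dataclass
class ConsensusPrediction:
    classes: CategorizedMatrix
    #: per backend, the raw vote matrix (targets x samples).
    votes: dict[str, pd.DataFrame]


def train_consensus(
    train: CategorizedMatrix, surrogates: ProbeSet, config: ConsensusConfig | None = None
) -> ConsensusModel:
    """Fit one classifier per backend per (non-constant) target probe.

    Targets whose training classes are constant are stored as constant
    predictors rather than fitted models.
    """
    cfg = config or ConsensusConfig()
    if not surrogates.probes:
        raise ValueError("surrogate set is empty")
    missing = sorted(surrogates.probes - set(train.probe_ids))
    if missing:
        raise ValueError(f"surrogate probes absent from training data: {missing[:5]}")
    surro = sorted(surrogates.probes)
    targets = [p for p in train.probe_ids if p not in surrogates.probes]

    X = train.classes.loc[surro].to_numpy(dtype=float).T  # samples x surrogates
    Yt = train.classes.loc[targets].to_numpy(dtype=np.int8)  # targets x samples

    constant_targets: dict[str, int] = {}
    variable_targets: list[str] = []
    var_rows: list[int] = []
    for i, t in enumerate(targets):
        row = Yt[i]
        if (row == row[0]).all():
            constant_targets[t] = int(row[0])
        else:
            variable_targets.append(t)
            var_rows.append(i)
    Yv = Yt[var_rows].T  # samples x variable targets

    predictors: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter on tiny data
        for backend in cfg.backends:
            params = cfg.backend_params.get(backend, {})
            if cfg.mode == "multioutput":
                if variable_targets:
                    model = make_multioutput_model(backend, seed=cfg.seed, **params)
                    model.fit(X, Yv)
                else:
                    model = None
                predictors[backend] = model
            else:
                per_target = {}
                for j, t in enumerate(variable_targets):
                    clf = make_classifier(backend, seed=cfg.seed, **params)
                    clf.fit(X, Yv[:, j])
                    per_target[t] = clf
                predictors[backend] = per_target

    return ConsensusModel(
        surrogates=surro,
        targets=targets,
        config=cfg,
        predictors=predictors,
        constant_targets=constant_targets,
        variable_targets=variable_targets,
    )


def majority_vote(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Majority of three ternary votes; a three-way split maps to unchanged.

    Symmetric under any permutation of the three voters.
    """
    return np.where(
        (a == b) | (a == c), a, np.where(b == c, b, np.int8(UNCHANGED))
    ).astype(np.int8)


def predict_consensus(
    model: ConsensusModel, surrogate_classes: CategorizedMatrix
) -> ConsensusPrediction:
    """Predict target classes for new samples from surrogate classes."""
    missing = [p for p in model.surrogates if p not in surrogate_classes.probe_ids]
    if missing:
        raise ValueError(f"missing surrogate probe(s): {missing[:5]}")
    samples = surrogate_classes.sample_ids
    X = surrogate_classes.classes.loc[model.surrogates].to_numpy(dtype=float).T

    votes: dict[str, pd.DataFrame] = {}
    for backend in model.config.backends:
        pred = np.zeros((len(model.targets), len(samples)), dtype=np.int8)
        t_index = {t: i for i, t in enumerate(model.targets)}
        for t, cls in model.constant_targets.items():
            pred[t_index[t], :] = cls
        if model.variable_targets:
            if model.config.mode == "multioutput":
                out = model.predictors[backend].predict(X)  # samples x variable
                out = np.atleast_2d(out)
                for j, t in enumerate(model.variable_targets):
                    pred[t_index[t], :] = out[:, j]
            else:
                for t in model.variable_targets:
                    pred[t_index[t], :] = model.predictors[backend][t].predict(X)
        votes[backend] = pd.DataFrame(pred, index=model.targets, columns=samples)

    b1, b2, b3 = (votes[b].to_numpy() for b in model.config.backends)
    final = majority_vote(b1, b2, b3)
    classes = CategorizedMatrix(
        pd.DataFrame(final, index=model.targets, columns=samples),
        surrogate_classes.sample_meta,
    )
    return ConsensusPrediction(classes=classes, votes=votes)
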