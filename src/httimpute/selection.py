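"""Sequential forward greedy selection of surrogate probes, and set algebra
over competing selections.

Each round scores every remaining candidate by the k-fold cross-validated
misclassification error of predicting the ternary classes of target probes
from the current selection plus that candidate, then appends the
``step_size`` best-scoring candidates.  Three backend families are supported;
selections from different backends are combined by >=2-of-3 membership.
"""
from __future__ import annotations

import dataclasses
import itertools
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .backends import BACKENDS, make_search_scorer
from .matrix import CategorizedMatrix, ProbeSet


@dataclasses.dataclass
class SelectionConfig:
    """Parameters of the greedy search.

    ``target_subsample`` limits how many target probes enter the objective
    each round (re-drawn per round from the seeded RNG); ``None`` uses all
    non-selected probes.  ``step_size=1`` gives an exact one-at-a-time mode.
    """

    step_size: int = 5
    budget: int = 2000
    n_folds: int = 10
    backend: str = "svm"
    target_subsample: int | None = 200
    candidate_pool: ProbeSet | None = None
    random_seed: int = 0
    scorer_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")
        if self.budget % self.step_size != 0:
            raise ValueError("budget must be a multiple of step_size")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")


@dataclasses.dataclass
class SurrogateSelection:
    selected: list[str]
    error_trace: list[tuple[int, float]]
    backend: str
    seed: int


@dataclasses.dataclass
class CombinedSet:
    probes: ProbeSet
    membership_counts: dict[str, int]


def _cv_error(
    X: np.ndarray,
    Y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    backend: str,
    seed: int,
    scorer_params: dict,
) -> float:
    errs = []
    for train_idx, test_idx in folds:
        scorer = make_search_scorer(backend, seed=seed, **scorer_params)
        scorer.fit(X[train_idx], Y[train_idx])
        pred = scorer.predict(X[test_idx])
        errs.append(float(np.mean(pred != Y[test_idx])))
    return float(np.mean(errs))


def greedy_select(data: CategorizedMatrix, config: SelectionConfig) -> SurrogateSelection:
    """Run the sequential forward search.

    Returns the ordered selection and the post-append cross-validated error
    recorded at each round.  Ties on equal error break toward the
    lexicographically smaller probe ID.  Targets constant across all samples
    carry no signal and are excluded from the objective with a warning.
    """
    cfg = config
    all_probes = data.probe_ids
    probe_index = {p: i for i, p in enumerate(all_probes)}
    if cfg.candidate_pool is not None:
        pool = sorted(cfg.candidate_pool.probes)
        unknown = [p for p in pool if p not in probe_index]
        if unknown:
            raise ValueError(f"candidate pool probes not in matrix: {unknown[:5]}")
    else:
        pool = sorted(all_probes)
    if cfg.budget > len(pool):
        raise ValueError(
            f"budget ({cfg.budget}) exceeds candidate pool size ({len(pool)})"
        )
    if cfg.n_folds > data.n_samples:
        raise ValueError("n_folds exceeds number of samples")

    classes = data.classes.to_numpy(dtype=np.int8)  # probes x samples
    constant = (classes == classes[:, [0]]).all(axis=1)
    n_constant = int(constant.sum())
    if n_constant:
        warnings.warn(
            f"{n_constant} probe(s) are single-class across all samples and are "
            "excluded from the selection objective"
        )
    target_universe = np.array(
        [probe_index[p] for p in sorted(all_probes) if not constant[probe_index[p]]],
        dtype=int,
    )
    if target_universe.size == 0:
        raise ValueError("no non-degenerate target probes available")

    rng = np.random.default_rng(cfg.random_seed)
    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.random_seed % (2**31))
    folds = [(tr, te) for tr, te in kf.split(np.arange(data.n_samples))]
    fit_seed = cfg.random_seed % (2**31)

    selected: list[str] = []
    selected_idx: list[int] = []
    remaining = list(pool)
    error_trace: list[tuple[int, float]] = []
    n_rounds = math.ceil(cfg.budget / cfg.step_size)

    for rnd in range(1, n_rounds + 1):
        sel_set = set(selected_idx)
        eligible = np.array([i for i in target_universe if i not in sel_set], dtype=int)
        if cfg.target_subsample is not None and cfg.target_subsample < eligible.size:
            targets = rng.choice(eligible, size=cfg.target_subsample, replace=False)
        else:
            targets = eligible
        targets = np.sort(targets)
        Y_full = classes[targets].T  # samples x targets

        scores: list[tuple[float, str]] = []
        for cand in remaining:
            ci = probe_index[cand]
            feat = selected_idx + [ci]
            X = classes[feat].T.astype(float)
            # A candidate that is itself a sampled target would be predicted
            # trivially from its own column; drop it from the objective.
            if ci in targets:
                mask = targets != ci
                Y = Y_full[:, mask]
            else:
                Y = Y_full
            err = _cv_error(X, Y, folds, cfg.backend, fit_seed, cfg.scorer_params)
            scores.append((err, cand))
        scores.sort(key=lambda t: (t[0], t[1]))
        take = [c for _, c in scores[: cfg.step_size]]
        for c in take:
            selected.append(c)
            selected_idx.append(probe_index[c])
            remaining.remove(c)

        sel_set = set(selected_idx)
        mask = np.array([t not in sel_set for t in targets])
        X_sel = classes[selected_idx].T.astype(float)
        if mask.any():
            post_err = _cv_error(
                X_sel, Y_full[:, mask], folds, cfg.backend, fit_seed, cfg.scorer_params
            )
        else:
            post_err = float("nan")
        error_trace.append((rnd, post_err))
        if len(selected) >= cfg.budget:
            break

    return SurrogateSelection(
        selected=selected[: cfg.budget],
        error_trace=error_trace,
        backend=cfg.backend,
        seed=cfg.random_seed,
    )


def combine_sets(a: ProbeSet, b: ProbeSet, c: ProbeSet) -> CombinedSet:
    """Probes present in at least 2 of the 3 selections."""
    counts: dict[str, int] = {}
    for s in (a, b, c):
        for p in s.probes:
            counts[p] = counts.get(p, 0) + 1
    combined = frozenset(p for p, n in counts.items() if n >= 2)
    name = f"combined({a.name},{b.name},{c.name})"
    return CombinedSet(ProbeSet(name, combined), counts)


def overlap_report(sets: Sequence[ProbeSet]) -> pd.DataFrame:
    """Cardinalities of every pairwise and higher-order intersection, the
    individual set sizes, and the count of probes in exactly one set."""
    if len(sets) < 2:
        raise ValueError("overlap report needs at least 2 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        names = [f"{s.name}#{i}" for i, s in enumerate(sets)]
    rows = []
    for s, name in zip(sets, names):
        rows.append({"sets": name, "order": 1, "count": len(s.probes)})
    for r in range(2, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), r):
            inter = frozenset.intersection(*(sets[i].probes for i in combo))
            rows.append(
                {
                    "sets": "&".join(names[i] for i in combo),
                    "order": r,
                    "count": len(inter),
                }
            )
    membership: dict[str, int] = {}
    for s in sets:
        for p in s.probes:
            membership[p] = membership.get(p, 0) + 1
    exactly_one = sum(1 for n in membership.values() if n == 1)
    rows.append({"sets": "exactly_one", "order": 0, "count": exactly_one})
    return pd.DataFrame(rows, columns=["sets", "order", "count"])
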