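"""Pathway Similarity Index (PSI) and the Y-scrambling null test.

PSI compares the pathway enrichment of predicted expression classes against
the enrichment of the actual classes.  With N significant pathways in the
actual enrichment, N_c of them also significant in the predicted enrichment,
and Q_i the number of query elements in pathway i,

    delta = sum_{i in common} Q_i / sum_{j in actual significant} Q_j
    PSI   = mean(N_c / N, delta)

Q is counted from the actual enrichment by default, which bounds delta (and
hence PSI) by 1; counting from the predicted enrichment is available via
``q_source="predicted"``.  PSI is asymmetric: the actual enrichment is the
reference.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusModel, predict_consensus
from .enrichment import EnrichmentConfig, EnrichmentResult, enrich, query_from_classes
from .matrix import CategorizedMatrix
from .ontology import Ontology


@dataclasses.dataclass
class PSIResult:
    n_actual: int
    n_common: int
    delta: float
    psi: float
    common_pathway_ids: list[str]


@dataclasses.dataclass
class PSISummary:
    """Per-sample PSI table (columns n_actual, n_common, delta, psi; NaN for
    samples whose actual enrichment has no significant pathway) and the mean
    over valid samples."""

    table: pd.DataFrame
    mean_psi: float


def compute_psi(
    actual: EnrichmentResult,
    predicted: EnrichmentResult,
    q_source: str = "actual",
) -> PSIResult:
    """PSI between an actual and a predicted enrichment result."""
    if q_source not in ("actual", "predicted"):
        raise ValueError("q_source must be 'actual' or 'predicted'")
    if actual.ontology_key != predicted.ontology_key:
        raise ValueError("enrichment results come from different ontologies")
    if actual.background != predicted.background:
        raise ValueError("enrichment results use different backgrounds")
    sig_actual = actual.significant_ids
    n = len(sig_actual)
    if n == 0:
        raise ValueError("actual enrichment has no significant pathway; PSI undefined")
    sig_pred = set(predicted.significant_ids)
    common = [cid for cid in sig_actual if cid in sig_pred]
    q_table = actual.table if q_source == "actual" else predicted.table
    q_common = float(q_table.loc[common, "query_elements"].sum()) if common else 0.0
    q_total = float(actual.table.loc[sig_actual, "query_elements"].sum())
    delta = q_common / q_total if q_total > 0 else 0.0
    psi = 0.5 * (len(common) / n + delta)
    return PSIResult(
        n_actual=n,
        n_common=len(common),
        delta=delta,
        psi=psi,
        common_pathway_ids=common,
    )


def psi_from_predictions(
    actual_classes: CategorizedMatrix,
    predicted_classes: CategorizedMatrix,
    ontology: Ontology,
    config: EnrichmentConfig | None = None,
    background: Sequence[str] | None = None,
    q_source: str = "actual",
) -> PSISummary:
    """Per-sample PSI between actual and predicted ternary class matrices.

    The query list of each sample is built from its up/down calls according
    to ``config.query_mode``.  The background defaults to the probes of the
    actual matrix.  Samples whose actual enrichment yields no significant
    pathway (or an empty query) are reported as NaN and excluded from the
    mean, with a warning.
    """
    cfg = config or EnrichmentConfig()
    if set(actual_classes.probe_ids) != set(predicted_classes.probe_ids):
        raise ValueError("actual and predicted matrices cover different probes")
    if actual_classes.sample_ids != predicted_classes.sample_ids:
        raise ValueError("actual and predicted matrices cover different samples")
    probes = actual_classes.probe_ids
    bg = list(background) if background is not None else probes
    pred_aligned = predicted_classes.classes.loc[probes]

    rows = []
    n_skipped = 0
    for sample in actual_classes.sample_ids:
        act_col = actual_classes.classes[sample].to_numpy()
        pred_col = pred_aligned[sample].to_numpy()
        query_act = query_from_classes(act_col, probes, cfg.query_mode)
        record = {"sample": sample, "n_actual": np.nan, "n_common": np.nan,
                  "delta": np.nan, "psi": np.nan}
        if not query_act:
            n_skipped += 1
            rows.append(record)
            continue
        res_act = enrich(query_act, ontology, bg, cfg)
        if not res_act.significant_ids:
            n_skipped += 1
            rows.append(record)
            continue
        query_pred = query_from_classes(pred_col, probes, cfg.query_mode)
        if query_pred:
            res_pred = enrich(query_pred, ontology, bg, cfg)
            psi = compute_psi(res_act, res_pred, q_source=q_source)
            record.update(
                n_actual=psi.n_actual, n_common=psi.n_common,
                delta=psi.delta, psi=psi.psi,
            )
        else:
            # No up/down calls predicted: nothing can be significant.
            record.update(n_actual=len(res_act.significant_ids), n_common=0,
                          delta=0.0, psi=0.0)
        rows.append(record)
    if n_skipped:
        warnings.warn(
            f"{n_skipped} sample(s) had no significant actual pathway (or an "
            "empty query) and were excluded from the mean PSI"
        )
    table = pd.DataFrame(rows).set_index("sample")
    mean_psi = float(table["psi"].mean(skipna=True))
    return PSISummary(table=table, mean_psi=mean_psi)


@dataclasses.dataclass
class ScrambleResult:
    null_means: list[float]
    null_mean: float
    quantiles: dict[str, float]


def y_scramble(
    actual_classes: CategorizedMatrix,
    model: ConsensusModel,
    ontology: Ontology,
    config: EnrichmentConfig | None = None,
    n_permutations: int = 10,
    seed: int = 0,
    permutations: list[np.ndarray] | None = None,
    q_source: str = "actual",
    full_profile: bool = True,
) -> ScrambleResult:
    """Null PSI distribution from scrambled sample labels.

    Each permutation feeds the model the surrogate profile of a *different*
    sample while keeping the actual target classes fixed, decoupling
    predictors from truth.  ``actual_classes`` must cover both the model's
    surrogate and target probes.  With ``full_profile`` the (scrambled)
    surrogate measurements are stacked with the predicted target classes
    before enrichment, matching the evaluation protocol; the identity
    permutation then reproduces the unscrambled PSI.
    """
    if n_permutations < 1 and permutations is None:
        raise ValueError("n_permutations must be >= 1")
    cfg = config or EnrichmentConfig()
    surro = actual_classes.subset_probes(model.surrogates)
    if full_profile:
        reference = actual_classes.subset_probes(model.surrogates + model.targets)
    else:
        reference = actual_classes.subset_probes(model.targets)
    n = actual_classes.n_samples
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = [rng.permutation(n) for _ in range(n_permutations)]

    means = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for perm in permutations:
            shuffled = CategorizedMatrix(
                pd.DataFrame(
                    surro.classes.to_numpy()[:, perm],
                    index=surro.probe_ids,
                    columns=surro.sample_ids,
                ),
                surro.sample_meta,
            )
            pred = predict_consensus(model, shuffled)
            if full_profile:
                predicted = CategorizedMatrix(
                    pd.concat([shuffled.classes, pred.classes.classes]),
                    surro.sample_meta,
                )
            else:
                predicted = pred.classes
            summary = psi_from_predictions(
                reference, predicted, ontology, cfg, q_source=q_source
            )
            means.append(summary.mean_psi)
    arr = np.array(means, dtype=float)
    quantiles = {
        "q05": float(np.nanquantile(arr, 0.05)),
        "q50": float(np.nanquantile(arr, 0.50)),
        "q95": float(np.nanquantile(arr, 0.95)),
    }
    return ScrambleResult(
        null_means=[float(m) for m in means],
        null_mean=float(np.nanmean(arr)),
        quantiles=quantiles,
    )
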