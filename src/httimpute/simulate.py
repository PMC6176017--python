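"""Synthetic expression compendia with latent-pathway structure.

The generator emulates the statistical premise of high-throughput
transcriptomics — strong correlation among pathway-co-regulated probes
across chemical exposures — with the simplest generative process that
exhibits it: each simulated chemical activates a small, signed subset of
pathways; a probe's relative expression is its pathway loading times the
activation, scaled monotonically by dose and time, plus Gaussian noise.
Signs are balanced within each chemical so the proportions of up- and
down-calls stay comparable across chemicals.  This is a fixture generator,
not a claim about the structure of any real compendium.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix import CategorizationConfig, CategorizedMatrix, ExpressionMatrix, ProbeSet, categorize
from .ontology import GeneSet, Ontology


@dataclasses.dataclass
class SimConfig:
    """Generator parameters.

    Defaults give 600 probes in 20 disjoint pathways of 25 probes (100
    background probes in no pathway), 30 chemicals at 3 dose levels and 3
    time points (270 samples), effect size ``loading_scale`` = 0.5 on the
    log-ratio scale against the ±0.1 call thresholds, and noise sigma 0.05.
    The chemical count is chosen so that, even under a compound-grouped
    train/holdout split, every pathway is expected to be activated several
    times in training — the diverse-coverage premise of the method.
    """

    n_probes: int = 600
    n_pathways: int = 20
    probes_per_pathway: int = 25
    n_chemicals: int = 30
    doses_per_chemical: int = 3
    times_per_chemical: int = 3
    n_active_pathways: int = 4
    loading_scale: float = 0.5
    noise_sigma: float = 0.05
    background_fraction: float | None = None
    class_thresholds: CategorizationConfig = dataclasses.field(
        default_factory=CategorizationConfig
    )
    seed: int = 0
    dose_multipliers: tuple[float, ...] = (0.6, 1.0, 1.4)
    time_multipliers: tuple[float, ...] = (0.8, 1.0, 1.2)

    def __post_init__(self) -> None:
        for field in (
            "n_probes", "n_pathways", "probes_per_pathway", "n_chemicals",
            "doses_per_chemical", "times_per_chemical", "n_active_pathways",
        ):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        members = self.n_pathways * self.probes_per_pathway
        if members > self.n_probes:
            raise ValueError(
                f"pathway membership ({members}) exceeds n_probes ({self.n_probes})"
            )
        if self.n_active_pathways > self.n_pathways:
            raise ValueError("n_active_pathways exceeds n_pathways")
        if len(self.dose_multipliers) != self.doses_per_chemical:
            raise ValueError("dose_multipliers length must equal doses_per_chemical")
        if len(self.time_multipliers) != self.times_per_chemical:
            raise ValueError("time_multipliers length must equal times_per_chemical")
        derived = (self.n_probes - members) / self.n_probes
        if self.background_fraction is None:
            self.background_fraction = derived
        elif abs(self.background_fraction - derived) > 0.5 / self.n_probes:
            raise ValueError(
                f"background_fraction {self.background_fraction} inconsistent with "
                f"derived value {derived:.4f}"
            )


@dataclasses.dataclass
class SimTruth:
    membership: dict[str, list[str]]
    activations: pd.DataFrame  # pathways x samples, signed magnitudes
    true_classes: CategorizedMatrix  # classes at noise 0


def simulate_compendium(
    config: SimConfig | None = None,
) -> tuple[ExpressionMatrix, Ontology, SimTruth]:
    """Generate an expression compendium, its pathway GMT and ground truth.

    Fully reproducible from ``config.seed``.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    width = max(5, len(str(cfg.n_probes)))
    probes = [f"P{i:0{width}d}" for i in range(1, cfg.n_probes + 1)]
    pathways = [f"PW{i:03d}" for i in range(1, cfg.n_pathways + 1)]

    shuffled = list(rng.permutation(probes))
    membership: dict[str, list[str]] = {}
    pos = 0
    for pw in pathways:
        membership[pw] = sorted(shuffled[pos : pos + cfg.probes_per_pathway])
        pos += cfg.probes_per_pathway

    probe_pathway = {p: pw for pw, ms in membership.items() for p in ms}
    loadings = {p: rng.uniform(0.8, 1.2) for p in shuffled if p in probe_pathway}

    sample_ids: list[str] = []
    meta_rows = []
    act_cols: dict[str, np.ndarray] = {}
    for ci in range(1, cfg.n_chemicals + 1):
        chem = f"CHEM{ci:03d}"
        active = rng.choice(cfg.n_pathways, size=cfg.n_active_pathways, replace=False)
        n_up = cfg.n_active_pathways // 2
        if cfg.n_active_pathways % 2:
            n_up += int(rng.integers(0, 2))
        signs = np.array([1] * n_up + [-1] * (cfg.n_active_pathways - n_up))
        rng.shuffle(signs)
        for d in range(cfg.doses_per_chemical):
            for t in range(cfg.times_per_chemical):
                sid = f"{chem}_d{d + 1}_t{t + 1}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "compound": chem, "dose_level": d + 1,
                     "time_point": t + 1}
                )
                act = np.zeros(cfg.n_pathways)
                act[active] = signs * cfg.dose_multipliers[d] * cfg.time_multipliers[t]
                act_cols[sid] = act
    activations = pd.DataFrame(act_cols, index=pathways)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")

    pw_index = {pw: i for i, pw in enumerate(pathways)}
    signal = np.zeros((cfg.n_probes, len(sample_ids)))
    act_matrix = activations.to_numpy()
    for r, p in enumerate(probes):
        pw = probe_pathway.get(p)
        if pw is not None:
            signal[r] = cfg.loading_scale * loadings[p] * act_matrix[pw_index[pw]]
    noise = rng.normal(0.0, cfg.noise_sigma, size=signal.shape) if cfg.noise_sigma else 0.0

    data = pd.DataFrame(signal + noise, index=probes, columns=sample_ids)
    matrix = ExpressionMatrix(data, meta)
    clean = ExpressionMatrix(pd.DataFrame(signal, index=probes, columns=sample_ids), meta)
    truth = SimTruth(
        membership=membership,
        activations=activations,
        true_classes=categorize(clean, cfg.class_thresholds),
    )
    categories = {
        pw: GeneSet(pw, f"simulated pathway {pw}", frozenset(ms))
        for pw, ms in membership.items()
    }
    return matrix, Ontology(categories), truth


def make_overlap_fixture(
    sizes: tuple[int, int, int],
    pairwise: tuple[int, int, int],
    triple: int,
    seed: int = 0,
) -> tuple[ProbeSet, ProbeSet, ProbeSet]:
    """Three probe sets with exact pairwise and triple intersection sizes.

    ``pairwise`` is (|A∩B|, |A∩C|, |B∩C|).  The seven Venn regions implied
    by inclusion-exclusion must all be non-negative, otherwise the violated
    inequality is reported.
    """
    size_a, size_b, size_c = sizes
    ab, ac, bc = pairwise
    regions = {
        "abc": triple,
        "ab_only": ab - triple,
        "ac_only": ac - triple,
        "bc_only": bc - triple,
        "a_only": size_a - ab - ac + triple,
        "b_only": size_b - ab - bc + triple,
        "c_only": size_c - ac - bc + triple,
    }
    constraints = {
        "abc": "triple >= 0",
        "ab_only": "|A∩B| >= triple",
        "ac_only": "|A∩C| >= triple",
        "bc_only": "|B∩C| >= triple",
        "a_only": "|A| >= |A∩B| + |A∩C| - triple",
        "b_only": "|B| >= |A∩B| + |B∩C| - triple",
        "c_only": "|C| >= |A∩C| + |B∩C| - triple",
    }
    for region, count in regions.items():
        if count < 0:
            raise ValueError(
                f"infeasible overlap cardinalities: {constraints[region]} violated "
                f"(region {region} would have {count} elements)"
            )
    total = sum(regions.values())
    rng = np.random.default_rng(seed)
    ids = [f"P{i:06d}" for i in rng.permutation(np.arange(1, total + 1))]
    pos = 0
    pools: dict[str, list[str]] = {}
    for region in ("abc", "ab_only", "ac_only", "bc_only", "a_only", "b_only", "c_only"):
        pools[region] = ids[pos : pos + regions[region]]
        pos += regions[region]
    set_a = pools["abc"] + pools["ab_only"] + pools["ac_only"] + pools["a_only"]
    set_b = pools["abc"] + pools["ab_only"] + pools["bc_only"] + pools["b_only"]
    set_c = pools["abc"] + pools["ac_only"] + pools["bc_only"] + pools["c_only"]
    return (
        ProbeSet("A", frozenset(set_a)),
        ProbeSet("B", frozenset(set_b)),
        ProbeSet("C", frozenset(set_c)),
    )
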