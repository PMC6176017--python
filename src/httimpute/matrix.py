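"""Core containers for probe-by-sample expression data and ternary calls.

Expression values are relative measures (log-ratio versus a matched vehicle
control); no normalisation is performed here.  Ternary calls discretise each
value into up-regulated (+1), down-regulated (-1) or unchanged (0) relative
to a dead zone around zero.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Integer codes for the three qualitative expression classes.
DOWN: int = -1
UNCHANGED: int = 0
UP: int = 1

CLASS_CODES: tuple[int, int, int] = (DOWN, UNCHANGED, UP)
CLASS_LABELS: Mapping[int, str] = {DOWN: "down", UNCHANGED: "unchanged", UP: "up"}

#: Expected sample-metadata columns (all optional in practice, but when a
#: metadata frame is supplied it must at least carry ``compound``).
META_COLUMNS = ("compound", "dose_level", "time_point")


def _find_duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


def _check_ids(index: pd.Index, kind: str) -> None:
    if index.has_duplicates:
        dups = _find_duplicates(index)
        raise ValueError(f"duplicate {kind} ID(s): {', '.join(map(str, dups[:5]))}")


def _align_meta(meta: pd.DataFrame | None, sample_ids: pd.Index) -> pd.DataFrame | None:
    if meta is None:
        return None
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"sample_meta missing entries for: {missing[:5]}")
    return meta.loc[sample_ids]


@dataclasses.dataclass(eq=False)
class ExpressionMatrix:
    """Probe x sample matrix of relative expression values.

    Parameters
    ----------
    data
        DataFrame with probe IDs as the index and sample IDs as columns.
        All values must be finite floats.
    sample_meta
        Optional per-sample annotation indexed by sample ID with columns
        ``compound``, ``dose_level``, ``time_point``.
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_ids(self.data.index, "probe")
        _check_ids(self.data.columns, "sample")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at probe {self.data.index[r]!r}, "
                f"sample {self.data.columns[c]!r}"
            )
        self.sample_meta = _align_meta(self.sample_meta, self.data.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise KeyError(f"unknown probe ID(s): {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(probes)], self.sample_meta)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ID(s): {missing[:5]}")
        meta = self.sample_meta.loc[list(samples)] if self.sample_meta is not None else None
        return ExpressionMatrix(self.data[list(samples)], meta)


@dataclasses.dataclass(frozen=True)
class CategorizationConfig:
    """Thresholds of the ternary discretisation.

    Values strictly above ``up_threshold`` are called up-regulated, values
    strictly below ``down_threshold`` down-regulated, everything else
    (including exact boundary values) unchanged.  The defaults of ±0.1 assume
    log-ratio input and were chosen to give comparable class proportions
    across heterogeneous chemicals.
    """

    down_threshold: float = -0.1
    up_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not self.down_threshold < self.up_threshold:
            raise ValueError(
                f"down_threshold ({self.down_threshold}) must be below "
                f"up_threshold ({self.up_threshold})"
            )


@dataclasses.dataclass(eq=False)
class CategorizedMatrix:
    """Probe x sample matrix of ternary class codes in {-1, 0, +1}."""

    classes: pd.DataFrame
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_ids(self.classes.index, "probe")
        _check_ids(self.classes.columns, "sample")
        values = self.classes.to_numpy()
        if values.size and not np.isin(values, CLASS_CODES).all():
            bad = values[~np.isin(values, CLASS_CODES)][0]
            raise ValueError(f"class codes must be -1, 0 or 1; found {bad!r}")
        self.classes = self.classes.astype(np.int8)
        self.sample_meta = _align_meta(self.sample_meta, self.classes.columns)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.classes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.classes.columns)

    @property
    def n_probes(self) -> int:
        return self.classes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.classes.shape[1]

    def subset_probes(self, probes: Sequence[str]) -> "CategorizedMatrix":
        missing = [p for p in probes if p not in self.classes.index]
        if missing:
            raise KeyError(f"unknown probe ID(s): {missing[:5]}")
        return CategorizedMatrix(self.classes.loc[list(probes)], self.sample_meta)

    def subset_samples(self, samples: Sequence[str]) -> "CategorizedMatrix":
        missing = [s for s in samples if s not in self.classes.columns]
        if missing:
            raise KeyError(f"unknown sample ID(s): {missing[:5]}")
        meta = self.sample_meta.loc[list(samples)] if self.sample_meta is not None else None
        return CategorizedMatrix(self.classes[list(samples)], meta)

    def class_counts(self) -> pd.Series:
        """Counts of each class code over all cells."""
        flat = self.classes.to_numpy().ravel()
        return pd.Series(
            {code: int((flat == code).sum()) for code in CLASS_CODES}, name="count"
        )


def categorize(
    matrix: ExpressionMatrix, config: CategorizationConfig | None = None
) -> CategorizedMatrix:
    """Discretise relative expression into ternary classes.

    Strict inequalities are used: a value equal to a threshold is called
    unchanged.
    """
    cfg = config or CategorizationConfig()
    values = matrix.data.to_numpy()
    codes = (values > cfg.up_threshold).astype(np.int8) - (
        values < cfg.down_threshold
    ).astype(np.int8)
    frame = pd.DataFrame(codes, index=matrix.data.index, columns=matrix.data.columns)
    return CategorizedMatrix(frame, matrix.sample_meta)


@dataclasses.dataclass(frozen=True)
class ProbeSet:
    """A named, unordered collection of probe identifiers."""

    name: str
    probes: frozenset[str]

    def __post_init__(self) -> None:
        if not isinstance(self.probes, frozenset):
            object.__setattr__(self, "probes", frozenset(self.probes))

    def __len__(self) -> int:
        return len(self.probes)

    def __contains__(self, probe: str) -> bool:
        return probe in self.probes
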