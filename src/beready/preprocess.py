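"""Housekeeper normalization, shifted-log transform and feature scaling.

The assay quantifies a fixed panel in which four stably expressed
housekeeper genes act as an internal depth reference: each sample's
counts are divided by the geometric mean of its housekeeper counts,
which removes library-size effects exactly (multiplying a whole sample
row by c > 0 leaves the normalized row unchanged).

Two downstream paths exist and their order is tracked by a state flag:

* statistics path: linear -> shifted-log (ln(x + 1)) for t-tests/ANOVA;
* model path: linear -> scaled (z-score with development-set mean/sd)
  for PCA and classification.

A housekeeper count of zero marks assay failure for that sample: the
sample is excluded (QC fail) rather than pseudocounted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CountMatrix

log = logging.getLogger(__name__)

_STATES = ("linear", "shifted-log", "scaled")


@dataclass
class NormalizedMatrix:
    """Real-valued samples x genes matrix after housekeeper normalization,
    with the transform state recorded (transitions only move forward)."""

    values: pd.DataFrame
    housekeeper_ids: tuple[str, ...]
    state: str = "linear"
    qc_failed: tuple[str, ...] = ()
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


def normalize_housekeepers(m: CountMatrix, housekeepers) -> NormalizedMatrix:
    """Divide each sample row by the geometric mean of its housekeeper
    counts (computed in log space for stability).

    Samples with any zero housekeeper count are flagged QC-fail and
    excluded from the output; raw data in ``m`` is never mutated.
    """
    hk = list(housekeepers)
    if not hk:
        raise ValueError("at least one housekeeper gene is required")
    missing = [g for g in hk if g not in m.counts.columns]
    if missing:
        raise ValueError(f"housekeeper gene(s) absent from matrix: {missing}")
    hk_counts = m.counts[hk].to_numpy(dtype=float)
    ok = (hk_counts > 0).all(axis=1)
    failed = tuple(np.asarray(m.sample_ids)[~ok])
    if failed:
        log.warning(
            "sample(s) %s excluded: zero housekeeper count (QC fail)", list(failed)
        )
    geomean = np.exp(np.log(hk_counts[ok]).mean(axis=1))
    values = m.counts.loc[ok].astype(float).div(geomean, axis=0)
    meta = m.meta.loc[ok]
    return NormalizedMatrix(values, tuple(hk), "linear", failed, meta)


def shifted_log(m: NormalizedMatrix, shift: float = 1.0) -> NormalizedMatrix:
    """Elementwise x -> ln(x + shift); the statistics-path transform."""
    if m.state != "linear":
        raise ValueError(f"shifted_log expects linear state, got {m.state!r}")
    arr = m.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative values: normalize before log-transforming")
    return NormalizedMatrix(
        np.log(m.values + shift), m.housekeeper_ids, "shifted-log",
        m.qc_failed, m.meta,
    )


@dataclass
class ScalingParams:
    """Per-gene center/scale learned on the development set.  Genes with
    zero variance in the development set are dropped and listed."""

    center: pd.Series
    scale: pd.Series
    dropped: tuple[str, ...] = ()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.center.index)


def fit_scaling(dev: NormalizedMatrix) -> ScalingParams:
    """Learn z-scoring parameters (mean, sd with ddof=1) on the
    development set; zero-variance genes are dropped."""
    if len(dev.values) < 2:
        raise ValueError("need >= 2 development samples to fit scaling")
    center = dev.values.mean(axis=0)
    scale = dev.values.std(axis=0, ddof=1)
    keep = scale > 0
    dropped = tuple(scale.index[~keep])
    if dropped:
        log.warning("zero-variance gene(s) dropped from scaling: %s", list(dropped))
    return ScalingParams(center[keep], scale[keep], dropped)


def apply_scaling(m: NormalizedMatrix, p: ScalingParams) -> NormalizedMatrix:
    """Z-score ``m`` with development-set parameters (never its own)."""
    if m.state == "scaled":
        raise ValueError("matrix is already scaled")
    missing = [g for g in p.gene_ids if g not in m.values.columns]
    if missing:
        raise ValueError(f"gene(s) required by model absent from matrix: {missing}")
    vals = (m.values[p.gene_ids] - p.center) / p.scale
    return NormalizedMatrix(vals, m.housekeeper_ids, "scaled", m.qc_failed, m.meta)
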