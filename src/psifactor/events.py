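"""Splicing-event domain model and PSI ("per cent spliced in") quantification.

Events are skipped exons (SE) or retained introns (RI) quantified from
inclusion- and skipping-supporting junction read counts.  This module owns
PSI computation with effective-junction normalization, condition means,
expressed-event filtering, row z-scoring, and sample-level PCA.

Coordinates are 0-based half-open throughout.  Strand is stored but PSI is
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "SpliceEvent",
    "JunctionCountTable",
    "compute_psi",
    "psi_matrix",
    "condition_mean_psi",
    "filter_expressed",
    "zscore_matrix",
    "pca_conditions",
]

#: The four cells of the genotype x treatment design.
CONDITIONS = ("WT_Veh", "WT_Drug", "MT_Veh", "MT_Drug")

#: Default effective-junction normalization constants per event type:
#: (inclusion norm, skipping norm).  SE inclusion is supported by two
#: junctions, skipping by one; RI evidence is aggregated one-to-one.
DEFAULT_NORMS = {"SE": (2, 1), "RI": (1, 1)}

EVENT_TYPES = ("SE", "RI")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    Parameters
    ----------
    event_id, gene_id : str
    event_type : {"SE", "RI"}
    chrom : str
    coordinates : tuple of int
        0-based half-open, strictly increasing.  SE: (upstream-exon end,
        cassette start, cassette end, downstream-exon start).  RI:
        (intron start, intron end).
    strand : {"+", "-"}
    inc_junction_count, skip_junction_count : int
        Effective junction counts used as PSI normalization constants.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str = "chr1"
    coordinates: tuple = ()
    strand: str = "+"
    inc_junction_count: int = 0  # 0 -> type default
    skip_junction_count: int = 0

    def __post_init__(self):
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        coords = tuple(int(c) for c in self.coordinates)
        if any(b <= a for a, b in zip(coords, coords[1:])):
            raise ValueError(
                f"coordinates must be strictly increasing: {coords}"
            )
        object.__setattr__(self, "coordinates", coords)
        inc_d, skip_d = DEFAULT_NORMS[self.event_type]
        inc = self.inc_junction_count or inc_d
        skip = self.skip_junction_count or skip_d
        if inc < 1 or skip < 1:
            raise ValueError("junction counts must be >= 1")
        object.__setattr__(self, "inc_junction_count", int(inc))
        object.__setattr__(self, "skip_junction_count", int(skip))


@dataclass
class JunctionCountTable:
    """Per-event, per-sample inclusion/skipping counts plus the sample sheet.

    ``inclusion_counts`` and ``skipping_counts`` are events x samples integer
    DataFrames indexed by event id; ``sample_conditions`` maps each sample to
    one of :data:`CONDITIONS`.
    """

    events: list
    inclusion_counts: pd.DataFrame
    skipping_counts: pd.DataFrame
    sample_conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.event_id for e in self.events]
        if list(self.inclusion_counts.index) != ids:
            raise ValueError("inclusion_counts index must match event ids")
        if list(self.skipping_counts.index) != ids:
            raise ValueError("skipping_counts index must match event ids")
        if list(self.inclusion_counts.columns) != list(
            self.skipping_counts.columns
        ):
            raise ValueError("count matrices must share sample columns")
        for df in (self.inclusion_counts, self.skipping_counts):
            arr = df.to_numpy()
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        for s in self.samples:
            cond = self.sample_conditions.get(s)
            if cond is not None and cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} for sample {s}")

    @property
    def samples(self) -> list:
        return list(self.inclusion_counts.columns)

    @property
    def event_ids(self) -> list:
        return [e.event_id for e in self.events]

    def event_map(self) -> dict:
        return {e.event_id: e for e in self.events}

    def samples_for(self, condition: str) -> list:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition label {condition!r}")
        return [s for s in self.samples if self.sample_conditions.get(s) == condition]

    def norms(self) -> pd.DataFrame:
        """Per-event (inc_norm, skip_norm) frame aligned to the count index."""
        return pd.DataFrame(
            {
                "inc_norm": [e.inc_junction_count for e in self.events],
                "skip_norm": [e.skip_junction_count for e in self.events],
            },
            index=self.event_ids,
        )


def compute_psi(
    inclusion: int,
    skipping: int,
    inc_norm: int = 1,
    skip_norm: int = 1,
) -> float:
    """PSI from inclusion/skipping counts with effective-length normalization.

    Returns ``(I/inc_norm) / (I/inc_norm + S/skip_norm)``; ``nan`` (missing)
    when both counts are zero.
    """
    if inclusion < 0 or skipping < 0:
        raise ValueError("counts must be non-negative")
    if inc_norm < 1 or skip_norm < 1:
        raise ValueError("normalization constants must be >= 1")
    if inclusion == 0 and skipping == 0:
        return float("nan")
    i = inclusion / inc_norm
    s = skipping / skip_norm
    return i / (i + s)


def psi_matrix(table: JunctionCountTable) -> pd.DataFrame:
    """Per-event, per-sample PSI matrix (NaN where uninformative)."""
    inc = table.inclusion_counts.to_numpy(dtype=float)
    skip = table.skipping_counts.to_numpy(dtype=float)
    norms = table.norms()
    i = inc / norms["inc_norm"].to_numpy()[:, None]
    s = skip / norms["skip_norm"].to_numpy()[:, None]
    tot = i + s
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(tot > 0, i / np.where(tot > 0, tot, 1.0), np.nan)
    return pd.DataFrame(psi, index=table.event_ids, columns=table.samples)


def condition_mean_psi(table: JunctionCountTable, condition: str) -> pd.Series:
    """Unweighted mean of per-sample PSI over a condition's samples.

    Samples with missing PSI are excluded; all-missing events yield NaN.
    """
    samples = table.samples_for(condition)
    if not samples:
        raise ValueError(f"no samples assigned to condition {condition!r}")
    return psi_matrix(table)[samples].mean(axis=1, skipna=True)


def filter_expressed(
    table: JunctionCountTable, min_mean_total: float = 10.0
) -> JunctionCountTable:
    """Keep events whose mean total (inclusion+skipping) count across all
    samples is >= ``min_mean_total`` (boundary inclusive)."""
    if min_mean_total < 0:
        raise ValueError("min_mean_total must be >= 0")
    total = table.inclusion_counts + table.skipping_counts
    keep = total.mean(axis=1) >= min_mean_total
    kept_ids = set(keep[keep].index)
    events = [e for e in table.events if e.event_id in kept_ids]
    idx = [e.event_id for e in events]
    return JunctionCountTable(
        events=events,
        inclusion_counts=table.inclusion_counts.loc[idx],
        skipping_counts=table.skipping_counts.loc[idx],
        sample_conditions=dict(table.sample_conditions),
    )


def zscore_matrix(values: pd.DataFrame) -> tuple:
    """Row-wise z-scoring with population SD.

    Rows with zero variance or any missing value are dropped and reported.

    Returns
    -------
    (zscored, dropped) : (DataFrame, list of row labels)
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples to z-score")
    arr = values.to_numpy(dtype=float)
    finite = np.isfinite(arr).all(axis=1)
    mean = np.nanmean(arr, axis=1)
    sd = np.nanstd(arr, axis=1)  # population SD
    ok = finite & (sd > 0)
    z = (arr[ok] - mean[ok, None]) / sd[ok, None]
    dropped = [lbl for lbl, keep in zip(values.index, ok) if not keep]
    return (
        pd.DataFrame(z, index=values.index[ok], columns=values.columns),
        dropped,
    )


def pca_conditions(values: pd.DataFrame, n_components: int = 3) -> tuple:
    """PCA of samples (observations) over z-scored event rows (features).

    Returns sample scores (samples x components) and the variance-explained
    fractions, non-increasing and summing to <= 1.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples for PCA")
    z, _ = zscore_matrix(values)
    if z.shape[0] <= n_components:
        raise ValueError("need more events than requested components")
    x = z.to_numpy().T  # samples x events
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return scores, frac[:k]
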