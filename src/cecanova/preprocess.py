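"""Count filtering, CSS normalization, rarefaction, taxonomy collapse and
average daily gain.

The filtering rules follow the study pipeline: samples with fewer than
5000 total counts are discarded; OTUs whose total count over all samples
is at most 2 (doubletons and singletons) are removed; and for the
differential-abundance analyses OTUs must be detected in at least 5% of
the samples ("at least" inclusive) and carry more than 0.01% of the grand
total count ("greater than" strict).

Cumulative sum scaling (CSS) divides each sample's counts by the sum of
its counts up to a chosen quantile of the sample's nonzero-count
distribution, then rescales by a fixed constant. The quantile is either
supplied or chosen adaptively from the instability of sample quantiles
around the across-sample reference (relative-difference threshold 0.1,
floored at 0.5).

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a common depth, dropping samples below the depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyResultError, LookupError_, ParameterError
from .io_formats import RANKS, UNASSIGNED, CountTable, TaxonomyMap

__all__ = [
    "NormalizedTable",
    "remove_low_depth_samples",
    "remove_doubletons",
    "prevalence_abundance_filter",
    "css_normalize",
    "choose_css_quantile",
    "rarefy",
    "collapse_taxa",
    "compute_adg",
    "adg_from_metadata",
]

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass
class NormalizedTable:
    """CSS-normalized abundance matrix with the per-sample scaling factors."""

    otu_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scaling_factors: np.ndarray
    quantile_used: float
    scale_constant: float = 1000.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.otu_ids, name="#OTU ID"),
                            columns=self.sample_ids)


def remove_low_depth_samples(t: CountTable, min_depth: int = 5000) -> CountTable:
    """Drop samples whose total count is strictly below ``min_depth``."""
    if min_depth < 0:
        raise ParameterError("min_depth must be >= 0")
    keep = t.sample_sums() >= min_depth
    if not keep.any():
        raise EmptyResultError("all samples below the depth threshold")
    return t.select_samples(keep)


def remove_doubletons(t: CountTable, max_total: int = 2) -> CountTable:
    """Drop OTUs whose total count across samples is <= ``max_total``."""
    return t.select_otus(t.otu_sums() > max_total)


def prevalence_abundance_filter(t: CountTable, min_prevalence: float = 0.05,
                                min_total_fraction: float = 0.0001) -> CountTable:
    """Keep OTUs detected in >= ceil(min_prevalence * n) samples (inclusive)
    whose total count exceeds min_total_fraction of the grand total (strict)."""
    if not (0 < min_prevalence < 1) or not (0 < min_total_fraction < 1):
        raise ParameterError("filter fractions must lie in (0, 1)")
    n_required = math.ceil(min_prevalence * t.n_samples)
    prevalence_ok = (t.counts > 0).sum(axis=1) >= n_required
    grand_total = t.counts.sum()
    abundance_ok = t.otu_sums() > min_total_fraction * grand_total
    return t.select_otus(prevalence_ok & abundance_ok)


def choose_css_quantile(t: CountTable, rel_threshold: float = 0.1) -> float:
    """Adaptive CSS quantile from the instability of sample quantiles.

    For a grid of probabilities, compute each sample's quantile of its
    nonzero counts, the across-sample median as reference, and the median
    absolute deviation of sample quantiles around that reference. The
    chosen probability is the smallest at which this deviation changes by
    at least ``rel_threshold`` relative to its previous value, floored at
    0.5. Falls back to 0.5 (with a warning) when no such point exists.
    """
    probs = np.arange(1, 100) / 100.0
    nz = [t.counts[:, j][t.counts[:, j] > 0] for j in range(t.n_samples)]
    if any(len(v) == 0 for v in nz):
        raise ParameterError("every sample needs at least one nonzero count")
    q = np.stack([np.quantile(v, probs) for v in nz])  # samples x probs
    ref = np.median(q, axis=0)
    mad = np.median(np.abs(q - ref[None, :]), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.diff(mad)) / np.where(mad[:-1] > 0, mad[:-1], np.nan)
    hits = np.flatnonzero(rel >= rel_threshold)
    if hits.size == 0:
        logger.warning("adaptive CSS quantile did not converge; using 0.5")
        return 0.5
    return float(max(probs[hits[0] + 1], 0.5))


def css_normalize(t: CountTable, quantile: float | None = None,
                  scale_constant: float = 1000.0) -> NormalizedTable:
    """Cumulative sum scaling.

    The scaling factor of sample j is the sum of counts that are <= the
    ``quantile``-th quantile of the sample's nonzero counts; normalized
    values are counts / s_j * scale_constant. Zeros stay zero.
    """
    sums = t.sample_sums()
    if (sums == 0).any():
        raise ParameterError("sample(s) with all-zero counts cannot be normalized")
    if quantile is None:
        quantile = choose_css_quantile(t)
    if not (0 < quantile < 1):
        raise ParameterError("quantile must lie in (0, 1)")
    s = np.empty(t.n_samples, dtype=float)
    for j in range(t.n_samples):
        col = t.counts[:, j]
        nz = col[col > 0]
        qj = np.quantile(nz, quantile)
        s[j] = col[col <= qj].sum()
    values = t.counts / s[None, :] * scale_constant
    return NormalizedTable(list(t.otu_ids), list(t.sample_ids), values, s,
                           float(quantile), float(scale_constant))


def rarefy(t: CountTable, depth: int = 10_000, seed: int | None = None) -> CountTable:
    """Subsample each sample without replacement to exactly ``depth`` counts.

    Samples whose total is below the depth are dropped (logged); the
    result is elementwise <= the original counts.
    """
    if depth < 1:
        raise ParameterError("depth must be >= 1")
    sums = t.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise EmptyResultError("all samples below the rarefaction depth")
    dropped = [sid for sid, k in zip(t.sample_ids, keep) if not k]
    if dropped:
        logger.info("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped[:10])
    t = t.select_samples(keep)
    rng = np.random.default_rng(seed)
    out = np.empty_like(t.counts)
    for j in range(t.n_samples):
        col = t.counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(list(t.otu_ids), list(t.sample_ids), out)


def collapse_taxa(nt: NormalizedTable, tax: TaxonomyMap, rank: str) -> pd.DataFrame:
    """Sum normalized values within each taxon at ``rank`` and rescale each
    sample to percentages; OTUs unassigned at the rank pool into an
    ``unclassified`` bucket. Returns taxa x samples percentages."""
    if rank not in RANKS:
        raise ParameterError(f"unknown rank {rank!r}")
    labels = tax.rank_of(nt.otu_ids, rank).to_numpy(dtype=object)
    labels = np.where(labels == UNASSIGNED, UNCLASSIFIED, labels)
    df = nt.to_frame()
    collapsed = df.groupby(pd.Index(labels, name=rank), sort=True).sum()
    totals = collapsed.sum(axis=0)
    if (totals == 0).any():
        raise ParameterError("sample with zero total after collapse")
    return collapsed / totals * 100.0


def compute_adg(weights: Sequence[tuple[float, float]]) -> float:
    """Average daily gain: OLS slope of body weight (g) on age (days)."""
    pts = [(float(a), float(w)) for a, w in weights]
    if len(pts) < 2:
        raise ParameterError("need at least two weight records")
    ages = np.array([a for a, _ in pts])
    if np.all(ages == ages[0]):
        raise ParameterError("slope undefined: all ages identical")
    ws = np.array([w for _, w in pts])
    return float(stats.linregress(ages, ws).slope)


def adg_from_metadata(meta: pd.DataFrame) -> pd.Series:
    """Per-sample average daily gain from ``weight_<age>`` columns."""
    from .io_formats import weight_columns

    cols = weight_columns(meta)
    if len(cols) < 2:
        raise ParameterError("need at least two weight_<age> columns")
    ages = [int(c.split("_")[1]) for c in cols]
    slopes = meta[cols].apply(
        lambda row: compute_adg(list(zip(ages, row.to_numpy()))), axis=1)
    slopes.index = meta["sample_id"]
    slopes.name = "adg"
    return slopes
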