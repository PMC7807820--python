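"""Alpha diversity on rarefied counts and group contrasts.

Two indices are computed per sample: the observed number of OTUs
(richness) and the Shannon index in natural-log units. Group differences
are assessed with the same cell-means ANOVA and contrast family as the
composition analyses, but with classical (theoretical-null) F tests —
permutation nulls are reserved for the per-taxon composition analyses.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ParameterError
from .io_formats import CountTable
from .perm_anova import (
    Contrast,
    bh_fdr,
    combined_factor,
    contrast_estimate,
    f_statistic,
    fit_cell_means,
    standard_contrasts,
)

__all__ = ["observed_otus", "shannon", "alpha_diversity", "alpha_contrasts"]


def observed_otus(counts: np.ndarray) -> int:
    """Number of OTUs with a nonzero count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon index -sum p_i log p_i (natural log by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ParameterError("Shannon index undefined for a zero-total sample")
    return float(stats.entropy(counts, base=base))


def alpha_diversity(t: CountTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample observed OTUs and Shannon index."""
    rows = [(sid, observed_otus(t.counts[:, j]), shannon(t.counts[:, j], base=base))
            for j, sid in enumerate(t.sample_ids)]
    return pd.DataFrame(rows, columns=["sample_id", "observed_otus", "shannon"])


def alpha_contrasts(div: pd.DataFrame, meta: pd.DataFrame,
                    contrasts: Sequence[Contrast] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Cell-means ANOVA contrasts on each alpha-diversity index.

    Reports estimate, SE, F, the classical F-test p-value (1 and
    residual-df degrees of freedom) and BH-adjusted p-values across the
    contrast family of each index.
    """
    indices = [c for c in ("observed_otus", "shannon") if c in div.columns]
    if not indices:
        raise ParameterError("no diversity index columns found")
    merged = meta.merge(div, on="sample_id", how="inner")
    if len(merged) != len(div):
        raise AlignmentError("samples in diversity table missing from metadata")
    if contrasts is None:
        contrasts = standard_contrasts(merged)
    cell_labels = list(combined_factor(merged))
    rows = []
    for index_name in indices:
        y = merged[index_name].to_numpy(dtype=float)
        fit = fit_cell_means(y, cell_labels)
        for c in contrasts:
            est, se = contrast_estimate(fit, c)
            f = f_statistic(fit, c)
            p = float(stats.f.sf(f, 1, fit.resid_df)) if np.isfinite(f) else 0.0
            rows.append((index_name, c.name, est, se, f, p))
    out = pd.DataFrame(rows, columns=["index", "contrast", "estimate", "se",
                                      "f_stat", "p_value"])
    out["p_fdr"] = np.nan
    for name, grp in out.groupby("index"):
        out.loc[grp.index, "p_fdr"] = bh_fdr(grp["p_value"].to_numpy())
    out["significant"] = out["p_fdr"] <= alpha
    return out
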