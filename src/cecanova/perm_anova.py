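"""Per-taxon permutation analysis of variance over the combined design
factor.

The model is a one-way cell-means ANOVA on the single factor whose levels
are the observed cells of farm x batch x antibiotic x feeding (12 under
the full study design). Comparisons of interest are zero-sum contrasts of
unweighted cell means: farm A vs farm B (averaged over batches and
feeding), feeding within each farm, and antibiotic within farm B (the
only farm where it varies). Each contrast is tested with an F statistic,
whose null distribution is obtained empirically by globally permuting the
response against the design, and p-values are adjusted per contrast
across taxa by Benjamini-Hochberg.

Directions follow the reported tables: farm = A - B, feeding = R - AL,
antibiotic = without - with.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    ContrastError,
    DegenerateFitError,
    ParameterError,
)

__all__ = [
    "Cell",
    "Contrast",
    "CellMeansFit",
    "combined_factor",
    "fit_cell_means",
    "contrast_estimate",
    "f_statistic",
    "standard_contrasts",
    "interaction_test",
    "permutation_pvalue",
    "bh_fdr",
    "run_differential_abundance",
]

Cell = tuple  # (farm, batch, antibiotic, feeding)


def combined_factor(meta: pd.DataFrame) -> pd.Series:
    """Per-sample design-cell label (farm, batch, antibiotic, feeding)."""
    cells = list(zip(meta["farm"], meta["batch"], meta["antibiotic"], meta["feeding"]))
    return pd.Series(cells, index=meta["sample_id"].to_numpy(), name="cell")


@dataclass(frozen=True)
class Contrast:
    """A zero-sum weighting of cell means.

    The positive and the negative part must each sum to one in absolute
    value, so the estimate is a difference of two unweighted group
    averages in response units.
    """

    name: str
    weights: Mapping[Cell, float]
    df: int = 1

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if w.size == 0:
            raise ContrastError(f"{self.name}: empty contrast")
        if abs(w.sum()) > 1e-9:
            raise ContrastError(f"{self.name}: weights must sum to zero")
        if abs(w[w > 0].sum() - 1.0) > 1e-9 or abs(w[w < 0].sum() + 1.0) > 1e-9:
            raise ContrastError(
                f"{self.name}: positive/negative parts must each sum to 1")

    def vector(self, cells: Sequence[Cell]) -> np.ndarray:
        missing = [c for c in self.weights if c not in cells]
        if missing:
            raise ContrastError(
                f"{self.name}: contrast touches unobserved cell(s) {missing[:3]}")
        return np.array([self.weights.get(c, 0.0) for c in cells])


@dataclass
class CellMeansFit:
    """OLS cell-means fit: per-cell means and pooled residual variance."""

    cells: list[Cell]
    n_per_cell: np.ndarray
    means: np.ndarray
    resid_ms: float
    resid_df: int


def _cell_codes(cell_labels: Sequence[Cell]) -> tuple[list[Cell], np.ndarray]:
    cells = sorted(set(cell_labels))
    index = {c: i for i, c in enumerate(cells)}
    codes = np.array([index[c] for c in cell_labels], dtype=np.intp)
    return cells, codes


def fit_cell_means(y: np.ndarray, cell_labels: Sequence[Cell]) -> CellMeansFit:
    """Ordinary least squares on the combined factor: cell means and the
    pooled within-cell variance (residual mean square)."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != len(cell_labels):
        raise AlignmentError("response and cell labels differ in length")
    cells, codes = _cell_codes(cell_labels)
    n_g = np.bincount(codes, minlength=len(cells)).astype(float)
    sums = np.bincount(codes, weights=y, minlength=len(cells))
    means = sums / n_g
    resid_df = int(y.size - len(cells))
    if resid_df < 1:
        raise DegenerateFitError("no residual degrees of freedom")
    rss = float(y @ y - (sums**2 / n_g).sum())
    return CellMeansFit(cells, n_g, means, max(rss, 0.0) / resid_df, resid_df)


def contrast_estimate(fit: CellMeansFit, c: Contrast) -> tuple[float, float]:
    """Contrast estimate and its OLS standard error."""
    w = c.vector(fit.cells)
    est = float(w @ fit.means)
    se = float(np.sqrt(fit.resid_ms * (w**2 / fit.n_per_cell).sum()))
    return est, se


def f_statistic(fit: CellMeansFit, c: Contrast) -> float:
    """F = (sum w_g m_g)^2 / (resid MS * sum w_g^2 / n_g) for 1-df
    contrasts; equals the squared pooled two-sample t for two cells.
    Defined as 0 when both the estimate and the residual MS vanish."""
    w = c.vector(fit.cells)
    est = float(w @ fit.means)
    denom = fit.resid_ms * (w**2 / fit.n_per_cell).sum()
    if denom == 0.0:
        return 0.0 if est == 0.0 else float("inf")
    return est**2 / denom


def standard_contrasts(meta: pd.DataFrame, feeding: str = "nested") -> list[Contrast]:
    """The study's contrast family over the observed cells.

    ``feeding="nested"`` emits feeding within each farm (the reported
    form); ``"averaged"`` emits a single feeding contrast averaged over
    farms. Contrasts whose factor does not vary in the design are
    skipped. All cell-level weights are unweighted averages.
    """
    if feeding not in ("nested", "averaged"):
        raise ParameterError("feeding must be 'nested' or 'averaged'")
    cells = sorted(set(combined_factor(meta)))
    out: list[Contrast] = []

    def balanced(pos: list[Cell], neg: list[Cell], name: str) -> Contrast | None:
        if not pos or not neg:
            return None
        w: dict[Cell, float] = {}
        for c in pos:
            w[c] = 1.0 / len(pos)
        for c in neg:
            w[c] = -1.0 / len(neg)
        return Contrast(name, w)

    farm_a = [c for c in cells if c[0] == "A"]
    farm_b = [c for c in cells if c[0] == "B"]
    c = balanced(farm_a, farm_b, "farm")
    if c:
        out.append(c)
    if feeding == "nested":
        for farm, group in (("A", farm_a), ("B", farm_b)):
            c = balanced([x for x in group if x[3] == "R"],
                         [x for x in group if x[3] == "AL"],
                         f"feeding_within_{farm}")
            if c:
                out.append(c)
    else:
        c = balanced([x for x in cells if x[3] == "R"],
                     [x for x in cells if x[3] == "AL"], "feeding")
        if c:
            out.append(c)
    c = balanced([x for x in farm_b if x[2] == "without"],
                 [x for x in farm_b if x[2] == "with"], "antibiotic_within_B")
    if c:
        out.append(c)
    if not out:
        raise ContrastError("no estimable contrast under this design")
    return out


# ---------------------------------------------------------------------------
# vectorized permutation engine

def _onehot(codes: np.ndarray, n_cells: int) -> np.ndarray:
    z = np.zeros((codes.size, n_cells))
    z[np.arange(codes.size), codes] = 1.0
    return z


def _f_many(Y: np.ndarray, onehot: np.ndarray, n_g: np.ndarray,
            W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimates, SEs and F statistics for many responses at once.

    Y is (B, n) responses, W is (C, G) contrast weight rows. Returns
    (B, C) arrays of estimates, SEs and F values.
    """
    n, G = onehot.shape
    S = Y @ onehot                       # (B, G) cell sums
    M = S / n_g[None, :]
    rss = np.maximum((Y**2).sum(axis=1) - (S**2 / n_g[None, :]).sum(axis=1), 0.0)
    ms = rss / (n - G)
    est = M @ W.T                        # (B, C)
    wfac = (W**2 / n_g[None, :]).sum(axis=1)   # (C,)
    denom = ms[:, None] * wfac[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(denom > 0, est**2 / denom,
                     np.where(est**2 > 0, np.inf, 0.0))
    return est, np.sqrt(denom), F


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    idx = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def permutation_pvalue(y: np.ndarray, cell_labels: Sequence[Cell], c: Contrast,
                       n_perm: int = 1000, seed: int | None = None,
                       add_one: bool = False) -> float:
    """Empirical p-value of the contrast F statistic under global
    permutation of the response.

    The plain estimator is #{F* >= F_obs} / n_perm (ties count as >=);
    ``add_one=True`` returns the smoothed (1 + #) / (1 + n_perm) variant,
    which is a valid p-value and never exactly zero.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    cells, codes = _cell_codes(cell_labels)
    n_g = np.bincount(codes, minlength=len(cells)).astype(float)
    Z = _onehot(codes, len(cells))
    W = c.vector(cells)[None, :]
    rng = np.random.default_rng(seed)
    _, _, F_obs = _f_many(y[None, :], Z, n_g, W)
    idx = _perm_indices(rng, y.size, n_perm)
    _, _, F_perm = _f_many(y[idx], Z, n_g, W)
    hits = int((F_perm[:, 0] >= F_obs[0, 0]).sum())
    if add_one:
        return (1 + hits) / (1 + n_perm)
    return hits / n_perm


def interaction_test(y: np.ndarray, meta: pd.DataFrame,
                     factors: tuple[str, str] = ("farm", "feeding"),
                     n_perm: int = 1000, seed: int | None = None,
                     add_one: bool = False) -> dict:
    """Difference-of-differences test for a two-factor interaction.

    Compares the unweighted effect of ``factors[1]`` between the first
    two levels of ``factors[0]`` (e.g. the feeding effect in farm A vs
    farm B) with a permutation p-value. Used to decide whether nested or
    averaged contrasts are reported.
    """
    fa, fb = factors
    col = {"farm": 0, "batch": 1, "antibiotic": 2, "feeding": 3}
    if fa not in col or fb not in col:
        raise ParameterError(f"unknown factor in {factors}")
    cell_labels = list(combined_factor(meta))
    cells = sorted(set(cell_labels))
    lev_a = sorted({c[col[fa]] for c in cells})
    lev_b = sorted({c[col[fb]] for c in cells})
    if len(lev_a) < 2 or len(lev_b) < 2:
        raise ContrastError(f"factor(s) in {factors} do not vary")
    weights: dict[Cell, float] = {}
    for sign_a, la in ((1.0, lev_a[0]), (-1.0, lev_a[1])):
        for sign_b, lb in ((1.0, lev_b[0]), (-1.0, lev_b[1])):
            grp = [c for c in cells if c[col[fa]] == la and c[col[fb]] == lb]
            if not grp:
                raise ContrastError(
                    f"interaction {factors} not estimable: empty cell "
                    f"({la}, {lb})")
            for c in grp:
                weights[c] = weights.get(c, 0.0) + sign_a * sign_b * 0.5 / len(grp)
    # weights now form a 1-df difference-of-differences contrast whose
    # positive/negative parts each sum to 1
    contrast = Contrast(f"{fa}x{fb}", weights)
    fit = fit_cell_means(np.asarray(y, float), cell_labels)
    return {
        "f_stat": f_statistic(fit, contrast),
        "p_emp": permutation_pvalue(y, cell_labels, contrast, n_perm=n_perm,
                                    seed=seed, add_one=add_one),
        "contrast": contrast,
    }


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _taxon_seed(master_seed: int, taxon: str) -> np.random.SeedSequence:
    # keyed on the taxon name so results do not depend on processing order
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF,
                                   zlib.crc32(taxon.encode("utf-8"))])


def run_differential_abundance(values: pd.DataFrame, meta: pd.DataFrame,
                               contrasts: Sequence[Contrast] | None = None,
                               n_perm: int = 1000, alpha: float = 0.05,
                               seed: int = 0, add_one: bool = True,
                               feeding: str = "nested",
                               interaction_alpha: float = 0.05) -> pd.DataFrame:
    """Permutation ANOVA for every taxon (row) and contrast.

    ``values`` is a taxa x samples matrix (CSS-normalized OTU values or
    relative abundances at some rank); columns must match
    ``meta['sample_id']`` as a set. Per taxon and contrast the function
    reports the estimate, OLS standard error, F statistic, empirical
    permutation p-value and the BH-adjusted p-value computed across taxa
    within each contrast. Permutation streams derive from the master seed
    and the taxon name, and are shared across a taxon's contrasts.

    ``feeding`` may be ``"nested"`` (report feeding within farm, the
    study's choice), ``"averaged"``, or ``"auto"`` — decide per taxon by a
    farm-by-feeding interaction permutation test at ``interaction_alpha``.
    ``add_one=True`` (default) uses the smoothed permutation p-value so
    that BH retains finite-permutation validity; ``False`` gives the
    plain proportion.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    sample_ids = list(meta["sample_id"])
    if set(values.columns) != set(sample_ids):
        raise AlignmentError("sample ids of the matrix and metadata differ")
    values = values[sample_ids]
    cell_labels = list(combined_factor(meta))
    cells, codes = _cell_codes(cell_labels)
    n_g = np.bincount(codes, minlength=len(cells)).astype(float)
    Z = _onehot(codes, len(cells))
    n = len(sample_ids)

    auto = contrasts is None and feeding == "auto"
    if contrasts is None:
        base_contrasts = standard_contrasts(
            meta, feeding="nested" if feeding == "auto" else feeding)
    else:
        base_contrasts = list(contrasts)
    if auto:
        averaged = {c.name: c for c in standard_contrasts(meta, feeding="averaged")}

    rows = []
    for taxon in values.index:
        y = values.loc[taxon].to_numpy(dtype=float)
        rng = np.random.default_rng(_taxon_seed(seed, str(taxon)))
        idx = _perm_indices(rng, n, n_perm)
        Yp = y[idx]

        taxon_contrasts = base_contrasts
        if auto:
            inter = interaction_test(y, meta, ("farm", "feeding"), n_perm=n_perm,
                                     seed=rng.integers(2**31), add_one=add_one)
            if inter["p_emp"] > interaction_alpha and "feeding" in averaged:
                taxon_contrasts = [c for c in base_contrasts
                                   if not c.name.startswith("feeding_within")]
                taxon_contrasts.append(averaged["feeding"])

        W = np.stack([c.vector(cells) for c in taxon_contrasts])
        est, se, F_obs = _f_many(y[None, :], Z, n_g, W)
        _, _, F_perm = _f_many(Yp, Z, n_g, W)
        hits = (F_perm >= F_obs[0][None, :]).sum(axis=0)
        if add_one:
            p_emp = (1 + hits) / (1 + n_perm)
        else:
            p_emp = hits / n_perm
        for k, c in enumerate(taxon_contrasts):
            w = W[k]
            pos = float(np.clip(w, 0, None) @ (np.bincount(codes, weights=y,
                                                           minlength=len(cells)) / n_g))
            neg = float(-np.clip(w, None, 0) @ (np.bincount(codes, weights=y,
                                                            minlength=len(cells)) / n_g))
            rows.append((str(taxon), c.name, est[0, k], se[0, k], F_obs[0, k],
                         p_emp[k], pos, neg))

    out = pd.DataFrame(rows, columns=["taxon", "contrast", "estimate", "se",
                                      "f_stat", "p_emp", "mean_pos", "mean_neg"])
    out["p_fdr"] = np.nan
    for name, grp in out.groupby("contrast"):
        out.loc[grp.index, "p_fdr"] = bh_fdr(grp["p_emp"].to_numpy())
    out["significant"] = out["p_fdr"] <= alpha
    return out
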