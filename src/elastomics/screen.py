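"""Gene screens against DTD abundance: correlation, enrichment, elastic net.

Per-gene Pearson correlation of normalized expression with the CLR DTD
readout (two-sided t-test p, Benjamini-Hochberg adjustment), threshold
selection at the screen cut-offs, preranked gene-set enrichment on the
correlation ordering, and cross-validated elastic-net nomination of
candidate tension regulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.linear_model import ElasticNetCV, LinearRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "InsufficientDataError",
    "correlate_genes",
    "threshold_genes",
    "preranked_enrichment",
    "enrichment_score",
    "elastic_net_regulators",
    "RegulatorFit",
]


class InsufficientDataError(RuntimeError):
    """Too few cells (or too small a universe) to run the screen."""


def _as_dense(matrix) -> np.ndarray:
    if sparse.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=float)
    return np.asarray(matrix, dtype=float)


def correlate_genes(
    expr,
    genes,
    dtd_clr,
    min_dtd_clr: float | None = None,
    method: str = "bh",
) -> pd.DataFrame:
    """Per-gene Pearson correlation with the DTD readout.

    ``expr`` is genes x cells (normalized); ``dtd_clr`` one value per
    cell. Cells below ``min_dtd_clr`` are excluded from the correlation
    (the low-import cell filter). P-values come from the t-transform
    with n-2 degrees of freedom; adjustment is Benjamini-Hochberg by
    default (``method='bonferroni'`` for the conservative variant).
    Constant genes are returned with r=0, p=1 and ``degenerate=True``.
    """
    x = _as_dense(expr)
    y = np.asarray(dtd_clr, dtype=float)
    if x.shape[1] != y.size:
        raise ValueError("expression columns and dtd_clr length differ")
    if min_dtd_clr is not None:
        keep = y >= min_dtd_clr
        x, y = x[:, keep], y[keep]
    n = y.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 cells after filtering, have {n}")

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    degenerate = (sx == 0) | (sy == 0)
    denom = np.where(degenerate, 1.0, sx * sy)
    r = np.clip((xc @ yc) / denom, -1.0, 1.0)
    r[degenerate] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[degenerate] = 1.0
    p = np.clip(p, 0.0, 1.0)

    adjust_method = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    p_adj = multipletests(p, method=adjust_method)[1]

    return pd.DataFrame(
        {
            "gene": list(genes),
            "pearson_r": r,
            "p_value": p,
            "p_adjusted": p_adj,
            "mean_expression": x.mean(axis=1),
            "degenerate": degenerate,
            "n_cells": n,
        }
    ).set_index("gene")


def threshold_genes(
    result: pd.DataFrame,
    r_min: float,
    p_max: float,
    mode: str = "greater",
    use_adjusted: bool = True,
) -> list[str]:
    """Genes passing the screen cut-offs.

    ``mode='greater'`` keeps r > r_min (one-sided, positive coupling);
    ``mode='two-sided'`` keeps |r| > r_min. ``use_adjusted`` selects
    the adjusted-p column (e.g. r > 0.2 and adjusted P < 1e-4) versus
    the raw p (e.g. r > 0.15 and P < 1e-10).
    """
    if result.empty:
        return []
    p_col = "p_adjusted" if use_adjusted else "p_value"
    r = result["pearson_r"]
    if mode == "greater":
        r_ok = r > r_min
    elif mode == "two-sided":
        r_ok = r.abs() > r_min
    else:
        raise ValueError(f"mode must be 'greater' or 'two-sided', got {mode!r}")
    mask = r_ok & (result[p_col] < p_max) & ~result["degenerate"].astype(bool)
    return result.index[mask].tolist()


def enrichment_score(
    ranked_genes, metric, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov running-sum enrichment score.

    Genes are assumed pre-ordered (descending metric). Hits advance the
    running sum by |metric|^weight (normalized over hits), misses
    retreat by 1/(N - N_hits); the ES is the extremum of largest
    absolute deviation from zero (signed). The sum returns to exactly 0
    at the end of the list.
    """
    genes = list(ranked_genes)
    metric = np.asarray(metric, dtype=float)
    in_set = np.fromiter((g in gene_set for g in genes), dtype=bool, count=len(genes))
    n_hits = int(in_set.sum())
    n_miss = len(genes) - n_hits
    if n_hits == 0 or n_miss == 0:
        raise ValueError("gene set must be a proper non-empty subset of the universe")
    hit_weights = np.abs(metric) ** weight
    hit_norm = hit_weights[in_set].sum()
    if hit_norm == 0:
        # all hit metrics are zero: fall back to unweighted steps
        increments = np.where(in_set, 1.0 / n_hits, -1.0 / n_miss)
    else:
        increments = np.where(in_set, hit_weights / hit_norm, -1.0 / n_miss)
    running = np.cumsum(increments)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def preranked_enrichment(
    ranked: pd.Series | pd.DataFrame,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked enrichment over user-supplied gene sets.

    ``ranked`` maps genes to the ranking metric (e.g. Pearson r with
    DTD abundance); genes are ordered by descending metric with ties
    broken by gene identifier. The permutation null shuffles gene
    labels (equivalently draws random sets of the same size);
    NES = ES / mean |null ES of the same sign|; p is the same-sign
    permutation tail probability with +1 smoothing. Sets with fewer
    than 2 members in the universe are skipped.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked = ranked["pearson_r"]
    order = sorted(ranked.index, key=lambda g: (-ranked[g], str(g)))
    metric = ranked.loc[order].to_numpy(dtype=float)
    universe = set(order)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in gene_sets.items():
        present = [g for g in set(members) if g in universe]
        if len(present) < 2:
            import warnings

            warnings.warn(f"gene set {name!r} has <2 members in the universe; skipped")
            continue
        es, _ = enrichment_score(order, metric, set(present), weight)
        k = len(present)
        null_es = np.empty(n_perm)
        idx = np.arange(len(order))
        for b in range(n_perm):
            perm = rng.choice(idx, size=k, replace=False)
            in_set = np.zeros(len(order), dtype=bool)
            in_set[perm] = True
            hit_weights = np.abs(metric) ** weight
            hit_norm = hit_weights[in_set].sum()
            if hit_norm == 0:
                increments = np.where(in_set, 1.0 / k, -1.0 / (len(order) - k))
            else:
                increments = np.where(in_set, hit_weights / hit_norm, -1.0 / (len(order) - k))
            running = np.cumsum(increments)
            null_es[b] = running[np.argmax(np.abs(running))]
        same_sign = null_es[np.sign(null_es) == np.sign(es)] if es != 0 else null_es
        if same_sign.size == 0:
            nes = np.nan
            p = 1.0 / (n_perm + 1.0)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        rows.append(
            {
                "gene_set": name,
                "size": k,
                "enrichment_score": es,
                "normalized_score": nes,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("gene_set") if rows else pd.DataFrame(
        columns=["size", "enrichment_score", "normalized_score", "p_value"]
    )


@dataclass
class RegulatorFit:
    """Elastic-net fit of DTD abundance on candidate-gene expression."""

    coefficients: pd.DataFrame  # per gene: s, abs_s, selected (|s| > cut)
    intercept: float
    alpha: float  # CV-optimal penalty strength
    l1_ratio: float  # mixing weight
    cv_curve: pd.DataFrame  # penalty path vs mean CV error
    coefficient_cut: float

    def top_genes(self, n: int = 10) -> list[str]:
        return self.coefficients.sort_values("abs_s", ascending=False).head(n).index.tolist()


def elastic_net_regulators(
    expr,
    genes,
    dtd_clr,
    mixing: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    coefficient_cut: float = 0.1,
    n_alphas: int = 60,
) -> RegulatorFit:
    """Cross-validated elastic net of DTD abundance on candidate genes.

    ``expr`` is candidate-genes x cells; the response is the per-cell
    CLR DTD value. The penalty strength is chosen by ``n_folds``-fold
    CV at fixed seed; coefficients ``s`` are reported at the CV-optimal
    penalty, on the standardized-predictor scale when ``standardize``
    (so the magnitude cut |s| > 0.1 compares like with like). Ridge
    (``mixing=0``) is approximated with a tiny L1 share because the
    coordinate-descent path requires one.
    """
    x = _as_dense(expr).T  # cells x genes
    y = np.asarray(dtd_clr, dtype=float)
    genes = list(genes)
    if x.shape[0] != y.size:
        raise ValueError("expression columns and response length differ")
    if x.shape[0] < n_folds:
        raise ValueError(f"{x.shape[0]} cells cannot support {n_folds}-fold CV")
    if not 0 <= mixing <= 1:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")

    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd

    l1_ratio = max(mixing, 1e-3)  # coordinate descent needs some L1 to build the path
    model = ElasticNetCV(
        l1_ratio=l1_ratio,
        alphas=n_alphas,
        cv=n_folds,
        random_state=seed,
        max_iter=50_000,
    )
    model.fit(x, y)
    coef = pd.DataFrame(
        {"s": model.coef_, "abs_s": np.abs(model.coef_)}, index=pd.Index(genes, name="gene")
    )
    coef["selected"] = coef["abs_s"] > coefficient_cut
    cv_curve = pd.DataFrame(
        {"alpha": model.alphas_, "mean_cv_mse": model.mse_path_.mean(axis=1)}
    )
    return RegulatorFit(
        coefficients=coef,
        intercept=float(model.intercept_),
        alpha=float(model.alpha_),
        l1_ratio=l1_ratio,
        cv_curve=cv_curve,
        coefficient_cut=coefficient_cut,
    )
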