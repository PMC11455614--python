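"""Pseudocell differential expression with robustness scoring.

Workflow: nuclei of one cell type are randomly aggregated into pseudocells
(~30 nuclei each, within sample/condition strata), expression is
normalized to counts-per-100,000 and log2(x+1)-transformed, a per-gene
linear model (condition + covariates) is fit, per-gene residual variances
are shrunk toward a mean-expression-dependent trend by an empirical-Bayes
rule, and genes are called responsive when they pass both an FDR and a
cross-condition sample-pair robustness criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.special import digamma, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "NucleusCounts",
    "PseudocellMatrix",
    "DisruptionResult",
    "build_pseudocells",
    "background_genes",
    "cp100k_log2",
    "moderated_t_de",
    "rob_scores",
    "call_trgs",
    "trg_correlation",
    "disruption_regression",
    "bh_adjust",
    "read_counts",
    "write_counts",
]

CP_SCALE = 1e5  # counts per 100,000


@dataclass
class NucleusCounts:
    """Sparse gene x nucleus counts plus per-nucleus metadata.

    ``meta`` must carry columns ``cell_type``, ``sample_id``, ``condition``
    (values 'T3' / 'control'); optionally ``cre_status`` ('pos'/'neg'/'n/a'),
    ``pct_mt`` and ``n_genes``.
    """

    counts: sp.spmatrix
    genes: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.meta)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.meta)} nuclei"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    def subset_cell_type(self, cell_type: str) -> "NucleusCounts":
        sel = (self.meta["cell_type"] == cell_type).to_numpy()
        return NucleusCounts(
            counts=self.counts[:, sel],
            genes=self.genes,
            meta=self.meta.loc[sel].reset_index(drop=True),
        )


@dataclass
class PseudocellMatrix:
    counts: sp.spmatrix | None
    genes: np.ndarray | None
    meta: pd.DataFrame | None  # sample_id, condition, cre_status, n_member_nuclei, pct_mt, n_genes
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class DisruptionResult:
    slope: float
    intercept: float
    r_squared: float
    disrupted_genes: list[str] = field(default_factory=list)


def build_pseudocells(
    nuclei: NucleusCounts,
    cell_type: str,
    target_size: int = 30,
    min_nuclei: int = 15,
    min_pseudocells: int = 6,
    seed: int = 0,
    stratify_cre: bool = False,
) -> PseudocellMatrix:
    """Randomly partition a cell type's nuclei into pseudocells.

    Nuclei are grouped within (sample, condition[, cre_status]) strata by a
    seeded shuffle followed by chunking into ``floor(n / target_size)``
    groups (minimum one), remainders distributed; every group holds at least
    ``min_nuclei`` nuclei or the stratum is skipped. Cell types with fewer
    than ``min_nuclei`` nuclei in total or fewer than ``min_pseudocells``
    constructed pseudocells are excluded — an outcome, not an error.
    """
    sub = nuclei.subset_cell_type(cell_type)
    n_cells = sub.counts.shape[1]
    if n_cells < min_nuclei:
        return PseudocellMatrix(
            None, None, None, excluded=True,
            exclusion_reason=f"{n_cells} nuclei < {min_nuclei}",
        )
    rng = np.random.default_rng(seed)
    strata_keys = ["sample_id", "condition"] + (["cre_status"] if stratify_cre else [])
    col_totals = np.asarray(sub.counts.sum(axis=0)).ravel()
    pct_mt = sub.meta["pct_mt"].to_numpy(float) if "pct_mt" in sub.meta else np.zeros(n_cells)

    groups: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for key, grp in sub.meta.groupby(strata_keys, sort=True, observed=True):
        idx = grp.index.to_numpy()
        if len(idx) < min_nuclei:
            continue
        idx = idx[rng.permutation(len(idx))]
        n_groups = max(len(idx) // target_size, 1)
        for chunk in np.array_split(idx, n_groups):
            groups.append(chunk)
            key_t = key if isinstance(key, tuple) else (key,)
            row = dict(zip(strata_keys, key_t))
            w = col_totals[chunk]
            row["n_member_nuclei"] = len(chunk)
            row["pct_mt"] = (
                float(np.average(pct_mt[chunk], weights=w)) if w.sum() > 0
                else float(np.mean(pct_mt[chunk]))
            )
            meta_rows.append(row)

    if len(groups) < min_pseudocells:
        return PseudocellMatrix(
            None, None, None, excluded=True,
            exclusion_reason=f"{len(groups)} pseudocells < {min_pseudocells}",
        )

    # aggregate: genes x pseudocells = counts @ membership indicator
    indic = sp.lil_matrix((n_cells, len(groups)))
    for j, chunk in enumerate(groups):
        indic[chunk, j] = 1.0
    agg = sp.csc_matrix(sub.counts @ sp.csc_matrix(indic))
    meta = pd.DataFrame(meta_rows)
    if "cre_status" not in meta:
        meta["cre_status"] = "n/a"
    meta["n_genes"] = np.asarray((agg > 0).sum(axis=0)).ravel()
    return PseudocellMatrix(counts=agg, genes=sub.genes, meta=meta)


def background_genes(
    nuclei: NucleusCounts, cell_type: str | None = None, min_fraction: float = 0.01
) -> np.ndarray:
    """Genes detected in strictly more than ``min_fraction`` of the
    subtype's cells (boolean mask over ``nuclei.genes``)."""
    sub = nuclei if cell_type is None else nuclei.subset_cell_type(cell_type)
    n = sub.counts.shape[1]
    if n == 0:
        return np.zeros(len(sub.genes), dtype=bool)
    det = np.asarray((sub.counts > 0).sum(axis=1)).ravel()
    return det / n > min_fraction


def cp100k_log2(counts: sp.spmatrix | np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Column-normalize to counts per 100k, then log2(x + pseudocount)."""
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    colsum = dense.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return np.log2(dense * (CP_SCALE / colsum) + pseudocount)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    cummin = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(cummin, 1.0)
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve polygamma(1, y) = x for y (Newton iteration)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _estimate_prior(
    s2: np.ndarray, amean: np.ndarray, d: int, trend_frac: float
) -> tuple[np.ndarray, float]:
    """Trend s0^2(g) and prior df d0 from the spread of log residual variances.

    The smooth of log(s2) on mean expression estimates log(sigma0^2) up to
    the chi-square log bias digamma(d/2) - log(d/2), which is removed; d0
    solves trigamma(d0/2) = var(log s2 - log s0^2) - trigamma(d/2).
    """
    logs2 = np.log(np.maximum(s2, 1e-300))
    if len(s2) >= 10 and np.ptp(amean) > 0:
        sm = lowess(logs2, amean, frac=trend_frac, return_sorted=False)
    else:
        sm = np.full_like(logs2, logs2.mean())
    bias = digamma(d / 2.0) - np.log(d / 2.0)
    log_s0 = sm - bias
    resid = logs2 - log_s0
    var_r = float(np.var(resid, ddof=1)) if len(resid) > 1 else 0.0
    excess = var_r - float(polygamma(1, d / 2.0))
    d0 = 2.0 * _trigamma_inverse(excess) if excess > 1e-8 else np.inf
    return np.exp(log_s0), d0


def moderated_t_de(
    pseudocells: PseudocellMatrix,
    covariates: tuple[str, ...] = ("pct_mt", "log2_n_genes"),
    background: np.ndarray | None = None,
    prior_df: float | str = "auto",
    trend_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression, T3 vs control.

    Fits ``log2(cp100k + 1) ~ intercept + condition + covariates`` by least
    squares; shrinks residual variances toward a lowess trend of log
    variance on mean expression with moment-estimated prior df. With
    ``prior_df=0`` shrinkage is disabled and results equal ordinary
    per-gene t-tests from the same linear model.

    Returns a DataFrame with columns gene, log2fc, t_mod, p, fdr, mean_expr.
    """
    if pseudocells.excluded:
        raise ValueError(f"pseudocell matrix excluded: {pseudocells.exclusion_reason}")
    meta = pseudocells.meta
    cond = (meta["condition"] == "T3").to_numpy(float)
    if cond.sum() < 2 or (1 - cond).sum() < 2:
        raise ValueError("need >= 2 pseudocells per condition")

    genes = pseudocells.genes
    Y = cp100k_log2(pseudocells.counts)
    if background is not None:
        Y = Y[background]
        genes = genes[background]
    nonzero = Y.sum(axis=1) > 0
    Y, genes = Y[nonzero], genes[nonzero]
    if len(genes) == 0:
        raise ValueError("no genes left after filtering")

    cols = {"intercept": np.ones(len(meta)), "condition": cond}
    for cv in covariates:
        if cv == "log2_n_genes":
            vals = np.log2(meta["n_genes"].to_numpy(float))
        elif cv in meta:
            vals = meta[cv].to_numpy(float)
        else:
            continue
        if np.ptp(vals) < 1e-12:
            continue  # constant covariate: aliased with intercept, dropped
        cols[cv] = vals
    X = np.column_stack(list(cols.values()))
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise np.linalg.LinAlgError(
            f"singular design; columns {list(cols)} are linearly dependent"
        )
    d = n - p
    if d < 1:
        raise ValueError("no residual degrees of freedom")

    xtx_inv = np.linalg.inv(X.T @ X)
    betas = Y @ X @ xtx_inv  # genes x p
    resid = Y - betas @ X.T
    s2 = (resid**2).sum(axis=1) / d
    amean = Y.mean(axis=1)
    ci = list(cols).index("condition")
    v_cond = xtx_inv[ci, ci]
    coef = betas[:, ci]

    if prior_df == "auto":
        s0_sq, d0 = _estimate_prior(s2, amean, d, trend_frac)
    elif prior_df == 0:
        s0_sq, d0 = np.ones_like(s2), 0.0
    else:
        d0 = float(prior_df)
        s0_sq, _ = _estimate_prior(s2, amean, d, trend_frac)
    if np.isinf(d0):
        s2_post, df_total = s0_sq, np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = coef / np.sqrt(s2_post * v_cond)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    return pd.DataFrame(
        {
            "gene": genes,
            "log2fc": coef,
            "t_mod": t_mod,
            "p": pvals,
            "fdr": bh_adjust(pvals),
            "mean_expr": amean,
        }
    )


def rob_scores(pseudocells: PseudocellMatrix, genes: np.ndarray | None = None) -> pd.DataFrame:
    """Signed concordance of per-sample summaries across cross-condition pairs.

    For every (T3 sample, control sample) pair a gene scores +1 when the T3
    member's summary exceeds the control member's, -1 when lower, 0 on
    ties; robScore = mean over pairs. ``robscore_logfc`` uses mean
    normalized log expression across each sample's pseudocells,
    ``robscore_pct`` the fraction of the sample's pseudocells with nonzero
    counts. Only cross-condition pairs are counted.
    """
    if pseudocells.excluded:
        raise ValueError("pseudocell matrix excluded")
    meta = pseudocells.meta
    Y = cp100k_log2(pseudocells.counts)
    nz = np.asarray((pseudocells.counts > 0).todense(), dtype=float)
    gene_names = pseudocells.genes
    if genes is not None:
        keep = np.isin(gene_names, genes)
        Y, nz, gene_names = Y[keep], nz[keep], gene_names[keep]

    def per_sample(mat: np.ndarray, condition: str) -> np.ndarray:
        samples = sorted(meta.loc[meta["condition"] == condition, "sample_id"].unique())
        if not samples:
            raise ValueError(f"condition {condition!r} has zero samples")
        out = np.empty((mat.shape[0], len(samples)))
        for j, sid in enumerate(samples):
            sel = ((meta["sample_id"] == sid) & (meta["condition"] == condition)).to_numpy()
            out[:, j] = mat[:, sel].mean(axis=1)
        return out

    def score(mat: np.ndarray) -> np.ndarray:
        t3 = per_sample(mat, "T3")
        ctl = per_sample(mat, "control")
        diff = t3[:, :, None] - ctl[:, None, :]  # genes x n_t3 x n_ctl
        return np.sign(diff).sum(axis=(1, 2)) / (diff.shape[1] * diff.shape[2])

    return pd.DataFrame(
        {
            "gene": gene_names,
            "robscore_logfc": score(Y),
            "robscore_pct": score(nz),
        }
    )


def call_trgs(
    de: pd.DataFrame,
    fdr_threshold: float = 0.05,
    rob_threshold: float = 0.5,
    n_top_expressed: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag responsive genes and derive the non-responsive reference set.

    A gene is flagged iff ``fdr < 0.05`` and ``|robscore_logfc| >= 0.5``.
    The non-responsive set is the top ``n_top_expressed`` most-expressed
    genes with fdr > 0.05, robscore_logfc == 0 and robscore_pct == 0.
    """
    de = de.copy()
    de["is_trg"] = (de["fdr"] < fdr_threshold) & (
        de["robscore_logfc"].abs() >= rob_threshold
    )
    eligible = de[
        (de["fdr"] > fdr_threshold)
        & (de["robscore_logfc"] == 0)
        & (de["robscore_pct"] == 0)
    ]
    non_trgs = eligible.nlargest(n_top_expressed, "mean_expr")
    return de, non_trgs


def trg_correlation(
    log2fc: pd.DataFrame, trg_sets: dict[str, set]
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Spearman correlation of effect sizes across cell types over the TRG
    union, plus Ward (ward.D2) clustering of the correlation-matrix rows.

    ``log2fc`` is cell_type x gene. Cell types without any TRG, or with no
    defined values over the union, are excluded.
    """
    with_trgs = [ct for ct in log2fc.index if trg_sets.get(ct)]
    union = sorted(set().union(*(trg_sets[ct] for ct in with_trgs))) if with_trgs else []
    if len(with_trgs) < 2:
        raise ValueError("need >= 2 cell types with TRGs")
    sub = log2fc.loc[with_trgs, [g for g in union if g in log2fc.columns]]
    sub = sub.dropna(axis=0, how="all")
    mat = sub.to_numpy(float)
    k = mat.shape[0]
    corr = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            corr[i, j] = corr[j, i] = stats.spearmanr(mat[i], mat[j]).statistic
    corr_df = pd.DataFrame(corr, index=sub.index, columns=sub.index)
    # scipy 'ward' on raw observations == R hclust ward.D2 on the distances
    Z = linkage(corr, method="ward")
    order = [str(sub.index[i]) for i in leaves_list(Z)]
    return corr_df, Z, order


def disruption_regression(
    original_log2fc: pd.Series,
    delta_log2fc: pd.Series,
    contrast_fdr: pd.Series | None = None,
    fdr_threshold: float = 0.05,
    frac_change_threshold: float = 0.25,
) -> DisruptionResult:
    """Regress the manipulation-induced expression change on the original
    effect size; identify significantly disrupted genes.

    Disrupted genes satisfy contrast FDR < 0.05 and an absolute fractional
    expression change (|2^delta - 1|) of at least 25%.
    """
    common = original_log2fc.index.intersection(delta_log2fc.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 aligned genes, got {len(common)}")
    x = original_log2fc.loc[common].to_numpy(float)
    y = delta_log2fc.loc[common].to_numpy(float)
    res = stats.linregress(x, y)
    disrupted: list[str] = []
    if contrast_fdr is not None:
        frac = np.abs(2.0 ** delta_log2fc.loc[common].to_numpy(float) - 1.0)
        sig = contrast_fdr.reindex(common).to_numpy(float) < fdr_threshold
        disrupted = [str(g) for g, s, f in zip(common, sig, frac)
                     if s and f >= frac_change_threshold]
    return DisruptionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        disrupted_genes=disrupted,
    )


# ---------------------------------------------------------------------------
# MTX + TSV container IO


def read_counts(mtx_path, genes_path, meta_path) -> NucleusCounts:
    from scipy.io import mmread

    counts = sp.csc_matrix(mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].to_numpy(str)
    meta = pd.read_csv(meta_path, sep="\t")
    return NucleusCounts(counts=counts, genes=genes, meta=meta)


def write_counts(nuclei: NucleusCounts, mtx_path, genes_path, meta_path) -> None:
    from scipy.io import mmwrite

    mmwrite(str(mtx_path), sp.coo_matrix(nuclei.counts))
    pd.Series(nuclei.genes).to_csv(genes_path, sep="\t", header=False, index=False)
    nuclei.meta.to_csv(meta_path, sep="\t", index=False)
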