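"""Count normalization and moderated differential expression.

The stage mirrors the standard bulk RNA-seq workflow for low-replicate
designs: CPM filtering, trimmed-mean-of-M-values (TMM) normalization,
log2-CPM with a prior count, mean-variance precision weights with
per-sample quality weights, gene-wise weighted least squares on a
treatment design matrix, empirical-Bayes variance moderation, and
Benjamini-Hochberg FDR control per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionMatrix:
    """Gene x sample integer counts plus derived normalization state."""

    counts: pd.DataFrame
    norm_factors: pd.Series | None = None
    logexpr: pd.DataFrame | None = None
    obs_weights: pd.DataFrame | None = None
    sample_weights: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if c.columns.duplicated().any():
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if (c.values < 0).any():
            raise ValueError("negative counts")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million; each column sums to 1e6."""
    lib = counts.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero-count sample(s): {zero.index.tolist()}")
    return counts / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in at least min_samples samples."""
    if min_cpm <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be > 0")
    cpm = compute_cpm(counts)
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed mean of M-values normalization factors, geometric mean 1.

    Reference sample: the column whose upper quartile of nonzero-scaled
    counts is closest to the mean upper quartile.  For each sample, M- and
    A-values against the reference are computed over genes expressed in
    both, both tails of M (trim_m each) and A (trim_a each) are trimmed,
    and the factor is 2**(weighted mean M) with inverse asymptotic-variance
    weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"zero-count sample(s): {bad}")
    y = counts.to_numpy(dtype=float)
    scaled = y / lib
    uq = np.array([np.quantile(scaled[:, k][scaled[:, k] > 0], 0.75) if (scaled[:, k] > 0).any() else 0.0
                   for k in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log2 = np.log2
    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        if k == ref:
            continue
        obs, refc = y[:, k], y[:, ref]
        keep = (obs > 0) & (refc > 0)
        if not keep.any():
            raise ValueError(
                f"sample {counts.columns[k]!r} shares no expressed genes with the reference"
            )
        o, r = obs[keep], refc[keep]
        m = log2((o / lib[k]) / (r / lib[ref]))
        a = 0.5 * log2((o / lib[k]) * (r / lib[ref]))
        # inverse of the asymptotic variance of M
        v = (lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not sel.any():
            continue
        f = np.sum(m[sel] / v[sel]) / np.sum(1.0 / v[sel])
        if not np.isfinite(f):
            f = 0.0
        factors[k] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_expression(
    counts: pd.DataFrame, factors: pd.Series | None = None, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2-CPM with a prior count on effective library sizes.

    value = log2((count + prior) / (libsize * factor + 2 * prior) * 1e6)
    """
    lib = counts.sum(axis=0).astype(float)
    f = pd.Series(1.0, index=counts.columns) if factors is None else factors
    eff = lib * f
    return np.log2(
        (counts + prior_count).div(eff + 2 * prior_count, axis=1) * 1e6
    )


def _check_design(design: pd.DataFrame, n_samples: int) -> np.ndarray:
    x = np.asarray(design, dtype=float)
    if x.shape[0] != n_samples:
        raise ValueError("design rows must match samples")
    if x.shape[0] <= x.shape[1]:
        raise ValueError(
            f"{x.shape[0]} samples cannot fit {x.shape[1]} design columns with residual df"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return x


def precision_weights(
    logexpr: pd.DataFrame, design: pd.DataFrame, lowess_frac: float = 0.5
) -> tuple[pd.DataFrame, pd.Series]:
    """Observation-level and sample-level precision weights.

    A gene-wise OLS fit to the design yields residual standard deviations;
    a lowess trend of sqrt(sd) against mean log-expression predicts the
    standard deviation at every fitted value, and observation weights are
    the inverse of the predicted variance (trend**-4).  Each sample's
    quality weight is the inverse of its mean squared standardized
    residual, normalized to mean 1.
    """
    y = logexpr.to_numpy(dtype=float)
    x = _check_design(design, y.shape[1])
    n, p = x.shape
    if n - p < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T                       # genes x p
    fitted = beta @ x.T                     # genes x samples
    resid = y - fitted
    s = np.sqrt((resid ** 2).sum(axis=1) / (n - p))
    mean_log = y.mean(axis=1)

    trend = lowess(np.sqrt(s), mean_log, frac=lowess_frac, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-4)
    sqrt_sd_hat = np.interp(fitted, tx, ty)   # flat extrapolation at the ends
    obs_w = sqrt_sd_hat ** -4.0

    ok = s > 0
    std_resid = resid[ok] / s[ok, None]
    msq = (std_resid ** 2).mean(axis=0)
    sw = 1.0 / np.maximum(msq, 1e-12)
    sw = sw / sw.mean()

    obs_weights = pd.DataFrame(obs_w, index=logexpr.index, columns=logexpr.columns)
    sample_weights = pd.Series(sw, index=logexpr.columns, name="sample_weight")
    return obs_weights, sample_weights


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes squeeze of gene variances toward a common prior.

    Moments estimation of the scaled-F prior (d0, s0^2) on log s^2;
    returns (d0, s0^2, posterior variances).  d0 = inf yields s0^2 for all.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.where(ok, s2, 1.0))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e[ok].mean()
    e_var = e[ok].var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        post = (d0 * s0_sq + df * s2) / (d0 + df)
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        post = np.full_like(s2, s0_sq)
    return d0, s0_sq, post


def fit_and_moderate(
    logexpr: pd.DataFrame,
    design: pd.DataFrame,
    contrasts: dict[str, pd.Series],
    obs_weights: pd.DataFrame | None = None,
    sample_weights: pd.Series | None = None,
    fdr: float = 0.05,
    lfc_threshold: float = 1.0,
    force_d0: float | None = None,
) -> pd.DataFrame:
    """Gene-wise weighted least squares with moderated t-tests per contrast.

    Returns a long table (gene, contrast, log2fc, t, p, padj, de) with
    BH adjustment within each contrast and the DE flag
    padj <= fdr AND |log2fc| >= lfc_threshold.  ``force_d0`` overrides the
    estimated prior degrees of freedom (inf gives the fully squeezed limit).
    """
    y = logexpr.to_numpy(dtype=float)
    x = _check_design(design, y.shape[1])
    n, p = x.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    genes = logexpr.index
    n_g = len(genes)

    w = np.ones_like(y)
    if obs_weights is not None:
        w = w * obs_weights.to_numpy(dtype=float)
    if sample_weights is not None:
        w = w * sample_weights.to_numpy(dtype=float)[None, :]
    if (w <= 0).any():
        raise ValueError("weights must be > 0")

    c_names = list(contrasts)
    c_mat = np.column_stack(
        [np.asarray(contrasts[name], dtype=float) for name in c_names]
    )  # p x n_contrasts
    if c_mat.shape[0] != p:
        raise ValueError("contrast length must match design columns")

    coefs = np.empty((n_g, len(c_names)))
    var_factors = np.empty((n_g, len(c_names)))
    s2 = np.empty(n_g)
    uniform_w = np.allclose(w, w[0:1, :]) if n_g else True
    xtwx_inv_cache = None
    for g in range(n_g):
        wg = w[g]
        if uniform_w and xtwx_inv_cache is not None:
            xtwx_inv = xtwx_inv_cache
        else:
            xtwx_inv = np.linalg.inv((x * wg[:, None]).T @ x)
            if uniform_w:
                xtwx_inv_cache = xtwx_inv
        beta = xtwx_inv @ (x * wg[:, None]).T @ y[g]
        r = y[g] - x @ beta
        s2[g] = float(wg @ (r ** 2)) / df_resid
        coefs[g] = c_mat.T @ beta
        var_factors[g] = np.einsum("ij,jk,ki->i", c_mat.T, xtwx_inv, c_mat)

    if force_d0 is None:
        d0, s0_sq, s2_post = moderate_variances(s2, df_resid)
    else:
        d0 = force_d0
        _, s0_sq, _ = moderate_variances(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)

    df_total = d0 + df_resid
    t_dist_df = df_total if np.isfinite(df_total) else 1e9

    frames = []
    for j, name in enumerate(c_names):
        se = np.sqrt(var_factors[:, j] * s2_post)
        tstat = coefs[:, j] / se
        pval = 2.0 * stats.t.sf(np.abs(tstat), t_dist_df)
        padj = bh_adjust(pval)
        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "contrast": name,
                    "log2fc": coefs[:, j],
                    "t": tstat,
                    "p": pval,
                    "padj": padj,
                    "de": (padj <= fdr) & (np.abs(coefs[:, j]) >= lfc_threshold),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_resid"] = df_resid
    return out


def treatment_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Cell-means design matrix: one indicator column per treatment."""
    d = pd.get_dummies(samples.set_index("sample")["treatment"]).astype(float)
    return d


def pairwise_contrasts(
    design: pd.DataFrame, pairs: list[tuple[str, str]]
) -> dict[str, pd.Series]:
    """Contrast vectors a - b over a cell-means design, named 'a_vs_b'."""
    out: dict[str, pd.Series] = {}
    for a, b in pairs:
        for t in (a, b):
            if t not in design.columns:
                raise ValueError(f"treatment {t!r} not in design")
        c = pd.Series(0.0, index=design.columns)
        c[a], c[b] = 1.0, -1.0
        out[f"{a}_vs_{b}"] = c
    return out
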