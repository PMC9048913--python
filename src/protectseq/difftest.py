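"""Negative-binomial Wald test for differential accumulation between treatments.

A deliberately small re-implementation of the DESeq2-style workflow the field
uses for protection-assay count tables: median-of-ratios size factors,
method-of-moments gene-wise dispersions shrunk toward a mean-dispersion trend,
a Wald test on the log2 ratio of group means with a delta-method standard
error from the NB variance mu + alpha*mu^2, and Benjamini-Hochberg correction.
No outlier refitting, independent filtering or fold-change shrinkage: the
downstream localization logic consumes only sign and significance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ALPHA_FLOOR = 1e-8
MU_FLOOR = 0.5  # normalized-count floor before log ratios
SHRINKAGE_WEIGHT = 0.5  # weight of the gene-wise estimate vs the fitted trend

CONTRASTS = (("R", "C", "R_vs_C"), ("TR", "C", "TR_vs_C"), ("TR", "R", "TR_vs_R"))


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios library size factors.

    s_j = median over features of K_ij / geometric-mean_i(K_i.), computed on
    features with nonzero counts in every sample. With ``pseudo_reference``
    the geometric mean ignores zeros instead (off by default).
    """
    arr = counts.to_numpy(dtype=float)
    if pseudo_reference:
        with np.errstate(divide="ignore"):
            logs = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), np.nan)
        loggeo = np.nanmean(logs, axis=1)
        keep = np.isfinite(loggeo)
    else:
        keep = (arr > 0).all(axis=1)
        if not keep.any():
            raise ValueError(
                "no feature has nonzero counts in all samples; consider the "
                "pseudo_reference=True fallback")
        loggeo = np.full(arr.shape[0], np.nan)
        loggeo[keep] = np.log(arr[keep]).mean(axis=1)
    sub = arr[keep]
    logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
    ratios = logs - loggeo[keep, None]
    s = np.exp(np.nanmedian(ratios, axis=0))
    out = pd.Series(s, index=counts.columns, name="size_factor")
    if not np.all(np.isfinite(out)) or (out <= 0).any():
        raise ValueError("degenerate size factors; check the count table")
    return out


def estimate_dispersions(
    counts: pd.DataFrame,
    s: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-feature NB dispersion: within-group method of moments, trend-shrunk.

    The gene-wise estimate alpha_i = max(0, (var - mean) / mean^2) is computed
    on normalized counts within each condition and pooled by degrees of
    freedom, then averaged (weight 0.5) with a fitted mean-dispersion trend
    alpha_tr(mu) = a0 + a1/mu. Requires >= 2 replicates in at least one group.
    """
    y = counts.div(s, axis=1)
    group_sizes = groups.value_counts()
    if (group_sizes < 2).all():
        raise ValueError("dispersion estimation requires >= 2 replicates per condition")
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for g, n_g in group_sizes.items():
        if n_g < 2:
            continue
        cols = groups.index[groups == g]
        sub = y[cols].to_numpy()
        mean_g = sub.mean(axis=1)
        var_g = sub.var(axis=1, ddof=1)
        num += (n_g - 1) * (var_g - mean_g)
        den += (n_g - 1) * mean_g ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, 0.0, None)

    base_mean = y.mean(axis=1).to_numpy()
    ok = base_mean > 0
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a0 = a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(base_mean > 0, a0 + a1 / np.maximum(base_mean, 1e-12), 0.0)
    alpha = np.maximum(ALPHA_FLOOR,
                       SHRINKAGE_WEIGHT * raw + (1 - SHRINKAGE_WEIGHT) * trend)
    out = pd.DataFrame({"alpha": alpha, "base_mean": base_mean, "alpha_raw": raw,
                        "alpha_trend": trend}, index=counts.index)
    out.attrs["trend"] = (a0, a1)
    return out


def wald_contrast(
    counts: pd.DataFrame,
    s: pd.Series,
    dispersions: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    label: str = "B_vs_A",
) -> pd.DataFrame:
    """Wald test of group B vs group A on the normalized scale.

    log2FC = log2(mu_B / mu_A) with means floored at 0.5 normalized counts;
    SE comes from the delta method on the NB variance mu + alpha*mu^2;
    p = 2(1 - Phi(|z|)). Features with all-zero counts in both groups get NA.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")
    alpha = dispersions["alpha"].to_numpy()

    def group_stats(cols):
        y = counts[cols].div(s[cols], axis=1).to_numpy()
        mu = y.mean(axis=1)
        f = np.maximum(mu, MU_FLOOR)
        inv_s = (1.0 / s[cols].to_numpy())
        var_mu = (f[:, None] * inv_s[None, :] + alpha[:, None] * f[:, None] ** 2).sum(axis=1) \
            / len(cols) ** 2
        return mu, f, var_mu

    mu_a, f_a, var_a = group_stats(group_a)
    mu_b, f_b, var_b = group_stats(group_b)
    ln2sq = np.log(2.0) ** 2
    lfc = np.log2(f_b / f_a)
    se = np.sqrt((var_a / f_a ** 2 + var_b / f_b ** 2) / ln2sq)
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = counts[list(group_a) + list(group_b)] \
        .div(s[list(group_a) + list(group_b)], axis=1).mean(axis=1).to_numpy()

    res = pd.DataFrame({
        "baseMean": base_mean, "log2FC": lfc, "SE": se, "z": z, "p": p,
    }, index=counts.index)
    allzero = (counts[list(group_a) + list(group_b)].sum(axis=1) == 0).to_numpy()
    res.loc[allzero, ["log2FC", "SE", "z", "p"]] = np.nan
    res["padj"] = bh_adjust(res["p"])
    res.attrs["contrast"] = label
    return res


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NA entries are excluded
    from the number of tests and stay NA."""
    p = np.asarray(pvalues, dtype=float)
    padj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m:
        pv = p[ok]
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        padj[ok] = adj
    if isinstance(pvalues, pd.Series):
        return pd.Series(padj, index=pvalues.index, name="padj")
    return padj


def run_contrasts(
    counts: pd.DataFrame,
    samplesheet: pd.DataFrame,
    contrasts=CONTRASTS,
) -> dict[str, pd.DataFrame]:
    """Size factors + dispersions + the standard treatment contrasts.

    ``samplesheet`` needs columns sample_id / treatment; contrast labels follow
    the B_vs_A convention (log2FC > 0 means more abundant in B).
    """
    groups = samplesheet.set_index("sample_id")["treatment"]
    s = size_factors(counts)
    disp = estimate_dispersions(counts, s, groups)
    out = {}
    for b, a, label in [(c[0], c[1], c[2]) for c in contrasts]:
        cols_a = list(groups.index[groups == a])
        cols_b = list(groups.index[groups == b])
        out[label] = wald_contrast(counts, s, disp, cols_a, cols_b, label)
    return out
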