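"""Bulk moderated-t contrasts, preranked GSEA, and paired DSP segment
analysis (Q3 normalization, paired t per gene, hierarchical clustering)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .containers import PairedSegmentsMatrix
from .scoring import GeneSetCollection


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < tol:
            break
    return float(x)


@dataclass
class ModeratedTResult:
    table: pd.DataFrame  # per gene: log2fc, t_ord, t_mod, df, p_raw, p_adj
    d0: float  # prior degrees of freedom
    s0_sq: float  # prior variance


def estimate_variance_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the spread of log sample variances.

    Under the hierarchical model s2_g ~ s0^2 * F(d_g, d0), log s2_g has
    excess variance trigamma(d0/2) beyond trigamma(d_g/2); inverting the
    trigamma recovers d0, and the mean recovers s0^2.  Non-positive excess
    variance yields d0 = inf (all variances shrunk fully to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    e = np.log(s2[ok])
    e_adj = e - digamma(d_g / 2.0) + np.log(d_g / 2.0)
    emean = e_adj.mean()
    evar = e_adj.var(ddof=1) - float(_trigamma(d_g / 2.0))
    if evar <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    expr: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    d0_override: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-group t test per gene.

    ``expr`` is genes x samples (log scale assumed); ``groups`` labels each
    sample with one of exactly two values.  Residual variances are shrunk
    toward the moment-matched prior: s2_post = (d0*s0^2 + d_g*s2_g)/(d0+d_g),
    and the moderated t is referred to a t distribution on d0 + d_g df.
    ``d0_override`` fixes the prior df (0 recovers the ordinary t exactly).
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"exactly 2 group labels required, got {list(labels)}")
    m1 = groups == labels[0]
    m2 = groups == labels[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples (zero residual df)")
    X = expr.to_numpy(dtype=float)
    mean1 = X[:, m1].mean(axis=1)
    mean2 = X[:, m2].mean(axis=1)
    diff = mean2 - mean1  # second label minus first
    d_g = n1 + n2 - 2
    ss = X[:, m1].var(axis=1, ddof=1) * (n1 - 1) + X[:, m2].var(axis=1, ddof=1) * (
        n2 - 1
    )
    s2 = ss / d_g
    stderr_unit = np.sqrt(1.0 / n1 + 1.0 / n2)

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = estimate_variance_prior(s2, d_g)
    else:
        d0, s0_sq = estimate_variance_prior(s2, d_g)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = float(d_g)
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = float(d0 + d_g)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = diff / (np.sqrt(s2) * stderr_unit)
        t_mod = diff / (np.sqrt(s2_post) * stderr_unit)
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "log2fc": diff,
            "t_ordinary": t_ord,
            "t_moderated": t_mod,
            "s2": s2,
            "s2_post": s2_post,
            "df": df_total,
            "p_raw": p_raw,
            "p_adj": p_adj,
        },
        index=expr.index,
    )
    return ModeratedTResult(table, d0=float(d0), s0_sq=float(s0_sq))


# ---------------------------------------------------------------------------
# DSP segments


def q3_normalize(
    segments: PairedSegmentsMatrix,
) -> tuple[PairedSegmentsMatrix, pd.Series]:
    """Scale each AOI so its 75th percentile matches the geometric mean of
    all AOI 75th percentiles; returns the scaled matrix and the factors."""
    vals = segments.values
    q3 = vals.quantile(0.75, axis=0)
    if (vals.sum(axis=0) == 0).any():
        bad = vals.columns[vals.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero AOIs: {bad}")
    if (q3 <= 0).any():
        bad = q3.index[q3 <= 0].tolist()
        raise ValueError(f"non-positive Q3 for AOIs: {bad}")
    anchor = np.exp(np.log(q3).mean())
    factors = anchor / q3
    scaled = vals * factors
    return PairedSegmentsMatrix(scaled, segments.annotations.copy()), factors.rename(
        "scale_factor"
    )


def paired_t_per_gene(
    segments: PairedSegmentsMatrix, log_transform: bool = True
) -> pd.DataFrame:
    """Paired t of vim_pos - vim_neg per gene across ROIs.

    Values are log2(x+1)-transformed by default.  Genes with identically
    zero differences report t = 0, p = 1.  Returns per-gene t, p_raw, p_adj,
    mean_diff, and the signed -log10(p) ranking metric used for GSEA.
    """
    pos = segments.segment_columns("vim_pos").to_numpy(dtype=float)
    neg = segments.segment_columns("vim_neg").to_numpy(dtype=float)
    n = pos.shape[1]
    if n < 3:
        raise ValueError("need >= 3 complete ROI pairs")
    if log_transform:
        pos = np.log2(pos + 1.0)
        neg = np.log2(neg + 1.0)
    d = pos - neg
    mean_d = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    zero = sd == 0
    t = np.where(zero & (mean_d == 0), 0.0, t)
    p = np.where(zero & (mean_d == 0), 1.0, p)
    # nonzero constant difference: infinitely precise under this model
    p = np.where(zero & (mean_d != 0), 0.0, p)
    p_adj = multipletests(np.clip(p, 0, 1), method="fdr_bh")[1]
    with np.errstate(divide="ignore"):
        metric = -np.log10(np.clip(p, 1e-300, None)) * np.sign(mean_d)
    return pd.DataFrame(
        {
            "mean_diff": mean_d,
            "t": t,
            "p_raw": p,
            "p_adj": p_adj,
            "rank_metric": metric,
        },
        index=segments.values.index,
    )


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class GSEAResult:
    table: pd.DataFrame  # per set: es, nes, p_nominal, q, n_matched
    leading_edge: dict[str, list[str]] = field(default_factory=dict)
    n_permutations: int = 0
    seed: int = 0
    skipped_sets: list[str] = field(default_factory=list)


def _gsea_es(metric_sorted: np.ndarray, in_set: np.ndarray, exponent: float) -> tuple[float, int]:
    """Weighted KS enrichment score on a pre-sorted ranking.

    Returns (ES, index of the extremum) — ES is the maximum running-sum
    deviation by absolute value, signed.
    """
    w = np.abs(metric_sorted) ** exponent
    w_hit = np.where(in_set, w, 0.0)
    nr = w_hit.sum()
    n_miss = len(in_set) - in_set.sum()
    if nr == 0 or n_miss == 0:
        return 0.0, 0
    steps = w_hit / nr - (~in_set) / n_miss
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_gsea(
    ranking: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 5,
) -> GSEAResult:
    """Preranked GSEA with gene-label permutations.

    NES = ES / mean |permuted ES| of matching sign; nominal p from the
    same-sign permutation tail with the +1 correction; q is the BH
    adjustment of the nominal p across tested sets (stable for the small
    set collections this pipeline tests; see docs).  Deterministic given
    ``seed``.  Sets with fewer than ``min_size`` matched genes are skipped.
    """
    ranking = ranking.dropna()
    if len(ranking) < 10:
        raise ValueError("ranking needs >= 10 genes")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes_sorted = ranking.index.to_numpy()
    metric_sorted = ranking.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    G = len(genes_sorted)
    rng = np.random.default_rng(seed)

    rows = []
    leading: dict[str, list[str]] = {}
    skipped: list[str] = []
    for name, gl in sets.items():
        pos = [gene_pos[g] for g in gl if g in gene_pos]
        if len(pos) < min_size:
            skipped.append(name)
            warnings.warn(
                f"set {name!r} has {len(pos)} matched genes (< {min_size}); skipped",
                stacklevel=2,
            )
            continue
        m = len(pos)
        in_set = np.zeros(G, dtype=bool)
        in_set[pos] = True
        es, i_ext = _gsea_es(metric_sorted, in_set, weight_exponent)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(G, dtype=bool)
            perm[rng.choice(G, size=m, replace=False)] = True
            null[b], _ = _gsea_es(metric_sorted, perm, weight_exponent)

        same_sign = null[null * es >= 0] if es != 0 else null
        if es >= 0:
            p_nom = (1.0 + np.sum(null >= es)) / (1.0 + n_perm)
            denom = np.mean(np.abs(null[null >= 0])) if (null >= 0).any() else np.nan
        else:
            p_nom = (1.0 + np.sum(null <= es)) / (1.0 + n_perm)
            denom = np.mean(np.abs(null[null < 0])) if (null < 0).any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan

        if es >= 0:
            le = [g for g in genes_sorted[: i_ext + 1] if in_set[gene_pos[g]]]
        else:
            le = [g for g in genes_sorted[i_ext:] if in_set[gene_pos[g]]]
        leading[name] = le
        rows.append(
            {"set": name, "es": es, "nes": nes, "p_nominal": p_nom, "n_matched": m}
        )

    if not rows:
        raise ValueError("no gene set had enough matched genes")
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = multipletests(table["p_nominal"].to_numpy(), method="fdr_bh")[1]
    return GSEAResult(table, leading, n_permutations=n_perm, seed=seed, skipped_sets=skipped)


def hier_cluster(
    matrix: pd.DataFrame, linkage_method: str = "average"
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage clustering of columns on 1 - Pearson correlation.

    Returns ``(linkage_matrix, leaf_order)``.  Constant columns make the
    correlation undefined and raise, naming the column.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 columns")
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = matrix.columns[sd == 0].tolist()
        raise ValueError(f"constant columns (undefined correlation): {bad}")
    corr = np.corrcoef(X.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    order = hierarchy.leaves_list(Z)
    return Z, [matrix.columns[i] for i in order]
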