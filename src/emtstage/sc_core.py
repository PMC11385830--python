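"""Single-cell preprocessing: QC, gene filtering, normalization, HVGs, PCA,
and shared-nearest-neighbor graph clustering.

QC outlier cuts are MAD-based and one-sided: lower tail for log1p library
size and log1p detected genes, upper tail for mitochondrial percentage, with
the 1.4826 normal-consistency constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormalizedMatrix

MAD_CONSTANT = 1.4826


def compute_qc_metrics(
    counts: CountMatrix, mito_flags: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-cell library size, detected-gene count, and mito percentage.

    Cells with zero total counts get ``mito_pct = 0`` by convention.
    """
    if mito_flags is None:
        mito_flags = counts.mito_flags()
    mito_flags = np.asarray(mito_flags, dtype=bool)
    if mito_flags.shape[0] != counts.n_genes:
        raise ValueError(
            f"mito_flags length {mito_flags.shape[0]} != n_genes {counts.n_genes}"
        )
    X = counts.X.tocsc()
    library_size = np.asarray(X.sum(axis=0)).ravel()
    n_detected = np.asarray((X > 0).sum(axis=0)).ravel()
    mito_counts = np.asarray(X[mito_flags, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(library_size > 0, 100.0 * mito_counts / library_size, 0.0)
    return pd.DataFrame(
        {
            "library_size": library_size.astype(np.int64),
            "n_detected": n_detected.astype(np.int64),
            "mito_pct": mito_pct,
        },
        index=counts.cells,
    )


def _mad(x: np.ndarray) -> float:
    med = np.median(x)
    return MAD_CONSTANT * np.median(np.abs(x - med))


def flag_outliers_mad(
    metrics: pd.DataFrame,
    k_libsize: float = 5.0,
    k_detected: float = 5.0,
    k_mito: float = 3.0,
) -> tuple[pd.Series, dict[str, float]]:
    """Keep/drop flags from one-sided MAD cuts on the QC metrics.

    A cell is dropped iff its log1p library size or log1p detected genes
    falls below ``median - k * MAD``, or its mito% rises above
    ``median + k * MAD``.  Returns ``(keep, thresholds)``.
    """
    if len(metrics) < 3:
        raise ValueError("need >= 3 cells for MAD-based QC")
    log_lib = np.log1p(metrics["library_size"].to_numpy(dtype=float))
    log_det = np.log1p(metrics["n_detected"].to_numpy(dtype=float))
    mito = metrics["mito_pct"].to_numpy(dtype=float)

    thr = {
        "log1p_library_size_min": float(np.median(log_lib) - k_libsize * _mad(log_lib)),
        "log1p_n_detected_min": float(np.median(log_det) - k_detected * _mad(log_det)),
        "mito_pct_max": float(np.median(mito) + k_mito * _mad(mito)),
    }
    keep = (
        (log_lib >= thr["log1p_library_size_min"])
        & (log_det >= thr["log1p_n_detected_min"])
        & (mito <= thr["mito_pct_max"])
    )
    if not keep.any():
        raise ValueError("QC dropped every cell; review MAD thresholds")
    return pd.Series(keep, index=metrics.index, name="keep"), thr


def filter_genes_min_cells(counts: CountMatrix, min_cells: int = 6) -> CountMatrix:
    """Keep genes expressed (count > 0) in at least ``min_cells`` cells.

    The default 6 encodes "expressed in more than five cells".
    """
    n_expressing = np.asarray((counts.X > 0).sum(axis=1)).ravel()
    mask = n_expressing >= min_cells
    if not mask.any():
        warnings.warn("gene filter removed every gene", stacklevel=2)
    return counts.subset(gene_mask=mask)


def normalize_log(counts: CountMatrix, target_sum: float = 1e4) -> NormalizedMatrix:
    """log2 CP-``target_sum`` normalization: log2(1 + c * target / libsize)."""
    lib = np.asarray(counts.X.sum(axis=0)).ravel().astype(float)
    if (lib == 0).any():
        bad = counts.cells[lib == 0].tolist()
        raise ValueError(f"zero-library cells present (should be QC'd): {bad[:5]}")
    dense = counts.X.toarray().astype(float)
    vals = np.log2(1.0 + dense * (target_sum / lib)[None, :])
    return NormalizedMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.cells),
        target_sum=target_sum,
    )


def pearson_residual_normalize(
    counts: CountMatrix, theta: float = 100.0
) -> pd.DataFrame:
    """Analytic Pearson residuals (fixed theta), offered for sensitivity
    analysis next to the default log2 CP10K transform.

    Residuals are clipped at sqrt(n_cells); returned as a plain DataFrame
    (can be negative, so not a NormalizedMatrix).
    """
    X = counts.X.toarray().astype(float)
    lib = X.sum(axis=0)
    gene_tot = X.sum(axis=1)
    total = X.sum()
    mu = np.outer(gene_tot, lib) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        res = (X - mu) / np.sqrt(mu + mu**2 / theta)
    res = np.nan_to_num(res)
    clip = np.sqrt(counts.n_cells)
    return pd.DataFrame(
        np.clip(res, -clip, clip), index=counts.genes, columns=counts.cells
    )


def select_hvg(norm: NormalizedMatrix, n_top: int = 3000) -> list[str]:
    """Top-``n_top`` genes by variance in excess of the mean-variance trend.

    The trend is a rolling median of per-gene variance over genes ordered by
    mean; the standardized variance is the residual from that trend.  Ties
    break lexicographically by gene id for determinism.
    """
    if n_top > len(norm.genes):
        raise ValueError(f"n_top={n_top} exceeds n_genes={len(norm.genes)}")
    vals = norm.values.to_numpy()
    mean = vals.mean(axis=1)
    var = vals.var(axis=1, ddof=1) if vals.shape[1] > 1 else np.zeros(len(mean))

    order = np.argsort(mean, kind="stable")
    window = min(201, 2 * (len(mean) // 4) + 1)
    trend_sorted = (
        pd.Series(var[order]).rolling(window, center=True, min_periods=1).median()
    )
    trend = np.empty_like(var)
    trend[order] = trend_sorted.to_numpy()
    std_var = var - trend
    std_var[var == 0] = -np.inf  # constant genes never selected before varying ones

    rank_df = pd.DataFrame({"std_var": std_var}, index=norm.genes)
    rank_df = rank_df.sort_values(["std_var"], ascending=False, kind="stable")
    # lexicographic tie-break
    rank_df = (
        rank_df.reset_index()
        .sort_values(["std_var", "gene"], ascending=[False, True], kind="stable")
        .set_index("gene")
    )
    return rank_df.index[:n_top].tolist()


def pca_embed(
    norm: NormalizedMatrix | pd.DataFrame,
    hvgs: list[str],
    n_pcs: int = 13,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the centered, unit-scaled HVG submatrix.

    Returns ``(embedding, explained_variance, loadings)`` with the embedding
    cells x n_pcs, loadings genes x n_pcs, components ordered by decreasing
    explained variance, and each component's sign fixed so its
    largest-magnitude gene loading is positive.  ``seed`` is accepted for
    interface symmetry; the exact SVD is deterministic.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    sub = values.loc[hvgs].to_numpy().T  # cells x genes
    n_cells, n_genes_ = sub.shape
    if n_pcs > min(n_cells, n_genes_):
        raise ValueError(
            f"n_pcs={n_pcs} must be <= min(n_cells, n_hvgs)={min(n_cells, n_genes_)}"
        )
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    tol = S.max() * max(Z.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int((S > tol).sum())
    if rank < n_pcs:
        raise ValueError(f"matrix rank {rank} < requested n_pcs {n_pcs}")
    # deterministic sign: largest-|loading| positive per component
    for j in range(n_pcs):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    emb = U[:, :n_pcs] * S[:n_pcs]
    explained = (S[:n_pcs] ** 2) / (n_cells - 1)
    return emb, explained, Vt[:n_pcs].T


def knn_cluster(
    embedding: np.ndarray, k: int = 20, resolution: float = 1.0, seed: int = 0
) -> pd.Series | np.ndarray:
    """Shared-nearest-neighbor graph + Leiden modularity communities.

    Edge weights are Jaccard overlaps of k-NN neighborhoods; labels are
    contiguous integers from 1, deterministic given the seed.
    """
    import igraph as ig
    import leidenalg
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = [set(row[1:]) | {i} for i, row in enumerate(idx)]

    edges, weights = [], []
    for i in range(n):
        for j in idx[i, 1:]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w > 0:
                edges.append((i, j))
                weights.append(w)

    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    labels = np.asarray(part.membership) + 1
    return labels
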