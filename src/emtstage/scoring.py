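"""Per-cell gene-set scoring, stage trends, weighted EMT score, and the
2^-ddCt fold-change utility."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedMatrix


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (e.g. the 50 hallmark signatures)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        # duplicate names are impossible in a dict; guarded at parse time

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class ScoreMatrix:
    """Gene-set x cell enrichment scores.

    ``nes`` is ``es`` rescaled by the global max |ES| so values lie in
    [-1, 1] and signs are preserved (range normalization; the method tag
    records this).
    """

    es: pd.DataFrame
    nes: pd.DataFrame
    normalization: str = "range_max_abs"
    coverage: dict[str, float] = field(default_factory=dict)
    skipped_sets: list[str] = field(default_factory=list)


def _cell_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Ranking order per cell: expression descending, ties by gene id."""
    # lexsort: last key primary
    return np.lexsort((gene_ids, -values))


def ssgsea_cell_scores(
    norm: NormalizedMatrix | pd.DataFrame,
    sets: GeneSetCollection,
    weight_exponent: float = 0.25,
) -> ScoreMatrix:
    """Single-sample rank-based enrichment score per (set, cell).

    For each cell, genes are ranked by expression (descending, ties broken
    lexicographically).  The score is the summed difference between the
    weighted in-set empirical CDF (weight = rank-from-bottom ** exponent)
    and the uniform out-of-set CDF — the classic single-sample running-sum
    integral.  Sets with fewer than two matched genes are skipped and named
    in ``skipped_sets``.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    genes = values.index.to_numpy()
    G = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    X = values.to_numpy()
    n_cells = X.shape[1]

    members: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    skipped: list[str] = []
    for name, gl in sets.items():
        matched = [gene_pos[g] for g in gl if g in gene_pos]
        coverage[name] = len(matched) / len(gl)
        if len(matched) < 2:
            skipped.append(name)
            warnings.warn(
                f"gene set {name!r} has {len(matched)} matched genes; skipped",
                stacklevel=2,
            )
            continue
        mask = np.zeros(G, dtype=bool)
        mask[matched] = True
        members[name] = mask

    if not members:
        raise ValueError("no gene set has >= 2 matched genes")

    gene_codes = np.argsort(np.argsort(genes))  # lexicographic codes
    rank_from_top = np.arange(1, G + 1)
    w_all = (G - rank_from_top + 1).astype(float) ** weight_exponent

    es = np.zeros((len(members), n_cells))
    set_names = list(members)
    for c in range(n_cells):
        order = np.lexsort((gene_codes, -X[:, c]))
        for s_i, name in enumerate(set_names):
            in_set = members[name][order]
            w = np.where(in_set, w_all, 0.0)
            cdf_in = np.cumsum(w) / w.sum()
            n_out = G - in_set.sum()
            cdf_out = np.cumsum(~in_set) / n_out
            es[s_i, c] = np.sum(cdf_in - cdf_out)

    es_df = pd.DataFrame(es, index=pd.Index(set_names, name="set"), columns=values.columns)
    max_abs = np.abs(es).max()
    nes_df = es_df / max_abs if max_abs > 0 else es_df.copy()
    return ScoreMatrix(es_df, nes_df, coverage=coverage, skipped_sets=skipped)


def stratum_median_nes(scores: ScoreMatrix, assign) -> pd.DataFrame:
    """Median NES per (gene set, stage); empty stages are NaN, not zero."""
    stages = assign.labels
    out = {}
    for stage in assign.stage_order:
        cells = assign.cells_in(stage)
        cells = cells.intersection(scores.nes.columns)
        out[stage] = scores.nes[cells].median(axis=1) if len(cells) else np.nan
    return pd.DataFrame(out, index=scores.nes.index)


def spearman_trend(
    scores: ScoreMatrix, assign, by_stage_median: bool = False
) -> pd.DataFrame:
    """Spearman rho of enrichment against ordinal stage, sorted descending.

    Default correlates per-cell NES with each cell's stage index (average
    ranks for ties); ``by_stage_median`` instead correlates the per-stage
    medians with stage order, a sensitivity variant.
    """
    idx = assign.stage_indices()
    populated = idx.nunique()
    if populated < 2:
        raise ValueError("need >= 2 populated stages for a trend")
    medians = stratum_median_nes(scores, assign)

    rows = []
    for name in scores.nes.index:
        if by_stage_median:
            med = medians.loc[name].dropna()
            stage_pos = [assign.stage_order.index(s) + 1 for s in med.index]
            rho, p = stats.spearmanr(stage_pos, med.to_numpy())
        else:
            common = idx.index.intersection(scores.nes.columns)
            rho, p = stats.spearmanr(
                idx.loc[common].to_numpy(), scores.nes.loc[name, common].to_numpy()
            )
        rows.append({"set": name, "rho": rho, "p": p})
    trend = pd.DataFrame(rows).set_index("set")
    trend = trend.join(medians)
    return trend.sort_values("rho", ascending=False)


def emt_score_weighted(
    norm: NormalizedMatrix | pd.DataFrame, weights: pd.Series
) -> pd.Series:
    """Weighted-sum EMT score per cell, centered to a grand mean of zero.

    Signature genes absent from the matrix are imputed at zero expression
    (with a coverage warning); negative centered scores read as mesenchymal,
    positive as epithelial.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    if weights.index.has_duplicates:
        raise ValueError("duplicate genes in weight table")
    if (weights == 0).all():
        raise ValueError("all weights are zero")
    present = weights.index.intersection(values.index)
    if len(present) == 0:
        raise ValueError("no weight genes present in matrix")
    if len(present) < len(weights):
        warnings.warn(
            f"{len(weights) - len(present)} of {len(weights)} signature genes "
            "absent; imputed as zero expression",
            stacklevel=2,
        )
    raw = values.loc[present].mul(weights.loc[present], axis=0).sum(axis=0)
    centered = raw - raw.mean()
    centered.name = "emt_score"
    return centered


def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    baseline_sample: str,
) -> pd.Series:
    """2^-ddCt relative quantification.

    ``ct`` is long-form with columns ``sample``, ``gene``, ``ct``.  Per
    sample, dCt = Ct(target) - Ct(reference); ddCt subtracts the baseline
    sample's dCt; fold = 2**(-ddCt), so the baseline fold is exactly 1.
    """
    wide = ct.pivot_table(index="sample", columns="gene", values="ct", aggfunc="first")
    for g in (target_gene, reference_gene):
        if g not in wide.columns:
            raise ValueError(f"gene {g!r} missing from Ct table")
    if baseline_sample not in wide.index:
        raise ValueError(f"baseline sample {baseline_sample!r} missing")
    missing_ref = wide.index[wide[reference_gene].isna()].tolist()
    if missing_ref:
        raise ValueError(f"missing reference-gene Ct for samples: {missing_ref}")
    if not np.isfinite(wide[[target_gene, reference_gene]].to_numpy()).all():
        raise ValueError("non-finite Ct values present")
    dct = wide[target_gene] - wide[reference_gene]
    ddct = dct - dct.loc[baseline_sample]
    fold = 2.0 ** (-ddct)
    fold.name = "fold_change"
    return fold
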