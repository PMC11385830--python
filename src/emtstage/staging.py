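"""Ordinal EMT staging by marker expression and per-stratum upregulation.

Cells are binned into half-open ``(a, b]`` strata of log2-normalized marker
expression ("VIM 0-1" ... "VIM 5-6"), contrasted against a reference stratum
by a Wilcoxon rank-sum test, and transcription factors are classified by the
earliest stratum of significant upregulation and whether that upregulation
persists through all later strata.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix


def bin_index(x: float, bin_width: float = 1.0, n_bins: int = 6) -> int:
    """Half-open (a, b] bin of ``x``: ceil(x / width), clamped to [1, n_bins].

    ``x = 0`` falls in bin 1; values above the top edge clamp to ``n_bins``.
    """
    i = math.ceil(x / bin_width)
    return min(max(i, 1), n_bins)


def stage_label(i: int, marker: str = "VIM", bin_width: float = 1.0) -> str:
    lo = (i - 1) * bin_width
    hi = i * bin_width
    fmt = lambda v: f"{v:g}"
    return f"{marker} {fmt(lo)}-{fmt(hi)}"


@dataclass
class StratumAssignment:
    """Per-cell ordinal stage labels derived from one marker gene."""

    labels: pd.Series  # ordered categorical, indexed by cell
    marker: str
    marker_values: pd.Series
    stage_order: list[str]

    def stage_indices(self) -> pd.Series:
        """1-based ordinal index of each cell's stage."""
        mapping = {s: i + 1 for i, s in enumerate(self.stage_order)}
        return self.labels.map(mapping).astype(int)

    def cells_in(self, stage: str) -> pd.Index:
        return self.labels.index[self.labels == stage]


def stratify_by_marker(
    norm: NormalizedMatrix,
    marker: str = "VIM",
    bin_width: float = 1.0,
    n_bins: int = 6,
    exclude_zero: bool = False,
) -> StratumAssignment:
    """Assign each cell to a marker-expression stratum.

    ``exclude_zero=True`` drops cells with zero marker expression (the strict
    reading of the "0 < x <= 1" bin definition); by default they join the
    lowest stratum so the reference group retains epithelial cells.
    """
    if marker not in norm.genes:
        raise KeyError(f"marker gene {marker!r} absent from matrix")
    x = norm.values.loc[marker]
    if exclude_zero:
        x = x[x > 0]
    order = [stage_label(i, marker, bin_width) for i in range(1, n_bins + 1)]
    labels = pd.Series(
        [stage_label(bin_index(v, bin_width, n_bins), marker, bin_width) for v in x],
        index=x.index,
        name="stage",
    )
    labels = pd.Series(
        pd.Categorical(labels, categories=order, ordered=True), index=x.index, name="stage"
    )
    return StratumAssignment(labels, marker, x.copy(), order)


def default_survival_scheme(base_order: list[str]) -> list[list[str]]:
    """Merge the two lowest strata (e.g. VIM 0-1 + VIM 1-2 -> VIM 0-2)."""
    return [base_order[:2]] + [[s] for s in base_order[2:]]


def _merged_label(group: list[str], marker: str) -> str:
    if len(group) == 1:
        return group[0]
    lo = group[0].rsplit(" ", 1)[1].split("-")[0]
    hi = group[-1].rsplit(" ", 1)[1].split("-")[1]
    return f"{marker} {lo}-{hi}"


def regroup_strata(
    assign: StratumAssignment, scheme: list[list[str]] | None = None
) -> StratumAssignment:
    """Merge consecutive strata into coarser ordinal groups.

    ``scheme`` is a list of lists of base labels partitioning the full base
    order; the default merges the two lowest strata.
    """
    if scheme is None:
        scheme = default_survival_scheme(assign.stage_order)
    flat = [s for grp in scheme for s in grp]
    if sorted(flat) != sorted(assign.stage_order) or len(flat) != len(set(flat)):
        raise ValueError(
            "scheme must cover every base stratum exactly once; "
            f"got {flat} vs {assign.stage_order}"
        )
    new_order = [_merged_label(grp, assign.marker) for grp in scheme]
    mapping = {s: _merged_label(grp, assign.marker) for grp in scheme for s in grp}
    labels = assign.labels.map(mapping)
    labels = pd.Series(
        pd.Categorical(labels, categories=new_order, ordered=True),
        index=assign.labels.index,
        name="stage",
    )
    return StratumAssignment(labels, assign.marker, assign.marker_values, new_order)


# ---------------------------------------------------------------------------
# rank-sum differential expression


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    idx = range(len(pooled))
    ws = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(idx, n_a)]
    )
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_ranksum_p(values: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorized two-sided normal-approximation rank-sum p per gene (rows).

    Ties corrected; continuity correction of 0.5 applied.
    """
    n = values.shape[1]
    n_b = n - n_a
    ranks = stats.rankdata(values, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    mu = n_a * (n + 1) / 2.0
    # tie correction: sum of (t^3 - t) over tie groups, per gene
    tie_term = np.zeros(values.shape[0])
    for g in range(values.shape[0]):
        _, t = np.unique(values[g], return_counts=True)
        tie_term[g] = np.sum(t**3 - t)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(w - mu) - 0.5) / sd
        z = np.clip(z, 0, None)
        p = 2.0 * stats.norm.sf(z)
    p = np.where(sd == 0, 1.0, p)
    return np.minimum(p, 1.0)


def de_rank_sum(
    norm: NormalizedMatrix,
    cells_a,
    cells_b,
    pseudo: float = 1e-9,
    contrast: str = "",
    exact_max: int = 8,
) -> pd.DataFrame:
    """Per-gene rank-sum test of group A vs group B with log2 fold changes.

    Exact enumeration when both groups have <= ``exact_max`` members, normal
    approximation with tie and continuity correction otherwise.  log2FC uses
    de-logged means (``2**x - 1``) with a pseudocount.  p values are BH
    adjusted across genes.
    """
    cells_a = pd.Index(cells_a)
    cells_b = pd.Index(cells_b)
    if len(cells_a.intersection(cells_b)) > 0:
        raise ValueError("cell sets overlap")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("each group needs >= 3 cells")

    A = norm.values[cells_a].to_numpy()
    B = norm.values[cells_b].to_numpy()
    pooled = np.hstack([A, B])

    if len(cells_a) <= exact_max and len(cells_b) <= exact_max:
        p_raw = np.array(
            [_exact_ranksum_p(A[g], B[g]) for g in range(pooled.shape[0])]
        )
    else:
        p_raw = _normal_ranksum_p(pooled, len(cells_a))

    mean_a = (2.0**A - 1.0).mean(axis=1)
    mean_b = (2.0**B - 1.0).mean(axis=1)
    log2fc = np.log2((mean_a + pseudo) / (mean_b + pseudo))
    p_adj = multipletests(p_raw, method="fdr_bh")[1]

    df = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
            "contrast": contrast,
        },
        index=norm.genes,
    )
    return df


def de_by_stage(
    norm: NormalizedMatrix,
    assign: StratumAssignment,
    reference: str | None = None,
    pseudo: float = 1e-9,
    min_cells: int = 3,
) -> dict[str, pd.DataFrame]:
    """Rank-sum DEG tables for every non-reference stage vs the reference."""
    reference = reference or assign.stage_order[0]
    if reference not in assign.stage_order:
        raise ValueError(f"reference stage {reference!r} not in {assign.stage_order}")
    ref_cells = assign.cells_in(reference)
    out: dict[str, pd.DataFrame] = {}
    for stage in assign.stage_order:
        if stage == reference:
            continue
        cells = assign.cells_in(stage)
        if len(cells) < min_cells or len(ref_cells) < min_cells:
            continue
        out[stage] = de_rank_sum(
            norm, cells, ref_cells, pseudo=pseudo, contrast=f"{stage} vs {reference}"
        )
    return out


def classify_tf_onset(
    degs_by_stage: dict[str, pd.DataFrame],
    tf_list,
    stage_order: list[str] | None = None,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    use_raw_p: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Earliest significant-upregulation stage and persistence per TF.

    Returns ``(onset_table, skipped_genes)``.  A TF's onset is the earliest
    stage with ``p < alpha`` (BH-adjusted by default; ``use_raw_p`` for the
    permissive reading) and ``log2fc >= min_lfc``; it is persistent iff every
    stage at or above onset is significant.  Rows are sorted by onset stage
    then gene id — the bubble-plot ordering.
    """
    if stage_order is None:
        stage_order = list(degs_by_stage)
    missing = [s for s in stage_order if s not in degs_by_stage]
    if missing:
        raise ValueError(f"missing contrasts for stages: {missing}")

    pcol = "p_raw" if use_raw_p else "p_adj"
    rows = []
    skipped: list[str] = []
    for tf in tf_list:
        if not any(tf in degs_by_stage[s].index for s in stage_order):
            skipped.append(tf)
            continue
        sig = []
        per_stage: dict[str, float] = {}
        for s in stage_order:
            tab = degs_by_stage[s]
            if tf in tab.index:
                row = tab.loc[tf]
                ok = bool(row[pcol] < alpha and row["log2fc"] >= min_lfc)
                per_stage[f"log2fc[{s}]"] = row["log2fc"]
                per_stage[f"p_adj[{s}]"] = row["p_adj"]
            else:
                ok = False
                per_stage[f"log2fc[{s}]"] = np.nan
                per_stage[f"p_adj[{s}]"] = np.nan
            sig.append(ok)
        if any(sig):
            onset_i = sig.index(True)
            onset = stage_order[onset_i]
            persistent = all(sig[onset_i:])
        else:
            onset, persistent = None, None
        rows.append(
            {"gene": tf, "onset_stage": onset, "persistent": persistent, **per_stage}
        )

    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["onset_stage", "persistent"]
    )
    if len(table):
        order_key = {s: i for i, s in enumerate(stage_order)}
        tmp = table.reset_index()
        tmp["_k"] = tmp["onset_stage"].map(order_key)
        tmp = tmp.sort_values(["_k", "gene"], na_position="last").drop(columns="_k")
        table = tmp.set_index("gene")
    return table, skipped
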