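"""Synthetic data generators with ground truth.

Four generators emulate the statistical structure the analysis assumes:

* :func:`simulate_emt_continuum` — single cells along a latent EMT axis
  ``u in [0, 1]`` with a monotonically rising mesenchymal marker, falling
  epithelial markers, and step-like TF activations that persist once on.
* :func:`simulate_bulk_groups` — two labeled bulk groups with a configurable
  fraction of shifted genes.
* :func:`simulate_survival_cohort` — expression plus exponential event times
  whose hazard depends on a latent signature activity.
* :func:`simulate_dsp_rois` — paired Vim+/Vim- segments sharing an ROI
  random effect.

Counts are negative binomial parameterized by (mean, dispersion theta) with
variance ``mu + mu**2 / theta``.  Per-gene log2 means are on the
``log2(1 + mean count)`` scale, so after log2 CP10K normalization (library
sizes are calibrated to the normalization target) the expected normalized
marker value tracks the configured profile — which is what the downstream
stage bins require.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, PairedSegmentsMatrix
from .staging import bin_index, stage_label

DEFAULT_MARKER_PROFILE: dict[str, tuple[float, float]] = {
    "VIM": (0.0, 6.0),
    "CDH1": (6.0, 0.0),
    "EPCAM": (6.0, 0.0),
}


@dataclass
class EMTSimConfig:
    """Configuration of the EMT-continuum single-cell generator.

    ``marker_profile`` maps a marker gene to ``(start, end)`` mean log2
    expression, interpolated linearly in the latent state ``u``.
    ``tf_onsets`` maps a TF gene to ``(onset, amplitude)``: its mean log2
    expression is ``tf_baseline + amplitude * 1[u >= onset]``.
    """

    n_cells: int = 1000
    n_genes: int = 500
    latent_distribution: str = "uniform"  # or "mixture"
    mixture_weights: tuple[float, float] = (0.5, 0.5)  # (epithelial, mesenchymal)
    marker_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PROFILE)
    )
    tf_onsets: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    tf_baseline: float = 1.0
    tf_sigmoid_steepness: float | None = None  # None => hard step
    nb_dispersion: float = 10.0
    libsize_sigma: float = 0.25
    mito_fraction: float = 0.05
    mito_gene_fraction: float = 0.05
    n_outlier_cells: int = 0
    lib_target: float = 1e4
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1:
            raise ValueError("n_cells and n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion (theta) must be > 0")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")
        if not 0 <= self.mito_fraction < 1:
            raise ValueError("mito_fraction must be in [0, 1)")
        for g, (o, a) in self.tf_onsets.items():
            if not 0 < o < 1:
                raise ValueError(f"onset for {g} must lie in (0, 1), got {o}")
            if a < 0:
                raise ValueError(f"amplitude for {g} must be >= 0, got {a}")
        for g, (lo, hi) in self.marker_profile.items():
            if lo < 0 or hi < 0:
                raise ValueError(f"marker means for {g} must be non-negative")
        n_named = len(self.marker_profile) + len(self.tf_onsets)
        if self.n_genes < n_named + 1:
            raise ValueError(
                f"n_genes={self.n_genes} cannot accommodate {n_named} named "
                "marker/TF genes plus background"
            )


@dataclass
class GroundTruth:
    """Simulation truth used by parameter-recovery tests."""

    u: np.ndarray | None = None  # per-cell latent state
    tf_onset_stage: dict[str, str] = field(default_factory=dict)
    tf_onset_u: dict[str, float] = field(default_factory=dict)
    de_genes: pd.Index | None = None  # truly shifted genes (bulk/DSP)
    outlier_cells: pd.Index | None = None
    beta_true: float | None = None
    z: np.ndarray | None = None  # latent signature activity (survival)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """NB draws with variance mu + mu^2/theta; zero mean yields zero."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = theta / (theta + mean[pos])
        out[pos] = rng.negative_binomial(theta, p)
    return out


def _marker_mu(profile: tuple[float, float], u: np.ndarray) -> np.ndarray:
    lo, hi = profile
    return lo + (hi - lo) * u


def true_onset_stage(
    onset: float,
    marker_profile: tuple[float, float],
    bin_width: float = 1.0,
    n_bins: int = 6,
    marker: str = "VIM",
) -> str:
    """Map a latent onset threshold to its marker-bin stage label."""
    v = _marker_mu(marker_profile, np.asarray([onset]))[0]
    return stage_label(bin_index(v, bin_width, n_bins), marker, bin_width)


def simulate_emt_continuum(config: EMTSimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate single cells along a latent EMT continuum.

    Returns the count matrix (mitochondrial genes flagged in ``gene_meta``)
    and the ground truth (latent states, true TF onset stages, injected
    outliers).  Identical config + seed reproduces identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells = config.n_cells
    if config.latent_distribution == "uniform":
        u = rng.uniform(0.0, 1.0, n_cells)
    elif config.latent_distribution == "mixture":
        w_epi, w_mes = config.mixture_weights
        comp = rng.uniform(0, 1, n_cells) < w_mes / (w_epi + w_mes)
        u = np.where(comp, rng.beta(5, 1.5, n_cells), rng.beta(1.5, 5, n_cells))
    else:
        raise ValueError(f"unknown latent_distribution {config.latent_distribution!r}")

    markers = list(config.marker_profile)
    tfs = list(config.tf_onsets)
    n_named = len(markers) + len(tfs)
    n_bg = config.n_genes - n_named
    n_mito = max(1, int(round(config.mito_gene_fraction * n_bg))) if config.mito_fraction > 0 else 0

    bg_names = [f"MT-G{i}" for i in range(n_mito)] + [f"G{i:04d}" for i in range(n_bg - n_mito)]
    genes = pd.Index(markers + tfs + bg_names, name="gene")

    # mean log2(1+count) per gene per cell
    mu = np.zeros((config.n_genes, n_cells))
    for i, m in enumerate(markers):
        mu[i] = _marker_mu(config.marker_profile[m], u)
    for j, tf in enumerate(tfs):
        onset, amp = config.tf_onsets[tf]
        if config.tf_sigmoid_steepness is None:
            act = (u >= onset).astype(float)
        else:
            act = 1.0 / (1.0 + np.exp(-config.tf_sigmoid_steepness * (u - onset)))
        mu[len(markers) + j] = config.tf_baseline + amp * act

    mean_counts = np.zeros_like(mu)
    mean_counts[:n_named] = 2.0 ** mu[:n_named] - 1.0

    # calibrate background means so the expected library size hits lib_target
    named_mass = mean_counts[:n_named].mean(axis=1).sum()
    bg_budget = max(config.lib_target - named_mass, 0.1 * config.lib_target)
    mito_budget = config.mito_fraction * bg_budget
    rest_budget = bg_budget - mito_budget
    n_rest = n_bg - n_mito
    # per-gene base means vary lognormally across genes (fixed per gene)
    bg_rel = rng.lognormal(0.0, 0.8, n_bg)
    if n_mito:
        bg_rel[:n_mito] *= mito_budget / bg_rel[:n_mito].sum()
    bg_rel[n_mito:] *= rest_budget / bg_rel[n_mito:].sum()
    mean_counts[n_named:] = bg_rel[:, None]

    size = rng.lognormal(0.0, config.libsize_sigma, n_cells)
    counts = _nb_sample(rng, mean_counts * size[None, :], config.nb_dispersion)

    # injected QC failures: shrunken libraries with inflated mito share
    outliers: list[str] = []
    if config.n_outlier_cells:
        n_out = config.n_outlier_cells
        u_out = rng.uniform(0, 1, n_out)
        mu_out = np.zeros((config.n_genes, n_out))
        for i, m in enumerate(markers):
            mu_out[i] = _marker_mu(config.marker_profile[m], u_out)
        mc_out = np.zeros_like(mu_out)
        mc_out[:n_named] = 2.0 ** mu_out[:n_named] - 1.0
        mc_out[n_named:] = bg_rel[:, None]
        mc_out *= 0.02  # collapsed library
        if n_mito:
            mc_out[n_named : n_named + n_mito] *= 30.0  # mito blow-up
        counts_out = _nb_sample(rng, mc_out, config.nb_dispersion)
        counts = np.hstack([counts, counts_out])
        u = np.concatenate([u, u_out])
        outliers = [f"OUTLIER-{i}" for i in range(n_out)]

    cells = pd.Index([f"CELL-{i:05d}" for i in range(n_cells)] + outliers, name="cell")
    gene_meta = pd.DataFrame(
        {"mito": [g.startswith("MT-") for g in genes]}, index=genes
    )
    cell_meta = pd.DataFrame({"latent_u": u}, index=cells)

    cm = CountMatrix(sp.csr_matrix(counts), genes, cells, gene_meta, cell_meta)
    truth = GroundTruth(
        u=u,
        tf_onset_stage={
            tf: true_onset_stage(config.tf_onsets[tf][0], config.marker_profile["VIM"])
            for tf in tfs
        },
        tf_onset_u={tf: config.tf_onsets[tf][0] for tf in tfs},
        outlier_cells=pd.Index(outliers),
    )
    return cm, truth


def simulate_bulk_groups(
    n_per_group: int,
    n_genes: int,
    de_fraction: float,
    effect_log2fc: float,
    seed: int,
    theta: float = 10.0,
    base_mean: float = 100.0,
) -> tuple[CountMatrix, GroundTruth]:
    """Two labeled NB bulk groups; ``de_fraction`` of genes shifted in group M."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (degrees-of-freedom floor)")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    genes = pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene")
    samples = pd.Index(
        [f"E{i}" for i in range(n_per_group)] + [f"M{i}" for i in range(n_per_group)],
        name="cell",
    )
    base = base_mean * rng.lognormal(0.0, 1.0, n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    means = np.tile(base[:, None], (1, 2 * n_per_group))
    means[de_idx, n_per_group:] *= 2.0**effect_log2fc
    counts = _nb_sample(rng, means, theta)

    cell_meta = pd.DataFrame(
        {"group": ["E"] * n_per_group + ["M"] * n_per_group}, index=samples
    )
    cm = CountMatrix(sp.csr_matrix(counts), genes, samples, cell_meta=cell_meta)
    truth = GroundTruth(de_genes=genes[np.sort(de_idx)])
    return cm, truth


def simulate_survival_cohort(
    n: int,
    signature_genes: Sequence[str],
    beta_true: float,
    censor_rate: float,
    seed: int,
    n_genes: int = 200,
    baseline_hazard: float = 0.1,
    signature_shift: float = 2.0,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Cohort expression + exponential event times with hazard exp(beta*z).

    Signature genes carry a per-sample mean shift proportional to the latent
    activity ``z``; censoring is independent exponential with its rate chosen
    so the expected censored fraction is ``censor_rate`` at beta = 0.
    """
    if n < 20:
        raise ValueError("n must be >= 20")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    signature_genes = list(signature_genes)
    rng = np.random.default_rng(seed)

    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="cell")
    others = [f"G{i:04d}" for i in range(n_genes - len(signature_genes))]
    genes = pd.Index(signature_genes + others, name="gene")

    z = rng.standard_normal(n)
    log_mu = np.tile(rng.normal(5.0, 1.0, len(genes))[:, None], (1, n))
    log_mu[: len(signature_genes), :] += signature_shift * z[None, :]
    expr = rng.lognormal(0, 0.3, log_mu.shape) * 2.0**log_mu
    counts = np.rint(expr).astype(np.int64)

    hazard = baseline_hazard * np.exp(beta_true * z)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        rate_c = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / rate_c, n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    cohort = pd.DataFrame({"sample": samples, "time": time, "event": event}).set_index(
        "sample"
    )
    cm = CountMatrix(sp.csr_matrix(counts), genes, samples)
    truth = GroundTruth(beta_true=beta_true, z=z)
    return cm, cohort, truth


def simulate_dsp_rois(
    n_rois: int,
    n_genes: int,
    emt_genes: Sequence[str],
    effect_log2fc: float,
    seed: int,
    roi_sigma: float = 0.3,
    noise_sd: float = 0.3,
    roi_ids: Sequence[str] | None = None,
) -> PairedSegmentsMatrix:
    """Paired Vim+/Vim- segments per ROI sharing an ROI random effect.

    Values are lognormal "normalized reads": ``2**(base_g + r_i + effect + eps)``
    with the effect applied to ``emt_genes`` in vim_pos segments only.  With
    ``roi_sigma = noise_sd = 0`` and zero effect the paired differences are
    identically zero.
    """
    if n_rois < 3:
        raise ValueError("n_rois must be >= 3")
    if roi_ids is None:
        roi_ids = [f"ROI{i + 1}" for i in range(n_rois)]
    if len(set(roi_ids)) != len(roi_ids):
        raise ValueError("duplicate ROI identifiers")
    if len(roi_ids) != n_rois:
        raise ValueError("roi_ids length must equal n_rois")
    emt_genes = list(emt_genes)
    rng = np.random.default_rng(seed)

    others = [f"G{i:04d}" for i in range(n_genes - len(emt_genes))]
    genes = pd.Index(emt_genes + others, name="gene")
    base = rng.normal(5.0, 1.0, len(genes))
    r = rng.normal(0.0, roi_sigma, n_rois) if roi_sigma > 0 else np.zeros(n_rois)

    cols, ann_rows = [], []
    values = np.zeros((len(genes), 2 * n_rois))
    is_emt = np.array([g in set(emt_genes) for g in genes], dtype=float)
    for i, roi in enumerate(roi_ids):
        for j, seg in enumerate(("vim_pos", "vim_neg")):
            log2v = base + r[i]
            if seg == "vim_pos":
                log2v = log2v + effect_log2fc * is_emt
            if noise_sd > 0:
                log2v = log2v + rng.normal(0.0, noise_sd, len(genes))
            values[:, 2 * i + j] = 2.0**log2v
            cols.append(f"{roi}_{seg}")
            ann_rows.append({"roi_id": roi, "segment": seg})

    vals = pd.DataFrame(values, index=genes, columns=cols)
    ann = pd.DataFrame(ann_rows, index=cols)
    return PairedSegmentsMatrix(vals, ann)
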