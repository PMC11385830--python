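"""Stage-signature derivation and survival stratification.

Signatures are the up-regulated DEGs of a merged-stratum contrast
intersected with the hallmark EMT set; a cohort is scored sample-wise with
the single-sample enrichment scorer, split at the mean score, and analyzed
with Kaplan-Meier curves, the log-rank test, and a Cox proportional-hazards
model (Breslow ties, damped Newton on the partial likelihood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .scoring import GeneSetCollection, ssgsea_cell_scores


@dataclass
class SignatureDefinition:
    stage: str
    genes: list[str]
    contrast: str = ""
    alpha: float = 0.05
    min_lfc: float = 1.0

    @property
    def empty(self) -> bool:
        return len(self.genes) == 0


@dataclass
class CoxFit:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    p_lr: float
    n_iter: int


def derive_stage_signature(
    degs: pd.DataFrame,
    hallmark_emt,
    stage: str = "",
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    use_raw_p: bool = False,
) -> SignatureDefinition:
    """Up-called genes of one contrast intersected with the hallmark EMT set."""
    hallmark_emt = set(hallmark_emt)
    if not hallmark_emt:
        raise ValueError("hallmark EMT set is empty")
    pcol = "p_raw" if use_raw_p else "p_adj"
    up = degs.index[(degs[pcol] < alpha) & (degs["log2fc"] >= min_lfc)]
    genes = sorted(set(up) & hallmark_emt)
    if not genes:
        warnings.warn(f"empty signature for stage {stage!r}", stacklevel=2)
    contrast = degs["contrast"].iloc[0] if "contrast" in degs.columns and len(degs) else ""
    return SignatureDefinition(stage, genes, contrast, alpha, min_lfc)


def score_cohort(
    expr: CountMatrix | pd.DataFrame,
    signature: SignatureDefinition,
    assume_normalized: bool = False,
) -> pd.Series:
    """Per-sample single-sample enrichment score for one signature.

    Raw counts are converted to log2 CPM internally; pass a DataFrame with
    ``assume_normalized=True`` to skip the transform.
    """
    if isinstance(expr, CountMatrix):
        dense = expr.to_dense().astype(float)
        lib = dense.sum(axis=0)
        values = np.log2(1.0 + dense * 1e6 / lib)
    else:
        values = expr if assume_normalized else np.log2(1.0 + expr)
    matched = [g for g in signature.genes if g in values.index]
    if len(matched) < 2:
        raise ValueError(
            f"signature has {len(matched)} genes matched in cohort; need >= 2"
        )
    sets = GeneSetCollection({"signature": signature.genes})
    sm = ssgsea_cell_scores(values, sets)
    score = sm.es.loc["signature"]
    score.name = "score"
    return score


def split_by_mean(scores: pd.Series) -> pd.Series:
    """High iff score > mean; ties at the mean go Low (deterministic rule)."""
    if len(scores) < 2:
        raise ValueError("need >= 2 samples to split")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no mean split possible")
    group = np.where(scores > scores.mean(), "High", "Low")
    return pd.Series(group, index=scores.index, name="group")


def km_estimate(time, event) -> pd.DataFrame:
    """Product-limit survival estimate over distinct event times.

    Returns a DataFrame with columns ``time, n_risk, n_events, survival``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time < 0).any():
        raise ValueError("negative times")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    rows = []
    s = 1.0
    n = len(time)
    for t in np.unique(time[event == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        rows.append({"time": t, "n_risk": n_risk, "n_events": d, "survival": s})
    if not rows:
        return pd.DataFrame(
            [{"time": 0.0, "n_risk": n, "n_events": 0, "survival": 1.0}]
        )
    return pd.DataFrame(rows)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank chi-square and its chi2(1) p-value."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(labels)}")
    for lab in labels:
        if (group == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    g1 = group == labels[0]

    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = obs_minus_exp**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _cox_loglik(beta: float, time, event, x):
    """Breslow partial log-likelihood with gradient and information."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    t, e, xv = time[order], event[order], x[order]
    eta = np.clip(beta * xv, -700.0, 700.0)  # guard overflow under separation
    w = np.exp(eta)
    # cumulative sums over risk sets (all with time >= t_i)
    cw = np.cumsum(w)
    cwx = np.cumsum(w * xv)
    cwx2 = np.cumsum(w * xv**2)
    # for tied times the risk set is everyone with time >= t, i.e. the last
    # cumulative position within the tie block
    last = np.empty(len(t), dtype=int)
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        last[i : j + 1] = j
        i = j + 1
    ll = 0.0
    grad = 0.0
    info = 0.0
    ev = e == 1
    S0 = cw[last[ev]]
    S1 = cwx[last[ev]]
    S2 = cwx2[last[ev]]
    ll = float(np.sum(eta[ev]) - np.sum(np.log(S0)))
    grad = float(np.sum(xv[ev]) - np.sum(S1 / S0))
    info = float(np.sum(S2 / S0 - (S1 / S0) ** 2))
    return ll, grad, info


def cox_fit(
    time, event, covariate, tol: float = 1e-8, max_iter: int = 100
) -> CoxFit:
    """Univariate Cox PH fit by damped Newton iteration (Breslow ties).

    ``covariate`` may be binary High/Low labels or a continuous score;
    High/Low is coded 1/0.  Reports the Wald CI from the observed
    information and a likelihood-ratio p against beta = 0.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS":
        uniq = sorted(set(cov.tolist()))
        if uniq == ["High", "Low"]:
            x = (cov == "High").astype(float)
        elif len(uniq) == 2:
            x = (cov == uniq[1]).astype(float)
        else:
            raise ValueError("non-numeric covariate must be binary")
    else:
        x = cov.astype(float)
    if event.sum() < 1:
        raise ValueError("no events; Cox model undefined")
    if np.allclose(x, x[0]):
        raise ValueError("covariate is constant")

    beta = 0.0
    ll0, _, _ = _cox_loglik(0.0, time, event, x)
    ll_prev = ll0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, info = _cox_loglik(beta, time, event, x)
        if info <= 0:
            raise RuntimeError("singular information matrix in Cox fit")
        step = grad / info
        # damping: halve until the likelihood does not decrease
        new_beta = beta + step
        for _ in range(30):
            ll_new, _, _ = _cox_loglik(new_beta, time, event, x)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
            new_beta = beta + step
        beta = new_beta
        if abs(beta) > 50:
            raise RuntimeError(
                "monotone partial likelihood (complete separation); "
                "Cox estimate diverges"
            )
        if abs(step) < tol:
            break
        ll_prev = ll
    else:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    ll_hat, _, info = _cox_loglik(beta, time, event, x)
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p_wald = 2.0 * stats.norm.sf(abs(z))
    lr = 2.0 * (ll_hat - ll0)
    p_lr = float(stats.chi2.sf(max(lr, 0.0), df=1))
    ci = (np.exp(beta - 1.959963984540054 * se), np.exp(beta + 1.959963984540054 * se))
    return CoxFit(
        beta=float(beta),
        se=float(se),
        hr=float(np.exp(beta)),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_wald=float(p_wald),
        p_lr=p_lr,
        n_iter=n_iter,
    )


def cox_score_test(time, event, covariate) -> tuple[float, float]:
    """Score test of beta = 0 (numerically equals the log-rank chi-square
    for a binary covariate without ties in the Breslow sense)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cov = np.asarray(covariate)
    if cov.dtype.kind in "OUS":
        x = (cov == sorted(set(cov.tolist()))[0]).astype(float)
    else:
        x = cov.astype(float)
    _, grad, info = _cox_loglik(0.0, time, event, x)
    if info == 0:
        return 0.0, 1.0
    chi2 = grad**2 / info
    return float(chi2), float(stats.chi2.sf(chi2, df=1))
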