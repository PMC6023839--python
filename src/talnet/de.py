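"""Differential expression with empirical-Bayes variance moderation.

Implements the standard microarray two-group workflow on log2 data:

* probe-to-gene collapse (keep the probe with the largest total signal),
* coefficient-of-variation filtering before module detection,
* a moderated t-test in which gene-wise variances are shrunk towards a
  common prior estimated by method of moments on the log variances
  (the empirical-Bayes scheme popularised by limma),
* Benjamini-Hochberg adjustment and |FC| / adjusted-p calling,
* the "stable expression" filter: complete separation of the two
  conditions' sample values for a feature.

Fold-change thresholds are applied on the log2 scale (|log2FC| > log2(FC)),
and the signed linear fold change is reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NS = "ns"


# ---------------------------------------------------------------------------
# probe collapse
# ---------------------------------------------------------------------------

def collapse_probes(matrix: ExpressionMatrix,
                    probe_to_gene: Mapping[str, str],
                    method: str = "max_total") -> ExpressionMatrix:
    """Collapse multiple probes per gene to a single row.

    ``method="max_total"`` keeps, for each gene, the probe whose total
    signal summed over all samples is largest (ties broken by probe order).
    ``method="sum"`` sums the probes instead.  Probes without a gene
    mapping are dropped.
    """
    if method not in ("max_total", "sum"):
        raise ValueError(f"unknown collapse method {method!r}")
    if not probe_to_gene:
        warnings.warn("empty probe map: collapse_probes is a pass-through")
        return matrix

    rows: dict[str, pd.Series] = {}
    totals: dict[str, float] = {}
    for probe in matrix.feature_ids:
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        row = matrix.values.loc[probe]
        if method == "sum":
            rows[gene] = rows[gene] + row if gene in rows else row.copy()
        else:
            total = float(row.sum())
            if gene not in rows or total > totals[gene]:
                rows[gene] = row
                totals[gene] = total
    if not rows:
        raise ValueError("probe map matched no probes in the matrix")
    collapsed = pd.DataFrame(rows).T
    collapsed.columns = matrix.sample_ids
    return ExpressionMatrix(collapsed, matrix.condition_of)


# ---------------------------------------------------------------------------
# CV filter
# ---------------------------------------------------------------------------

def cv_filter(matrix: ExpressionMatrix, min_cv: float = 0.10) -> ExpressionMatrix:
    """Keep features whose coefficient of variation sd/|mean| >= ``min_cv``.

    Computed over all samples.  Features with mean exactly zero are kept
    (CV treated as infinite) and logged.
    """
    vals = matrix.values.to_numpy()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0.0, np.inf, sd / np.abs(mean))
    n_zero = int((mean == 0.0).sum())
    if n_zero:
        logger.info("cv_filter: %d features with zero mean kept (CV=inf)", n_zero)
    keep = cv >= min_cv
    kept = [f for f, k in zip(matrix.feature_ids, keep) if k]
    if not kept:
        raise ValueError("cv_filter removed every feature")
    return matrix.subset(kept)


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate prior df ``d0`` and prior variance ``s0^2``.

    Method of moments on z = log(s^2): under a scaled-F model,
    E[z] and Var[z] are expressible through digamma/trigamma functions of
    df/2 and d0/2; matching the sample moments gives the prior.  A
    non-positive excess variance means the gene-wise variances are no more
    dispersed than sampling alone allows, and the prior df is infinite
    (complete shrinkage to the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive gene-wise variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s02 = float(np.exp(e_mean - special.digamma(d0 / 2.0) + np.log(d0 / 2.0)))
    return d0, s02


def moderated_t_test(matrix: ExpressionMatrix, moderate: bool = True) -> pd.DataFrame:
    """Two-group (relapse vs remission) moderated t-test per feature.

    Returns a DataFrame indexed by feature with columns ``log2FC``
    (relapse mean minus remission mean), ``fold_change`` (signed linear),
    ``t``, ``p_value``, ``adj_p`` (Benjamini-Hochberg) and ``call``
    (initially all ``ns``; see :func:`call_differential`).

    With ``moderate=False`` no shrinkage is applied and the statistic is
    the ordinary pooled-variance two-sample t.
    """
    g1 = matrix.condition_values("relapse").to_numpy()
    g2 = matrix.condition_values("remission").to_numpy()
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two samples per condition")
    df_resid = n1 + n2 - 2
    m1 = g1.mean(axis=1)
    m2 = g2.mean(axis=1)
    diff = m1 - m2
    ss = ((g1 - m1[:, None]) ** 2).sum(axis=1) + ((g2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid

    if moderate:
        d0, s02 = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
            df_total = np.inf
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        s2_post = s2
        df_total = float(df_resid)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    if np.any(se == 0):
        bad = [matrix.feature_ids[i] for i in np.nonzero(se == 0)[0][:5]]
        raise ValueError(f"zero residual variance for features {bad}")
    t = diff / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    adj_p = multipletests(p, method="fdr_bh")[1]

    log2fc = diff
    fc = np.where(log2fc >= 0, 2.0 ** log2fc, -(2.0 ** (-log2fc)))
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "fold_change": fc,
            "t": t,
            "p_value": p,
            "adj_p": adj_p,
            "call": CALL_NS,
        },
        index=pd.Index(matrix.feature_ids, name="feature"),
    )


def call_differential(result: pd.DataFrame, fc_threshold: float = 1.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Assign up/down/ns calls: |log2FC| > log2(fc_threshold), adj_p < alpha.

    Strict inequalities on both gates; ``up`` means higher in relapse.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (linear scale)")
    cut = np.log2(fc_threshold)
    out = result.copy()
    sig = out["adj_p"].to_numpy() < alpha
    up = sig & (out["log2FC"].to_numpy() > cut)
    down = sig & (out["log2FC"].to_numpy() < -cut)
    calls = np.where(up, CALL_UP, np.where(down, CALL_DOWN, CALL_NS))
    out["call"] = calls
    return out


def de_features(result: pd.DataFrame) -> list[str]:
    """Feature ids called up or down."""
    return list(result.index[result["call"].isin([CALL_UP, CALL_DOWN])])


# ---------------------------------------------------------------------------
# stable expression filter
# ---------------------------------------------------------------------------

def stable_expression_filter(matrix: ExpressionMatrix,
                             features: Iterable[str] | None = None) -> pd.Series:
    """Complete-separation filter relative to relapse.

    A feature is ``stable_up`` when every relapse sample exceeds every
    remission sample (min(relapse) > max(remission)); ``stable_down`` when
    every relapse sample is below every remission sample.  Ties exclude a
    feature.  Returns a Series mapping each qualifying feature to its
    direction, in matrix order.
    """
    feats = matrix.feature_ids if features is None else list(features)
    sub = matrix.subset(feats)
    rel = sub.condition_values("relapse").to_numpy()
    rem = sub.condition_values("remission").to_numpy()
    up = rel.min(axis=1) > rem.max(axis=1)
    down = rel.max(axis=1) < rem.min(axis=1)
    out = {}
    for f, u, d in zip(sub.feature_ids, up, down):
        if u:
            out[f] = "stable_up"
        elif d:
            out[f] = "stable_down"
    return pd.Series(out, dtype=object, name="stable")
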