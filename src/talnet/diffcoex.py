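"""Differential co-expression detection between two conditions.

Genes are clustered by average-linkage on the Pearson correlation distance
(1 - r) computed within ONE condition's samples, the tree is cut at a fixed
height (h = 0.4 by default, i.e. mean within-group correlation above 0.6),
and each resulting group is scored in BOTH conditions with a group
t-statistic over its pairwise correlations.  The "probability of
randomness" of a group is a resampling p-value: the fraction of random
same-sized gene sets (drawn from the clustered universe) whose group
t-statistic reaches the observed one, with an add-one pseudo-count so the
estimate is never exactly zero.

A group is condition-specific when it is large enough (N >= 30 by
default), non-random in the condition it was clustered in
(pr_active <= 0.05) and indistinguishable from random in the other
(pr_inactive >= 0.05).  Inclusive thresholds are the default; a strict
variant is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import CONDITIONS, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class DiffCoexGroup:
    """A coXpress-style gene group with per-condition coherence statistics.

    ``pr_g1``/``mean_cor1`` always refer to the relapse subset and
    ``pr_g2``/``mean_cor2`` to the remission subset, regardless of which
    condition the group was clustered in (recorded in ``clustered_in``).
    """

    group_id: int
    genes: list[str]
    clustered_in: str
    mean_cor1: float
    mean_cor2: float
    t1: float
    t2: float
    pr_g1: float = np.nan
    pr_g2: float = np.nan
    selected: bool = False

    @property
    def n(self) -> int:
        return len(self.genes)


def _condition_unit_rows(matrix: ExpressionMatrix, condition: str) -> tuple[np.ndarray, list[str]]:
    """Row-standardised (zero-mean, unit-norm) data for one condition.

    Constant genes (undefined correlation) are excluded with a warning.
    """
    vals = matrix.condition_values(condition).to_numpy()
    mu = vals.mean(axis=1, keepdims=True)
    centered = vals - mu
    norms = np.linalg.norm(centered, axis=1)
    ok = norms > 0
    if not ok.all():
        dropped = [f for f, o in zip(matrix.feature_ids, ok) if not o]
        warnings.warn(f"{len(dropped)} constant genes excluded in {condition}: "
                      f"{dropped[:5]}")
    unit = centered[ok] / norms[ok][:, None]
    feats = [f for f, o in zip(matrix.feature_ids, ok) if o]
    return unit, feats


def cluster_in_condition(matrix: ExpressionMatrix, condition: str,
                         h: float = 0.4) -> list[list[str]]:
    """Average-linkage groups at distance 1 - Pearson r within a condition.

    Groups are numbered (list order) by decreasing size, ties by the
    position of their first gene in the matrix.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if len(matrix.samples_in(condition)) < 3:
        raise ValueError("need at least three samples in the clustering condition")
    unit, feats = _condition_unit_rows(matrix, condition)
    if len(feats) < 2:
        raise ValueError("fewer than two non-constant genes to cluster")
    r = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=h, criterion="distance")
    order = {f: i for i, f in enumerate(matrix.feature_ids)}
    groups: dict[int, list[str]] = {}
    for f, lab in zip(feats, labels):
        groups.setdefault(int(lab), []).append(f)
    out = list(groups.values())
    out.sort(key=lambda gs: (-len(gs), min(order[g] for g in gs)))
    return out


def _pair_t(unit_sub: np.ndarray) -> tuple[float, float]:
    """(mean pairwise correlation, group t) for unit-row data of one group."""
    n = unit_sub.shape[0]
    r = np.clip(unit_sub @ unit_sub.T, -1.0, 1.0)
    iu = np.triu_indices(n, k=1)
    cors = r[iu]
    mean_cor = float(cors.mean())
    if n == 2:
        return mean_cor, mean_cor  # degenerate sd: t defined as mean_cor
    sd = float(cors.std(ddof=1))
    if sd == 0.0:
        return mean_cor, float(np.inf) if mean_cor > 0 else float(-np.inf)
    return mean_cor, mean_cor / (sd / np.sqrt(cors.size))


def group_statistic(genes: list[str], matrix: ExpressionMatrix,
                    condition: str) -> tuple[float, float]:
    """Mean pairwise Pearson correlation and group t within one condition.

    t = mean_cor / (sd(pairwise correlations) / sqrt(#pairs)); for a
    two-gene group the sd is degenerate and t is defined as mean_cor.
    """
    if len(genes) < 2:
        raise ValueError("group must have at least two genes")
    if len(matrix.samples_in(condition)) < 3:
        raise ValueError("need at least three samples")
    sub = matrix.subset(genes)
    unit, feats = _condition_unit_rows(sub, condition)
    if len(feats) < len(genes):
        raise ValueError("constant gene in group: correlation undefined")
    return _pair_t(unit)


def null_t_distribution(n_genes: int, matrix: ExpressionMatrix, condition: str,
                        universe: list[str], B: int, rng: np.random.Generator) -> np.ndarray:
    """Group t for B random size-``n_genes`` gene sets from ``universe``."""
    if n_genes >= len(universe):
        raise ValueError("group size must be below the universe size")
    sub = matrix.subset(universe)
    unit, feats = _condition_unit_rows(sub, condition)
    m = unit.shape[0]
    if n_genes >= m:
        raise ValueError("too few non-constant universe genes")
    # B draws without replacement via per-row random argsort
    idx = rng.random((B, m)).argsort(axis=1)[:, :n_genes]
    sel = unit[idx]                               # (B, N, s)
    r = np.clip(sel @ sel.transpose(0, 2, 1), -1.0, 1.0)
    iu = np.triu_indices(n_genes, k=1)
    cors = r[:, iu[0], iu[1]]                     # (B, n_pairs)
    mean_cor = cors.mean(axis=1)
    if n_genes == 2:
        return mean_cor
    sd = cors.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean_cor / (sd / np.sqrt(cors.shape[1])),
                     np.sign(mean_cor) * np.inf)
    return t


def probability_of_randomness(genes: list[str], matrix: ExpressionMatrix,
                              condition: str, universe: list[str],
                              B: int = 1000,
                              seed: int | np.random.Generator = 0,
                              null_t: np.ndarray | None = None) -> float:
    """Resampling p-value of a group's within-condition coherence.

    pr = (1 + #{random t >= observed t}) / (B + 1) over B random gene
    sets of the group's size drawn without replacement from ``universe``.
    A precomputed ``null_t`` (e.g. shared across same-sized groups) may be
    supplied.
    """
    _, t_obs = group_statistic(genes, matrix, condition)
    if null_t is None:
        rng = seed if isinstance(seed, np.random.Generator) else \
            np.random.default_rng(seed)
        null_t = null_t_distribution(len(genes), matrix, condition, universe, B, rng)
    return float((1 + np.sum(null_t >= t_obs)) / (null_t.size + 1))


def analyze_condition_specific(matrix: ExpressionMatrix, active_condition: str,
                               h: float = 0.4, min_n: int = 30,
                               pr_active: float = 0.05,
                               pr_inactive: float = 0.05,
                               B: int = 1000,
                               seed: int | np.random.Generator = 0,
                               inclusive: bool = True,
                               pr_all_groups: bool = False) -> list[DiffCoexGroup]:
    """Cluster in ``active_condition`` and score every group in both conditions.

    Returns all groups with N >= 2 (numbered by size); the ``selected``
    flag marks condition-specific ones per the size and pr gates.  With the
    default ``inclusive=True`` the gates are N >= min_n,
    pr_active <= threshold, pr_inactive >= threshold; ``inclusive=False``
    switches to strict inequalities (N > min_n, pr < / pr >).

    The probability of randomness is computed for groups passing the size
    gate (all groups when ``pr_all_groups`` is set); the resampling frame
    is the clustered universe.  Null t distributions are shared across
    groups of equal size for efficiency.
    """
    other = "remission" if active_condition == "relapse" else "relapse"
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    groups = cluster_in_condition(matrix, active_condition, h=h)
    order = {f: i for i, f in enumerate(matrix.feature_ids)}
    universe = sorted({g for gs in groups for g in gs}, key=order.__getitem__)

    size_ok = (lambda n: n >= min_n) if inclusive else (lambda n: n > min_n)
    pr_act_ok = (lambda p: p <= pr_active) if inclusive else (lambda p: p < pr_active)
    pr_inact_ok = (lambda p: p >= pr_inactive) if inclusive else (lambda p: p > pr_inactive)

    need_pr = [gs for gs in groups
               if len(gs) >= 2 and (pr_all_groups or size_ok(len(gs)))]
    null_cache: dict[tuple[str, int], np.ndarray] = {}
    for cond in (active_condition, other):
        for n in sorted({len(gs) for gs in need_pr}):
            if n < len(universe):
                null_cache[(cond, n)] = null_t_distribution(
                    n, matrix, cond, universe, B, rng)

    out: list[DiffCoexGroup] = []
    for gid, genes in enumerate(groups, start=1):
        if len(genes) < 2:
            continue
        mc_rel, t_rel = group_statistic(genes, matrix, "relapse")
        mc_rem, t_rem = group_statistic(genes, matrix, "remission")
        grp = DiffCoexGroup(gid, list(genes), active_condition,
                            mc_rel, mc_rem, t_rel, t_rem)
        want_pr = pr_all_groups or size_ok(len(genes))
        if want_pr and (active_condition, len(genes)) in null_cache:
            pr_rel = probability_of_randomness(
                genes, matrix, "relapse", universe,
                null_t=null_cache[("relapse", len(genes))])
            pr_rem = probability_of_randomness(
                genes, matrix, "remission", universe,
                null_t=null_cache[("remission", len(genes))])
            grp.pr_g1, grp.pr_g2 = pr_rel, pr_rem
            pr_act = pr_rel if active_condition == "relapse" else pr_rem
            pr_inact = pr_rem if active_condition == "relapse" else pr_rel
            grp.selected = (size_ok(grp.n) and pr_act_ok(pr_act)
                            and pr_inact_ok(pr_inact))
        out.append(grp)
    n_sel = sum(g.selected for g in out)
    logger.info("%s-specific run: %d groups, %d selected",
                active_condition, len(out), n_sel)
    return out


def groups_frame(groups: list[DiffCoexGroup]) -> pd.DataFrame:
    """Table-shaped export: group, N, pr.g1, pr.g2, mean.cor1, mean.cor2."""
    return pd.DataFrame(
        {
            "group": [g.group_id for g in groups],
            "N": [g.n for g in groups],
            "pr.g1": [g.pr_g1 for g in groups],
            "pr.g2": [g.pr_g2 for g in groups],
            "mean.cor1": [g.mean_cor1 for g in groups],
            "mean.cor2": [g.mean_cor2 for g in groups],
            "t1": [g.t1 for g in groups],
            "t2": [g.t2 for g in groups],
            "selected": [g.selected for g in groups],
            "condition": [g.clustered_in for g in groups],
            "genes": [",".join(g.genes) for g in groups],
        }
    )
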