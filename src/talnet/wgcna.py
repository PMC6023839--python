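"""Weighted co-expression network analysis.

Unsigned weighted network on all samples: adjacency ``|cor|^beta`` with the
soft-thresholding power chosen by the scale-free topology criterion
(R^2 >= 0.9 by default), topological overlap smoothing, average-linkage
clustering of the TOM dissimilarity with a static cut, a minimum module
size, and iterative merging of modules whose eigengenes are highly
correlated.

The module eigengene is the leading right-singular direction of the
row-standardised module sub-matrix — the per-sample summary profile that
explains the most variance of any single direction — sign-oriented to
correlate positively with the module's mean expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

# WGCNA-style colour labels, assigned by decreasing module size.
_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
UNASSIGNED = "grey"


@dataclass
class SoftThresholdScan:
    """Scale-free fit per candidate power and the chosen power."""

    powers: list[int]
    r_squared: list[float]        # signed: negated when the fit slope is positive
    mean_connectivity: list[float]
    chosen: int
    reached_cut: bool             # False => fell back to argmax R^2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "power": self.powers,
                "scale_free_r2": self.r_squared,
                "mean_connectivity": self.mean_connectivity,
                "chosen": [p == self.chosen for p in self.powers],
            }
        )


@dataclass
class WeightedModule:
    label: str
    genes: list[str]
    eigengene: pd.Series | None = None

    @property
    def size(self) -> int:
        return len(self.genes)


def _correlation(matrix: ExpressionMatrix) -> np.ndarray:
    vals = matrix.values.to_numpy()
    sd = vals.std(axis=1)
    degenerate = [f for f, s in zip(matrix.feature_ids, sd) if s == 0]
    if degenerate:
        raise ValueError(f"constant features have undefined correlation: "
                         f"{degenerate[:10]}")
    return np.corrcoef(vals)


def adjacency(matrix: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with zero diagonal."""
    a = np.abs(_correlation(matrix)) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are histogrammed into ``n_bins`` equal-width bins; the
    regression is log10(bin frequency) on log10(bin mean connectivity),
    restricted to non-empty bins.  R^2 is negated when the slope is
    positive (anti-scale-free).
    """
    k = np.asarray(connectivity, dtype=float)
    if k.size < 2:
        raise ValueError("need at least two connectivities")
    lo, hi = k.min(), k.max()
    if hi <= lo:
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.sum() / k.size
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return 0.0
    fit = linregress(xs, ys)
    r2 = float(fit.rvalue ** 2)
    return -r2 if fit.slope > 0 else r2


def soft_threshold_scan(matrix: ExpressionMatrix,
                        powers: list[int] | None = None,
                        r2_cut: float = 0.9,
                        n_bins: int = 10) -> SoftThresholdScan:
    """Scan candidate powers and pick the smallest reaching ``r2_cut``.

    If no power reaches the cut the power with maximal signed R^2 is
    chosen and ``reached_cut`` is False (with a warning).
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least three samples")
    if matrix.n_features < 20:
        raise ValueError("need at least 20 features")
    if powers is None:
        powers = list(range(1, 21))
    absr = np.abs(_correlation(matrix))
    np.fill_diagonal(absr, 0.0)
    r2s, ks = [], []
    for beta in powers:
        a = absr ** beta
        k = a.sum(axis=1)
        r2s.append(scale_free_fit(k, n_bins=n_bins))
        ks.append(float(k.mean()))
    chosen = None
    for p, r2 in zip(powers, r2s):
        if r2 >= r2_cut:
            chosen = p
            break
    reached = chosen is not None
    if not reached:
        chosen = powers[int(np.argmax(r2s))]
        warnings.warn(
            f"no power reached scale-free R^2 {r2_cut}; "
            f"using argmax R^2 at beta={chosen}"
        )
    return SoftThresholdScan(list(powers), r2s, ks, chosen, reached)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency matrix.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) where
    l_ij = sum_u a_iu a_uj; the diagonal is set to 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    ell = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (ell + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(matrix: ExpressionMatrix, genes: list[str]) -> pd.Series:
    """Leading singular direction of the standardised module sub-matrix.

    Rows (genes) are z-scored; the eigengene is the first right-singular
    vector (one value per sample, unit norm), with its sign chosen so it
    correlates positively with the module's mean standardised expression.
    """
    x = matrix.subset(genes).values.to_numpy()
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant gene in module")
    z = (x - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    ref = z.mean(axis=0)
    if np.dot(eig, ref) < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.sample_ids, name="eigengene")


def detect_modules(tom: np.ndarray,
                   matrix: ExpressionMatrix | None = None,
                   feature_ids: list[str] | None = None,
                   min_module_size: int = 20,
                   merge_height: float = 0.2,
                   cut_height: float = 0.98) -> tuple[list[WeightedModule], list[str]]:
    """Cut the TOM dendrogram into modules and merge correlated eigengenes.

    Average-linkage clustering of dissimilarity 1 - TOM, static cut at
    ``cut_height``; clusters below ``min_module_size`` go to the
    unassigned pool.  When an expression matrix is given, eigengenes are
    computed and module pairs with eigengene dissimilarity (1 - cor)
    below ``merge_height`` are merged iteratively (closest pair first).

    Returns ``(modules, unassigned_ids)`` with modules labelled by
    colour in decreasing size order.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if feature_ids is None:
        feature_ids = matrix.feature_ids if matrix is not None else [
            f"g{i}" for i in range(n)
        ]
    if len(feature_ids) != n:
        raise ValueError("feature_ids length does not match TOM")
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned")
        return [], list(feature_ids)

    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = linkage(squareform(diss, checks=False), method="average")
    labels = fcluster(z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for fid, lab in zip(feature_ids, labels):
        clusters.setdefault(int(lab), []).append(fid)
    modules = [genes for genes in clusters.values() if len(genes) >= min_module_size]
    unassigned = [g for genes in clusters.values() if len(genes) < min_module_size
                  for g in genes]
    # deterministic order: size desc, then first gene id
    modules.sort(key=lambda gs: (-len(gs), gs[0]))

    if matrix is not None and len(modules) > 1:
        modules = _merge_by_eigengene(matrix, modules, merge_height)
        modules.sort(key=lambda gs: (-len(gs), gs[0]))

    out: list[WeightedModule] = []
    for i, genes in enumerate(modules):
        label = _COLORS[i] if i < len(_COLORS) else f"module{i + 1}"
        eig = module_eigengene(matrix, genes) if matrix is not None else None
        out.append(WeightedModule(label, genes, eig))
    unassigned.sort()
    return out, unassigned


def _merge_by_eigengene(matrix: ExpressionMatrix, modules: list[list[str]],
                        merge_height: float) -> list[list[str]]:
    mods = [sorted(genes) for genes in modules]
    while len(mods) > 1:
        eigs = np.array([module_eigengene(matrix, genes).to_numpy()
                         for genes in mods])
        cor = np.corrcoef(eigs)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if 1.0 - cor[i, j] >= merge_height:
            break
        i, j = min(i, j), max(i, j)
        logger.info("merging modules of sizes %d and %d (eigengene cor %.3f)",
                    len(mods[i]), len(mods[j]), cor[i, j])
        mods[i] = sorted(mods[i] + mods[j])
        del mods[j]
    return mods


def assignments_frame(modules: list[WeightedModule],
                      unassigned: list[str]) -> pd.DataFrame:
    rows = [(g, m.label) for m in modules for g in m.genes]
    rows += [(g, UNASSIGNED) for g in unassigned]
    return pd.DataFrame(rows, columns=["gene", "module"])
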