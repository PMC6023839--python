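"""Hypergeometric merging of the two module systems into condition gene sets.

Each condition-specific differential co-expression group is tested for
overlap against every weighted co-expression module with the
hypergeometric upper tail P(X >= k) over a shared universe (the
CV-filtered gene set).  Weighted modules significantly overlapping at
least one group of a condition are assigned to that condition, and the
condition gene set is the union of the condition's group genes with the
assigned modules' genes.  Raw p-values are compared to the significance
level (no multiplicity adjustment), mirroring the original screening.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def hypergeom_overlap_p(universe: int, m: int, n: int, k: int,
                        tail: str = "upper") -> float:
    """Hypergeometric overlap p-value.

    Probability that two sets of sizes ``m`` and ``n``, drawn from a
    universe of ``universe`` genes, share at least ``k`` members
    (``tail="upper"``, the enrichment convention).  ``tail="strict_upper"``
    gives P(X > k).  Computed from the survival function of the
    hypergeometric distribution (log-space internally, stable for large
    counts).
    """
    if not (0 <= m <= universe and 0 <= n <= universe):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= k <= min(m, n)):
        raise ValueError("overlap must satisfy 0 <= k <= min(m, n)")
    if m + n - k > universe:
        raise ValueError("sets of these sizes cannot fit in the universe")
    dist = stats.hypergeom(universe, m, n)
    if tail == "upper":
        p = dist.sf(k - 1)
    elif tail == "strict_upper":
        p = dist.sf(k)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(min(max(p, 0.0), 1.0))


@dataclass
class OverlapTest:
    condition: str
    group_id: int
    module_label: str
    universe: int
    m: int          # group size within the universe
    n: int          # module size within the universe
    k: int          # overlap
    p_value: float
    assigned: bool


@dataclass
class ConditionGeneSet:
    condition: str
    genes: list[str]
    # gene -> list of sources ("group:<id>" / "module:<label>")
    provenance: dict[str, list[str]] = field(default_factory=dict)
    assigned_modules: list[str] = field(default_factory=list)


def merge_modules(groups_by_condition: dict[str, list[tuple[int, list[str]]]],
                  weighted_modules: list[tuple[str, list[str]]],
                  universe: list[str],
                  alpha: float = 0.01) -> tuple[dict[str, ConditionGeneSet],
                                                pd.DataFrame]:
    """Assign weighted modules to conditions by hypergeometric overlap.

    Parameters
    ----------
    groups_by_condition
        ``{"relapse": [(group_id, genes), ...], "remission": [...]}`` —
        the selected condition-specific groups.
    weighted_modules
        ``[(label, genes), ...]`` from the weighted network.
    universe
        The shared gene frame both detectors ran on; overlaps and sizes
        are computed within it.
    alpha
        Raw-p significance level for assignment (p < alpha).

    Returns the per-condition gene sets and the full overlap-test table.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    tests: list[OverlapTest] = []
    gene_sets: dict[str, ConditionGeneSet] = {}
    order = {g: i for i, g in enumerate(universe)}

    for condition, groups in groups_by_condition.items():
        provenance: dict[str, list[str]] = {}
        assigned: list[str] = []
        if not groups:
            warnings.warn(f"no condition-specific groups for {condition}")
        for gid, genes in groups:
            for g in genes:
                provenance.setdefault(g, []).append(f"group:{gid}")
        for label, mod_genes in weighted_modules:
            mod_in = set(mod_genes) & uni
            hit_any = False
            for gid, genes in groups:
                grp_in = set(genes) & uni
                k = len(grp_in & mod_in)
                p = hypergeom_overlap_p(len(uni), len(grp_in), len(mod_in), k)
                sig = p < alpha
                tests.append(OverlapTest(condition, gid, label, len(uni),
                                         len(grp_in), len(mod_in), k, p, sig))
                hit_any = hit_any or sig
            if hit_any:
                assigned.append(label)
                for g in mod_genes:
                    provenance.setdefault(g, []).append(f"module:{label}")
        genes = sorted(provenance, key=lambda g: order.get(g, len(order)))
        gene_sets[condition] = ConditionGeneSet(condition, genes, provenance,
                                                assigned)
        logger.info("%s gene set: %d genes from %d groups + %d modules",
                    condition, len(genes), len(groups), len(assigned))

    both = set(gene_sets.get("relapse", ConditionGeneSet("relapse", [])).assigned_modules) \
        & set(gene_sets.get("remission", ConditionGeneSet("remission", [])).assigned_modules)
    if both:
        logger.info("modules assigned to both conditions: %s", sorted(both))

    table = pd.DataFrame(
        {
            "condition": [t.condition for t in tests],
            "group": [t.group_id for t in tests],
            "module": [t.module_label for t in tests],
            "U": [t.universe for t in tests],
            "m": [t.m for t in tests],
            "n": [t.n for t in tests],
            "k": [t.k for t in tests],
            "p": [t.p_value for t in tests],
            "assigned": [t.assigned for t in tests],
        }
    )
    return gene_sets, table
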