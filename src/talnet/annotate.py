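"""Gene-set enrichment, pathway crosstalk, and the drug-miRNA network.

Over-representation analysis (ORA) is a hypergeometric upper-tail test of
a query gene set against each pathway of a GMT collection, with
Benjamini-Hochberg adjustment across pathways.  Crosstalk is
operationalised as shared membership: a bipartite gene-pathway graph over
the enriched pathways, with crosstalk genes defined as genes annotated to
at least two of them, and a pathway-pathway projection weighted by
shared-gene counts.

The drug-miRNA network restricts a drug-effect table to differentially
expressed miRNAs and flags candidate edges whose drug effect opposes the
miRNA's relapse direction (a drug that up-regulates a miRNA that is down
in relapse, or vice versa).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .integrate import hypergeom_overlap_p

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT format: pathway <tab> description <tab> gene1 <tab> gene2 ..."""
    pathways: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        pathways[fields[0]] = fields[2:]
    return pathways


def write_gmt(pathways: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    lines = []
    for name, genes in pathways.items():
        desc = descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def ora_enrichment(query: list[str], pathways: dict[str, list[str]],
                   universe: list[str], alpha: float = 0.01,
                   adjust: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    Pathways and the query are intersected with the universe first.
    Returns one row per pathway sorted by p then name, with an
    ``enriched`` flag at level ``alpha`` on the BH-adjusted p
    (raw p when ``adjust=False``).
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query) & uni
    if set(query) - uni:
        logger.info("ora: %d query genes outside the universe ignored",
                    len(set(query) - uni))
    rows = []
    for name in sorted(pathways):
        pset = set(pathways[name]) & uni
        k = len(pset & q)
        p = hypergeom_overlap_p(len(uni), len(pset), len(q), k)
        rows.append((name, k, len(pset), len(uni), p))
    df = pd.DataFrame(rows, columns=["pathway", "hits", "set_size",
                                     "universe", "p"])
    if len(df):
        from statsmodels.stats.multitest import multipletests
        df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1]
        crit = df["adj_p"] if adjust else df["p"]
        df["enriched"] = crit < alpha
        df = df.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
    else:
        df["adj_p"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# crosstalk
# ---------------------------------------------------------------------------

def build_crosstalk_graph(genes: list[str],
                          enriched_pathways: dict[str, list[str]]
                          ) -> tuple[nx.Graph, list[str], pd.DataFrame]:
    """Bipartite gene-pathway graph over enriched pathways.

    Returns the bipartite graph (node attr ``kind`` in {gene, pathway}),
    the crosstalk gene list (genes linked to >= 2 enriched pathways), and
    the pathway-pathway projection table weighted by shared genes.
    """
    gset = set(genes)
    g = nx.Graph()
    for pw in sorted(enriched_pathways):
        members = sorted(set(enriched_pathways[pw]) & gset)
        for gene in members:
            if gene not in g:
                g.add_node(gene, kind="gene")
            if pw not in g:
                g.add_node(pw, kind="pathway")
            g.add_edge(gene, pw)
    crosstalk = sorted(
        n for n, d in g.nodes(data=True)
        if d["kind"] == "gene" and g.degree(n) >= 2
    )
    names = sorted(enriched_pathways)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared = len((set(enriched_pathways[a]) & gset)
                         & (set(enriched_pathways[b]) & gset))
            if shared:
                rows.append((a, b, shared))
    proj = pd.DataFrame(rows, columns=["pathway_a", "pathway_b", "shared_genes"])
    return g, crosstalk, proj


# ---------------------------------------------------------------------------
# drug-miRNA network
# ---------------------------------------------------------------------------

def build_drug_mirna_network(dem_calls: dict[str, str],
                             drug_table: pd.DataFrame) -> pd.DataFrame:
    """Drug-miRNA edges restricted to DE miRNAs, with concordance flags.

    ``dem_calls`` maps miRNA id to its relapse call (up/down).  Rows whose
    miRNA is not differentially expressed are skipped (counted in the
    log); rows with a malformed effect value are rejected and logged.
    A candidate (concordant) edge has the drug effect opposing the
    relapse direction.
    """
    required = {"drug", "mirna", "effect"}
    if not required <= set(drug_table.columns):
        raise ValueError(f"drug table needs columns {sorted(required)}")
    dems = {m for m, c in dem_calls.items() if c in ("up", "down")}
    rows = []
    n_unknown = n_bad = 0
    for drug, mirna, effect in zip(drug_table["drug"], drug_table["mirna"],
                                   drug_table["effect"]):
        if effect not in ("up", "down"):
            n_bad += 1
            continue
        if mirna not in dems:
            n_unknown += 1
            continue
        call = dem_calls[mirna]
        concordant = (effect == "down" and call == "up") or \
                     (effect == "up" and call == "down")
        rows.append((drug, mirna, effect, call, concordant))
    if n_unknown:
        logger.info("drug network: %d rows referencing non-DE miRNAs skipped",
                    n_unknown)
    if n_bad:
        logger.warning("drug network: %d rows with malformed effect rejected",
                       n_bad)
    df = pd.DataFrame(rows, columns=["drug", "mirna", "effect",
                                     "relapse_call", "candidate"])
    return df.sort_values(["drug", "mirna"], kind="mergesort").reset_index(drop=True)


def drug_network_graph(edges: pd.DataFrame) -> nx.Graph:
    g = nx.Graph()
    for drug, mirna, cand in zip(edges["drug"], edges["mirna"],
                                 edges["candidate"]):
        g.add_node(drug, kind="drug")
        g.add_node(mirna, kind="miRNA")
        g.add_edge(drug, mirna, candidate=bool(cand))
    return g
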