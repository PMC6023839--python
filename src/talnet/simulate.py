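"""Synthetic two-condition expression data with known planted structure.

The generator emulates the study design the pipeline targets: a small
two-group microarray cohort (5 relapse vs 7 remission samples), paired
gene and miRNA log2 matrices, typed regulatory edge tables, pathway sets
and a drug-miRNA effect table.  Everything detectable downstream is
planted explicitly and recorded in a :class:`SyntheticTruth`:

* co-expressed modules follow a single-factor model per module and
  condition — gene = baseline + loading * factor + noise — so the
  within-module pairwise correlation has the closed form
  loading^2 / (loading^2 + noise_sd^2); a module is active in relapse,
  remission, or both (an inactive condition contributes no factor);
* differential features receive a condition mean shift on the log2 scale;
* "stable" features are built with complete separation of the two
  conditions' sample values (shift 6x noise_sd, then verified and nudged
  if a noise draw ever breaks the separation);
* regulatory edge tables contain every planted miRNA-TF-gene
  feed-forward loop plus Bernoulli background edges at a stated density;
* the drug table carries forced drug-miRNA-effect rows plus random ones.

One global seed fans out to per-stage child seeds, so each artefact is
individually reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, sample_table

DEFAULT_EDGE_DENSITY = {
    "mirna_gene": 0.004,
    "mirna_tf": 0.01,
    "tf_gene": 0.006,
    "tf_mirna": 0.004,
}


@dataclass
class PlantedModule:
    name: str
    gene_ids: list[str]
    active: str              # "relapse" | "remission" | "both"
    loading: float

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError(f"module {self.name}: needs >= 2 genes")
        if not 0 < self.loading <= 1:
            raise ValueError(f"module {self.name}: loading must be in (0, 1]")
        if self.active not in ("relapse", "remission", "both"):
            raise ValueError(f"module {self.name}: bad active={self.active!r}")


@dataclass
class DEFeature:
    feature: str
    log2_shift: float        # positive magnitude
    direction: str           # "up" | "down" (relative to relapse)

    def __post_init__(self) -> None:
        if self.log2_shift <= 0:
            raise ValueError(f"{self.feature}: log2_shift must be positive")
        if self.direction not in ("up", "down"):
            raise ValueError(f"{self.feature}: bad direction {self.direction!r}")


@dataclass
class StableFeature:
    feature: str
    direction: str           # "up" | "down" (relative to relapse)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"{self.feature}: bad direction {self.direction!r}")


@dataclass
class SimulationConfig:
    n_genes: int = 800
    n_mirnas: int = 80
    n_tfs: int = 40
    n_samples_relapse: int = 5
    n_samples_remission: int = 7
    modules: list[PlantedModule] = field(default_factory=list)
    de_spec: list[DEFeature] = field(default_factory=list)
    stable_spec: list[StableFeature] = field(default_factory=list)
    noise_sd: float = 0.25
    baseline_range: tuple[float, float] = (2.5, 5.0)
    ffl_spec: list[tuple[str, str, str]] = field(default_factory=list)
    edge_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EDGE_DENSITY))
    orthogonal_factors: bool = False
    # core-periphery attachment: per-gene multiplier on the module loading,
    # drawn uniformly from this range ((1, 1) = homogeneous modules, for
    # which the loading^2/(loading^2+noise_sd^2) calibration holds exactly)
    attachment_range: tuple[float, float] = (1.0, 1.0)
    # optional background connectivity continuum: the LAST background_n
    # genes of the universe load on one shared axis per condition with
    # per-gene strength background_cmax * U^background_cpow (emulates the
    # dominant global covariation of real expression data, which gives the
    # network its approximately scale-free connectivity spectrum)
    background_n: int = 0
    background_cmax: float = 0.9
    background_cpow: float = 1.0
    seed: int = 0

    # -- universes ---------------------------------------------------------

    def gene_universe(self) -> list[str]:
        """Gene ids with TF ids interleaved at regular positions."""
        if self.n_tfs > self.n_genes:
            raise ValueError("more TFs than genes")
        step = max(1, self.n_genes // max(self.n_tfs, 1))
        tf_positions = set(range(0, step * self.n_tfs, step))
        ids, tf_i, g_i = [], 0, 0
        for pos in range(self.n_genes):
            if pos in tf_positions and tf_i < self.n_tfs:
                tf_i += 1
                ids.append(f"TF{tf_i:03d}")
            else:
                g_i += 1
                ids.append(f"G{g_i:04d}")
        return ids

    def tf_list(self) -> list[str]:
        return [f"TF{i:03d}" for i in range(1, self.n_tfs + 1)]

    def mirna_universe(self) -> list[str]:
        return [f"miR-{i:03d}" for i in range(1, self.n_mirnas + 1)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        rel = [f"R{i}" for i in range(1, self.n_samples_relapse + 1)]
        rem = [f"N{i}" for i in range(1, self.n_samples_remission + 1)]
        return rel, rem

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for count in (self.n_genes, self.n_mirnas, self.n_tfs,
                      self.n_samples_relapse, self.n_samples_remission):
            if count <= 0:
                raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        genes = set(self.gene_universe())
        mirnas = set(self.mirna_universe())
        universe = genes | mirnas
        for mod in self.modules:
            unknown = set(mod.gene_ids) - genes
            if unknown:
                raise ValueError(f"module {mod.name}: unknown genes "
                                 f"{sorted(unknown)[:5]}")
        directions: dict[str, str] = {}
        for spec in [*self.de_spec, *self.stable_spec]:
            if spec.feature not in universe:
                raise ValueError(f"unknown feature {spec.feature!r} in spec")
            prev = directions.setdefault(spec.feature, spec.direction)
            if prev != spec.direction:
                raise ValueError(
                    f"conflicting directions for {spec.feature!r}: "
                    f"{prev} vs {spec.direction}")
        tfs = set(self.tf_list())
        for m, t, g in self.ffl_spec:
            if m not in mirnas:
                raise ValueError(f"ffl_spec: unknown miRNA {m!r}")
            if t not in tfs:
                raise ValueError(f"ffl_spec: unknown TF {t!r}")
            if g not in genes or g in tfs:
                raise ValueError(f"ffl_spec: unknown target gene {g!r}")
        for key, dens in self.edge_density.items():
            if key not in DEFAULT_EDGE_DENSITY:
                raise ValueError(f"unknown edge type {key!r}")
            if not 0 <= dens <= 1:
                raise ValueError(f"edge density {key} out of [0,1]")
        lo, hi = self.attachment_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("attachment_range must satisfy 0 < lo <= hi <= 1")
        if self.background_n < 0 or self.background_n > self.n_genes:
            raise ValueError("background_n out of range")


@dataclass
class SyntheticTruth:
    """Ground-truth record of everything the generator planted."""

    modules: list[PlantedModule] = field(default_factory=list)
    de_genes_up: list[str] = field(default_factory=list)
    de_genes_down: list[str] = field(default_factory=list)
    de_mirnas_up: list[str] = field(default_factory=list)
    de_mirnas_down: list[str] = field(default_factory=list)
    stable_genes: dict[str, str] = field(default_factory=dict)
    stable_mirnas: dict[str, str] = field(default_factory=dict)
    ffls: list[tuple[str, str, str]] = field(default_factory=list)
    drug_concordant: list[tuple[str, str]] = field(default_factory=list)

    def modules_active_in(self, condition: str) -> list[PlantedModule]:
        return [m for m in self.modules if m.active in (condition, "both")]

    def to_json(self, path: str | Path) -> None:
        data = {
            "modules": [
                {"name": m.name, "genes": m.gene_ids, "active": m.active,
                 "loading": m.loading}
                for m in self.modules
            ],
            "de_genes_up": self.de_genes_up,
            "de_genes_down": self.de_genes_down,
            "de_mirnas_up": self.de_mirnas_up,
            "de_mirnas_down": self.de_mirnas_down,
            "stable_genes": self.stable_genes,
            "stable_mirnas": self.stable_mirnas,
            "ffls": [list(f) for f in self.ffls],
            "drug_concordant": [list(p) for p in self.drug_concordant],
        }
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            modules=[PlantedModule(d["name"], list(d["genes"]), d["active"],
                                   d["loading"]) for d in data["modules"]],
            de_genes_up=list(data["de_genes_up"]),
            de_genes_down=list(data["de_genes_down"]),
            de_mirnas_up=list(data["de_mirnas_up"]),
            de_mirnas_down=list(data["de_mirnas_down"]),
            stable_genes=dict(data["stable_genes"]),
            stable_mirnas=dict(data["stable_mirnas"]),
            ffls=[tuple(f) for f in data["ffls"]],
            drug_concordant=[tuple(p) for p in data["drug_concordant"]],
        )


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------

def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    names = ("gene", "mirna", "edges", "pathways", "drugs")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _condition_factors(rng: np.random.Generator, n_samples: int, k: int,
                       orthogonal: bool) -> np.ndarray:
    """k latent factor sample-vectors, zero mean, unit sd; optionally
    mutually orthogonal (requires k <= n_samples - 1)."""
    if k == 0:
        return np.empty((0, n_samples))
    raw = rng.standard_normal((n_samples, k))
    if not orthogonal:
        return raw.T
    if k > n_samples - 1:
        raise ValueError(
            f"cannot orthogonalise {k} factors in {n_samples} samples "
            f"(needs k <= n_samples - 1)")
    centered = raw - raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(centered)
    return (q * np.sqrt(n_samples - 1)).T


def _apply_stable(values: np.ndarray, rel_idx: np.ndarray, rem_idx: np.ndarray,
                  direction: str) -> np.ndarray:
    """Enforce complete separation for one feature row (in place)."""
    hi, lo = (rel_idx, rem_idx) if direction == "up" else (rem_idx, rel_idx)
    gap = values[hi].min() - values[lo].max()
    if gap <= 0:
        values[hi] += -gap + 0.05
    return values


def generate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix,
                                   SyntheticTruth]:
    """Generate the paired gene and miRNA matrices and the truth record."""
    config.validate()
    rngs = _stage_rngs(config.seed)
    rel, rem = config.sample_ids()
    samples = rel + rem
    cond = {**{s: "relapse" for s in rel}, **{s: "remission" for s in rem}}
    rel_idx = np.arange(len(rel))
    rem_idx = np.arange(len(rel), len(samples))

    truth = SyntheticTruth(modules=list(config.modules),
                           ffls=list(config.ffl_spec))

    def build_matrix(universe: list[str], rng: np.random.Generator,
                     with_modules: bool) -> np.ndarray:
        n = len(universe)
        lo, hi = config.baseline_range
        vals = np.tile(rng.uniform(lo, hi, size=n)[:, None], (1, len(samples)))
        if with_modules:
            index = {g: i for i, g in enumerate(universe)}
            a_lo, a_hi = config.attachment_range
            attach = {m.name: rng.uniform(a_lo, a_hi, len(m.gene_ids))
                      for m in config.modules}
            bg_strength = None
            if config.background_n:
                bg_strength = (config.background_cmax
                               * rng.random(config.background_n)
                               ** config.background_cpow)
            for condition, idx in (("relapse", rel_idx), ("remission", rem_idx)):
                active = [m for m in config.modules
                          if m.active in (condition, "both")]
                factors = _condition_factors(rng, len(idx), len(active),
                                             config.orthogonal_factors)
                for mod, fac in zip(active, factors):
                    gi = [index[g] for g in mod.gene_ids]
                    load = mod.loading * attach[mod.name]
                    vals[np.ix_(gi, idx)] += load[:, None] * fac[None, :]
                if bg_strength is not None:
                    fac = rng.standard_normal(len(idx))
                    vals[-config.background_n:, idx] += \
                        bg_strength[:, None] * fac[None, :]
        return vals

    gene_ids = config.gene_universe()
    mirna_ids = config.mirna_universe()
    gene_vals = build_matrix(gene_ids, rngs["gene"], with_modules=True)
    mirna_vals = build_matrix(mirna_ids, rngs["mirna"], with_modules=False)

    gidx = {g: i for i, g in enumerate(gene_ids)}
    midx = {m: i for i, m in enumerate(mirna_ids)}

    def shift_feature(feature: str, shift: float, direction: str) -> None:
        signed = shift if direction == "up" else -shift
        if feature in gidx:
            gene_vals[gidx[feature], rel_idx] += signed
        else:
            mirna_vals[midx[feature], rel_idx] += signed

    for spec in config.de_spec:
        shift_feature(spec.feature, spec.log2_shift, spec.direction)
        is_gene = spec.feature in gidx
        target = (truth.de_genes_up if is_gene else truth.de_mirnas_up) \
            if spec.direction == "up" else \
            (truth.de_genes_down if is_gene else truth.de_mirnas_down)
        target.append(spec.feature)

    stable_shift = 6.0 * config.noise_sd
    for spec in config.stable_spec:
        shift_feature(spec.feature, stable_shift, spec.direction)
        if spec.feature in gidx:
            truth.stable_genes[spec.feature] = f"stable_{spec.direction}"
        else:
            truth.stable_mirnas[spec.feature] = f"stable_{spec.direction}"

    gene_vals += rngs["gene"].normal(0.0, config.noise_sd, gene_vals.shape)
    mirna_vals += rngs["mirna"].normal(0.0, config.noise_sd, mirna_vals.shape)

    for spec in config.stable_spec:
        if spec.feature in gidx:
            _apply_stable(gene_vals[gidx[spec.feature]], rel_idx, rem_idx,
                          spec.direction)
        else:
            _apply_stable(mirna_vals[midx[spec.feature]], rel_idx, rem_idx,
                          spec.direction)

    gene_em = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=gene_ids, columns=samples), cond)
    mirna_em = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirna_ids, columns=samples), cond)
    return gene_em, mirna_em, truth


# ---------------------------------------------------------------------------
# regulatory edges
# ---------------------------------------------------------------------------

def generate_regulatory_edges(config: SimulationConfig,
                              truth: SyntheticTruth,
                              rng: np.random.Generator | None = None
                              ) -> pd.DataFrame:
    """Typed edge table containing all planted FFLs plus background edges.

    Background edges are Bernoulli draws per candidate (source, target)
    pair at the per-type densities in ``config.edge_density``; no
    self-edges, no duplicate (source, target) rows.
    """
    config.validate()
    if rng is None:
        rng = _stage_rngs(config.seed)["edges"]
    tfs = config.tf_list()
    genes = [g for g in config.gene_universe() if g not in set(tfs)]
    mirnas = config.mirna_universe()

    pair_spaces = {
        "mirna_gene": (mirnas, genes, "miRNA", "gene"),
        "mirna_tf": (mirnas, tfs, "miRNA", "TF"),
        "tf_gene": (tfs, genes, "TF", "gene"),
        "tf_mirna": (tfs, mirnas, "TF", "miRNA"),
    }
    rows: list[tuple[str, str, str, str]] = []
    seen: set[tuple[str, str]] = set()

    for m, t, g in truth.ffls:
        for src, tgt, st, tt in ((m, t, "miRNA", "TF"),
                                 (m, g, "miRNA", "gene"),
                                 (t, g, "TF", "gene")):
            if (src, tgt) not in seen:
                seen.add((src, tgt))
                rows.append((src, tgt, st, tt))

    for key in sorted(pair_spaces):
        sources, targets, st, tt = pair_spaces[key]
        dens = config.edge_density.get(key, 0.0)
        if dens <= 0:
            continue
        mask = rng.random((len(sources), len(targets))) < dens
        for i, j in zip(*np.nonzero(mask)):
            src, tgt = sources[i], targets[j]
            if src == tgt or (src, tgt) in seen:
                continue
            seen.add((src, tgt))
            rows.append((src, tgt, st, tt))

    return pd.DataFrame(rows, columns=["source", "target", "source_type",
                                       "target_type"])


# ---------------------------------------------------------------------------
# pathways and drugs
# ---------------------------------------------------------------------------

def generate_pathway_annotation(universe: list[str], sizes: list[int],
                                seed: int | np.random.Generator,
                                disjoint: bool = False,
                                bias_pools: dict[int, tuple[list[str], float]]
                                | None = None) -> dict[str, list[str]]:
    """Random pathway gene sets drawn from ``universe``.

    ``sizes[i]`` is the size of pathway ``PATHWAY_{i+1:02d}``; with
    ``disjoint=True`` the sets are sampled without replacement across
    pathways.  ``bias_pools`` may map a pathway index to ``(pool, frac)``
    so that a fraction of that pathway's genes is drawn from a specific
    pool (e.g. a planted module) to create a recoverable enrichment.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    if sum(sizes) > len(universe) and disjoint:
        raise ValueError("disjoint pathway sizes exceed the universe")
    if max(sizes, default=0) > len(universe):
        raise ValueError("pathway size exceeds the universe")
    bias_pools = bias_pools or {}
    available = list(universe)
    pathways: dict[str, list[str]] = {}
    for i, size in enumerate(sizes):
        name = f"PATHWAY_{i + 1:02d}"
        chosen: list[str] = []
        if i in bias_pools:
            pool, frac = bias_pools[i]
            pool = [g for g in pool if g in set(available)]
            n_bias = min(int(round(frac * size)), len(pool))
            chosen.extend(rng.choice(pool, size=n_bias, replace=False))
        rest_pool = [g for g in available if g not in set(chosen)]
        n_rest = size - len(chosen)
        if n_rest > len(rest_pool):
            raise ValueError(f"pathway {name}: not enough genes left")
        chosen.extend(rng.choice(rest_pool, size=n_rest, replace=False))
        pathways[name] = sorted(chosen)
        if disjoint:
            available = [g for g in available if g not in set(chosen)]
    return pathways


def generate_drug_mirna_table(mirna_universe: list[str], n_drugs: int,
                              seed: int | np.random.Generator,
                              forced_pairs: list[tuple[str, str, str]]
                              | None = None,
                              targets_per_drug: tuple[int, int] = (1, 5)
                              ) -> pd.DataFrame:
    """Drug-miRNA effect table (effect in {up, down}).

    ``forced_pairs`` rows (drug, mirna, effect) are included verbatim;
    each drug additionally targets a random number of random miRNAs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    forced = forced_pairs or []
    mset = set(mirna_universe)
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for drug, mirna, effect in forced:
        if mirna not in mset:
            raise ValueError(f"forced pair references unknown miRNA {mirna!r}")
        if effect not in ("up", "down"):
            raise ValueError(f"forced pair has bad effect {effect!r}")
        if (drug, mirna) not in seen:
            seen.add((drug, mirna))
            rows.append((drug, mirna, effect))
    lo, hi = targets_per_drug
    for i in range(1, n_drugs + 1):
        drug = f"DRUG{i:02d}"
        n_targets = int(rng.integers(lo, hi + 1))
        targets = rng.choice(mirna_universe, size=min(n_targets, len(mset)),
                             replace=False)
        for mirna in targets:
            effect = "up" if rng.random() < 0.5 else "down"
            if (drug, mirna) not in seen:
                seen.add((drug, mirna))
                rows.append((drug, str(mirna), effect))
    return pd.DataFrame(rows, columns=["drug", "mirna", "effect"])


# ---------------------------------------------------------------------------
# default configuration and full dataset
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, orthogonal_factors: bool = False
                   ) -> SimulationConfig:
    """The default desk-scale study: 800 genes (40 of them TFs), 80 miRNAs.

    Plants 20 co-expression modules (16 both-condition with sizes 20-50
    and loadings 0.80-0.95, two relapse-specific and two remission-specific
    of sizes 30-35 at loading 0.9), 60 differential genes (fold change
    2-4x), 20 stable genes, 25 differential miRNAs (5 up / 20 down,
    echoing the strong down-skew of the motivating design), 4 stable
    miRNAs, 6 feed-forward loops wired into the condition-specific
    modules, and background regulatory edges.
    """
    cfg = SimulationConfig(seed=seed, orthogonal_factors=orthogonal_factors)
    genes = cfg.gene_universe()
    mirnas = cfg.mirna_universe()
    tfset = set(cfg.tf_list())

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        chunk = genes[cursor:cursor + n]
        if len(chunk) < n:
            raise ValueError("default universe too small")
        cursor += n
        return chunk

    modules: list[PlantedModule] = []
    modules.append(PlantedModule("relapse_A", take(42), "relapse", 0.9))
    modules.append(PlantedModule("remission_A", take(40), "remission", 0.9))
    modules.append(PlantedModule("relapse_B", take(38), "relapse", 0.9))
    modules.append(PlantedModule("remission_B", take(36), "remission", 0.9))
    both_sizes = [20, 21, 22, 23, 24, 25, 26, 27, 29, 31, 33, 36, 39, 42, 46, 50]
    loadings = [0.95, 0.9, 0.85, 0.8]
    for i, size in enumerate(both_sizes):
        modules.append(PlantedModule(f"both_{i + 1:02d}", take(size), "both",
                                     loadings[i % len(loadings)]))
    cfg.modules = modules

    shifts = [1.0, 1.2, 1.5, 1.8, 2.0]
    de_genes_up = take(30)
    de_genes_down = take(30)
    cfg.de_spec = [DEFeature(g, shifts[i % len(shifts)], "up")
                   for i, g in enumerate(de_genes_up)]
    cfg.de_spec += [DEFeature(g, shifts[i % len(shifts)], "down")
                    for i, g in enumerate(de_genes_down)]

    stable_up = take(12)
    stable_down = take(8)
    cfg.stable_spec = [StableFeature(g, "up") for g in stable_up]
    cfg.stable_spec += [StableFeature(g, "down") for g in stable_down]

    mirna_up = mirnas[:5]
    mirna_down = mirnas[5:25]
    cfg.de_spec += [DEFeature(m, shifts[i % len(shifts)], "up")
                    for i, m in enumerate(mirna_up)]
    cfg.de_spec += [DEFeature(m, shifts[i % len(shifts)], "down")
                    for i, m in enumerate(mirna_down)]
    cfg.stable_spec += [StableFeature(m, "up") for m in mirnas[25:27]]
    cfg.stable_spec += [StableFeature(m, "down") for m in mirnas[27:29]]

    def module_tf_gene(mod: PlantedModule) -> tuple[str, str]:
        tfs_in = [g for g in mod.gene_ids if g in tfset]
        genes_in = [g for g in mod.gene_ids if g not in tfset]
        if not tfs_in or not genes_in:
            raise ValueError(f"module {mod.name} lacks a TF or gene for FFLs")
        return tfs_in[0], genes_in[0]

    ffls: list[tuple[str, str, str]] = []
    for i, mod_name in enumerate(["relapse_A", "relapse_B", "relapse_A",
                                  "remission_A", "remission_B", "remission_A"]):
        mod = next(m for m in modules if m.name == mod_name)
        tf, gene = module_tf_gene(mod)
        if i in (2, 5):  # second FFL in the same module: next gene
            gene = [g for g in mod.gene_ids if g not in tfset][1]
        mirna = (mirna_down + mirna_up)[i]
        ffls.append((mirna, tf, gene))
    cfg.ffl_spec = ffls
    return cfg


def wgcna_benchmark_config(seed: int = 0) -> SimulationConfig:
    """A 20-module structure for weighted-network benchmarking.

    Heavy-tailed module sizes (20-115 genes), cycling loadings
    0.95/0.90/0.85/0.80, core-periphery attachment U(0.7, 1), and a
    700-gene background connectivity continuum, all active in both
    conditions.  Emulates the continuously varying connectivity of real
    co-expression data at the 5+7-sample design scale.
    """
    sizes = [20, 20, 20, 21, 21, 22, 22, 23, 24, 25,
             26, 28, 30, 33, 37, 43, 52, 65, 85, 115]
    loadings = [0.95, 0.9, 0.85, 0.8]
    n_bg = 700
    cfg = SimulationConfig(seed=seed, n_genes=sum(sizes) + n_bg,
                           n_mirnas=10, n_tfs=10,
                           attachment_range=(0.7, 1.0),
                           background_n=n_bg)
    genes = cfg.gene_universe()
    cur = 0
    mods = []
    for i, size in enumerate(sizes):
        mods.append(PlantedModule(f"both_{i + 1:02d}", genes[cur:cur + size],
                                  "both", loadings[i % len(loadings)]))
        cur += size
    cfg.modules = mods
    return cfg


def diffcoex_benchmark_config(seed: int = 0) -> SimulationConfig:
    """Condition-specific co-expression benchmark.

    Two relapse-specific modules (35 and 32 genes, loading 0.9), two
    both-condition modules (40 and 30 genes), orthogonalised latent
    factors (4 active factors in the 5 relapse samples, the maximum the
    design permits), noise sd 0.25, and a pure-noise remainder that the
    CV filter removes.
    """
    cfg = SimulationConfig(seed=seed, n_genes=300, n_mirnas=10, n_tfs=10,
                           orthogonal_factors=True)
    genes = cfg.gene_universe()
    cur = 0

    def take(n: int) -> list[str]:
        nonlocal cur
        chunk = genes[cur:cur + n]
        cur += n
        return chunk

    cfg.modules = [
        PlantedModule("relapse_A", take(35), "relapse", 0.9),
        PlantedModule("relapse_B", take(32), "relapse", 0.9),
        PlantedModule("both_A", take(40), "both", 0.9),
        PlantedModule("both_B", take(30), "both", 0.9),
    ]
    return cfg


def default_drug_forced_pairs(config: SimulationConfig
                              ) -> list[tuple[str, str, str]]:
    """Three concordant candidates echoing the drug-reactivates-miRNA
    pattern (drug up-regulates a miRNA that is down in relapse)."""
    mirnas = config.mirna_universe()
    return [
        ("DRUG01", mirnas[5], "up"),    # down-in-relapse miRNA, drug raises it
        ("DRUG02", mirnas[6], "up"),
        ("DRUG03", mirnas[0], "down"),  # up-in-relapse miRNA, drug lowers it
    ]


def write_dataset(config: SimulationConfig, outdir: str | Path
                  ) -> dict[str, Path]:
    """Generate and write the complete synthetic dataset.

    Writes gene/miRNA expression TSVs, the sample table, the typed edge
    table, the TF list, a GMT pathway collection (two pathways biased
    towards the relapse-/remission-specific module genes so enrichment is
    recoverable), the drug table and the truth JSON.  Returns the path of
    each artefact.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(config.seed)

    gene_em, mirna_em, truth = generate_expression(config)
    edges = generate_regulatory_edges(config, truth, rngs["edges"])

    rel_pool = [g for m in truth.modules if m.active == "relapse"
                for g in m.gene_ids]
    rem_pool = [g for m in truth.modules if m.active == "remission"
                for g in m.gene_ids]
    sizes = [40, 40] + [int(s) for s in
                        rngs["pathways"].integers(25, 61, size=10)]
    bias: dict[int, tuple[list[str], float]] = {}
    if rel_pool:
        bias[0] = (rel_pool, 0.7)
    if rem_pool:
        bias[1] = (rem_pool, 0.7)
    pathways = generate_pathway_annotation(config.gene_universe(), sizes,
                                           rngs["pathways"], bias_pools=bias)

    forced = default_drug_forced_pairs(config)
    drugs = generate_drug_mirna_table(config.mirna_universe(), 15,
                                      rngs["drugs"], forced_pairs=forced)

    de_dir = {m: "up" for m in truth.de_mirnas_up}
    de_dir.update({m: "down" for m in truth.de_mirnas_down})
    for m, flag in truth.stable_mirnas.items():
        de_dir.setdefault(m, flag.replace("stable_", ""))
    truth.drug_concordant = sorted(
        (d, m) for d, m, eff in zip(drugs["drug"], drugs["mirna"],
                                    drugs["effect"])
        if m in de_dir and ((eff == "up" and de_dir[m] == "down")
                            or (eff == "down" and de_dir[m] == "up"))
    )

    paths = {
        "gene_expression": outdir / "gene_expression.tsv",
        "mirna_expression": outdir / "mirna_expression.tsv",
        "samples": outdir / "samples.tsv",
        "edges": outdir / "edges.tsv",
        "tf_list": outdir / "tf_list.txt",
        "pathways": outdir / "pathways.gmt",
        "drug_mirna": outdir / "drug_mirna.tsv",
        "truth": outdir / "truth.json",
    }
    gene_em.to_tsv(paths["gene_expression"], paths["samples"])
    mirna_em.to_tsv(paths["mirna_expression"])
    edges.to_csv(paths["edges"], sep="\t", index=False)
    paths["tf_list"].write_text("\n".join(config.tf_list()) + "\n")
    from .annotate import write_gmt
    write_gmt(pathways, paths["pathways"])
    drugs.to_csv(paths["drug_mirna"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
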