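import numpy as np
import pandas as pd
import pytest

from talnet import simulate
from talnet.matrix import ExpressionMatrix
from talnet.simulate import DEFeature, PlantedModule, SimulationConfig, StableFeature


def make_matrix(values: np.ndarray, n_relapse: int = 5, n_remission: int = 7,
                features=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with R*/N* sample ids."""
    n_feat = values.shape[0]
    cols = [f"R{i + 1}" for i in range(n_relapse)] + \
           [f"N{i + 1}" for i in range(n_remission)]
    cond = {c: ("relapse" if c.startswith("R") else "remission") for c in cols}
    if features is None:
        features = [f"g{i}" for i in range(n_feat)]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=cols),
                            cond)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def small_config(seed: int = 0) -> SimulationConfig:
    """A miniature study: 2 condition-specific + 1 both module, a few DE
    and stable features, one planted FFL — runs in seconds."""
    cfg = SimulationConfig(seed=seed, n_genes=160, n_mirnas=20, n_tfs=8)
    genes = cfg.gene_universe()
    mirnas = cfg.mirna_universe()
    cfg.modules = [
        PlantedModule("rel", genes[:32], "relapse", 0.9),
        PlantedModule("rem", genes[32:64], "remission", 0.9),
        PlantedModule("both", genes[64:96], "both", 0.9),
    ]
    cfg.de_spec = [DEFeature(g, 1.2, "up") for g in genes[96:104]]
    cfg.de_spec += [DEFeature(g, 1.2, "down") for g in genes[104:112]]
    cfg.de_spec += [DEFeature(m, 1.5, "down") for m in mirnas[:4]]
    cfg.stable_spec = [StableFeature(g, "up") for g in genes[112:116]]
    cfg.stable_spec += [StableFeature(mirnas[5], "down")]
    tf_in_rel = next(g for g in cfg.modules[0].gene_ids if g.startswith("TF"))
    gene_in_rel = next(g for g in cfg.modules[0].gene_ids
                       if not g.startswith("TF"))
    cfg.ffl_spec = [(mirnas[0], tf_in_rel, gene_in_rel)]
    return cfg


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """The full default synthetic dataset written to disk once per session."""
    outdir = tmp_path_factory.mktemp("data")
    cfg = simulate.default_config(seed=7)
    paths = simulate.write_dataset(cfg, outdir)
    truth = simulate.SyntheticTruth.from_json(paths["truth"])
    return {"config": cfg, "paths": paths, "truth": truth, "dir": outdir}
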