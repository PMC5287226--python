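import numpy as np
import pandas as pd
import pytest

from shapegene.config import PipelineConfig
from shapegene import morphology, synthdata


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def study(cfg):
    """One shared synthetic study (frozen seed) for cross-module tests."""
    return synthdata.generate_study(cfg)


@pytest.fixture(scope="session")
def correlations(cfg, study):
    records, significant = morphology.correlate_shape(
        study.expression, study.summary, cfg)
    return records, significant


@pytest.fixture(scope="session")
def edge_table(cfg, study, tmp_path_factory):
    from shapegene import netbuild

    path = tmp_path_factory.mktemp("edges") / "edges.tsv"
    study.edges.to_csv(path, sep="\t", index=False)
    return netbuild.load_edges(path, cfg.string_min_score)


@pytest.fixture(scope="session")
def network(cfg, study, correlations, edge_table):
    from shapegene import netbuild

    _, sig = correlations
    G = netbuild.build_network(sig, edge_table, cfg)
    return netbuild.analyze(G)


@pytest.fixture(scope="session")
def subnetwork(cfg, network):
    from shapegene import netbuild

    features = [v for v, d in network.nodes(data=True)
                if d.get("node_type") == "feature"]
    pathsets = [
        netbuild.extract_paths(network, f, tf, cfg)
        for f in sorted(features) for tf in ("SMAD3", "RELA")
    ]
    return netbuild.assemble_subnetwork(pathsets, network)


@pytest.fixture(scope="session")
def panel(cfg, study):
    from shapegene import rnai

    return rnai.preprocess_panel(study.panel, cfg)
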