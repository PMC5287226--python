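import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from shapegene import rnai
from shapegene.rnai import (
    KnockdownPanel,
    RawKnockdownPanel,
    TFTargetSet,
    call_direction,
    classify,
    define_targets,
    hypergeom_upper_tail,
    infer_edge_directions,
    preprocess_panel,
)


def _raw(values: dict, targets: dict, index) -> RawKnockdownPanel:
    return RawKnockdownPanel(
        values=pd.DataFrame(values, index=index).astype(float),
        pert_targets=pd.Series(targets),
    )


def _panel(z: dict, index) -> KnockdownPanel:
    return KnockdownPanel(z=pd.DataFrame(z, index=index).astype(float))


# ----------------------------------------------------------------------
# hypergeometric oracle


def _hyper_oracle(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    hits = set(range(K))
    count = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(hits.intersection(draw)) >= k:
            count += 1
    return count / total


def test_spec_worked_example_matches_enumeration():
    p = hypergeom_upper_tail(4, 10, 5, 4)
    assert p == pytest.approx(_hyper_oracle(4, 10, 5, 4))
    assert p == pytest.approx(5 / 210)
    assert p < 0.05


@pytest.mark.parametrize("N", [4, 7, 9])
def test_hypergeom_matches_enumeration(N):
    for K in range(N + 1):
        for n in range(N + 1):
            for k in range(min(K, n) + 1):
                assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                    _hyper_oracle(k, N, K, n), abs=1e-12)


def test_saturated_overlap_is_uninformative():
    assert hypergeom_upper_tail(5, 5, 5, 5) == pytest.approx(1.0)


# ----------------------------------------------------------------------
# preprocessing


def test_two_valid_probes_averaged(cfg):
    idx = ["G", "X", "Y"]
    raw = _raw(
        {"shG_1": [-2.0, 1.0, 0.0], "shG_2": [-3.0, 3.0, 0.0],
         "shX_1": [0.0, -2.0, 1.0], "shY_1": [1.0, 0.0, -2.0]},
        {"shG_1": "G", "shG_2": "G", "shX_1": "X", "shY_1": "Y"}, idx)
    panel = preprocess_panel(raw, cfg)
    assert list(panel.z.columns).count("G") == 1
    # consolidated pre-z values: G column averages the two probes
    assert panel.dropped == {}


def test_weak_knockdown_dropped(cfg):
    idx = ["G", "X"]
    raw = _raw({"shG_1": [-0.3, 1.0], "shX_1": [0.5, -2.0]},
               {"shG_1": "G", "shX_1": "X"}, idx)
    panel = preprocess_panel(raw, cfg)
    assert "G" not in panel.z.columns
    assert "shG_1" in panel.dropped


def test_boundary_exactly_at_threshold_dropped(cfg):
    idx = ["G", "X"]
    raw = _raw({"shG_1": [-0.4, 1.0], "shX_1": [0.5, -2.0]},
               {"shG_1": "G", "shX_1": "X"}, idx)
    panel = preprocess_panel(raw, cfg)
    assert "G" not in panel.z.columns  # z >= kd_valid_z is invalid


def test_unmeasured_target_dropped_not_error(cfg):
    idx = ["A", "B"]
    raw = _raw({"shZ_1": [0.1, 0.2], "shA_1": [-2.0, 0.0]},
               {"shZ_1": "Z", "shA_1": "A"}, idx)
    panel = preprocess_panel(raw, cfg)
    assert "Z" not in panel.z.columns
    assert panel.dropped["shZ_1"] == "target not measured"


def test_targeted_gene_most_negative_in_own_column(cfg, study, panel):
    # genes that receive planted downregulation from another knockdown
    # (regulon targets, expression-regulated TFs) can legitimately go lower
    # there; every other targeted gene bottoms out in its own column
    receives_effect = set()
    for regulon in study.truth.regulons.values():
        receives_effect |= set(regulon)
    for (_g, tf), (mode, _d) in study.truth.regulators.items():
        if mode == "expression":
            receives_effect.add(tf)
    for gene in panel.z.columns:
        if gene in receives_effect:
            continue
        assert panel.z.loc[gene].idxmin() == gene


# ----------------------------------------------------------------------
# target definition


def test_all_zero_column_gives_empty_targets(cfg):
    idx = ["TF", "A", "B"]
    panel = _panel({"TF": [0.0, 0.0, 0.0], "A": [0, 2, 0]}, idx)
    targets = define_targets(panel, "TF", cfg)
    assert targets.size == 0


def test_boundary_z_excluded(cfg):
    idx = ["TF", "A", "B"]
    panel = _panel({"TF": [-3.0, 1.5, 1.6]}, idx)
    targets = define_targets(panel, "TF", cfg)
    assert set(targets.signs) == {"B"}  # 1.5 is not > 1.5


def test_tf_excluded_from_own_targets(cfg):
    idx = ["TF", "A"]
    panel = _panel({"TF": [-3.0, 2.0]}, idx)
    targets = define_targets(panel, "TF", cfg)
    assert "TF" not in targets.signs


def test_absent_tf_errors(cfg):
    panel = _panel({"A": [0.0]}, ["A"])
    with pytest.raises(ValueError, match="TF"):
        define_targets(panel, "TF", cfg)


def test_planted_regulon_recovered(cfg, study, panel):
    for tf, regulon in study.truth.regulons.items():
        targets = define_targets(panel, tf, cfg)
        planted = set(regulon)
        called = set(targets.signs)
        assert planted <= called
        for g in planted:
            assert targets.signs[g] == regulon[g]


# ----------------------------------------------------------------------
# classification


def test_planted_regulators_classified(cfg, study, panel):
    calls = {}
    for tf in study.truth.regulons:
        targets = define_targets(panel, tf, cfg)
        for gene in panel.z.columns:
            if gene == tf:
                continue
            for call in classify(gene, tf, panel, targets, cfg):
                calls[(gene, tf, call.mode)] = call
    for (gene, tf), (mode, direction) in study.truth.regulators.items():
        if mode == "activation":
            call = calls[(gene, tf, "activation_regulator")]
            assert call.direction == direction
            assert call.p < cfg.hyper_alpha
            assert 0 <= call.k <= min(call.n, call.K) <= call.N
        else:
            call = calls[(gene, tf, "expression_regulator")]
            assert call.direction == direction
    # planted effectors: shape genes inside each regulon
    for tf, regulon in study.truth.regulons.items():
        for gene, sign in regulon.items():
            if gene.startswith("SG"):
                call = calls[(gene, tf, "tf_effector")]
                assert call.direction == ("up" if sign > 0 else "down")


def test_missing_column_yields_no_call(cfg):
    idx = ["TF", "A"]
    panel = _panel({"TF": [-3.0, 2.0]}, idx)
    targets = define_targets(panel, "TF", cfg)
    assert classify("A", "TF", panel, targets, cfg) == []


def test_direction_all_concordant(cfg):
    idx = ["TF", "A", "B", "C", "G"]
    panel = _panel({
        "TF": [-3.0, 2.0, -2.0, 2.0, 0.0],
        "G": [0.0, 2.0, -2.0, 2.0, -3.0],
    }, idx)
    targets = define_targets(panel, "TF", cfg)
    direction, conc = call_direction("G", "TF", panel, targets, cfg)
    assert direction == "activator"
    assert conc == 1.0


def test_direction_all_discordant(cfg):
    idx = ["TF", "A", "B", "C", "G"]
    panel = _panel({
        "TF": [-3.0, 2.0, -2.0, 2.0, 0.0],
        "G": [0.0, -2.0, 2.0, -2.0, -3.0],
    }, idx)
    targets = define_targets(panel, "TF", cfg)
    direction, conc = call_direction("G", "TF", panel, targets, cfg)
    assert direction == "inhibitor"
    assert conc == 0.0


def test_direction_zero_overlap_errors(cfg):
    idx = ["TF", "A", "G"]
    panel = _panel({"TF": [-3.0, 2.0, 0.0], "G": [0.0, 0.0, -3.0]}, idx)
    targets = define_targets(panel, "TF", cfg)
    with pytest.raises(ValueError, match="overlap"):
        call_direction("G", "TF", panel, targets, cfg)


def test_sign_flip_swaps_direction_keeps_p(cfg, study, panel):
    tf = "SMAD3"
    targets = define_targets(panel, tf, cfg)
    gene = next(g for (g, t), (m, d) in study.truth.regulators.items()
                if t == tf and m == "activation" and d == "activator")
    call = next(c for c in classify(gene, tf, panel, targets, cfg)
                if c.mode == "activation_regulator")
    flipped = KnockdownPanel(z=panel.z.copy())
    flipped.z[gene] = -flipped.z[gene]
    call_f = next(c for c in classify(gene, tf, flipped, targets, cfg)
                  if c.mode == "activation_regulator")
    assert call.direction == "activator"
    assert call_f.direction == "inhibitor"
    assert call_f.p == pytest.approx(call.p)
    assert call_f.concordance == pytest.approx(1.0 - call.concordance)


def test_raising_target_z_shrinks_sets(cfg, panel):
    loose = define_targets(panel, "SMAD3", cfg)
    strict = define_targets(panel, "SMAD3", cfg.replace(target_z=2.5))
    assert set(strict.signs) <= set(loose.signs)


def test_saturated_overlap_no_activation_call(cfg):
    # every measured gene is both a TF target and changed by G's knockdown
    idx = ["TF", "G", "A", "B", "C"]
    panel = _panel({
        "TF": [-3.0, 2.0, 2.0, 2.0, 2.0],
        "G": [2.0, -3.0, 2.0, 2.0, 2.0],
    }, idx)
    targets = define_targets(panel, "TF", cfg)
    calls = classify("G", "TF", panel, targets, cfg)
    assert not any(c.mode == "activation_regulator" for c in calls)


# ----------------------------------------------------------------------
# edge directionality


def test_edge_directions(cfg):
    idx = ["A", "B", "C"]
    panel = _panel({
        "A": [-3.0, 2.0, 0.0],   # A knockdown changes B
        "B": [0.0, -3.0, 0.0],   # B knockdown changes nothing else
        "C": [0.0, 0.0, -3.0],
    }, idx)
    G = nx.Graph()
    G.add_edge("A", "B", edge_type="interaction")
    G.add_edge("B", "C", edge_type="interaction")
    directed = infer_edge_directions(G, panel, cfg)
    assert ("A", "B") in directed
    assert ("B", "A") not in directed
    assert not any(e in directed for e in [("B", "C"), ("C", "B")])
    assert G.edges["A", "B"]["directions"] == "A->B"
    assert G.edges["B", "C"]["directions"] == ""


def test_planted_expression_regulator_edge_directed(cfg, study, panel, subnetwork):
    directed = infer_edge_directions(subnetwork.copy(), panel, cfg)
    for (gene, tf), (mode, _d) in study.truth.regulators.items():
        if mode == "expression" and subnetwork.has_edge(gene, tf):
            assert (gene, tf) in directed
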