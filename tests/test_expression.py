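"""Compendium assembly, quantile thresholds, penalties, GPR propagation."""

import math

import numpy as np
import pandas as pd
import pytest

import teamflux as tf
from teamflux.model import BoolOp, Gene


# ---------------------------------------------------------------------------
# Quantiles
# ---------------------------------------------------------------------------

def _nearest_rank_oracle(values, theta):
    """Independent sort-and-index quantile: 1-based rank ceil(theta/100 * n)."""
    v = sorted(values)
    if theta == 0:
        return v[0]
    rank = int(math.ceil(theta / 100.0 * len(v)))
    return v[min(rank, len(v)) - 1]


def test_quantile_degenerate_and_extremes():
    assert tf.empirical_quantile([5.0], 37.0) == 5.0
    grid = np.arange(1.0, 101.0)
    assert tf.empirical_quantile(grid, 0) == 1.0
    assert tf.empirical_quantile(grid, 100) == 100.0
    with pytest.raises(ValueError):
        tf.empirical_quantile([], 50)
    with pytest.raises(ValueError):
        tf.empirical_quantile([1.0], 101)


def test_quantile_matches_sort_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        v = rng.normal(size=rng.integers(1, 40))
        for theta in (0, 1, 10, 33, 50, 66.6, 90, 99, 100):
            assert tf.empirical_quantile(v, theta) == _nearest_rank_oracle(v, theta)


# ---------------------------------------------------------------------------
# Compendium assembly
# ---------------------------------------------------------------------------

def _frames():
    genes = ["g1", "g2", "g3", "g4"]
    ref = pd.DataFrame(np.arange(12).reshape(4, 3), index=genes,
                       columns=["r1", "r2", "r3"])
    exp = pd.DataFrame(np.arange(8).reshape(4, 2), index=genes, columns=["e1", "e2"])
    return ref, exp


def test_build_compendium_pools_columns():
    ref, exp = _frames()
    comp = tf.build_compendium(ref, exp)
    assert comp.values.shape == (4, 5)
    assert comp.source_labels == ["reference"] * 3 + ["experiment"] * 2


def test_build_compendium_disjoint_genes_error():
    ref, exp = _frames()
    exp.index = ["x1", "x2", "x3", "x4"]
    with pytest.raises(ValueError, match="empty gene intersection"):
        tf.build_compendium(ref, exp)


def test_scenario_compendium_sample_count(scenario):
    """Per-gene pooled count = reference arrays + time-course arrays (310)."""
    spec = scenario.spec
    assert scenario.compendium.n_samples == spec.compendium_size + spec.n_expression_timepoints
    assert scenario.compendium.n_samples == 310


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def _comp(data):
    genes = list(data)
    return tf.ExpressionCompendium(genes, np.array([data[g] for g in genes], float),
                                   ["reference"] * len(next(iter(data.values()))))


def test_type2_thresholds_are_per_gene_medians():
    comp = _comp({"g1": [1, 2, 3], "g2": [10, 20, 30]})
    spec = tf.compute_thresholds(comp, 2, 50)
    assert spec.x_g == {"g1": 2.0, "g2": 20.0}


def test_type1_threshold_pools_all_values():
    comp = _comp({"g1": [1, 2, 3], "g2": [10, 20, 30]})
    spec = tf.compute_thresholds(comp, 1, 50)
    assert spec.x_global == _nearest_rank_oracle([1, 2, 3, 10, 20, 30], 50)


def test_type2_equals_type1_on_identical_distributions():
    samples = [4.0, 7.0, 1.0, 9.0, 5.0]
    comp = _comp({"g1": samples, "g2": samples, "g3": samples})
    for theta in (10, 25, 50, 75, 95):
        t1 = tf.compute_thresholds(comp, 1, theta)
        t2 = tf.compute_thresholds(comp, 2, theta)
        assert all(x == t1.x_global for x in t2.x_g.values())


def test_thresholds_monotone_in_theta(scenario):
    comp = scenario.compendium
    prev1, prev2 = -np.inf, {g: -np.inf for g in comp.gene_ids}
    for theta in range(1, 100):
        x1 = tf.compute_thresholds(comp, 1, theta).x_global
        assert x1 >= prev1
        prev1 = x1
        spec2 = tf.compute_thresholds(comp, 2, theta)
        for g, x in spec2.x_g.items():
            assert x >= prev2[g]
        prev2 = spec2.x_g


def test_type3_requires_two_samples():
    comp = _comp({"g1": [1.0], "g2": [2.0]})
    with pytest.raises(ValueError, match="2 samples"):
        tf.compute_thresholds(comp, 3, 50)


# ---------------------------------------------------------------------------
# Penalties
# ---------------------------------------------------------------------------

def test_gene_penalty_rules():
    spec2 = tf.ThresholdSpec(2, 50, x_g={"g": 3.0})
    assert tf.compute_gene_penalties({"g": 5.0}, spec2)["g"] == 0.0
    assert tf.compute_gene_penalties({"g": 2.0}, spec2)["g"] == 1.0
    spec3 = tf.ThresholdSpec(3, 50, x_g={"g": 3.0}, sigma_g={"g": 0.5})
    assert tf.compute_gene_penalties({"g": 2.0}, spec3)["g"] == 2.0


def test_missing_genes_get_zero_penalty():
    spec = tf.ThresholdSpec(2, 50, x_g={"g": 3.0})
    p = tf.compute_gene_penalties({"g": 1.0}, spec, genes=["g", "unmeasured"])
    assert p["unmeasured"] == 0.0


def test_theta_zero_implies_no_penalties(scenario):
    """No expression value lies below the distribution minimum."""
    spec = tf.compute_thresholds(scenario.compendium, 2, 0)
    for t in scenario.expression_ts.times:
        p = tf.compute_gene_penalties(scenario.expression_ts.at(t), spec)
        assert all(v == 0.0 for v in p.values())
        pen = tf.propagate_reaction_penalties(p, scenario.model)
        assert np.all(pen.c == 0.0)


def test_type3_scale_invariance():
    """Scaling one gene's samples and expression by k scales x_g and sigma_g
    by k and leaves its penalty unchanged."""
    rng = np.random.default_rng(3)
    base = rng.normal(10, 2, size=50)
    for k in (0.1, 3.0, 250.0):
        comp = _comp({"g1": base, "g2": base * k})
        spec = tf.compute_thresholds(comp, 3, 70)
        assert spec.x_g["g2"] == pytest.approx(k * spec.x_g["g1"])
        assert spec.sigma_g["g2"] == pytest.approx(k * spec.sigma_g["g1"])
        expr = {"g1": 8.0, "g2": 8.0 * k}
        p = tf.compute_gene_penalties(expr, spec)
        assert p["g2"] == pytest.approx(p["g1"])


# ---------------------------------------------------------------------------
# GPR propagation
# ---------------------------------------------------------------------------

def test_propagation_and_or_rules(chain_model):
    model = tf.make_toy_overflow_model()
    j_tca = model.reaction_index("TCA")  # sdhA AND sdhB
    j_pta = model.reaction_index("PTA")  # pta OR ackA
    pen = tf.propagate_reaction_penalties(
        {"sdhA": 1.0, "sdhB": 3.0, "pta": 1.0, "ackA": 3.0}, model)
    assert pen.c[j_tca] == 3.0  # complex limited by the worst subunit
    assert pen.c[j_pta] == 1.0  # best isoenzyme carries the flux
    assert all(pen.c[j] == 0.0 for j in model.exchange_set)
    assert pen.c[model.biomass_reaction] == 0.0  # no GPR


def _oracle_eval(node, p):
    """Independent recursive evaluator (min/max over children)."""
    if isinstance(node, Gene):
        return p.get(node.name, 0.0)
    vals = tuple(_oracle_eval(c, p) for c in node.children)
    return {"and": max, "or": min}[node.op](vals)


def test_propagation_matches_recursive_oracle():
    from test_model import _random_tree

    rng = np.random.default_rng(17)
    genes = [f"g{i}" for i in range(6)]
    for _ in range(500):
        tree = _random_tree(rng, genes, depth=3)
        p = {g: float(rng.uniform(0, 5)) for g in genes}
        assert tf.evaluate_gpr(tree, p) == _oracle_eval(tree, p)


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def test_interpolation_basics():
    assert tf.interpolate_timeseries([0, 2], [0.0, 4.0], [1.0])[0] == 2.0
    out = tf.interpolate_timeseries([0, 1, 3], [5.0, 1.0, 9.0], [0, 1, 3])
    np.testing.assert_array_equal(out, [5.0, 1.0, 9.0])
    with pytest.raises(ValueError, match="outside"):
        tf.interpolate_timeseries([0, 2], [0.0, 4.0], [3.0])


def test_interpolation_recovers_piecewise_linear_truth():
    rng = np.random.default_rng(5)
    knots = np.sort(rng.uniform(0, 50, size=8))
    knots[0], knots[-1] = 0.0, 50.0
    vals = rng.uniform(0, 10, size=(3, 8))
    dense_t = np.linspace(0, 50, 101)
    dense = tf.interpolate_timeseries(knots, vals, dense_t)
    # querying the dense reconstruction reproduces it exactly at its own grid
    again = tf.interpolate_timeseries(dense_t, dense, dense_t[::7])
    np.testing.assert_allclose(again, dense[:, ::7], atol=1e-12)
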