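"""PLS path modelling: closed forms, recovery, bootstrap, effects."""

import numpy as np
import pandas as pd
import pytest

from lakeassembly import (
    PathModelSpec,
    bootstrap_paths,
    default_block_spec,
    fit_plspm,
    indirect_effects,
)
from lakeassembly.exceptions import ConfigError, InvalidInputError


def _chain_data(n=500, a=0.6, b=-0.4, noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = a * x + noise * rng.normal(size=n)
    y = b * m + noise * rng.normal(size=n)
    return pd.DataFrame({"x1": x, "m1": m, "y1": y})


def enumerate_paths(edges, src, dst, path=None):
    """Independent recursive enumeration of simple directed paths."""
    path = path or [src]
    if src == dst:
        return [path]
    out = []
    for s, t in edges:
        if s == src and t not in path:
            out.extend(enumerate_paths(edges, t, dst, path + [t]))
    return out


class TestSpecValidation:
    def test_duplicate_manifest_rejected(self):
        with pytest.raises(ConfigError, match="appears in blocks"):
            PathModelSpec(blocks={"A": ["x"], "B": ["x"]}, paths=[("A", "B")])

    def test_cycle_rejected(self):
        with pytest.raises(ConfigError, match="cycle"):
            PathModelSpec(blocks={"A": ["x"], "B": ["y"]}, paths=[("A", "B"), ("B", "A")])

    def test_unknown_lv_rejected(self):
        with pytest.raises(ConfigError, match="not in blocks"):
            PathModelSpec(blocks={"A": ["x"]}, paths=[("A", "Z")])


class TestFit:
    def test_two_lv_path_equals_pearson(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        data = pd.DataFrame({"x1": x, "y1": y})
        spec = PathModelSpec(blocks={"X": ["x1"], "Y": ["y1"]}, paths=[("X", "Y")])
        res = fit_plspm(data, spec)
        assert res.path("X", "Y") == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_single_indicator_gof_identity(self):
        res = fit_plspm(_chain_data(), _chain_spec())
        np.testing.assert_allclose(res.communalities.to_numpy(), 1.0, atol=1e-12)
        assert res.gof == pytest.approx(np.sqrt(np.mean(list(res.r_squared.values()))), abs=1e-12)

    def test_gof_identity_multi_indicator(self):
        data = _multiblock_data()
        res = fit_plspm(data, _multiblock_spec())
        expected = np.sqrt(res.communalities.mean() * np.mean(list(res.r_squared.values())))
        assert res.gof == pytest.approx(expected, abs=1e-12)

    def test_linear_sem_recovery(self):
        a, b, noise = 0.6, -0.4, 0.3
        data = _chain_data(n=500, a=a, b=b, noise=noise, seed=7)
        res = fit_plspm(data, _chain_spec())
        # true standardized coefficients of the generating model
        sd_m = np.sqrt(a**2 + noise**2)
        true_xm = a / sd_m
        sd_y = np.sqrt(b**2 * sd_m**2 + noise**2)
        true_my = b * sd_m / sd_y
        assert res.path("X", "M") == pytest.approx(true_xm, abs=0.1)
        assert res.path("M", "Y") == pytest.approx(true_my, abs=0.1)

    def test_saturated_single_indicator_equals_ols(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        z = rng.normal(size=300)
        y = 0.4 * x - 0.6 * z + rng.normal(size=300)
        data = pd.DataFrame({"x1": x, "z1": z, "y1": y})
        spec = PathModelSpec(
            blocks={"X": ["x1"], "Z": ["z1"], "Y": ["y1"]},
            paths=[("X", "Y"), ("Z", "Y"), ("X", "Z")],
        )
        res = fit_plspm(data, spec)
        xs = (x - x.mean()) / x.std(ddof=1)
        zs = (z - z.mean()) / z.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        beta = np.linalg.lstsq(np.column_stack([xs, zs]), ys, rcond=None)[0]
        assert res.path("X", "Y") == pytest.approx(beta[0], abs=1e-10)
        assert res.path("Z", "Y") == pytest.approx(beta[1], abs=1e-10)

    def test_column_order_invariance_within_block(self):
        data = _multiblock_data()
        spec1 = _multiblock_spec()
        spec2 = PathModelSpec(
            blocks={"A": ["a2", "a1"], "B": ["b1", "b2"]},
            paths=[("A", "B")],
        )
        r1 = fit_plspm(data, spec1)
        r2 = fit_plspm(data, spec2)
        assert r1.path("A", "B") == pytest.approx(r2.path("A", "B"), abs=1e-9)

    def test_scores_unit_variance(self):
        res = fit_plspm(_multiblock_data(), _multiblock_spec())
        np.testing.assert_allclose(res.scores.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_named(self):
        data = _chain_data()
        data["m1"] = 1.0
        with pytest.raises(InvalidInputError, match="m1"):
            fit_plspm(data, _chain_spec())


class TestBootstrap:
    def test_deterministic_p_values(self):
        data = _chain_data(n=120, seed=2)
        a = bootstrap_paths(data, _chain_spec(), n_boot=100, seed=9)
        b = bootstrap_paths(data, _chain_spec(), n_boot=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_strong_path_significant(self):
        data = _chain_data(n=400, a=0.8, seed=4)
        out = bootstrap_paths(data, _chain_spec(), n_boot=200, seed=1)
        row = out[(out.source == "X") & (out.target == "M")].iloc[0]
        assert row["p_value"] < 0.1 and row["significant"]


class TestIndirectEffects:
    def test_chain_product_rule(self):
        res = fit_plspm(_chain_data(seed=1), _chain_spec())
        eff = indirect_effects(res).set_index(["source", "target"])
        xm = res.path("X", "M")
        my = res.path("M", "Y")
        assert eff.loc[("X", "Y"), "indirect"] == pytest.approx(xm * my, abs=1e-12)
        assert eff.loc[("X", "Y"), "direct"] == 0.0
        assert eff.loc[("X", "M"), "indirect"] == 0.0

    def test_diamond_sums_both_routes_against_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        n = 400
        x = rng.normal(size=n)
        m1 = 0.5 * x + rng.normal(size=n)
        m2 = -0.4 * x + rng.normal(size=n)
        y = 0.3 * m1 + 0.6 * m2 + rng.normal(size=n)
        data = pd.DataFrame({"x1": x, "p1": m1, "q1": m2, "y1": y})
        spec = PathModelSpec(
            blocks={"X": ["x1"], "P": ["p1"], "Q": ["q1"], "Y": ["y1"]},
            paths=[("X", "P"), ("X", "Q"), ("P", "Y"), ("Q", "Y")],
        )
        res = fit_plspm(data, spec)
        eff = indirect_effects(res).set_index(["source", "target"])
        coefs = {
            (r["source"], r["target"]): r["coefficient"]
            for _, r in res.path_coefficients.iterrows()
        }
        expected = sum(
            np.prod([coefs[(a, b)] for a, b in zip(p[:-1], p[1:])])
            for p in enumerate_paths(list(coefs), "X", "Y")
            if len(p) >= 3
        )
        assert eff.loc[("X", "Y"), "indirect"] == pytest.approx(expected, abs=1e-12)

    def test_default_template_is_valid(self):
        spec = default_block_spec()
        assert "stability" in spec.blocks
        assert ("richness", "stability") in spec.paths


def _chain_spec():
    return PathModelSpec(
        blocks={"X": ["x1"], "M": ["m1"], "Y": ["y1"]},
        paths=[("X", "M"), ("M", "Y")],
    )


def _multiblock_data(n=300, seed=8):
    rng = np.random.default_rng(seed)
    lv_a = rng.normal(size=n)
    lv_b = 0.7 * lv_a + 0.5 * rng.normal(size=n)
    return pd.DataFrame(
        {
            "a1": lv_a + 0.4 * rng.normal(size=n),
            "a2": lv_a + 0.4 * rng.normal(size=n),
            "b1": lv_b + 0.4 * rng.normal(size=n),
            "b2": lv_b + 0.4 * rng.normal(size=n),
        }
    )


def _multiblock_spec():
    return PathModelSpec(blocks={"A": ["a1", "a2"], "B": ["b1", "b2"]}, paths=[("A", "B")])
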