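import numpy as np
import pandas as pd
import pytest

from translatome import polysome


def make_table(signals_by_pool, condition="control"):
    return pd.DataFrame(
        [
            {"gene_id": "g1", "condition": condition, "replicate": 1, "pool": p, "signal": s}
            for p, s in signals_by_pool.items()
        ]
    )


class TestCorrectSampling:
    @pytest.mark.parametrize(
        "pool,fraction,expected",
        [
            ("F", 0.142, 704.23),  # 14.2% of the free pool used for cDNA synthesis
            ("H", 0.004, 25000.0),  # 0.4% of the heavy polysome pool
            ("L", 1.0, 100.0),  # full pool used: identity
        ],
    )
    def test_division_by_fraction(self, pool, fraction, expected):
        table = make_table({pool: 100.0})
        fractions = pd.DataFrame([{"pool": pool, "condition": "control", "fraction": fraction}])
        out = polysome.correct_sampling(table, fractions)
        assert out["signal"].iloc[0] == pytest.approx(expected, rel=1e-4)

    def test_missing_fraction_raises(self):
        table = make_table({"F": 1.0, "H": 2.0})
        fractions = pd.DataFrame([{"pool": "F", "condition": "control", "fraction": 0.1}])
        with pytest.raises(ValueError, match="missing sampling fraction"):
            polysome.correct_sampling(table, fractions)

    def test_nonpositive_fraction_raises(self):
        table = make_table({"F": 1.0})
        fractions = pd.DataFrame([{"pool": "F", "condition": "control", "fraction": 0.0}])
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            polysome.correct_sampling(table, fractions)

    def test_invertibility(self, rng):
        """Correcting then re-multiplying by the fractions recovers the input."""
        pools = list("FSLH")
        table = pd.DataFrame(
            {
                "gene_id": ["g"] * 4,
                "condition": "control",
                "replicate": 1,
                "pool": pools,
                "signal": rng.uniform(1, 100, 4),
            }
        )
        fr = pd.DataFrame({"pool": pools, "condition": "control", "fraction": rng.uniform(0.01, 1, 4)})
        out = polysome.correct_sampling(table, fr)
        back = out["signal"].to_numpy() * fr["fraction"].to_numpy()
        np.testing.assert_allclose(back, table["signal"].to_numpy(), rtol=1e-12)


class TestPoolDistribution:
    @pytest.mark.parametrize(
        "signals,expected",
        [
            ((10, 10, 40, 40), (0.1, 0.1, 0.4, 0.4)),
            ((0, 0, 0, 1), (0.0, 0.0, 0.0, 1.0)),
        ],
    )
    def test_normalization(self, signals, expected):
        table = make_table(dict(zip("FSLH", signals)))
        out = polysome.pool_distribution(table)
        assert tuple(out[list(polysome.PROP_COLS)].iloc[0]) == pytest.approx(expected)
        assert out["valid"].iloc[0]

    def test_all_zero_flagged_undefined(self):
        out = polysome.pool_distribution(make_table(dict(zip("FSLH", (0, 0, 0, 0)))))
        assert not out["valid"].iloc[0]
        assert out[list(polysome.PROP_COLS)].isna().all().all()

    def test_missing_pool_raises_with_gene(self):
        table = make_table({"F": 1.0, "S": 1.0, "L": 1.0})
        with pytest.raises(ValueError, match="g1"):
            polysome.pool_distribution(table)

    def test_scale_invariance(self, rng):
        sig = rng.uniform(1, 50, 4)
        a = polysome.pool_distribution(make_table(dict(zip("FSLH", sig))))
        b = polysome.pool_distribution(make_table(dict(zip("FSLH", sig * 7.3))))
        np.testing.assert_allclose(
            a[list(polysome.PROP_COLS)].to_numpy(), b[list(polysome.PROP_COLS)].to_numpy(), rtol=1e-12
        )

    def test_proportions_sum_to_one(self, small_polysome, unit_fractions):
        signals, fractions, _ = small_polysome
        dists = polysome.pool_distribution(polysome.correct_sampling(signals, fractions))
        sums = dists[list(polysome.PROP_COLS)].sum(axis=1)
        np.testing.assert_allclose(sums[dists["valid"]], 1.0, atol=1e-9)


class TestRibosomeLoad:
    def make_dist(self, pF, pS, pL, pH):
        return pd.DataFrame(
            [{"gene_id": "g1", "condition": "control", "replicate": 1,
              "pF": pF, "pS": pS, "pL": pL, "pH": pH, "valid": True}]
        )

    @pytest.mark.parametrize(
        "pL,pH,hl",
        [
            (0.4, 0.4, 1.0),
            (0.25, 0.69, 2.76),    # control pool medians
            (0.21, 0.73, 3.47619),  # stimulated pool medians
        ],
    )
    def test_ratio(self, pL, pH, hl):
        out = polysome.ribosome_load(self.make_dist(0.0, 0.0, pL, pH))
        assert out["hl"].iloc[0] == pytest.approx(hl, rel=1e-5)
        assert out["log2_hl"].iloc[0] == pytest.approx(np.log2(hl), rel=1e-5)

    def test_zero_light_pool_flagged_not_raised(self):
        out = polysome.ribosome_load(self.make_dist(0.5, 0.5, 0.0, 0.0))
        assert not out["valid"].iloc[0]
        assert not np.isfinite(out["hl"].iloc[0])

    def test_hl_invariant_to_uniform_scaling_of_fractions(self, rng):
        """H/L does not change when all pools share one sampling fraction."""
        sig = dict(zip("FSLH", rng.uniform(1, 100, 4)))
        base = polysome.ribosome_load(polysome.pool_distribution(make_table(sig)))
        fr = pd.DataFrame({"pool": list("FSLH"), "condition": "control", "fraction": 0.37})
        corrected = polysome.correct_sampling(make_table(sig), fr)
        scaled = polysome.ribosome_load(polysome.pool_distribution(corrected))
        assert scaled["hl"].iloc[0] == pytest.approx(base["hl"].iloc[0], rel=1e-12)


class TestMedianPoolProportions:
    def test_single_gene_is_its_own_median(self):
        dists = polysome.pool_distribution(make_table(dict(zip("FSLH", (10, 10, 40, 40)))))
        med = polysome.median_pool_proportions(dists, "control")
        assert tuple(med) == pytest.approx((0.1, 0.1, 0.4, 0.4))

    def test_median_between_two_genes(self):
        rows = []
        for gid, pH in (("a", 0.6), ("b", 0.8)):
            rows.append({"gene_id": gid, "condition": "control", "replicate": 1,
                         "pF": 0.0, "pS": 0.0, "pL": 1 - pH, "pH": pH, "valid": True})
        med = polysome.median_pool_proportions(pd.DataFrame(rows), "control")
        assert med["pH"] == pytest.approx(0.7)

    def test_empty_condition_raises(self):
        dists = polysome.pool_distribution(make_table(dict(zip("FSLH", (1, 1, 1, 1)))))
        with pytest.raises(ValueError, match="no valid distributions"):
            polysome.median_pool_proportions(dists, "stimulated")

    def test_matches_generator_baseline(self, small_polysome):
        """Control medians recover the configured latent baseline within MC error."""
        signals, fractions, _ = small_polysome
        dists = polysome.pool_distribution(polysome.correct_sampling(signals, fractions))
        med = polysome.median_pool_proportions(dists, "control")
        assert med["pH"] == pytest.approx(0.69, abs=0.03)
        assert med["pL"] == pytest.approx(0.25, abs=0.03)


class TestPercentPolysomal:
    def test_rectangular_trace(self):
        # flat zero baseline; monosome rectangle height 1 width 1, polysome height 1 width 3
        pos = np.array([0.0, 1.0, 1.0001, 2.0, 2.0001, 5.0, 5.0001, 6.0])
        ab = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        pct = polysome.percent_polysomal(pos, ab, 1.0, 2.0, 5.0, baseline="none")
        assert pct == pytest.approx(75.0, abs=0.1)

    def test_zero_polysome_area(self):
        pos = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        ab = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        pct = polysome.percent_polysomal(pos, ab, 0.0, 2.0, 4.0, baseline="none")
        assert pct == pytest.approx(0.0)

    def test_non_monotone_positions_raise(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            polysome.percent_polysomal(np.array([0.0, 2.0, 1.0]), np.zeros(3), 0, 1, 2)

    def test_against_fine_grid_oracle(self, rng):
        """Random piecewise-linear trace vs dense numerical integration."""
        pos = np.sort(rng.uniform(0, 10, 40))
        pos[0], pos[-1] = 0.0, 10.0
        ab = rng.uniform(0.5, 2.0, 40)
        ab[0] = ab[-1] = 0.2  # low endpoints so the baseline stays below the peaks
        b0, b1, b2 = 2.0, 4.5, 9.0
        got = polysome.percent_polysomal(pos, ab, b0, b1, b2)
        grid = np.linspace(0, 10, 200001)
        base = np.interp(grid, [0, 10], [ab[0], ab[-1]])
        vals = np.interp(grid, pos, ab) - base
        a80 = np.trapezoid(vals[(grid >= b0) & (grid <= b1)], grid[(grid >= b0) & (grid <= b1)])
        apoly = np.trapezoid(vals[(grid >= b1) & (grid <= b2)], grid[(grid >= b1) & (grid <= b2)])
        expected = 100 * apoly / (a80 + apoly)
        assert got == pytest.approx(expected, rel=1e-3)
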