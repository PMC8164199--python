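"""Grey relational coefficients and degrees: worked example, the two
extreme conventions, algebraic invariants, and oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

import reference_values as ref
from gra_oracle import gra_oracle
from greytox.errors import ConfigError, DegeneratePanelError
from greytox.gra import (
    GraConfig,
    GreyRelationalTransform,
    abs_difference,
    grey_coefficient,
    grey_degree,
    run_gra,
)
from greytox.panel import Receptor, ToxicityPanel


class TestConfig:
    @pytest.mark.parametrize("bad", [
        dict(rho=0.0), dict(rho=1.0), dict(reference_value=0.0),
        dict(normalization="rowwise"), dict(weights=(0.5, 0.6)),
        dict(weights=(-0.5, 1.5)),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            GraConfig(**bad)

    def test_weight_length_mismatch(self, panel):
        cfg = GraConfig(weights=(0.5, 0.5))
        diffs = abs_difference(panel)
        coeffs = grey_coefficient(diffs)
        with pytest.raises(ConfigError):
            grey_degree(coeffs, cfg)


class TestWorkedExample:
    """The published 14-phthalate panel, cell for cell."""

    def test_differences_match_printed_table(self, panel):
        diffs = abs_difference(panel)
        for compound, row in ref.EXPECTED_DIFFERENCES.items():
            for receptor, expected in row.items():
                assert diffs.values.loc[compound, receptor] == pytest.approx(
                    expected, abs=6e-7
                ), (compound, receptor)

    def test_column_extremes(self, panel):
        diffs = abs_difference(panel)
        for receptor in ref.RECEPTORS:
            assert diffs.column_min[receptor] == pytest.approx(
                ref.EXPECTED_COLUMN_MIN[receptor], abs=6e-7)
            assert diffs.column_max[receptor] == pytest.approx(
                ref.EXPECTED_COLUMN_MAX[receptor], abs=6e-7)
        assert diffs.global_min == pytest.approx(0.398, abs=1e-9)
        assert diffs.global_max == pytest.approx(1 - 0.00000143, abs=1e-9)

    def test_coefficients_match_printed_table(self, panel):
        coeffs = run_gra(panel).coefficients.values
        for compound, row in ref.EXPECTED_COEFFICIENTS.items():
            for receptor, expected in row.items():
                assert coeffs.loc[compound, receptor] == pytest.approx(
                    expected, abs=1e-3
                ), (compound, receptor)

    def test_degrees_match_printed_table(self, panel):
        degrees = run_gra(panel).degrees.values
        for compound, expected in ref.EXPECTED_DEGREES.items():
            assert degrees[compound] == pytest.approx(expected, abs=1e-3), compound

    def test_normalization_modes_diverge_at_dehp_fish(self, panel):
        compound, receptor = ref.DIVERGENCE_CELL
        per_seq = run_gra(panel, GraConfig()).coefficients.values
        glob = run_gra(panel, GraConfig(normalization="global")).coefficients.values
        assert per_seq.loc[compound, receptor] == pytest.approx(
            ref.DIVERGENCE_PER_SEQUENCE, abs=1e-3)
        assert glob.loc[compound, receptor] == pytest.approx(
            ref.DIVERGENCE_GLOBAL, abs=1e-3)

    def test_degenerate_weighting_recovers_single_column(self, panel):
        cfg = GraConfig(weights=(0.0, 0.0, 0.0, 1.0))  # fish only
        degrees = run_gra(panel, cfg).degrees.values
        assert degrees["DEHP"] == pytest.approx(0.7268, abs=1e-3)


class TestEdgeCases:
    def test_single_compound_panel_all_coefficients_one(self):
        panel = ToxicityPanel([[0.2, 0.5, 0.01]], compounds=["only"],
                              receptors=[Receptor(c) for c in "abc"])
        coeffs = run_gra(panel).coefficients.values
        assert np.allclose(coeffs.to_numpy(), 1.0)

    def test_all_values_at_reference_is_degenerate(self):
        panel = ToxicityPanel([[1.0, 1.0], [1.0, 1.0]],
                              compounds=["c1", "c2"],
                              receptors=[Receptor("a"), Receptor("b")])
        for mode in ("per_sequence", "global"):
            with pytest.raises(DegeneratePanelError):
                run_gra(panel, GraConfig(normalization=mode))

    def test_value_equal_to_reference_gives_zero_difference(self):
        panel = ToxicityPanel([[1.0], [0.5]], compounds=["c1", "c2"],
                              receptors=[Receptor("a")])
        diffs = abs_difference(panel)
        assert diffs.values.loc["c1", "a"] == 0.0
        coeffs = grey_coefficient(diffs)
        assert coeffs.values.loc["c1", "a"] == 1.0


def _random_panel(rng, n=5, m=3):
    values = 10.0 ** rng.uniform(-5, -0.05, size=(n, m))
    return ToxicityPanel(values, compounds=[f"c{i}" for i in range(n)],
                         receptors=[Receptor(f"r{j}") for j in range(m)])


class TestInvariants:
    def test_coefficient_bounds(self, panel):
        for mode in ("per_sequence", "global"):
            result = run_gra(panel, GraConfig(normalization=mode))
            c = result.coefficients.values.to_numpy()
            assert (c > 0).all() and (c <= 1 + 1e-12).all()
            d = result.degrees.values.to_numpy()
            assert (d > 0).all() and (d <= 1 + 1e-12).all()

    def test_coefficient_is_one_iff_delta_is_column_min(self, panel):
        diffs = abs_difference(panel)
        coeffs = grey_coefficient(diffs).values
        for receptor in ref.RECEPTORS:
            at_min = np.isclose(diffs.values[receptor],
                                diffs.column_min[receptor])
            is_one = np.isclose(coeffs[receptor], 1.0)
            assert (at_min == is_one).all()

    def test_scale_invariance_of_difference_matrix(self, panel):
        """Multiplying every difference (hence the extremes) by c > 0
        cancels out of the coefficient under both conventions."""
        from greytox.gra import DifferenceMatrix

        base = abs_difference(panel)
        for c in (0.25, 7.0):
            scaled = DifferenceMatrix(
                values=base.values * c,
                column_min=base.column_min * c,
                column_max=base.column_max * c,
                global_min=base.global_min * c,
                global_max=base.global_max * c,
            )
            for mode in ("per_sequence", "global"):
                cfg = GraConfig(normalization=mode)
                a = grey_coefficient(base, cfg).values.to_numpy()
                b = grey_coefficient(scaled, cfg).values.to_numpy()
                assert np.allclose(a, b, rtol=1e-12)

    def test_compound_permutation_equivariance(self, panel):
        rng = np.random.default_rng(7)
        perm = rng.permutation(panel.shape[0])
        shuffled = ToxicityPanel(panel.values.iloc[perm],
                                 receptors=list(panel.receptors))
        base = run_gra(panel).degrees.values
        moved = run_gra(shuffled).degrees.values
        assert np.allclose(base.iloc[perm].to_numpy(), moved.to_numpy())

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("mode", ["per_sequence", "global"])
    def test_oracle_equivalence_random_panels(self, seed, mode):
        """Vectorized pipeline agrees with a literal loop recomputation."""
        rng = np.random.default_rng(seed)
        panel = _random_panel(rng)
        result = run_gra(panel, GraConfig(normalization=mode))
        diffs, coeffs, degrees = gra_oracle(
            panel.values.to_numpy().tolist(), mode=mode)
        assert np.allclose(result.differences.values.to_numpy(),
                           np.array(diffs), atol=1e-12)
        assert np.allclose(result.coefficients.values.to_numpy(),
                           np.array(coeffs), atol=1e-12)
        assert np.allclose(result.degrees.values.to_numpy(),
                           np.array(degrees), atol=1e-12)

    def test_monotone_remission(self):
        """With all values below the reference, moving one compound's
        profile uniformly toward the boundary (without touching the
        extremes) never lowers its degree."""
        rng = np.random.default_rng(3)
        values = 10.0 ** rng.uniform(-4, -0.5, size=(6, 4))
        receptors = [Receptor(f"r{j}") for j in range(4)]
        compounds = [f"c{i}" for i in range(6)]
        base = ToxicityPanel(values, compounds=compounds, receptors=receptors)
        fitted = GreyRelationalTransform().fit(base)
        d0 = fitted.degrees(base)["c2"]
        for factor in (1.5, 2.0, 3.0):
            shifted = values.copy()
            shifted[2] = np.minimum(shifted[2] * factor, 0.999)
            moved = ToxicityPanel(shifted, compounds=compounds,
                                  receptors=receptors)
            d1 = fitted.degrees(moved)["c2"]
            assert d1 >= d0 - 1e-12
            d0 = d1


class TestTransformerContract:
    def test_get_set_params_roundtrip(self):
        t = GreyRelationalTransform(rho=0.3, normalization="global")
        params = t.get_params()
        assert params["rho"] == 0.3
        clone = GreyRelationalTransform().set_params(**params)
        assert clone.get_params() == params

    def test_transform_before_fit_raises(self, panel):
        with pytest.raises(ConfigError):
            GreyRelationalTransform().transform(panel)

    def test_fit_attributes(self, panel):
        t = GreyRelationalTransform().fit(panel)
        assert t.n_features_in_ == 4
        assert list(t.feature_names_in_) == ref.RECEPTORS
        assert t.column_min_["daphnid"] == pytest.approx(0.398)

    def test_held_out_compound_scored_against_training_extremes(self, panel):
        t = GreyRelationalTransform().fit(panel)
        new = pd.DataFrame([[0.149, 0.602, 0.095, 0.417]],
                           index=["BCHP-copy"], columns=ref.RECEPTORS)
        coeffs = t.transform(new)
        assert np.allclose(coeffs.to_numpy(), 1.0, atol=1e-12)

    def test_sklearn_pipeline_compatibility(self, panel):
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("gra", GreyRelationalTransform())])
        out = pipe.fit_transform(panel.values)
        assert out.shape == panel.shape

    def test_invalid_receptor_count_rejected(self, panel):
        t = GreyRelationalTransform().fit(panel)
        with pytest.raises(ConfigError):
            t.transform(panel.values.iloc[:, :2])
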