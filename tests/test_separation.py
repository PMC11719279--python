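"""Critical threshold, separation formulas and the two-cluster report."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mipca import (
    CRITICAL_THRESHOLD_CLOSED_FORM,
    EmbeddingCoordinates,
    SimulationSpec,
    compare_separations,
    critical_threshold,
    decompose,
    exact_normalized_difference,
    filter_loci,
    gate_test,
    impute_missing,
    linear_separation,
    linearized_difference,
    make_embedding,
    mi_separation_sq,
    signed_rescale,
    simulate_balding_nichols,
    standardize,
)

pos_rhos = st.floats(min_value=0.01, max_value=0.98)


class TestFormulas:
    def test_mi_separation_reference_values(self):
        assert mi_separation_sq(0.5, 0.7) == pytest.approx(0.0371839, abs=1e-6)
        assert mi_separation_sq(0.2, 0.9) == pytest.approx(0.6560265, abs=1e-6)

    @given(r1=pos_rhos, r2=pos_rhos)
    def test_identity_with_rescaled_difference(self, r1, r2):
        # 1/4 (ln((1-r2^2)/(1-r1^2)))^2 == (r(r2) - r(r1))^2 exactly
        lhs = mi_separation_sq(r1, r2)
        rhs = (signed_rescale(r2).value - signed_rescale(r1).value) ** 2
        assert lhs == pytest.approx(rhs, abs=1e-12, rel=1e-9)

    @given(r1=pos_rhos, r2=pos_rhos)
    def test_symmetry_under_swap(self, r1, r2):
        assert mi_separation_sq(r1, r2) == pytest.approx(mi_separation_sq(r2, r1), rel=1e-12)

    def test_linearized_reference_values(self):
        assert linearized_difference(0.7, 0.8) == pytest.approx(0.0088389, abs=1e-6)
        assert linearized_difference(0.5, 0.55) == pytest.approx(-0.0013889, abs=1e-6)

    def test_linearization_approximates_exact_difference(self):
        # for small gaps the linearized and exact differences agree to
        # second order; halving the gap should shrink the error ~8x
        for r1 in (0.4, 0.7):
            errs = []
            for eps in (0.02, 0.01):
                exact = exact_normalized_difference(r1, r1 + eps)
                lin = linearized_difference(r1, r1 + eps)
                errs.append(abs(exact - lin))
            assert errs[0] / errs[1] > 4.0  # cubic error: exactly 8 in the limit

    def test_linear_separation_basic(self):
        assert linear_separation(0.0, 3.0, 1.5) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            linear_separation(0.0, 1.0, 0.0)

    def test_negative_or_out_of_range_rho_rejected(self):
        for bad in ((-0.2, 0.5), (0.5, -0.2), (0.0, 0.5), (0.5, 1.0)):
            with pytest.raises(ValueError):
                mi_separation_sq(*bad)
            with pytest.raises(ValueError):
                linearized_difference(*bad)


class TestCriticalThreshold:
    def test_bisection_matches_closed_form(self):
        assert critical_threshold() == pytest.approx(
            CRITICAL_THRESHOLD_CLOSED_FORM, abs=1e-10
        )

    def test_closed_form_is_inverse_golden_ratio(self):
        phi = (1 + np.sqrt(5)) / 2
        assert CRITICAL_THRESHOLD_CLOSED_FORM == pytest.approx(1 / phi, abs=1e-15)

    def test_defining_equation(self):
        r = critical_threshold()
        assert r * r == pytest.approx((1 - r * r) ** 2, abs=1e-10)

    def test_sign_change_of_linearized_coefficient(self):
        # scan rho1 on a fine grid: the linearized difference at fixed small
        # gap flips from negative to positive exactly once, at rho*
        grid = np.arange(0.05, 0.95, 1e-3)
        signs = np.sign([linearized_difference(r, r + 1e-4) for r in grid])
        flips = np.flatnonzero(np.diff(signs) != 0)
        assert flips.size == 1
        crossing = grid[flips[0]]
        assert abs(crossing - CRITICAL_THRESHOLD_CLOSED_FORM) < 2e-3


class TestGateTest:
    def test_null_rho_gives_half(self):
        r0 = critical_threshold()
        assert gate_test(r0, 103) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_r_and_n(self):
        assert gate_test(0.8, 100) < gate_test(0.7, 100) < gate_test(0.62, 100)
        assert gate_test(0.7, 400) < gate_test(0.7, 50)

    def test_matches_direct_normal_formula(self):
        from scipy.stats import norm

        r, n, r0 = 0.75, 200, 0.618
        z = (np.arctanh(r) - np.arctanh(r0)) * np.sqrt(n - 3)
        assert gate_test(r, n, r0) == pytest.approx(float(norm.sf(z)), rel=1e-12)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            gate_test(0.5, 3)
        with pytest.raises(ValueError):
            gate_test(1.5, 100)
        with pytest.warns(UserWarning):
            assert gate_test(1.0, 100) == 0.0


def _toy_embedding(loadings_a, loadings_b, lam=5.0):
    """Two-cluster embedding built directly from member loadings."""
    load = np.array(loadings_a + loadings_b, dtype=float)[:, None]
    conv = load * np.sqrt(lam)
    resc = np.array([signed_rescale(v).value for v in load[:, 0]])[:, None] * np.sqrt(lam)
    n = load.shape[0]
    return EmbeddingCoordinates(
        sample_ids=[f"s{i}" for i in range(n)],
        axes=[1],
        conventional=conv,
        rescaled=resc,
        loadings=load,
        eigenvalues=np.array([lam]),
        population_labels=["A"] * len(loadings_a) + ["B"] * len(loadings_b),
    )


class TestCompareSeparationsFallback:
    def test_above_threshold_pair(self):
        emb = _toy_embedding([0.68, 0.72], [0.78, 0.82])
        rep = compare_separations(["A", "A", "B", "B"], emb, 1)
        assert rep.rho1 == pytest.approx(0.70) and rep.rho2 == pytest.approx(0.80)
        assert rep.label1 == "A" and rep.label2 == "B"
        assert rep.above_threshold and rep.linearized_diff > 0
        assert rep.delta_mu_tilde_sq_scaled == pytest.approx(
            mi_separation_sq(0.7, 0.8), rel=1e-12
        )
        assert rep.gate_n == 2  # fallback: min cluster size

    def test_below_threshold_pair(self):
        emb = _toy_embedding([0.28, 0.32], [0.38, 0.42])
        rep = compare_separations(["A", "A", "B", "B"], emb, 1)
        assert not rep.above_threshold and rep.linearized_diff < 0

    def test_labels_as_dict_and_ordering_invariance(self):
        emb = _toy_embedding([0.78, 0.82], [0.68, 0.72])  # B has the smaller rho
        lab = {f"s{i}": ("X" if i < 2 else "Y") for i in range(4)}
        rep = compare_separations(lab, emb, 1)
        assert rep.label1 == "Y" and rep.rho1 == pytest.approx(0.70)

    def test_both_negative_reflects_axis(self):
        emb = _toy_embedding([-0.68, -0.72], [-0.78, -0.82])
        rep = compare_separations(["A", "A", "B", "B"], emb, 1)
        assert rep.axis_reflected and rep.rho1 == pytest.approx(0.70)

    def test_mixed_signs_rejected(self):
        emb = _toy_embedding([0.68, 0.72], [-0.78, -0.82])
        with pytest.raises(ValueError, match="outside"):
            compare_separations(["A", "A", "B", "B"], emb, 1)

    def test_delta_mu_matches_hand_computation(self):
        emb = _toy_embedding([0.28, 0.32], [0.40, 0.44])
        rep = compare_separations(["A", "A", "B", "B"], emb, 1)
        lam = 5.0
        mu1, mu2 = 0.30 * np.sqrt(lam), 0.42 * np.sqrt(lam)
        sd = np.sqrt(lam) * 0.02 * np.sqrt(2)  # both clusters: sd of {x-.02, x+.02}
        assert rep.delta_mu == pytest.approx(abs(mu2 - mu1) / sd, rel=1e-10)

    def test_validation_errors(self):
        emb = _toy_embedding([0.3, 0.4], [0.5, 0.6])
        with pytest.raises(ValueError, match="axis"):
            compare_separations(["A", "A", "B", "B"], emb, 2)
        with pytest.raises(ValueError, match="two cluster labels"):
            compare_separations(["A", "B", "C", "A"], emb, 1)
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_separations(["A", "B", "B", "B"], emb, 1)
        with pytest.raises(ValueError, match="without a cluster label"):
            compare_separations({"s0": "A"}, emb, 1)

    def test_report_serializes_to_json(self):
        import json

        emb = _toy_embedding([0.68, 0.72], [0.78, 0.82])
        rep = compare_separations(["A", "A", "B", "B"], emb, 1)
        payload = json.loads(rep.to_json())
        assert payload["above_threshold"] is True
        assert set(payload) == set(rep.__dataclass_fields__)


@pytest.fixture(scope="module")
def hierarchical():
    # two close populations plus one outgroup: the leading axis carries
    # the outgroup split, giving center correlations above rho* for the
    # two focal populations
    spec = SimulationSpec(
        n_pops=3, n_per_pop=100, n_loci=4000, fst=[0.01, 0.01, 0.4], seed=7
    )
    gm = simulate_balding_nichols(spec)
    gm, _ = filter_loci(gm)
    gm = impute_missing(gm)
    sm = standardize(gm)
    decomp = decompose(sm, 5)
    emb = make_embedding(decomp, [1, 2], population_labels=gm.population_labels)
    # the separation comparison is pairwise, so restrict the embedding
    # to the two focal populations; sm and decomp stay cohort-wide
    keep = [i for i, p in enumerate(gm.population_labels) if p != "pop2"]
    sub_emb = EmbeddingCoordinates(
        sample_ids=[emb.sample_ids[i] for i in keep],
        axes=emb.axes,
        conventional=emb.conventional[keep],
        rescaled=emb.rescaled[keep],
        loadings=emb.loadings[keep],
        eigenvalues=emb.eigenvalues,
        population_labels=[gm.population_labels[i] for i in keep],
    )
    labels = [gm.population_labels[i] for i in keep]
    return labels, sub_emb, sm, decomp


class TestCenterOfMassRoute:
    def test_center_correlations_in_high_regime(self, hierarchical):
        labels, sub_emb, sm, decomp = hierarchical
        rep = compare_separations(
            labels, sub_emb, 1, standardized=sm, decomposition=decomp
        )
        assert rep.gate_n == sm.Z.shape[1]
        assert 0.55 < rep.rho1 < rep.rho2 < 1.0
        assert rep.above_threshold
        assert rep.gate_p_value < 0.05
        assert rep.delta_mu_tilde_sq_scaled > (rep.rho2 - rep.rho1) ** 2

    def test_missing_sample_in_standardized_raises(self, hierarchical):
        labels, sub_emb, sm, decomp = hierarchical
        renamed = EmbeddingCoordinates(
            sample_ids=["ghost_" + s for s in sub_emb.sample_ids],
            axes=sub_emb.axes,
            conventional=sub_emb.conventional,
            rescaled=sub_emb.rescaled,
            loadings=sub_emb.loadings,
            eigenvalues=sub_emb.eigenvalues,
        )
        with pytest.raises(ValueError, match="not present"):
            compare_separations(labels, renamed, 1, standardized=sm, decomposition=decomp)
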