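"""Attractor criteria and eigenvalue oracles for the controlled systems."""

import numpy as np
import pytest

from immunodyn import (ControlParams, ModelParams, NO_CONTROL,
                       analytic_verdicts, classify_at,
                       controlled_boundary_eigenvalues,
                       e212_closed_form_pairwise, jacobian,
                       pairwise_e1_attractor, pairwise_e212_attractor,
                       pairwise_e212_charpoly_factors, product_e2_attractor,
                       sample_controls, sample_params)


def numeric_attractor(params, control, coords):
    lam = np.linalg.eigvals(jacobian(params, control, coords))
    return bool(np.all(lam.real < 0)), float(np.min(np.abs(lam.real)))


class TestProductPairCriterion:
    @pytest.mark.parametrize("p4,gamma,expected", [
        (0.5, -2.0, True),    # 0.5 < 2 and 1 - 2 < 0
        (0.5, 0.0, False),    # transverse eigenvalue a3 = 1 > 0
        (3.0, -2.0, False),   # viral eigenvalue 3 - 2 > 0
    ])
    def test_hand_cases(self, p4, gamma, expected):
        params = ModelParams.unit(p4=p4)
        ctrl = ControlParams("product", 0.1, 0.1, gamma)
        got = product_e2_attractor(params, ctrl)
        assert got is expected

    def test_agrees_with_numeric_classifier(self, unit_params):
        """Predicate vs eigenvalues at E212 = (a1/b1, a2/b2, 0, 0), away
        from the equality boundaries."""
        coords = np.array([1.0, 1.0, 0.0, 0.0])
        draws = sample_params(60, seed=41)
        ctrls = sample_controls(60, seed=42, kind="product")
        for params, ctrl in zip(draws, ctrls):
            cap = params.carrying_capacity
            xy = np.array([cap[0], cap[1], 0.0, 0.0])
            attract, margin = numeric_attractor(params, ctrl, xy)
            if margin < 1e-6:
                continue
            assert product_e2_attractor(params, ctrl) is attract

    def test_wrong_kind_rejected(self, unit_params):
        with pytest.raises(ValueError, match="product"):
            product_e2_attractor(unit_params, ControlParams("pairwise_sum"))


class TestPairwiseSingleCriterion:
    @pytest.mark.parametrize("p4,beta,gamma,expected", [
        (0.5, -2.0, -2.0, True),
        (0.5, -2.0, 0.0, False),   # third inequality fails
        (2.0, -2.0, -2.0, False),  # 2 > p1 a1 / b1 = 1
    ])
    def test_hand_cases(self, p4, beta, gamma, expected):
        params = ModelParams.unit(p4=p4)
        ctrl = ControlParams("pairwise_sum", 0.0, beta, gamma)
        assert pairwise_e1_attractor(params, ctrl) is expected

    def test_agrees_with_numeric_classifier(self):
        draws = sample_params(60, seed=43)
        ctrls = sample_controls(60, seed=44, kind="pairwise_sum")
        for params, ctrl in zip(draws, ctrls):
            coords = np.array([params.carrying_capacity[0], 0.0, 0.0, 0.0])
            attract, margin = numeric_attractor(params, ctrl, coords)
            if margin < 1e-6:
                continue
            assert pairwise_e1_attractor(params, ctrl) is attract


class TestPairwisePairCriterion:
    def test_zero_cross_controls_reduce_to_capacity_form(self, unit_params):
        """With alpha = beta = 0 the E212 coordinates fall back to the
        capacities, the viral condition collapses to the uncontrolled sum
        condition p4 < p1 a1/b1 + p2 a2/b2, and the gamma bound becomes
        gamma < -a3 / (a1/b1 + a2/b2)."""
        for gamma, expected in [(-2.0, True), (-0.4, False), (0.3, False)]:
            pw = ControlParams("pairwise_sum", 0.0, 0.0, gamma)
            exists, verdict = pairwise_e212_attractor(unit_params, pw)
            assert exists
            # sum condition holds (0.5 < 2); bound is gamma < -1/2
            assert verdict is expected
        # exactly on the gamma bound the criterion is indeterminate
        pw = ControlParams("pairwise_sum", 0.0, 0.0, -0.5)
        assert pairwise_e212_attractor(unit_params, pw) == (True, None)

    def test_agrees_with_numeric_classifier(self, unit_params):
        ctrl = ControlParams("pairwise_sum", 0.1, 0.1, -2.0)
        exists, verdict = pairwise_e212_attractor(unit_params, ctrl)
        coords = e212_closed_form_pairwise(unit_params, ctrl)
        attract, _ = numeric_attractor(unit_params, ctrl, coords)
        assert exists and verdict is attract

    def test_random_draw_agreement(self):
        draws = sample_params(80, seed=45)
        ctrls = sample_controls(80, seed=46, kind="pairwise_sum")
        checked = 0
        for params, ctrl in zip(draws, ctrls):
            den = params.b[0] * params.b[1] - ctrl.alpha * ctrl.beta
            if abs(den) < 1e-6:
                continue
            coords = e212_closed_form_pairwise(params, ctrl)
            attract, margin = numeric_attractor(params, ctrl, coords)
            if margin < 1e-6:
                continue
            exists, verdict = pairwise_e212_attractor(params, ctrl)
            assert exists and verdict is attract
            checked += 1
        assert checked > 50

    def test_negative_denominator_saddle(self, unit_params):
        """With b1 b2 - alpha beta < 0 and both numerators negative, the
        point sits below the capacities but is a saddle."""
        ctrl = ControlParams("pairwise_sum", -2.0, -2.0, 0.0)
        coords = e212_closed_form_pairwise(unit_params, ctrl)
        assert 0 < coords[0] < 1 and 0 < coords[1] < 1
        exists, verdict = pairwise_e212_attractor(unit_params, ctrl)
        assert exists and verdict is False
        rep = classify_at(unit_params, ctrl, coords)
        assert rep.classification == "saddle"

    def test_charpoly_factorization_matches_numeric(self):
        """Expanding (X - lam3)(X - lam4)(X^2 + q1 X + q0) reproduces the
        numeric characteristic polynomial at E212."""
        draws = sample_params(30, seed=47)
        ctrls = sample_controls(30, seed=48, kind="pairwise_sum")
        for params, ctrl in zip(draws, ctrls):
            if abs(params.b[0] * params.b[1] - ctrl.alpha * ctrl.beta) < 1e-6:
                continue
            coords = e212_closed_form_pairwise(params, ctrl)
            l3, l4, (q1, q0) = pairwise_e212_charpoly_factors(params, ctrl)
            expanded = np.polymul(np.polymul([1, -l3], [1, -l4]),
                                  [1, q1, q0])
            numeric = np.real(np.poly(np.linalg.eigvals(
                jacobian(params, ctrl, coords))))
            np.testing.assert_allclose(expanded, numeric, rtol=1e-8,
                                       atol=1e-8 * max(1, np.max(
                                           np.abs(numeric))))


class TestBoundaryEigenvalues:
    def test_product_origin(self, unit_params):
        ctrl = ControlParams("product", 0.1, 0.1, 0.1)
        np.testing.assert_allclose(
            controlled_boundary_eigenvalues(unit_params, ctrl, "E0"),
            [1, 1, 1, 0.5])

    def test_pairwise_e11_hand_values(self, unit_params):
        ctrl = ControlParams("pairwise_sum", 0.0, -2.0, -2.0)
        np.testing.assert_allclose(
            sorted(controlled_boundary_eigenvalues(unit_params, ctrl, "E11")),
            [-1, -1, -1, -0.5])

    @pytest.mark.parametrize("kind,labels", [
        ("product", ["E0", "E11", "E12", "E13", "E212", "E213", "E223"]),
        ("pairwise_sum", ["E0", "E11", "E12", "E13"]),
    ])
    def test_matches_numeric_eigensolver(self, kind, labels):
        draws = sample_params(20, seed=49)
        ctrls = sample_controls(20, seed=50, kind=kind)
        for params, ctrl in zip(draws, ctrls):
            cap = params.carrying_capacity
            for label in labels:
                if label == "E0":
                    coords = np.zeros(4)
                elif label.startswith("E1"):
                    coords = np.zeros(4)
                    coords[int(label[2]) - 1] = cap[int(label[2]) - 1]
                else:
                    i, j = int(label[2]) - 1, int(label[3]) - 1
                    coords = np.zeros(4)
                    coords[i], coords[j] = cap[i], cap[j]
                printed = np.sort(controlled_boundary_eigenvalues(
                    params, ctrl, label))
                numeric = np.sort(np.linalg.eigvals(
                    jacobian(params, ctrl, coords)).real)
                np.testing.assert_allclose(printed, numeric, rtol=1e-9,
                                           atol=1e-9 * max(1, np.max(
                                               np.abs(numeric))))

    def test_unsupported_label_rejected(self, unit_params):
        ctrl = ControlParams("pairwise_sum", 0.1, 0.1, 0.1)
        with pytest.raises(ValueError, match="no printed eigenvalues"):
            controlled_boundary_eigenvalues(unit_params, ctrl, "E212")


class TestZeroControlConsistency:
    def test_predicates_match_uncontrolled_verdicts(self):
        """With all control constants zero, every controlled predicate
        reproduces the uncontrolled classification of its point."""
        for params in sample_params(40, seed=51):
            verdicts = analytic_verdicts(params)
            prod0 = ControlParams("product")
            pw0 = ControlParams("pairwise_sum")
            got = product_e2_attractor(params, prod0)
            if got is not None:
                assert got == (verdicts["E212"] == "attractor")
            got = pairwise_e1_attractor(params, pw0)
            if got is not None:
                assert got == (verdicts["E11"] == "attractor")
            exists, got = pairwise_e212_attractor(params, pw0)
            assert exists
            if got is not None:
                assert got == (verdicts["E212"] == "attractor")
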