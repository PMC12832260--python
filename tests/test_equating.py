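import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorlink.calibration import QuadratureGrid
from anchorlink.equating import (
    AnchorPairs,
    DegenerateAnchorError,
    EquatingCoefficients,
    chain_compose,
    compute_coefficients,
    irf_coefficients,
    mgm_coefficients,
    mm_coefficients,
    ms_coefficients,
    transform_item,
    transform_theta,
    trf_coefficients,
)
from anchorlink.irt_core import ItemParams, icc_probability


def make_pairs(a_s, b_s, a_t, b_t, c_s=None, c_t=None):
    n = len(a_s)
    return AnchorPairs(
        item_ids=tuple(f"anchor{k}" for k in range(n)),
        a_source=np.asarray(a_s, dtype=float),
        b_source=np.asarray(b_s, dtype=float),
        c_source=np.zeros(n) if c_s is None else np.asarray(c_s, dtype=float),
        a_target=np.asarray(a_t, dtype=float),
        b_target=np.asarray(b_t, dtype=float),
        c_target=np.zeros(n) if c_t is None else np.asarray(c_t, dtype=float),
    )


def linear_pairs(A, B, a_s=(0.8, 1.0, 1.3, 0.6), b_s=(-1.2, -0.1, 0.7, 1.5), c=0.0):
    """Anchors exactly linearly related by (A, B): the zero-loss construction."""
    a_s = np.asarray(a_s, dtype=float)
    b_s = np.asarray(b_s, dtype=float)
    cs = np.full(a_s.size, c)
    return make_pairs(a_s, b_s, a_s / A, A * b_s + B, c_s=cs, c_t=cs)


IDENTICAL = make_pairs([0.8, 1.0, 1.2], [-1.0, 0.0, 1.0], [0.8, 1.0, 1.2], [-1.0, 0.0, 1.0])


class TestMS:
    def test_hand_computed(self):
        pairs = make_pairs([1, 1, 1], [-1, 0, 1], [1, 1, 1], [-1, 1, 3])
        coef = ms_coefficients(pairs)
        assert coef.A == pytest.approx(2.0)
        assert coef.B == pytest.approx(1.0)

    def test_identity(self):
        coef = ms_coefficients(IDENTICAL)
        assert coef.A == pytest.approx(1.0)
        assert coef.B == pytest.approx(0.0, abs=1e-12)

    def test_pure_shift(self):
        b = np.array([-1.0, 0.0, 1.0])
        pairs = make_pairs([1, 1, 1], b, [1, 1, 1], b + 5)
        coef = ms_coefficients(pairs)
        assert coef.A == pytest.approx(1.0)
        assert coef.B == pytest.approx(5.0)

    def test_single_anchor_inapplicable(self):
        pairs = make_pairs([1.0], [0.0], [1.0], [1.0])
        with pytest.raises(DegenerateAnchorError):
            ms_coefficients(pairs)

    def test_zero_spread_rejected(self):
        pairs = make_pairs([1, 1], [0.5, 0.5], [1, 1], [-1, 1])
        with pytest.raises(DegenerateAnchorError):
            ms_coefficients(pairs)


class TestMM:
    def test_hand_computed(self):
        pairs = make_pairs([0.8, 1.0, 1.2], [-1, 0, 1], [0.4, 0.5, 0.6], [-1, 1, 3])
        coef = mm_coefficients(pairs)
        assert coef.A == pytest.approx(2.0)  # 3.0 / 1.5
        assert coef.B == pytest.approx(1.0)

    def test_identity(self):
        coef = mm_coefficients(IDENTICAL)
        assert coef.A == pytest.approx(1.0)
        assert coef.B == pytest.approx(0.0, abs=1e-12)

    def test_single_anchor(self):
        pairs = make_pairs([2.0], [0.0], [1.0], [1.0])
        coef = mm_coefficients(pairs)
        assert coef.A == pytest.approx(2.0)
        assert coef.B == pytest.approx(1.0)


class TestMGM:
    def test_constant_ratios(self):
        pairs = make_pairs([2.0, 1.6, 0.8], [-1, 0, 1], [1.0, 0.8, 0.4], [-1, 1, 3])
        assert mgm_coefficients(pairs).A == pytest.approx(2.0)

    def test_geometric_mean_of_ratios(self):
        pairs = make_pairs([1.0, 2.0], [0.0, 1.0], [1.0, 0.5], [0.0, 1.0])
        assert mgm_coefficients(pairs).A == pytest.approx(2.0)  # sqrt(1 * 4)

    def test_identity(self):
        coef = mgm_coefficients(IDENTICAL)
        assert coef.A == pytest.approx(1.0)
        assert coef.B == pytest.approx(0.0, abs=1e-12)


class TestCurveMethods:
    @pytest.mark.parametrize("fn", [irf_coefficients, trf_coefficients])
    def test_zero_loss_construction(self, fn):
        coef = fn(linear_pairs(2.0, 1.0))
        assert coef.A == pytest.approx(2.0, abs=1e-4)
        assert coef.B == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("fn", [irf_coefficients, trf_coefficients])
    def test_identity(self, fn):
        coef = fn(IDENTICAL)
        assert coef.A == pytest.approx(1.0, abs=1e-5)
        assert coef.B == pytest.approx(0.0, abs=1e-5)

    def test_perturbed_init_recovers_truth(self):
        pairs = linear_pairs(2.0, 1.0)
        init = EquatingCoefficients(A=2.1, B=1.1)
        coef = irf_coefficients(pairs, init=init)
        assert coef.A == pytest.approx(2.0, abs=1e-4)
        assert coef.B == pytest.approx(1.0, abs=1e-4)

    def test_single_anchor_irf_equals_trf(self):
        pairs = make_pairs([1.4], [0.3], [0.9], [0.8])
        c1 = irf_coefficients(pairs)
        c2 = trf_coefficients(pairs)
        assert c1.A == pytest.approx(c2.A, abs=1e-6)
        assert c1.B == pytest.approx(c2.B, abs=1e-6)

    def test_zero_loss_with_guessing(self):
        pairs = linear_pairs(1.5, -0.5, c=0.2)
        coef = trf_coefficients(pairs)
        assert coef.A == pytest.approx(1.5, abs=1e-4)
        assert coef.B == pytest.approx(-0.5, abs=1e-4)


class TestAllMethodsConsistent:
    def test_noiseless_exact_recovery(self):
        pairs = linear_pairs(2.0, 1.0)
        for method in ("MS", "MM", "MGM", "IRF", "TRF"):
            coef = compute_coefficients(method, pairs)
            assert coef.A == pytest.approx(2.0, abs=1e-4), method
            assert coef.B == pytest.approx(1.0, abs=1e-4), method

    def test_method_agreement_under_noise(self):
        """The five slope estimates stay strongly correlated across noisy draws."""
        rng = np.random.default_rng(77)
        estimates = {m: [] for m in ("MS", "MM", "MGM", "IRF", "TRF")}
        for _ in range(60):
            A_true = rng.uniform(0.7, 1.4)
            B_true = rng.uniform(-0.5, 0.5)
            a_s = rng.lognormal(0, 0.2, 8)
            b_s = rng.normal(0, 1, 8)
            pairs = make_pairs(
                a_s * np.exp(rng.normal(0, 0.05, 8)),
                b_s + rng.normal(0, 0.05, 8),
                a_s / A_true * np.exp(rng.normal(0, 0.05, 8)),
                A_true * b_s + B_true + rng.normal(0, 0.05, 8),
            )
            for m in estimates:
                estimates[m].append(compute_coefficients(m, pairs).A)
        methods = list(estimates)
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                r = np.corrcoef(estimates[methods[i]], estimates[methods[j]])[0, 1]
                assert r > 0.9, (methods[i], methods[j], r)


class TestTransforms:
    def test_transform_item_substitution(self):
        item = ItemParams("i", a=1.2, b=0.5, c=0.2)
        out = transform_item(item, EquatingCoefficients(A=2.0, B=1.0))
        assert out.a == pytest.approx(0.6)
        assert out.b == pytest.approx(2.0)
        assert out.c == 0.2  # guessing is scale-invariant

    def test_identity_transform(self):
        item = ItemParams("i", a=1.2, b=0.5, c=0.2)
        out = transform_item(item, EquatingCoefficients(A=1.0, B=0.0))
        assert out == item

    def test_round_trip_inverse(self):
        item = ItemParams("i", a=0.9, b=-1.3, c=0.1)
        coef = EquatingCoefficients(A=1.7, B=0.4)
        back = transform_item(transform_item(item, coef), coef.inverse())
        assert back.a == pytest.approx(item.a, abs=1e-12)
        assert back.b == pytest.approx(item.b, abs=1e-12)

    def test_transform_theta(self):
        coef = EquatingCoefficients(A=2.0, B=1.0)
        assert transform_theta(0.5, coef) == pytest.approx(2.0)
        assert transform_theta(0.0, EquatingCoefficients(A=1.0, B=0.0)) == 0.0

    def test_icc_invariance(self):
        item = ItemParams("i", a=1.1, b=0.3, c=0.15)
        coef = EquatingCoefficients(A=1.8, B=-0.6)
        titem = transform_item(item, coef)
        for theta in np.linspace(-3, 3, 13):
            p0 = icc_probability(theta, item, "3PL")
            p1 = icc_probability(transform_theta(theta, coef), titem, "3PL")
            assert p1 == pytest.approx(p0, abs=1e-12)


class TestChainCompose:
    def test_two_links_hand_computed(self):
        c1 = EquatingCoefficients(A=2.0, B=1.0, n_anchors=3)
        c2 = EquatingCoefficients(A=0.5, B=-1.0, n_anchors=3)
        comp = chain_compose([c1, c2])
        assert comp.A == pytest.approx(1.0, abs=1e-12)
        assert comp.B == pytest.approx(-0.5, abs=1e-12)

    def test_two_link_closed_form(self):
        # A_c = A12 * A23; B_c = A23 * B12 + B23
        c1 = EquatingCoefficients(A=1.3, B=0.4, n_anchors=2)
        c2 = EquatingCoefficients(A=0.8, B=-0.2, n_anchors=2)
        comp = chain_compose([c1, c2])
        assert comp.A == pytest.approx(1.3 * 0.8, abs=1e-12)
        assert comp.B == pytest.approx(0.8 * 0.4 - 0.2, abs=1e-12)

    def test_inverse_cancels(self):
        c = EquatingCoefficients(A=1.7, B=0.3, n_anchors=2)
        comp = chain_compose([c, c.inverse()])
        assert comp.A == pytest.approx(1.0, abs=1e-12)
        assert comp.B == pytest.approx(0.0, abs=1e-12)

    def test_single_link(self):
        c = EquatingCoefficients(A=1.7, B=0.3, n_anchors=2)
        comp = chain_compose([c])
        assert (comp.A, comp.B) == (c.A, c.B)

    def test_matches_sequential_application(self):
        links = [
            EquatingCoefficients(A=1.2, B=0.1, n_anchors=1),
            EquatingCoefficients(A=0.9, B=-0.4, n_anchors=1),
            EquatingCoefficients(A=1.5, B=0.7, n_anchors=1),
        ]
        comp = chain_compose(links)
        for b in (-2.0, 0.0, 1.3):
            step = b
            for c in links:
                step = c.A * step + c.B
            assert comp.A * b + comp.B == pytest.approx(step, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(
        As=st.lists(st.floats(0.5, 2.0), min_size=3, max_size=3),
        Bs=st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3),
    )
    def test_associativity(self, As, Bs):
        links = [EquatingCoefficients(A=A, B=B, n_anchors=1) for A, B in zip(As, Bs)]
        left = chain_compose([chain_compose(links[:2]), links[2]])
        right = chain_compose([links[0], chain_compose(links[1:])])
        assert left.A == pytest.approx(right.A, rel=1e-12)
        assert left.B == pytest.approx(right.B, abs=1e-12)

    def test_broken_path_rejected(self):
        c1 = EquatingCoefficients(A=1.0, B=0.0, n_anchors=1, source_form=1, target_form=2)
        c2 = EquatingCoefficients(A=1.0, B=0.0, n_anchors=1, source_form=3, target_form=2)
        with pytest.raises(ValueError, match="broken chain"):
            chain_compose([c1, c2])


class TestValidation:
    def test_nonpositive_discrimination_rejected(self):
        with pytest.raises(ValueError):
            make_pairs([1.0, -0.5], [0, 0], [1.0, 1.0], [0, 0])

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown equating method"):
            compute_coefficients("EQ", IDENTICAL)

    def test_coefficients_require_positive_slope(self):
        with pytest.raises(ValueError):
            EquatingCoefficients(A=-1.0, B=0.0)
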