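import numpy as np
import pytest

from growthzones import (
    ContinuationSettings,
    NondimParams,
    build_diagram,
    classify_branch,
    detect_special_points,
    neto_length,
    switch_branch,
    trace_branch,
    NO_NETO,
)
from growthzones.continuation import BranchSwitchError, FAST_SETTINGS
from growthzones.equilibria import enumerate_equilibria, refine_equilibrium

from oracle import oracle_equilibria


def _pitchforks(diagram):
    sym = [b for b in diagram.branches if b.label in ("orb", "symmetric_unstable")]
    pts = {round(sp.l, 6) for b in sym for sp in b.special_points
           if sp.kind == "branch_point"}
    return sorted(pts)


class TestTraceBranch:
    def test_symmetric_diagonal_is_invariant(self, symmetric_params):
        """The symmetric subspace is Newton-invariant: a trace started on the
        diagonal stays on it to near machine precision."""
        start = enumerate_equilibria(symmetric_params, 0.05)[0]
        b = trace_branch(symmetric_params, start, (0.05, 2.5))
        assert np.max(np.abs(b.x[:, 0] - b.x[:, 1])) < 1e-10

    def test_points_satisfy_residual_invariant(self, symmetric_params):
        from growthzones import model
        start = enumerate_equilibria(symmetric_params, 0.05)[0]
        b = trace_branch(symmetric_params, start, (0.05, 2.5))
        res = [np.max(np.abs(model.rhs(symmetric_params, l, x)))
               for l, x in zip(b.l, b.x)]
        assert max(res) < 1e-8

    def test_self_convergence_at_half_step(self, symmetric_params):
        """Halving the maximum step keeps the traced polyline within a small
        tube of the original."""
        start = enumerate_equilibria(symmetric_params, 0.05)[0]
        coarse = trace_branch(symmetric_params, start, (0.05, 2.5))
        fine = trace_branch(
            symmetric_params, start, (0.05, 2.5),
            ContinuationSettings(ds_max=2.5e-2),
        )
        Uc = np.hstack([coarse.x, coarse.l[:, None]])
        Uf = np.hstack([fine.x, fine.l[:, None]])
        from growthzones.continuation import _point_polyline_dist
        worst = max(_point_polyline_dist(Uc, p) for p in Uf)
        assert worst < 10 * 5e-2


class TestSpecialPoints:
    def test_symmetric_branch_carries_two_pitchforks(self, symmetric_diagram):
        pfs = _pitchforks(symmetric_diagram)
        assert len(pfs) == 2
        assert pfs[0] < pfs[1]

    def test_monopolar_branch_has_two_folds(self, symmetric_diagram):
        mono = symmetric_diagram.branches_labelled("monopolar_1")[0]
        folds = [sp for sp in mono.special_points if sp.kind == "fold"]
        assert len(folds) == 2

    def test_fold_agrees_with_oracle_count_change(self, symmetric_params):
        """Bisecting the l at which the brute-force equilibrium count changes
        brackets the detected NETO fold."""
        d = build_diagram(symmetric_params, (0.05, 2.5))
        l_star = neto_length(d, "monopolar_1")
        lo, hi = l_star - 0.05, l_star + 0.05
        n_lo = len(oracle_equilibria(symmetric_params, lo))
        n_hi = len(oracle_equilibria(symmetric_params, hi))
        assert n_lo != n_hi
        for _ in range(26):
            mid = 0.5 * (lo + hi)
            if len(oracle_equilibria(symmetric_params, mid)) == n_lo:
                lo = mid
            else:
                hi = mid
        assert abs(0.5 * (lo + hi) - l_star) < 1e-6

    def test_too_short_branch_yields_nothing(self, symmetric_params):
        start = enumerate_equilibria(symmetric_params, 0.5)[0]
        b = trace_branch(symmetric_params, start, (0.49, 0.51))
        assert detect_special_points(b) == [] or all(
            sp.kind in ("fold", "branch_point") for sp in detect_special_points(b)
        )


class TestSwitchBranch:
    def test_mirror_starts_at_first_pitchfork(self, symmetric_params, symmetric_diagram):
        pf_l = _pitchforks(symmetric_diagram)[0]
        orb = symmetric_diagram.branches_labelled("orb")[0]
        sp = [s for s in orb.special_points if s.kind == "branch_point"][0]
        starts = switch_branch(symmetric_params, sp)
        assert len(starts) == 2
        x1, x2 = starts[0].x_array, starts[1].x_array
        assert (x1[0] - x1[1]) * (x2[0] - x2[1]) < 0  # opposite dominance
        # mutual swaps for equal weights
        assert np.max(np.abs(x1 - x2[::-1])) < 1e-8

    def test_halved_perturbation_converges_to_same_branch(self, symmetric_params, symmetric_diagram):
        orb = symmetric_diagram.branches_labelled("orb")[0]
        sp = [s for s in orb.special_points if s.kind == "branch_point"][0]
        s1 = switch_branch(symmetric_params, sp, delta=0.02)
        s2 = switch_branch(symmetric_params, sp, delta=0.01)
        d = min(
            np.max(np.abs(a.x_array - b.x_array)) + abs(a.l - b.l)
            for a in s1 for b in s2
        )
        assert d < 1e-6

    def test_fold_is_rejected(self, symmetric_diagram, symmetric_params):
        mono = symmetric_diagram.branches_labelled("monopolar_1")[0]
        fold = [sp for sp in mono.special_points if sp.kind == "fold"][0]
        with pytest.raises(ValueError, match="fold"):
            switch_branch(symmetric_params, fold)


class TestDiagramAssembly:
    def test_wild_type_label_set(self, symmetric_diagram):
        labels = set(symmetric_diagram.labels())
        assert {"orb", "monopolar_1", "monopolar_2", "bipolar",
                "symmetric_unstable"} <= labels

    def test_oracle_validation_passes(self, symmetric_diagram):
        v = symmetric_diagram.provenance["validation"]
        assert not v["count_mismatch"]
        assert v["max_distance"] < 1e-5
        assert not symmetric_diagram.incomplete

    def test_large_basal_rate_single_branch(self):
        p = NondimParams(0.5, 20.0, (0.5, 0.5))
        d = build_diagram(p, (0.05, 2.5))
        assert len(d.special_points()) == 0
        assert len(d.branches) == 1

    def test_epsilon_zero_rejected(self):
        with pytest.raises(ValueError):
            build_diagram(NondimParams(0.0, 20.0, (0.5, 0.5)), (0.05, 2.5))

    def test_mirror_branches_are_exact_images(self, symmetric_diagram):
        """For equal weights the two monopolar branches are mirror images."""
        m1 = symmetric_diagram.branches_labelled("monopolar_1")[0]
        m2 = symmetric_diagram.branches_labelled("monopolar_2")[0]
        lo = max(m1.l[m1.stable_mask()].min(), m2.l[m2.stable_mask()].min())
        hi = min(m1.l[m1.stable_mask()].max(), m2.l[m2.stable_mask()].max())
        worst = 0.0
        for l0 in np.linspace(lo + 1e-3, hi - 1e-3, 9):
            s1 = [x for x, s in m1.solutions_at(l0) if s == "stable"]
            s2 = [x[::-1] for x, s in m2.solutions_at(l0) if s == "stable"]
            assert s1 and s2
            worst = max(worst, min(np.max(np.abs(a - b)) for a in s1 for b in s2))
        assert worst < 1e-8


class TestClassifyBranch:
    def test_zero_threshold_degenerates_as_documented(self, symmetric_diagram):
        orb = symmetric_diagram.branches_labelled("orb")[0]
        # any positive activity counts as active at threshold zero
        assert classify_branch(orb, activity_threshold=0.0) in ("bipolar", "mixed")

    def test_monopolar_labels_identify_the_active_zone(self, symmetric_diagram):
        m1 = symmetric_diagram.branches_labelled("monopolar_1")[0]
        stable = m1.x[m1.stable_mask()]
        assert np.all(stable[:, 0] > stable[:, 1])


class TestNeto:
    def test_neto_is_the_monopolar_fold(self, symmetric_diagram):
        l_star = neto_length(symmetric_diagram, "monopolar_1")
        mono = symmetric_diagram.branches_labelled("monopolar_1")[0]
        folds = [sp.l for sp in mono.special_points if sp.kind == "fold"]
        assert l_star == pytest.approx(max(folds), abs=1e-9)

    def test_absent_label_raises(self, symmetric_diagram):
        with pytest.raises(KeyError):
            neto_length(symmetric_diagram, "tripolar")

    def test_no_neto_sentinel_when_branch_reaches_l_max(self, symmetric_params):
        d = build_diagram(symmetric_params, (0.05, 1.1))
        assert neto_length(d, "monopolar_1") == NO_NETO


class TestReduction:
    def test_zero_weight_zone_reproduces_two_zone_diagram(self):
        """The three-zone system restricted to a_3 = 0 projects onto the
        two-zone diagram."""
        p3 = NondimParams(0.1, 20.0, (0.5, 0.5, 0.0))
        p2 = NondimParams(0.1, 20.0, (0.5, 0.5))
        d3 = build_diagram(p3, (0.05, 2.5), FAST_SETTINGS)
        d2 = build_diagram(p2, (0.05, 2.5), FAST_SETTINGS)
        for l0 in np.linspace(0.2, 2.3, 8):
            s3 = [x[:2] for x in d3.stable_states_at(l0)]
            s2 = d2.stable_states_at(l0)
            assert len(s3) == len(s2)
            for a in s3:
                assert min(np.max(np.abs(a - b)) for b in s2) < 1e-6
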