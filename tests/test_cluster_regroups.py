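"""Cycle clustering: quadratic surface fits, region growing against ground
truth on clean wave patterns, orphan handling, and manual regrouping."""

from __future__ import annotations

import numpy as np
import pytest

from slowwave.cluster_regroups import (
    edit_cluster,
    fit_activation_surface,
    regroups_cluster,
)
from slowwave.core import ElectrodeLayout, EventMarks, Mark, SlowWaveError
from slowwave.params import ParameterSet
from slowwave.synthgen import SyntheticScenario, generate_recording

from conftest import marks_from_truth


def _grid_points(nr, nc, f):
    return [(float(x), float(y), f(x, y)) for y in range(nr) for x in range(nc)]


class TestSurfaceFit:
    def test_exact_linear_recovery(self):
        s = fit_activation_surface(_grid_points(3, 3, lambda x, y: 2 + 0.5 * x))
        np.testing.assert_allclose(s.coeffs, [2, 0.5, 0, 0, 0, 0], atol=1e-12)
        assert s.residual_rms < 1e-12

    def test_exact_quadratic_recovery(self):
        s = fit_activation_surface(_grid_points(4, 4, lambda x, y: 1 + x * x - 0.3 * x * y))
        np.testing.assert_allclose(s.coeffs, [1, 0, 0, 1, -0.3, 0], atol=1e-9)
        assert s.residual_rms < 1e-9

    def test_collinear_points_degenerate(self):
        pts = [(float(x), 0.0, float(x)) for x in range(8)]
        with pytest.raises(SlowWaveError, match="degenerate configuration"):
            fit_activation_surface(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(SlowWaveError, match="6"):
            fit_activation_surface(_grid_points(1, 5, lambda x, y: x))

    def test_noisy_coefficients_match_normal_equations_error(self):
        # Monte-Carlo RMSE of fitted coefficients vs the closed-form
        # least-squares standard error from the normal equations
        rng = np.random.default_rng(0)
        truth = np.array([1.0, 0.2, -0.1, 0.05, 0.02, -0.03])
        xy = [(float(x), float(y)) for y in range(8) for x in range(8)]
        A = np.array([[1, x, y, x * x, x * y, y * y] for x, y in xy])
        sigma = 0.1
        cov = sigma ** 2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        errs = []
        for _ in range(200):
            t = A @ truth + rng.normal(0, sigma, len(xy))
            s = fit_activation_surface([(x, y, tt) for (x, y), tt in zip(xy, t)])
            errs.append(s.coeffs - truth)
        rmse = np.sqrt(np.mean(np.square(errs), axis=0))
        assert np.all(rmse < 3 * se)


class TestRegroups:
    def test_two_planar_waves_fully_recovered(self, layout8):
        # two clean wavefronts 20 s apart: clustering must match the
        # brute-force time-gap bisection oracle exactly
        scn = SyntheticScenario(duration_s=45.0, seed=0)
        _, truth = generate_recording(scn)
        marks = marks_from_truth(truth)
        assert marks.n_marks() == 128
        asg = regroups_cluster(marks, layout8)
        assert asg.n_cycles() == 2 and len(asg.orphans) == 0
        # oracle: cycle membership by bisecting at the 10 s gap
        for ch, ms in marks.by_channel.items():
            for m in ms:
                want = 1 if m.time_s < 15.0 else 2
                assert asg.cycle_of(ch, m.time_s) == want

    def test_single_mark_forms_singleton_cycle(self, layout8):
        marks = EventMarks({"0": [Mark(3.0)]})
        asg = regroups_cluster(marks, layout8)
        assert asg.n_cycles() == 1 and asg.cycle_members(1) == {"0": 3.0}

    def test_single_mark_orphaned_when_min_size_two(self, layout8):
        marks = EventMarks({"0": [Mark(3.0)]})
        asg = regroups_cluster(marks, layout8,
                               ParameterSet().replace(regroups_min_cycle_size=2))
        assert asg.n_cycles() == 0 and asg.orphans == {("0", 3.0)}

    def test_spurious_marks_orphaned_memberships_unchanged(self, layout8):
        scn = SyntheticScenario(duration_s=45.0, seed=0)
        _, truth = generate_recording(scn)
        clean = marks_from_truth(truth)
        ref = regroups_cluster(clean, layout8,
                               ParameterSet().replace(regroups_min_cycle_size=2))
        noisy = clean.copy()
        # five spurious marks at least 8 s off any wavefront
        for ch, t in [("3", 35.0), ("17", 36.0), ("33", 34.5), ("50", 36.5), ("62", 35.5)]:
            noisy.by_channel[ch] = sorted(
                noisy.by_channel[ch] + [Mark(t)], key=lambda m: m.time_s
            )
        asg = regroups_cluster(noisy, layout8,
                               ParameterSet().replace(regroups_min_cycle_size=2))
        spurious = {("3", 35.0), ("17", 36.0), ("33", 34.5), ("50", 36.5), ("62", 35.5)}
        assert spurious <= asg.orphans
        for k in range(1, ref.n_cycles() + 1):
            assert asg.cycle_members(k) == ref.cycle_members(k)

    @pytest.mark.parametrize("fixture", ["clean_planar", "clean_radial", "clean_retrograde"])
    def test_clean_patterns_zero_errors(self, fixture, layout8, request):
        scn, _, truth = request.getfixturevalue(fixture)
        marks = marks_from_truth(truth)
        asg = regroups_cluster(marks, layout8)
        assert len(asg.orphans) == 0
        assert asg.n_cycles() == truth.n_cycles
        for ch, ms in marks.by_channel.items():
            for m, want in zip(ms, truth.cycle_of[ch]):
                assert asg.cycle_of(ch, m.time_s) == int(want)

    def test_conservation_invariant(self, layout8):
        scn = SyntheticScenario(duration_s=65.0, seed=1)
        _, truth = generate_recording(scn)
        marks = marks_from_truth(truth)
        asg = regroups_cluster(marks, layout8)
        asg.check_conservation(marks)
        assert marks.n_marks() == sum(len(c) for c in asg.cycles) + len(asg.orphans)

    def test_renumbering_idempotent_and_ordered(self, layout8):
        scn = SyntheticScenario(duration_s=65.0, seed=1)
        _, truth = generate_recording(scn)
        asg = regroups_cluster(marks_from_truth(truth), layout8)
        means = [np.mean(list(c.values())) for c in asg.cycles]
        assert means == sorted(means)
        before = [dict(c) for c in asg.cycles]
        asg.renumber()
        assert [dict(c) for c in asg.cycles] == before

    def test_empty_marks_rejected(self, layout8):
        with pytest.raises(SlowWaveError):
            regroups_cluster(EventMarks({}), layout8)


class TestEditCluster:
    def _asg(self, layout8):
        marks = EventMarks({"0": [Mark(1.0)], "1": [Mark(1.5)], "2": [Mark(40.0)]})
        return marks, regroups_cluster(marks, layout8)

    def test_move_orphan_into_cycle(self, layout8):
        marks, asg = self._asg(layout8)
        asg2 = edit_cluster(asg, ("2", 40.0), "orphan")
        assert ("2", 40.0) in asg2.orphans
        asg3 = edit_cluster(asg2, ("2", 40.0), 1)
        assert asg3.cycle_of("2", 40.0) == 1
        assert len(asg3.orphans) == 0

    def test_move_to_orphan_and_back_is_identity(self, layout8):
        marks, asg = self._asg(layout8)
        k = asg.cycle_of("2", 40.0)
        back = edit_cluster(edit_cluster(asg, ("2", 40.0), "orphan"), ("2", 40.0), "new_cycle")
        assert back.cycles == asg.cycles and back.orphans == asg.orphans

    def test_channel_conflict_names_displaced_mark(self, layout8):
        marks = EventMarks({"0": [Mark(1.0), Mark(30.0)], "1": [Mark(1.5)]})
        asg = regroups_cluster(marks, layout8)
        k = asg.cycle_of("0", 1.0)
        with pytest.raises(SlowWaveError, match="1.0"):
            edit_cluster(asg, ("0", 30.0), k)

    def test_manual_fix_on_conduction_block(self, layout8):
        # a long block delay splits one wavefront; manually re-merging the
        # late patch reproduces the generator's membership
        scn = SyntheticScenario(pattern="block", duration_s=24.0, period_s=22.0,
                                block_rect=(0, 6, 7, 7), block_delay_s=8.0, seed=0)
        _, truth = generate_recording(scn)
        marks = marks_from_truth(truth)
        asg = regroups_cluster(marks, layout8)
        if asg.n_cycles() > 1:
            main = max(range(1, asg.n_cycles() + 1), key=lambda k: len(asg.cycle_members(k)))
            for k in range(1, asg.n_cycles() + 1):
                if k == main:
                    continue
                for ch, t in asg.cycle_members(k).items():
                    asg = edit_cluster(asg, (ch, t), main if main <= asg.n_cycles() else 1)
                    main = 1 if asg.n_cycles() == 1 else main
        for (ch, t) in list(asg.orphans):
            asg = edit_cluster(asg, (ch, t), 1)
        assert asg.n_cycles() == 1
        assert len(asg.cycle_members(1)) == marks.n_marks()
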