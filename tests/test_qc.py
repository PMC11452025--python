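import numpy as np
import pytest

from triplocall.calling import NA_DOSAGE, assign_single_pop
from triplocall.qc import (MarkerCategory, QCMetrics, QCThresholds,
                           apply_nocall_rules, categorize, compute_fld,
                           compute_hetso, compute_homro, compute_metrics)
from conftest import model_from_groups


THR = QCThresholds()


def tight(c, n):
    return np.full(n, c) + np.linspace(-0.01, 0.01, n)


class TestNoCallRules:
    def test_low_membership_probability_blanked(self):
        groups = [tight(-1.5, 3), tight(-0.5, 3)]
        P = np.array([[1, 0], [1, 0], [0.80, 0.20],
                      [0, 1], [0, 1], [0.1, 0.9]], float)
        model = model_from_groups(groups, P=P)
        calls = assign_single_pop(model, 3)
        out = apply_nocall_rules(model, calls, THR)
        assert out.dosage[2] == NA_DOSAGE       # probability 0.80 < 0.85
        assert (out.dosage != NA_DOSAGE).sum() == 5

    def test_overdispersed_cluster_blanked_wholesale(self):
        wide = np.array([-0.52, -0.3, 0.0, 0.3, 0.52])  # sd ~0.43 > 0.28 cap
        assert wide.std(ddof=1) > 0.28 * (1 + 0.5 * abs(wide.mean()))
        model = model_from_groups([wide, tight(1.5, 5)])
        calls = assign_single_pop(model, 3)
        out = apply_nocall_rules(model, calls, THR)
        assert np.all(out.dosage[:5] == NA_DOSAGE)
        assert np.all(out.dosage[5:] != NA_DOSAGE)

    def test_distance_rule_blanks_far_members(self):
        x = np.concatenate([tight(0.5, 40), [0.5 + 0.2]])  # sd ~0.012
        model = model_from_groups([x])
        calls = assign_single_pop(model, 3)
        out = apply_nocall_rules(model, calls, THR)
        assert out.dosage[-1] == NA_DOSAGE
        assert np.all(out.dosage[:-1] != NA_DOSAGE)

    def test_gaussian_cluster_distance_nocall_rate(self):
        """Under normality ~0.5% of a clean cluster falls outside +/-2.8 SD."""
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(0.5, 0.12, 20000), 3)
        model = model_from_groups([x])
        calls = assign_single_pop(model, 3)
        out = apply_nocall_rules(model, calls, THR)
        frac = (out.dosage == NA_DOSAGE).mean()
        assert 0.003 <= frac <= 0.007


class TestFLD:
    def test_direct_evaluation(self):
        g1 = np.array([-0.25, 0.25])          # mean 0, var 0.125
        g2 = np.array([0.75, 1.25])           # mean 1, var 0.125
        model = model_from_groups([g2, g1])
        calls = assign_single_pop(model, 3)
        # pooled sd = sqrt(0.125) -> FLD = 1 / 0.35355
        assert compute_fld(model, calls) == pytest.approx(1 / np.sqrt(0.125))

    def test_matches_brute_force_on_random_models(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = rng.integers(2, 5)
            centres = np.sort(rng.uniform(-2, 2, k))
            while np.min(np.diff(centres)) < 0.4:
                centres = np.sort(rng.uniform(-2, 2, k))
            groups = [rng.normal(c, 0.1, rng.integers(5, 30)) for c in centres]
            model = model_from_groups(groups)
            calls = assign_single_pop(model, 3)
            got = compute_fld(model, calls)
            # brute force: all pairs, nearest by mean distance
            stats = [(g.mean(), g.var(ddof=1), len(g)) for g in groups]
            best = None
            for i in range(k):
                for j in range(i + 1, k):
                    c1, v1, n1 = stats[i]
                    c2, v2, n2 = stats[j]
                    d = abs(c1 - c2)
                    if best is None or d < best[0]:
                        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
                        best = (d, d / sp)
            assert got == pytest.approx(best[1])

    def test_single_genotype_absent(self):
        model = model_from_groups([tight(0.5, 10)])
        calls = assign_single_pop(model, 3)
        assert compute_fld(model, calls) is None

    def test_invariant_under_shift_and_scale(self):
        groups = [np.array([0.0, 0.1, -0.1]), np.array([1.0, 1.1, 0.9])]
        m0 = model_from_groups(groups)
        base = compute_fld(m0, assign_single_pop(m0, 3))
        for f in (lambda g: g + 0.7, lambda g: g * 2.5):
            m = model_from_groups([f(g) for g in groups])
            assert compute_fld(m, assign_single_pop(m, 3)) == pytest.approx(base)


class TestHetSO:
    def _model4(self, xs, ys):
        return model_from_groups([tight(x, 5) for x in xs],
                                 groups_y=[np.full(5, y) for y in ys])

    def test_het_above_homozygote_line(self):
        # homozygotes at (-1, 1.0) and (1, 1.0); the lowest het offset is the
        # het at (0.2, 1.2) against the interpolated baseline 1.0 -> +0.2
        model = self._model4([-1.0, -0.3, 0.2, 1.0], [1.0, 1.25, 1.2, 1.0])
        calls = assign_single_pop(model, 3)
        assert compute_hetso(model, calls) == pytest.approx(0.2, abs=1e-6)

    def test_depressed_het_flags_off_target(self):
        model = self._model4([-1.0, -0.5, 0.0, 1.0], [1.0, 1.0, 0.6, 1.0])
        calls = assign_single_pop(model, 3)
        assert compute_hetso(model, calls) == pytest.approx(-0.4, abs=1e-6)
        metrics = compute_metrics(model, calls)
        cat = categorize(calls, metrics, THR, ploidy=3)
        assert cat is MarkerCategory.OFF_TARGET_VARIANT

    def test_no_heterozygote_absent(self):
        single = model_from_groups([tight(1.5, 5)])
        assert compute_hetso(single, assign_single_pop(single, 3)) is None

    def test_sloped_homozygote_baseline_interpolated(self):
        # line from hom (-1, 0.8) to hom (1, 1.2) has y = 1.0 at x = 0
        model = self._model4([-1.0, 0.0, 0.5, 1.0], [0.8, 1.1, 1.3, 1.2])
        calls = assign_single_pop(model, 3)
        assert compute_hetso(model, calls) == pytest.approx(0.1, abs=1e-6)

    def test_single_homozygote_baseline(self):
        # three clusters: one homozygote only; its strength is the baseline
        model = model_from_groups(
            [tight(-1.5, 5), tight(-0.5, 5), tight(0.5, 5)],
            groups_y=[np.full(5, 1.0), np.full(5, 1.2), np.full(5, 1.1)])
        calls = assign_single_pop(model, 3)
        assert compute_hetso(model, calls) == pytest.approx(0.1, abs=1e-6)


class TestHomRO:
    def test_both_homozygotes(self):
        model = model_from_groups([tight(1.2, 5), tight(0.1, 5), tight(-1.1, 5)])
        # force the full ladder so both homs are present
        model4 = model_from_groups([tight(c, 5) for c in (1.2, 0.4, -0.4, -1.1)])
        calls = assign_single_pop(model4, 3)
        assert compute_homro(model4, calls) == pytest.approx(1.1, abs=0.02)

    def test_single_positive_homozygote_below_threshold(self):
        model = model_from_groups([tight(0.5, 30)])
        calls = assign_single_pop(model, 3)
        assert compute_homro(model, calls) == pytest.approx(0.5, abs=0.01)
        metrics = compute_metrics(model, calls)
        assert metrics.n_genotypes == 1
        assert THR.homro_min(1, 3) == 0.6
        assert categorize(calls, metrics, THR, 3) is MarkerCategory.OTHERS

    def test_b_homozygote_sign_convention(self):
        model = model_from_groups([tight(-0.8, 30)])
        calls = assign_single_pop(model, 3)
        assert compute_homro(model, calls) == pytest.approx(0.8, abs=0.01)


class TestCategorize:
    def metrics(self, **kw):
        base = dict(call_rate=1.0, fld=10.0, hetso=0.1, homro=1.2, n_genotypes=4)
        base.update(kw)
        return QCMetrics(**base)

    def calls(self, collision=False):
        model = model_from_groups([tight(c, 10) for c in (1.5, 0.5, -0.5, -1.5)])
        c = assign_single_pop(model, 3)
        c.collision = collision
        return c

    @pytest.mark.parametrize("kw, expected", [
        (dict(), MarkerCategory.POLY_HIGH_RESOLUTION),
        (dict(n_genotypes=1), MarkerCategory.MONO_HIGH_RESOLUTION),
        (dict(n_genotypes=2), MarkerCategory.NO_MINOR_HOMOZYGOTE),
        (dict(n_genotypes=3), MarkerCategory.NO_MINOR_HOMOZYGOTE),
        (dict(call_rate=0.96), MarkerCategory.CALL_RATE_BELOW_THRESHOLD),
        (dict(hetso=-0.4), MarkerCategory.OFF_TARGET_VARIANT),
        (dict(fld=3.36), MarkerCategory.OTHERS),   # just below the 3.4 bound
        (dict(fld=3.4), MarkerCategory.OTHERS),    # the bound itself fails
        (dict(homro=-1.0), MarkerCategory.OTHERS),
        (dict(fld=None, hetso=None, homro=None, n_genotypes=1),
         MarkerCategory.MONO_HIGH_RESOLUTION),
    ])
    def test_examples(self, kw, expected):
        assert categorize(self.calls(), self.metrics(**kw), THR, 3) is expected

    def test_call_rate_is_checked_first(self):
        m = self.metrics(call_rate=0.9, hetso=-0.5, fld=1.0)
        assert categorize(self.calls(), m, THR, 3) is MarkerCategory.CALL_RATE_BELOW_THRESHOLD

    def test_call_rate_boundary(self):
        # 1200 of 1230 called -> 0.9756 >= 0.97 passes
        m = self.metrics(call_rate=1200 / 1230)
        assert categorize(self.calls(), m, THR, 3) is MarkerCategory.POLY_HIGH_RESOLUTION

    def test_collision_rejected_as_others(self):
        assert categorize(self.calls(collision=True), self.metrics(), THR, 3) \
            is MarkerCategory.OTHERS

    def test_every_marker_gets_exactly_one_category(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = self.metrics(
                call_rate=rng.uniform(0.9, 1.0),
                fld=rng.choice([None, rng.uniform(0, 10)]),
                hetso=rng.choice([None, rng.uniform(-1, 1)]),
                homro=rng.choice([None, rng.uniform(-2, 2)]),
                n_genotypes=int(rng.integers(1, 5)))
            assert categorize(self.calls(), m, THR, 3) in MarkerCategory

    def test_loosening_thresholds_never_rejects_accepted(self):
        rng = np.random.default_rng(3)
        loose = QCThresholds(cr_min=0.9, fld_min=2.0,
                             homro_min_by_k={1: 0.3, 2: 0.0, 3: 0.0, 4: -1.2})
        for _ in range(200):
            m = self.metrics(
                call_rate=rng.uniform(0.9, 1.0),
                fld=rng.uniform(0, 10),
                hetso=rng.uniform(-0.2, 1),
                homro=rng.uniform(-2, 2),
                n_genotypes=int(rng.integers(1, 5)))
            strict_cat = categorize(self.calls(), m, THR, 3)
            loose_cat = categorize(self.calls(), m, loose, 3)
            if strict_cat.accepted:
                assert loose_cat.accepted
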