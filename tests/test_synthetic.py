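"""Synthetic cohort generator: calibration, lesion geometry, modality links,
planted effects, and determinism."""

import numpy as np
import pytest
from scipy import stats

import lesionpls as lp
from lesionpls.synthetic import MODALITY_BASELINES, UNIQUE_CHANNELS


@pytest.fixture(scope="module")
def big_behaviour():
    """n=5000 draw at default calibration, fixed seed."""
    spec = lp.CohortSpec(seed=1)
    behaviour, severity = lp.generate_behaviour(spec, n=5000, rng=np.random.default_rng(1))
    return behaviour, severity


class TestAqScore:
    def test_printed_subtest_means_give_printed_aq_mean(self):
        assert lp.aq_score(11.4, 5.4, 5.2, 7.7) == pytest.approx(59.4)

    def test_extremes(self):
        assert lp.aq_score(0, 0, 0, 0) == 0.0
        assert lp.aq_score(20, 10, 10, 10) == 100.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="naming"):
            lp.aq_score(5.0, 10.5, 5.0, 5.0)


class TestBehaviourCalibration:
    def test_pairwise_correlations_match_targets(self, big_behaviour):
        scores, _ = big_behaviour[0].scores, big_behaviour[1]
        R = np.corrcoef(scores.T)
        targets = np.asarray(lp.CohortSpec().subtest_correlations)
        for i in range(4):
            for j in range(i + 1, 4):
                assert R[i, j] == pytest.approx(targets[i, j], abs=0.03)

    def test_means_and_sds_match_targets(self, big_behaviour):
        scores = big_behaviour[0].scores
        spec = lp.CohortSpec()
        for j in range(4):
            assert scores[:, j].mean() == pytest.approx(spec.subtest_means[j], abs=0.25)
            assert scores[:, j].std(ddof=1) == pytest.approx(spec.subtest_sds[j], rel=0.06)

    def test_identity_correlation_target_gives_independence(self):
        eye = tuple(tuple(float(i == j) for j in range(4)) for i in range(4))
        spec = lp.CohortSpec(subtest_correlations=eye, seed=2)
        behaviour, _ = lp.generate_behaviour(spec, n=5000, rng=np.random.default_rng(2))
        R = np.corrcoef(behaviour.scores.T)
        off = R[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_emergent_aq_consistency(self, big_behaviour):
        """AQ statistics are not calibration targets; they must emerge from
        the printed subtest covariance structure."""
        s = big_behaviour[0].scores
        aq = lp.aq_score(s[:, 0], s[:, 1], s[:, 2], s[:, 3])
        assert aq.std(ddof=1) == pytest.approx(23.0, abs=1.0)
        assert np.corrcoef(s[:, 0], aq)[0, 1] == pytest.approx(0.96, abs=0.03)

    def test_scores_respect_bounds(self, big_behaviour):
        scores = big_behaviour[0].scores
        maxima = lp.CohortSpec().maxima
        assert np.all(scores >= 0) and np.all(scores <= maxima)

    def test_severity_is_probability_scale(self, big_behaviour):
        sev = big_behaviour[1]
        assert np.all((sev >= 0) & (sev <= 1))
        # worse (higher) severity goes with lower scores
        assert np.corrcoef(sev, big_behaviour[0].scores.sum(axis=1))[0, 1] < -0.4


class TestLesions:
    def test_zero_severity_zero_noise_gives_empty_lesion(self):
        spec = lp.small_cohort_spec(seed=0)
        spec.noise_sd["lesion"] = 0.0
        rng = np.random.default_rng(0)
        lesion = lp.generate_lesions(spec, np.zeros(5), rng)
        assert np.all(lesion.values == 0.0)

    def test_full_severity_saturates_territory(self):
        spec = lp.small_cohort_spec(seed=0)
        rng = np.random.default_rng(0)
        lesion = lp.generate_lesions(spec, np.ones(5), rng)
        terr = list(spec.territory)
        assert np.all(lesion.values[:, terr] >= 90.0)

    def test_damage_tracks_severity_across_cohort(self):
        spec = lp.small_cohort_spec(seed=3)
        rng = np.random.default_rng(3)
        sev = rng.uniform(0, 1, 500)
        lesion = lp.generate_lesions(spec, sev, rng)
        mean_territory = lesion.values[:, list(spec.territory)].mean(axis=1)
        assert np.corrcoef(mean_territory, sev)[0, 1] > 0.7

    def test_adjacent_territory_regions_positively_correlated(self):
        spec = lp.small_cohort_spec(seed=4)
        rng = np.random.default_rng(4)
        sev = rng.uniform(0, 1, 500)
        D = lp.generate_lesions(spec, sev, rng).values
        terr = list(spec.territory)
        rs = [np.corrcoef(D[:, a], D[:, b])[0, 1] for a, b in zip(terr[:-1], terr[1:])]
        assert np.mean(rs) > 0.3

    def test_damage_bounded(self):
        spec = lp.small_cohort_spec(seed=5)
        rng = np.random.default_rng(5)
        D = lp.generate_lesions(spec, rng.uniform(0, 1, 50), rng).values
        assert np.all((D >= 0) & (D <= 100))


class TestDerivedModalities:
    def test_zero_damage_zero_noise_recovers_baselines(self):
        spec = lp.small_cohort_spec(seed=0, noise_sd={m: 0.0 for m in lp.dataset.ALL_MODALITIES})
        rng = np.random.default_rng(0)
        lesion = lp.generate_lesions(spec, np.zeros(4), rng)
        mods = lp.derive_modalities(spec, lesion, np.zeros(4), rng)
        for mod, (base, _) in MODALITY_BASELINES.items():
            assert np.allclose(mods[mod].values, base), mod
        assert np.all(mods["i3mT1"].values == 0.0)

    def test_fully_damaged_endpoint_attenuates_edges(self):
        spec = lp.small_cohort_spec(n_subjects=2, seed=0, noise_sd={m: 0.0 for m in lp.dataset.ALL_MODALITIES})
        rng = np.random.default_rng(0)
        lesion_full = lp.generate_lesions(spec, np.array([0.0, 1.0]), rng)
        mods = lp.derive_modalities(spec, lesion_full, np.array([0.0, 1.0]), rng)
        sc = mods["sc"].values
        terr0 = spec.territory[0]
        labels = mods["sc"].feature_labels
        names = spec.regions.names
        touched = [k for k, lab in enumerate(labels) if names[terr0] in lab.split("|")]
        healthy = sc[0, touched]
        lesioned = sc[1, touched]
        assert np.all(lesioned <= 0.1 * healthy + 1e-9)

    def test_damage_sign_links_md_up_fa_down(self):
        spec = lp.small_cohort_spec(n_subjects=500, seed=6)
        cohort = lp.generate_cohort(spec)
        D = cohort.modalities["lesion"].values
        terr = [r for r in spec.territory if r not in spec.shared_regions]
        for r in terr[:10]:
            d = D[:, r]
            if d.std() == 0:
                continue
            assert np.corrcoef(d, cohort.modalities["md"].values[:, r])[0, 1] > 0
            assert np.corrcoef(d, cohort.modalities["fa"].values[:, r])[0, 1] < 0

    def test_all_outputs_finite_and_in_range(self, small_cohort):
        for mod, mfm in small_cohort.modalities.items():
            assert np.isfinite(mfm.values).all(), mod
        assert np.all((small_cohort.modalities["i3mT1"].values >= 0)
                      & (small_cohort.modalities["i3mT1"].values <= 1))
        assert np.all(np.abs(small_cohort.modalities["fc"].values) <= 1)
        assert np.all(small_cohort.modalities["sc"].values >= 0)


class TestPlantedEffects:
    def test_zero_unique_effect_leaves_no_residual_association(self):
        spec = lp.small_cohort_spec(
            n_subjects=400, seed=7,
            unique_effects={s: 0.0 for s in lp.SUBTESTS},
        )
        cohort = lp.generate_cohort(spec)
        r = spec.unique_regions["auditory_comprehension"][0]
        md = cohort.modalities["md"].values[:, r]
        ac = cohort.behaviour.column("auditory_comprehension")
        # channel deviations are still injected; scores must not follow them
        resid = ac - np.polyval(np.polyfit(cohort.severity, ac, 1), cohort.severity)
        assert abs(np.corrcoef(md, resid)[0, 1]) < 0.12

    def test_unique_effect_targets_its_own_subtest(self):
        spec = lp.small_cohort_spec(n_subjects=500, seed=8)
        cohort = lp.generate_cohort(spec)
        r = spec.unique_regions["auditory_comprehension"][0]
        md = cohort.modalities["md"].values[:, r]
        sev = cohort.severity
        partials = {}
        for s in lp.SUBTESTS:
            y = cohort.behaviour.column(s)
            ry = y - np.polyval(np.polyfit(sev, y, 1), sev)
            rx = md - np.polyval(np.polyfit(sev, md, 1), sev)
            partials[s] = abs(np.corrcoef(rx, ry)[0, 1])
        assert partials["auditory_comprehension"] == max(partials.values())

    def test_overlapping_shared_and_unique_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            lp.small_cohort_spec(unique_regions={"naming": (9,)})

    def test_deviation_shared_across_injected_channels(self):
        spec = lp.small_cohort_spec(n_subjects=400, seed=9)
        cohort = lp.generate_cohort(spec)
        r = spec.unique_regions["auditory_comprehension"][0]
        md = cohort.modalities["md"].values[:, r]
        fa = cohort.modalities["fa"].values[:, r]
        # MD rises and FA falls with the same integrity deviation
        assert np.corrcoef(md, fa)[0, 1] < -0.5
        assert set(UNIQUE_CHANNELS) >= {"md", "fa"}


class TestDeterminism:
    def test_identical_seed_reproduces_cohort_bitwise(self):
        a = lp.generate_cohort(lp.small_cohort_spec(seed=42))
        b = lp.generate_cohort(lp.small_cohort_spec(seed=42))
        assert np.array_equal(a.behaviour.scores, b.behaviour.scores)
        for mod in a.modalities:
            assert np.array_equal(a.modalities[mod].values, b.modalities[mod].values), mod
        assert a.ground_truth == b.ground_truth

    def test_different_seeds_differ(self):
        a = lp.generate_cohort(lp.small_cohort_spec(seed=1))
        b = lp.generate_cohort(lp.small_cohort_spec(seed=2))
        assert not np.array_equal(a.behaviour.scores, b.behaviour.scores)


@pytest.mark.parametrize("seed", range(6))
def test_random_specs_respect_type_invariants(seed):
    r = np.random.default_rng(seed)
    spec = lp.small_cohort_spec(
        n_subjects=int(r.integers(8, 30)),
        seed=seed,
        severity_noise=float(r.uniform(0.2, 2.0)),
        stray_lesion_rate=float(r.uniform(0.0, 0.05)),
    )
    cohort = lp.generate_cohort(spec)
    assert np.all((cohort.behaviour.scores >= 0) & (cohort.behaviour.scores <= spec.maxima))
    lesion = cohort.modalities["lesion"].values
    assert np.all((lesion >= 0) & (lesion <= 100))
    for mfm in cohort.modalities.values():
        assert np.isfinite(mfm.values).all()
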