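import numpy as np
import pytest

from methdeg.io import CLASS_ORDER
from methdeg.synthdata import (
    CohortConfig,
    generate_binary_cohort,
    generate_multiclass_cohort,
)


class TestBinaryCohort:
    def test_zero_effect_means_indistinguishable(self):
        cfg = CohortConfig(n_samples_per_class=50, n_cpgs=100,
                           n_informative_per_class=10, effect_delta=0.0, seed=1)
        co = generate_binary_cohort(cfg)
        y = np.asarray(co.labels.labels)
        planted = [co.beta.cpg_ids.index(c) for c in co.truth[1]]
        diff = (co.beta.values[y == 1][:, planted].mean(axis=0)
                - co.beta.values[y == 0][:, planted].mean(axis=0))
        # Monte-Carlo noise only: s=50 gives sd ~0.07 per probe, n=50/class
        assert np.abs(diff).max() < 0.06

    def test_planted_effect_size(self):
        # sample-mean oracle: class-mean difference at each planted probe
        cfg = CohortConfig(n_samples_per_class=200, n_cpgs=500,
                           n_informative_per_class=25, effect_delta=0.3,
                           precision=50.0, background_mean_range=(0.35, 0.65),
                           seed=7)
        co = generate_binary_cohort(cfg)
        y = np.asarray(co.labels.labels)
        planted = [co.beta.cpg_ids.index(c) for c in co.truth[1]]
        diff = (co.beta.values[y == 1][:, planted].mean(axis=0)
                - co.beta.values[y == 0][:, planted].mean(axis=0))
        assert np.all(np.abs(np.abs(diff) - 0.3) < 0.05)

    def test_determinism(self):
        cfg = CohortConfig(n_samples_per_class=30, n_cpgs=50, seed=9)
        a = generate_binary_cohort(cfg)
        b = generate_binary_cohort(cfg)
        np.testing.assert_array_equal(a.beta.values, b.beta.values)
        assert a.truth == b.truth

    def test_values_in_unit_interval(self, binary_cohort):
        assert binary_cohort.beta.values.min() >= 0.0
        assert binary_cohort.beta.values.max() <= 1.0

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            generate_binary_cohort(CohortConfig(n_samples_per_class=0))
        with pytest.raises(ValueError):
            generate_binary_cohort(CohortConfig(effect_delta=1.5))
        with pytest.raises(ValueError):
            generate_binary_cohort(CohortConfig(precision=-1))
        with pytest.raises(ValueError):
            generate_binary_cohort(
                CohortConfig(n_cpgs=10, n_informative_per_class=20)
            )


class TestMulticlassCohort:
    def test_configured_counts(self):
        counts = dict(zip(CLASS_ORDER, (409, 386, 367, 381)))
        cfg = CohortConfig(n_samples_per_class=counts, n_cpgs=50,
                           n_informative_per_class=4, seed=2)
        co = generate_multiclass_cohort(cfg)
        labels = co.labels.labels
        for cls, n in counts.items():
            assert labels.count(cls) == n

    def test_bimodal_healthy_ages(self):
        cfg = CohortConfig(
            n_samples_per_class={"neurodegenerative": 10, "bone_degenerative": 10,
                                 "breast_cancer": 10, "healthy": 400},
            n_cpgs=60, n_informative_per_class=4,
            healthy_age_means=(33.74, 62.38), healthy_age_sd=5.0, seed=3,
        )
        co = generate_multiclass_cohort(cfg)
        ages = np.asarray(list(co.ages.values()))
        assert len(ages) == 400
        mid = (33.74 + 62.38) / 2
        # mixture-component oracle: split at the midpoint, compare means
        assert abs(ages[ages < mid].mean() - 33.74) < 2.0
        assert abs(ages[ages >= mid].mean() - 62.38) < 2.0

    def test_subtype_counts(self):
        cfg = CohortConfig(n_samples_per_class=40, n_cpgs=200,
                           n_informative_per_class=8,
                           n_subtypes_per_class={"breast_cancer": 4}, seed=4)
        co = generate_multiclass_cohort(cfg)
        bc = [s for s, l in zip(co.labels.sample_ids, co.labels.labels)
              if l == "breast_cancer"]
        assert len({co.subtype_of[s] for s in bc}) == 4

    def test_truth_disjoint_across_classes(self, multiclass_cohort):
        seen = set()
        for cls, cpgs in multiclass_cohort.truth.items():
            assert not (seen & set(cpgs))
            seen |= set(cpgs)

    def test_ages_only_for_healthy(self, multiclass_cohort):
        healthy = {s for s, l in zip(multiclass_cohort.labels.sample_ids,
                                     multiclass_cohort.labels.labels)
                   if l == "healthy"}
        assert set(multiclass_cohort.ages) == healthy

    def test_determinism(self):
        cfg = CohortConfig(n_samples_per_class=20, n_cpgs=40,
                           n_informative_per_class=3, seed=6)
        a = generate_multiclass_cohort(cfg)
        b = generate_multiclass_cohort(cfg)
        np.testing.assert_array_equal(a.beta.values, b.beta.values)
        assert a.ages == b.ages
        assert a.subtype_of == b.subtype_of


class TestChanceLevelWithoutSignal:
    def test_null_cohort_classifier_at_chance(self):
        # with delta=0 a classifier cannot beat chance in expectation
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.model_selection import cross_val_score

        cfg = CohortConfig(n_samples_per_class=60, n_cpgs=80,
                           n_informative_per_class=10, effect_delta=0.0, seed=21)
        co = generate_binary_cohort(cfg)
        y = np.asarray(co.labels.labels)
        clf = RandomForestClassifier(n_estimators=100, random_state=0, n_jobs=1)
        acc = cross_val_score(clf, co.beta.values, y, cv=5).mean()
        sigma = np.sqrt(0.25 / len(y))
        assert abs(acc - 0.5) < 3 * sigma + 0.05


def test_write_cohort_files(tmp_path, multiclass_cohort):
    paths = multiclass_cohort.write(tmp_path)
    assert paths["beta"].exists()
    assert paths["truth"].read_text().startswith("cpg_id\tclass\n")
    assert paths["ages"].exists()
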