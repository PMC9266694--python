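import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from sidfuse.corpus import ValidationError
from sidfuse.ensemble import (
    EnsembleSpec,
    FusionEnsembleClassifier,
    build_meta_features,
    enumerate_studied_feature_sets,
    split_blocks,
)
from sidfuse.features.base import FeatureBlock
from sidfuse.selection import parse_recipe
from sidfuse.zoo import ModelSpec, make_folds


@pytest.fixture(scope="module")
def labels(small_corpus):
    return small_corpus.labels()


@pytest.fixture(scope="module")
def two_set_spec():
    return EnsembleSpec(
        feature_sets=(parse_recipe("BSC+RFS"), parse_recipe("WEC")),
        base_models=(ModelSpec("Log-l2", seed=0), ModelSpec("Log-l2", seed=0)),
        seed=0,
    )


class TestEnsembleSpec:
    def test_coverage_rule_rejects_missing_family(self):
        with pytest.raises(ValidationError, match="WEC"):
            EnsembleSpec(feature_sets=(parse_recipe("BSC"), parse_recipe("RFS")))

    def test_at_least_two_feature_sets(self):
        with pytest.raises(ValidationError, match="two feature sets"):
            EnsembleSpec(feature_sets=(parse_recipe("BSC+RFS+WEC"),))

    def test_base_models_must_align(self):
        with pytest.raises(ValidationError):
            EnsembleSpec(
                feature_sets=(parse_recipe("BSC+RFS"), parse_recipe("WEC")),
                base_models=(ModelSpec("NB"),),
            )


class TestMetaFeatures:
    def test_shape_and_probability_range(self, two_set_spec, small_blocks, labels):
        meta = build_meta_features(two_set_spec, small_blocks, labels)
        assert meta.shape == (len(labels), 2)
        assert np.all((meta >= 0) & (meta <= 1))

    def test_out_of_fold_rows_do_not_depend_on_their_own_fold_labels(
        self, two_set_spec, small_blocks, labels
    ):
        """Flipping one fold's labels must leave that fold's meta-feature rows
        unchanged — they are predicted by models that never saw the fold."""
        splits = make_folds(labels, 5, seed=0)
        base = build_meta_features(two_set_spec, small_blocks, labels, splits=splits)
        fold_train, fold_test = splits[2]
        flipped = labels.copy()
        flipped[fold_test] = 1 - flipped[fold_test]
        altered = build_meta_features(two_set_spec, small_blocks, flipped, splits=splits)
        assert np.allclose(base[fold_test], altered[fold_test])
        other = np.setdiff1d(np.arange(len(labels)), fold_test)
        assert not np.allclose(base[other], altered[other])

    def test_deterministic_given_seed(self, two_set_spec, small_blocks, labels):
        a = build_meta_features(two_set_spec, small_blocks, labels)
        b = build_meta_features(two_set_spec, small_blocks, labels)
        assert np.array_equal(a, b)

    def test_unchosen_spec_is_rejected(self, small_blocks, labels):
        spec = EnsembleSpec(feature_sets=(parse_recipe("BSC+RFS"), parse_recipe("WEC")))
        with pytest.raises(ValidationError, match="base models"):
            build_meta_features(spec, small_blocks, labels)


class TestFusionClassifier:
    def test_fit_predict_contract(self, small_blocks, labels):
        clf = FusionEnsembleClassifier(
            feature_sets=("BSC+RFS", "WEC"),
            base_models=("Log-l2", "NB"),
            seed=0,
        )
        clf.fit(small_blocks, labels)
        pred = clf.predict(small_blocks)
        proba = clf.predict_proba(small_blocks)
        assert set(np.unique(pred)) <= {0, 1}
        assert proba.shape == (len(labels), 2)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_accepts_single_tagged_feature_block(self, small_blocks, labels):
        combined = FeatureBlock.hstack([small_blocks[f] for f in ("BSC", "RFS", "WEC")])
        clf = FusionEnsembleClassifier(
            feature_sets=("BSC+RFS", "WEC"), base_models=("Log-l2", "Log-l2"), seed=0
        )
        clf.fit(combined, labels)
        assert split_blocks(combined).keys() == {"BSC", "RFS", "WEC"}
        assert clf.predict(combined).shape == (len(labels),)

    def test_identical_sets_and_bases_agree_with_base_ranking(self, small_blocks, labels):
        """With two identical feature sets and identical base models the
        fused score is a monotone recalibration of the base probability, so
        the ranking (AUC) is unchanged."""
        clf = FusionEnsembleClassifier(
            feature_sets=("BSC+RFS+WEC", "BSC+RFS+WEC"),
            base_models=("Log-l2", "Log-l2"),
            seed=0,
        )
        clf.fit(small_blocks, labels)
        base_proba = clf._meta_matrix(small_blocks)[:, 0]
        fused_proba = clf.predict_proba(small_blocks)[:, 1]
        assert roc_auc_score(labels, fused_proba) == pytest.approx(
            roc_auc_score(labels, base_proba)
        )

    def test_unfit_predict_is_an_error(self, small_blocks):
        with pytest.raises(ValidationError):
            FusionEnsembleClassifier().predict(small_blocks)

    def test_sklearn_get_set_params(self):
        clf = FusionEnsembleClassifier(seed=3)
        assert clf.get_params()["seed"] == 3
        clf.set_params(folds=3)
        assert clf.folds == 3


class TestPaperFeatureSets:
    def test_eleven_configurations(self):
        specs = enumerate_studied_feature_sets()
        assert len(specs) == 11

    def test_headline_configuration_present(self):
        names = {tuple(r.name for r in s.feature_sets) for s in enumerate_studied_feature_sets()}
        assert ("(BSC+RFS)-fs", "WEC-fs") in names

    def test_every_configuration_covers_all_families(self):
        for spec in enumerate_studied_feature_sets():
            covered = {b for r in spec.feature_sets for b in r.blocks}
            assert covered == {"BSC", "RFS", "WEC"}
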