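import numpy as np
import pytest

from sidfuse.corpus import ValidationError
from sidfuse.features.base import FeatureBlock
from sidfuse.selection import (
    SelectionConfig,
    TreeImportanceSelector,
    apply_recipe,
    fit_importance_selector,
    parse_recipe,
)


def stump_impurity_decrease(x, y):
    """Best single-split gini decrease of one column — the brute-force oracle
    for what a depth-1 tree can see."""
    def gini(labels):
        if len(labels) == 0:
            return 0.0
        p = labels.mean()
        return 2 * p * (1 - p)

    n = len(y)
    base = gini(y)
    best = 0.0
    for t in np.unique(x):
        left, right = y[x <= t], y[x > t]
        dec = base - (len(left) / n) * gini(left) - (len(right) / n) * gini(right)
        best = max(best, dec)
    return best


def make_block(X, prefix="f", family="BSC"):
    return FeatureBlock(X, [f"{prefix}{i}" for i in range(X.shape[1])],
                        [family] * X.shape[1], [f"r{i}" for i in range(X.shape[0])])


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(1)
    n = 200
    y = rng.integers(0, 2, n)
    noise = rng.normal(size=(n, 50))
    X = np.column_stack([y.astype(float), noise])  # column 0 separates perfectly
    return X, y


def test_perfect_column_dominates_stump_oracle_and_ranking(separable):
    X, y = separable
    decs = [stump_impurity_decrease(X[:, j], y) for j in range(X.shape[1])]
    assert np.argmax(decs) == 0  # oracle: its impurity decrease dominates
    sel = TreeImportanceSelector(n_trees=100, seed=0).fit(X, y)
    assert sel.ranking_[0] == 0


def test_importances_normalized_and_ordering_non_increasing(separable):
    X, y = separable
    sel = TreeImportanceSelector(n_trees=100, seed=0).fit(X, y)
    assert sel.importances_.sum() == pytest.approx(1.0)
    ranked = sel.importances_[sel.ranking_]
    assert np.all(np.diff(ranked) <= 1e-12)


def test_top_k_equal_to_width_is_identity(separable):
    X, y = separable
    sel = TreeImportanceSelector(n_trees=50, top_k=X.shape[1], seed=0).fit(X, y)
    assert np.array_equal(sel.kept_idx_, np.arange(X.shape[1]))
    assert np.array_equal(sel.transform(X), X)


def test_top_k_selection_is_idempotent(separable):
    X, y = separable
    first = TreeImportanceSelector(n_trees=100, top_k=5, seed=0).fit(X, y)
    X1 = first.transform(X)
    second = TreeImportanceSelector(n_trees=100, top_k=5, seed=0).fit(X1, y)
    assert np.array_equal(second.transform(X1), X1)


def test_single_class_labels_rejected(separable):
    X, _ = separable
    with pytest.raises(ValidationError):
        TreeImportanceSelector(seed=0).fit(X, np.zeros(len(X)))


def test_selector_on_feature_block_preserves_metadata(separable):
    X, y = separable
    block = make_block(X)
    sel = fit_importance_selector(block, y, SelectionConfig(n_trees=50, top_k=3, seed=0))
    out = sel.transform(block)
    assert out.n_features == 3
    assert out.row_ids == block.row_ids
    assert set(out.column_names) <= set(block.column_names)


class TestRecipeParsing:
    @pytest.mark.parametrize(
        "text,blocks,mode",
        [
            ("BSC+RFS", ("BSC", "RFS"), "direct"),
            ("BSC+RFS+WEC", ("BSC", "RFS", "WEC"), "direct"),
            ("(BSC+RFS)-fs", ("BSC", "RFS"), "combine-then-select"),
            ("(BSC-fs)+(WEC-fs)", ("BSC", "WEC"), "select-then-combine"),
            ("WEC-fs", ("WEC",), "combine-then-select"),
            ("BSC", ("BSC",), "direct"),
        ],
    )
    def test_fs_notation_round_trip(self, text, blocks, mode):
        recipe = parse_recipe(text)
        assert recipe.blocks == blocks
        assert recipe.mode == mode
        assert parse_recipe(recipe.name).blocks == blocks

    def test_invalid_strings_rejected(self):
        for bad in ("", "BSC+", "(BSC+RFS", "XYZ+RFS", "BSC+BSC"):
            with pytest.raises(ValidationError):
                parse_recipe(bad)


@pytest.fixture(scope="module")
def blocks_and_labels():
    rng = np.random.default_rng(2)
    n = 150
    y = rng.integers(0, 2, n)
    bsc = make_block(rng.normal(size=(n, 8)), "b", "BSC")
    rfs = make_block(np.column_stack([y + rng.normal(0, 0.3, n),
                                      rng.normal(size=(n, 5))]), "r", "RFS")
    return {"BSC": bsc, "RFS": rfs}, y


class TestApplyRecipe:

    def test_direct_width_is_sum_of_block_widths(self, blocks_and_labels):
        blocks, y = blocks_and_labels
        out = apply_recipe(parse_recipe("BSC+RFS"), blocks, y)
        assert out.n_features == 8 + 6
        assert out.column_block == ["BSC"] * 8 + ["RFS"] * 6

    def test_select_then_combine_width_is_sum_of_per_block_top_k(self, blocks_and_labels):
        blocks, y = blocks_and_labels
        sel = SelectionConfig(n_trees=50, top_k=4, seed=0)
        out = apply_recipe(parse_recipe("(BSC-fs)+(RFS-fs)", sel), blocks, y)
        assert out.n_features == min(4, 8) + min(4, 6)

    def test_selection_requires_labels(self, blocks_and_labels):
        blocks, _ = blocks_and_labels
        with pytest.raises(ValidationError):
            apply_recipe(parse_recipe("(BSC+RFS)-fs"), blocks)


def test_xor_split_across_blocks_distinguishes_the_two_selection_modes():
    """A pair of columns that is informative only jointly (XOR) is kept by
    combine-then-select but discarded by per-block selection, which prefers
    weak marginal correlates — verified against the stump oracle."""
    rng = np.random.default_rng(0)
    n = 300
    x1 = rng.integers(0, 2, n)
    x2 = rng.integers(0, 2, n)
    y = x1 ^ x2
    w1 = np.where(rng.random(n) < 0.4, 1 - y, y)  # weak noisy correlates
    w2 = np.where(rng.random(n) < 0.4, 1 - y, y)
    blocks = {
        "BSC": make_block(np.column_stack([x1, w1]).astype(float), "a", "BSC"),
        "RFS": make_block(np.column_stack([x2, w2]).astype(float), "c", "RFS"),
    }
    # stump oracle: alone, each XOR half is useless while the weak columns help
    assert stump_impurity_decrease(x1.astype(float), y) < 0.01
    assert stump_impurity_decrease(w1.astype(float), y) > 0.01

    per_block = SelectionConfig(n_trees=200, top_k=1, seed=0)
    joint = SelectionConfig(n_trees=200, top_k=2, seed=0)
    stc = apply_recipe(parse_recipe("(BSC-fs)+(RFS-fs)", per_block), blocks, y)
    cts = apply_recipe(parse_recipe("(BSC+RFS)-fs", joint), blocks, y)
    assert set(stc.column_names) != set(cts.column_names)
    assert set(cts.column_names) == {"a0", "c0"}  # the XOR pair, kept jointly
    assert set(stc.column_names) == {"a1", "c1"}  # the weak marginals
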