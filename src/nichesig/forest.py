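"""Bagged decision-tree ensemble with out-of-bag bookkeeping.

The habitat classifier needs three things a stock ensemble wrapper does not
expose together: per-strain out-of-bag (OOB) class-vote proportions, OOB
permutation variable importance (mean decrease in OOB accuracy, the classic
randomForest importance), and full reproducibility from a single seed.  With
fewer than a dozen training strains the trees are tiny, so an explicit
bagging loop over scikit-learn decision trees is both transparent and fast.

Classes are encoded as integers 0/1 by the caller; vote proportions are
reported in that order.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import ParameterError

_MAX_SEED = 2**31 - 1


class BaggedTreeEnsemble:
    """Bootstrap-aggregated decision trees over a fixed training matrix.

    Parameters
    ----------
    n_trees :
        Number of bootstrap trees.
    mtry :
        Number of candidate features examined at each split.
    seed :
        Seed for the bootstrap draws, per-tree split randomness and the
        importance permutations.
    """

    def __init__(self, n_trees: int, mtry: int, seed: int = 0):
        if n_trees < 1:
            raise ParameterError("n_trees must be >= 1")
        if mtry < 1:
            raise ParameterError("mtry must be >= 1")
        self.n_trees = int(n_trees)
        self.mtry = int(mtry)
        self.seed = int(seed)
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_mask_: np.ndarray | None = None  # (n_trees, n_samples)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedTreeEnsemble":
        X = np.ascontiguousarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        n, p = X.shape
        if self.mtry > p:
            raise ParameterError(f"mtry={self.mtry} exceeds feature count {p}")
        if len(np.unique(y)) < 2:
            raise ParameterError("training labels contain a single class")

        rng = np.random.default_rng(self.seed)
        tree_seeds = rng.integers(0, _MAX_SEED, size=self.n_trees)
        perm_seeds = rng.integers(0, _MAX_SEED, size=self.n_trees)

        self._X = X
        self._y = y
        self._perm_seeds = perm_seeds
        self.trees_ = []
        oob_mask = np.ones((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            inbag = rng.integers(0, n, size=n)
            oob_mask[t, inbag] = False
            tree = DecisionTreeClassifier(
                max_features=self.mtry, random_state=int(tree_seeds[t])
            )
            tree.fit(X[inbag], y[inbag])
            self.trees_.append(tree)
        self.oob_mask_ = oob_mask
        return self

    # ------------------------------------------------------------------ OOB

    def oob_vote_counts(self) -> np.ndarray:
        """(n_samples, 2) counts of OOB tree votes per class."""
        self._check_fitted()
        n = self._X.shape[0]
        counts = np.zeros((n, 2), dtype=np.int64)
        for t, tree in enumerate(self.trees_):
            oob = self.oob_mask_[t]
            if not oob.any():
                continue
            pred = tree.predict(self._X[oob])
            idx = np.flatnonzero(oob)
            counts[idx, 0] += pred == 0
            counts[idx, 1] += pred == 1
        return counts

    def oob_vote_proportions(self) -> np.ndarray:
        """(n_samples, 2) OOB vote proportions; rows sum to 1.

        A sample never out of bag (vanishingly rare for n_trees >= ~50)
        gets a 0.5/0.5 row so that downstream accounting never divides by
        zero; it can then never match its label under a strict majority.
        """
        counts = self.oob_vote_counts().astype(float)
        totals = counts.sum(axis=1, keepdims=True)
        props = np.full_like(counts, 0.5)
        np.divide(counts, totals, out=props, where=totals > 0)
        return props

    def oob_majority_calls(self, vote_threshold: float = 0.5) -> np.ndarray:
        """Class call per sample: 1 where the class-1 vote share exceeds the threshold."""
        props = self.oob_vote_proportions()
        return (props[:, 1] > vote_threshold).astype(np.int64)

    def oob_accuracy(self, vote_threshold: float = 0.5) -> float:
        self._check_fitted()
        calls = self.oob_majority_calls(vote_threshold)
        return float(np.mean(calls == self._y))

    # ----------------------------------------------------------- importance

    def permutation_importance(self) -> np.ndarray:
        """OOB permutation importance per feature (mean decrease in accuracy).

        For each tree, each feature used by that tree is permuted among the
        tree's OOB samples and the drop in that tree's OOB accuracy recorded;
        the importance of a feature is the average drop over all trees
        (trees not using the feature contribute zero).  Features never used
        by any tree have importance exactly 0; noise features that happen to
        help in-bag but mislead out-of-bag can come out negative.
        """
        self._check_fitted()
        p = self._X.shape[1]
        imp = np.zeros(p, dtype=float)
        for t, tree in enumerate(self.trees_):
            oob = self.oob_mask_[t]
            n_oob = int(oob.sum())
            if n_oob == 0:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base_acc = np.mean(tree.predict(Xo) == yo)
            features = np.unique(tree.tree_.feature)
            features = features[features >= 0]
            if features.size == 0:
                continue
            rng = np.random.default_rng(self._perm_seeds[t])
            Xp = Xo.copy()
            for f in features:
                saved = Xp[:, f].copy()
                Xp[:, f] = saved[rng.permutation(n_oob)]
                perm_acc = np.mean(tree.predict(Xp) == yo)
                Xp[:, f] = saved
                imp[f] += base_acc - perm_acc
        return imp / self.n_trees

    def impurity_importance(self) -> np.ndarray:
        """Mean decrease in impurity, averaged over trees."""
        self._check_fitted()
        p = self._X.shape[1]
        imp = np.zeros(p, dtype=float)
        for tree in self.trees_:
            imp += tree.feature_importances_
        return imp / self.n_trees

    # ------------------------------------------------------------- predict

    def predict_vote_proportions(self, X_new: np.ndarray) -> np.ndarray:
        """(n_new, 2) full-forest vote proportions for new samples."""
        self._check_fitted()
        X_new = np.ascontiguousarray(X_new, dtype=np.float64)
        counts = np.zeros((X_new.shape[0], 2), dtype=np.int64)
        for tree in self.trees_:
            pred = tree.predict(X_new)
            counts[:, 0] += pred == 0
            counts[:, 1] += pred == 1
        return counts / self.n_trees

    def _check_fitted(self) -> None:
        if not self.trees_:
            raise ParameterError("ensemble is not fitted")
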