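"""Microbiome-based TMAO-producer phenotype classifier.

Feature selection correlates log10-transformed OTU relative abundances
with the subject's log10 urine TMAO_MAX response and keeps the top-k OTUs
by absolute Pearson r (default k = 39).  A bagged decision-tree ensemble
(random forest) is then fitted to predict the low/high producer label;
accuracy is estimated by leave-one-out cross-validation, pooling the
out-of-fold vote fractions into a single ROC curve, and feature relevance
is ranked by mean decrease accuracy (out-of-bag permutation importance).

The classifier follows a statsmodels-style layout: build a
:class:`ProducerPhenotypeModel` from data, call :meth:`fit`, and read
estimates, cross-validated accuracy and diagnostics off the returned
:class:`ProducerPhenotypeResults` (``summary()`` prints the usual table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.tree import DecisionTreeClassifier

from .community import OtuTable, relative_abundance

__all__ = [
    "correlate_features",
    "select_top",
    "default_pseudocount",
    "VoteForest",
    "RocResult",
    "roc_from_scores",
    "loocv_scores",
    "ProducerPhenotypeModel",
    "ProducerPhenotypeResults",
    "DEFAULT_N_FEATURES",
    "DEFAULT_N_TREES",
]

#: Number of top-correlated OTUs kept for the classifier (top ~2.5% of 1637).
DEFAULT_N_FEATURES = 39
#: Ensemble size of the bagged decision-tree classifier.
DEFAULT_N_TREES = 500


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def default_pseudocount(rel_abund: pd.DataFrame) -> float:
    """Half the smallest non-zero relative abundance in the table.

    Used before the log10 transform so absent OTUs map to a finite value
    below every observed one, preserving rank order.
    """
    values = rel_abund.to_numpy()
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("relative abundance table is all zeros")
    return float(nonzero.min() / 2.0)


def correlate_features(
    table: OtuTable | pd.DataFrame,
    response: pd.Series | np.ndarray,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each OTU's log10 abundance with the response.

    Parameters
    ----------
    table
        Rarefied OTU table (or a relative-abundance DataFrame).
    response
        Per-sample response, conventionally log10 urine TMAO_MAX.
    pseudocount
        Added to relative abundances before log10; defaults to half the
        smallest non-zero relative abundance.

    Returns
    -------
    DataFrame with columns ``otu_id``, ``pearson_r`` and 1-based ``rank``
    by descending \\|r\\| (ties broken by OTU id).  Constant features get r = 0.
    """
    ra = relative_abundance(table) if isinstance(table, OtuTable) else table
    y = np.asarray(
        response.loc[ra.index] if isinstance(response, pd.Series) else response,
        dtype=float,
    )
    if ra.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate features")
    if y.shape[0] != ra.shape[0]:
        raise ValueError("response must be defined for every sample")
    if pseudocount is None:
        pseudocount = default_pseudocount(ra)
    x = np.log10(ra.to_numpy() + pseudocount)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.where((sx == 0) | (sy == 0), 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    ranking = pd.DataFrame({"otu_id": ra.columns.astype(str), "pearson_r": r})
    order = ranking.sort_values(
        ["pearson_r", "otu_id"],
        key=lambda s: -s.abs() if s.name == "pearson_r" else s,
        kind="mergesort",
    )
    ranking["rank"] = pd.Series(
        np.arange(1, len(ranking) + 1), index=order.index
    ).sort_index()
    return ranking


def select_top(ranking: pd.DataFrame, k: int = DEFAULT_N_FEATURES) -> list[str]:
    """The ``k`` OTU ids with largest \\|r\\| (deterministic under ties)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} available features")
    return ranking.sort_values("rank", kind="mergesort")["otu_id"].head(k).tolist()


# ---------------------------------------------------------------------------
# bagged decision-tree ensemble
# ---------------------------------------------------------------------------

class VoteForest:
    """Random forest as an explicit bagging loop over sklearn decision trees.

    Each tree is grown on a bootstrap sample (with replacement, same size as
    the training set) considering sqrt(m) features per split; predicted
    class probabilities are hard-vote fractions across trees.  Keeping the
    bootstrap indices makes out-of-bag scoring, and hence mean decrease
    accuracy, straightforward.
    """

    def __init__(self, n_trees: int = DEFAULT_N_TREES, seed: int = 0,
                 max_features: str | int = "sqrt") -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.max_features = max_features
        self.trees_: list[DecisionTreeClassifier] = []
        self.inbag_: list[np.ndarray] = []
        self.n_samples_: int = 0

    def fit(self, X: np.ndarray, y: np.ndarray) -> "VoteForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.n_samples_ = n
        self.trees_, self.inbag_ = [], []
        for _ in range(self.n_trees):
            for _attempt in range(100):
                inbag = rng.integers(0, n, size=n)
                if len(np.unique(y[inbag])) == 2:
                    break
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[inbag], y[inbag])
            self.trees_.append(tree)
            self.inbag_.append(inbag)
        return self

    def vote_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for the positive class, in [0, 1]."""
        if not self.trees_:
            raise ValueError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes / self.n_trees

    def oob_accuracy(self) -> float:
        """Out-of-bag accuracy of the majority vote (diagnostic)."""
        raise_if_unfitted(self)
        n = self.n_samples_
        votes = np.zeros(n)
        counts = np.zeros(n)
        for tree, inbag in zip(self.trees_, self.inbag_, strict=True):
            oob = np.setdiff1d(np.arange(n), inbag, assume_unique=False)
            if oob.size:
                votes[oob] += tree.predict(self._X[oob])
                counts[oob] += 1
        covered = counts > 0
        pred = (votes[covered] / counts[covered]) > 0.5
        return float((pred == self._y[covered].astype(bool)).mean())

    # kept by fit() callers that need OOB diagnostics
    def remember_training_data(self, X: np.ndarray, y: np.ndarray) -> None:
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)

    def mean_decrease_accuracy(self, X: np.ndarray, y: np.ndarray,
                               seed: int | None = None) -> np.ndarray:
        """Per-feature out-of-bag accuracy drop under within-feature permutation.

        For each tree, accuracy on its out-of-bag samples is compared with
        the accuracy after shuffling one feature column among those samples;
        drops are averaged over trees (Breiman's mean decrease accuracy).
        """
        raise_if_unfitted(self)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.seed + 101 if seed is None else seed)
        n, m = X.shape
        drops = np.zeros(m)
        used = 0
        for tree, inbag in zip(self.trees_, self.inbag_, strict=True):
            oob = np.setdiff1d(np.arange(n), inbag)
            if oob.size < 2:
                continue
            used += 1
            X_oob, y_oob = X[oob], y[oob]
            base = (tree.predict(X_oob) == y_oob).mean()
            for j in range(m):
                perm = rng.permutation(oob.size)
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                drops[j] += base - (tree.predict(X_perm) == y_oob).mean()
        if used == 0:
            raise ValueError("no tree has out-of-bag samples")
        return drops / used


def raise_if_unfitted(forest: VoteForest) -> None:
    if not forest.trees_:
        raise ValueError("forest is not fitted")


# ---------------------------------------------------------------------------
# ROC machinery
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """ROC curve summary: AUROC, Youden-optimal cutoff, optional bootstrap CI."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auroc: float
    optimal_cutoff: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    n_positive: int = 0
    n_negative: int = 0

    def as_dict(self) -> dict:
        d = {
            "auroc": round(self.auroc, 4),
            "optimal_cutoff": round(self.optimal_cutoff, 4),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }
        if self.ci_lower is not None:
            d["auroc_ci95"] = [round(self.ci_lower, 4), round(self.ci_upper, 4)]
        return d


def roc_from_scores(
    labels: np.ndarray,
    scores: np.ndarray,
    n_bootstrap: int = 0,
    seed: int | None = None,
) -> RocResult:
    """Build a ROC curve from scores, with the Youden-optimal cutoff.

    The optimal cutoff maximises sensitivity + specificity - 1.  When
    ``n_bootstrap`` > 0 a stratified bootstrap of the scores yields a
    percentile 95% CI for the AUROC.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auroc = float(_sk_auc(fpr, tpr))
    youden = tpr - fpr
    best = int(np.argmax(youden))
    ci_lo = ci_hi = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos, neg = s[y == 1], s[y == 0]
        reps = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            yb = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
            fb, tb, _ = _sk_roc_curve(yb, np.concatenate([bp, bn]))
            reps[b] = _sk_auc(fb, tb)
        ci_lo, ci_hi = (float(q) for q in np.quantile(reps, [0.025, 0.975]))
    return RocResult(
        thresholds=thr,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auroc=auroc,
        optimal_cutoff=float(thr[best]),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        n_positive=int((y == 1).sum()),
        n_negative=int((y == 0).sum()),
    )


def loocv_scores(
    X: np.ndarray, y: np.ndarray, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> np.ndarray:
    """Leave-one-out out-of-fold vote fractions.

    Each sample is scored by a forest trained on the other n-1 samples;
    the pooled scores define a single cross-validated ROC curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    scores = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        forest = VoteForest(n_trees=n_trees, seed=int(fold_seeds[i]))
        forest.fit(X[mask], y[mask])
        scores[i] = forest.vote_scores(X[i : i + 1])[0]
    return scores


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class ProducerPhenotypeModel:
    """Random-forest classifier of the low/high TMAO-producer phenotype.

    Parameters
    ----------
    features
        Samples x features matrix (relative abundances of the selected
        OTUs).
    labels
        Binary per-sample producer status (1 = high, 0 = low), aligned with
        ``features``.
    n_trees, seed
        Ensemble size and the seed for every stochastic step.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: pd.Series | np.ndarray,
        n_trees: int = DEFAULT_N_TREES,
        seed: int = 0,
    ) -> None:
        if isinstance(labels, pd.Series):
            labels = labels.loc[features.index]
        y = np.asarray(labels)
        if y.dtype.kind in "OU":
            y = (y == "high").astype(int)
        y = y.astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("labels contain a single class")
        if features.shape[0] != y.shape[0]:
            raise ValueError("features and labels are misaligned")
        self.features = features
        self.labels = y
        self.feature_ids = list(features.columns.astype(str))
        self.n_trees = int(n_trees)
        self.seed = int(seed)
        self.ranking_: pd.DataFrame | None = None

    @classmethod
    def from_otu_table(
        cls,
        table: OtuTable,
        response: pd.Series | np.ndarray,
        labels: pd.Series | np.ndarray,
        k: int = DEFAULT_N_FEATURES,
        pseudocount: float | None = None,
        n_trees: int = DEFAULT_N_TREES,
        seed: int = 0,
    ) -> "ProducerPhenotypeModel":
        """Correlation-ranked feature selection straight from an OTU table.

        ``response`` is the per-sample log10 urine TMAO_MAX used for the
        Pearson ranking; ``labels`` is the producer status to classify.
        ``k=None`` keeps every OTU (the all-features reference model).
        """
        ra = relative_abundance(table)
        if k is None:
            model = cls(ra, labels, n_trees=n_trees, seed=seed)
            return model
        ranking = correlate_features(table, response, pseudocount=pseudocount)
        chosen = select_top(ranking, k)
        model = cls(ra[chosen], labels, n_trees=n_trees, seed=seed)
        model.ranking_ = ranking
        return model

    def fit(self) -> "ProducerPhenotypeResults":
        """Fit the full-data forest and return the results object."""
        forest = VoteForest(n_trees=self.n_trees, seed=self.seed)
        X = self.features.to_numpy(dtype=float)
        forest.fit(X, self.labels)
        forest.remember_training_data(X, self.labels)
        return ProducerPhenotypeResults(self, forest)


class ProducerPhenotypeResults:
    """Fitted classifier with cross-validated accuracy and diagnostics."""

    def __init__(self, model: ProducerPhenotypeModel, forest: VoteForest) -> None:
        self.model = model
        self.forest = forest
        self._loocv_cache: dict[tuple, RocResult] = {}

    # -- scoring ---------------------------------------------------------
    def predict_scores(self, features: pd.DataFrame) -> np.ndarray:
        """Vote fractions for new samples on the training feature set.

        Features are aligned by id; taxa missing from the new matrix are
        imputed as absent (0).
        """
        overlap = [f for f in self.model.feature_ids if f in features.columns]
        if not overlap:
            raise ValueError("no overlapping features with the training set")
        aligned = features.reindex(columns=self.model.feature_ids, fill_value=0.0)
        return self.forest.vote_scores(aligned.to_numpy(dtype=float))

    def resubstitution_roc(self) -> RocResult:
        scores = self.forest.vote_scores(self.model.features.to_numpy(dtype=float))
        return roc_from_scores(self.model.labels, scores)

    def loocv_roc(
        self,
        n_trees: int | None = None,
        seed: int | None = None,
        n_bootstrap: int = 0,
    ) -> RocResult:
        """Single ROC from pooled leave-one-out out-of-fold scores."""
        n_trees = self.model.n_trees if n_trees is None else int(n_trees)
        seed = self.model.seed if seed is None else int(seed)
        key = (n_trees, seed, n_bootstrap)
        if key not in self._loocv_cache:
            scores = loocv_scores(
                self.model.features.to_numpy(dtype=float),
                self.model.labels,
                n_trees=n_trees,
                seed=seed,
            )
            self._loocv_cache[key] = roc_from_scores(
                self.model.labels, scores, n_bootstrap=n_bootstrap, seed=seed
            )
        return self._loocv_cache[key]

    def importance(self, seed: int | None = None) -> pd.DataFrame:
        """Features ranked by mean decrease accuracy (descending)."""
        mda = self.forest.mean_decrease_accuracy(
            self.model.features.to_numpy(dtype=float), self.model.labels, seed=seed
        )
        out = pd.DataFrame(
            {"feature": self.model.feature_ids, "mean_decrease_accuracy": mda}
        ).sort_values(
            ["mean_decrease_accuracy", "feature"],
            ascending=[False, True],
            kind="mergesort",
        )
        out["rank"] = np.arange(1, len(out) + 1)
        return out.reset_index(drop=True)

    def external_validate(
        self,
        features: pd.DataFrame,
        labels: pd.Series | np.ndarray,
        n_bootstrap: int = 0,
        seed: int | None = None,
    ) -> RocResult:
        """ROC of the fixed model on an external cohort (no refitting)."""
        if isinstance(labels, pd.Series):
            labels = labels.loc[features.index]
        y = np.asarray(labels)
        if y.dtype.kind in "OU":
            y = (y == "high").astype(int)
        scores = self.predict_scores(features)
        return roc_from_scores(y.astype(int), scores, n_bootstrap=n_bootstrap, seed=seed)

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table in the statsmodels tradition."""
        m = self.model
        resub = self.resubstitution_roc()
        lines = [
            "TMAO producer phenotype classifier (bagged decision trees)",
            "=" * 62,
            f"{'No. samples:':<28}{m.features.shape[0]:>10}",
            f"{'No. features:':<28}{m.features.shape[1]:>10}",
            f"{'No. trees:':<28}{m.n_trees:>10}",
            f"{'Positives (high producers):':<28}{int(m.labels.sum()):>10}",
            f"{'Negatives (low producers):':<28}{int((1 - m.labels).sum()):>10}",
            f"{'Resubstitution AUROC:':<28}{resub.auroc:>10.3f}",
        ]
        for key, roc in self._loocv_cache.items():
            lines.append(f"{'LOOCV AUROC:':<28}{roc.auroc:>10.3f}")
            lines.append(f"{'LOOCV optimal cutoff:':<28}{roc.optimal_cutoff:>10.3f}")
            break
        lines.append("=" * 62)
        return "\n".join(lines)
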