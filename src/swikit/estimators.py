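"""scikit-learn estimators wrapping the SWI scoring and training pipeline.

``SWIFeaturizer`` turns raw protein sequences into numeric solubility
features; ``SWISolubilityClassifier`` runs the full homology-aware
bootstrap/Nelder–Mead weight-training pipeline in ``fit`` and predicts
probability of solubility through a logistic calibration refitted on the
training data.  Both accept X as a list/array of residue strings, like
sklearn's text estimators accept raw documents.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .scales import ResidueScale, get_scale
from .scoring import (
    PUBLISHED_CALIBRATION,
    WINDOW_SIZE,
    global_flexibility,
    gravy,
    probability_of_solubility,
    swi,
)
from .seqio import SequenceRecord
from .training import (
    LabeledDataset,
    TrainingConfig,
    fit_logistic,
    greedy_cluster,
    train_swi,
)


def _as_strings(X) -> list[str]:
    seqs = [x.residues if isinstance(x, SequenceRecord) else str(x) for x in X]
    if not seqs:
        raise ValueError("X must contain at least one sequence")
    return seqs


def _as_scale(value: str | ResidueScale) -> ResidueScale:
    return get_scale(value) if isinstance(value, str) else value


class SWIFeaturizer(TransformerMixin, BaseEstimator):
    """Transform protein sequences into solubility feature columns.

    Columns: ``swi``, ``probability``, ``flexibility_window`` (NaN for
    sequences shorter than the 9-residue window), ``flexibility_mean`` and
    ``gravy``.

    Parameters
    ----------
    weights : str or ResidueScale, default="swi_final"
        Residue weights used for the SWI column.
    flexibility_scale : str or ResidueScale, default="vihinen1994"
        Normalized B-factors behind the flexibility columns.
    calibration : LogisticCalibration, default=published calibration
        Logistic link for the probability column.
    """

    def __init__(
        self,
        weights: str | ResidueScale = "swi_final",
        flexibility_scale: str | ResidueScale = "vihinen1994",
        calibration=PUBLISHED_CALIBRATION,
    ):
        self.weights = weights
        self.flexibility_scale = flexibility_scale
        self.calibration = calibration

    def fit(self, X=None, y=None):
        self.weights_ = _as_scale(self.weights)
        self.flexibility_scale_ = _as_scale(self.flexibility_scale)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        rows = []
        for seq in _as_strings(X):
            x = swi(seq, self.weights_)
            rows.append(
                [
                    x,
                    probability_of_solubility(x, self.calibration),
                    global_flexibility(seq, self.flexibility_scale_, "window")
                    if len(seq) >= WINDOW_SIZE
                    else math.nan,
                    global_flexibility(seq, self.flexibility_scale_, "mean"),
                    gravy(seq),
                ]
            )
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None):
        return np.array(
            ["swi", "probability", "flexibility_window", "flexibility_mean", "gravy"]
        )


class SWISolubilityClassifier(ClassifierMixin, BaseEstimator):
    """Solubility classifier trained by AUC-maximizing weight refinement.

    ``fit`` clusters the training sequences (unless cluster ids are
    supplied), builds homology-aware folds, and for every fold optimizes
    residue weights on class-balanced bootstrap resamples with Nelder–Mead;
    the averaged weights are then calibrated with a logistic link fitted to
    the training SWI scores.

    Parameters
    ----------
    initial_weights : str or ResidueScale, default="smith2003"
        Starting scale for the optimization (normalized B-factors).
    n_folds, n_bootstrap, n_per_class : int
        Cross-validation and resampling structure; the study-scale defaults
        are 10 folds x 1000 resamples of 1000 + 1000 proteins.
    trim_tags_for_clustering : bool, default=True
        Remove the fixed His-tag affixes before clustering only (scoring
        and training always use the full sequences).
    random_state : int, default=0
        Root seed for fold tie-breaks and bootstrap draws.

    Attributes
    ----------
    weights_ : ResidueScale
        Final trained weights W = <V_k>.
    calibration_ : LogisticCalibration
        Logistic link fitted on the training data under ``weights_``.
    result_ : TrainedWeights
        Per-fold weight vectors and train/test AUCs.
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        initial_weights: str | ResidueScale = "smith2003",
        n_folds: int = 10,
        n_bootstrap: int = 1000,
        n_per_class: int = 1000,
        nm_maxiter: int = 5000,
        trim_tags_for_clustering: bool = True,
        random_state: int = 0,
    ):
        self.initial_weights = initial_weights
        self.n_folds = n_folds
        self.n_bootstrap = n_bootstrap
        self.n_per_class = n_per_class
        self.nm_maxiter = nm_maxiter
        self.trim_tags_for_clustering = trim_tags_for_clustering
        self.random_state = random_state

    def _dataset(self, X, y, clusters) -> LabeledDataset:
        seqs = _as_strings(X)
        y = np.asarray(y)
        if y.shape[0] != len(seqs):
            raise ValueError("X and y length mismatch")
        records = [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
        if clusters is None:
            from .seqio import SequenceError, trim_his_tag

            to_cluster = []
            for rec in records:
                try:
                    to_cluster.append(trim_his_tag(rec) if self.trim_tags_for_clustering else rec)
                except SequenceError:
                    to_cluster.append(rec)  # tag-only sequence: cluster as-is
            assignment = greedy_cluster(to_cluster)
            clusters = [assignment[rec.id] for rec in records]
        return LabeledDataset(
            tuple(
                (rec, int(label), str(cluster))
                for rec, label, cluster in zip(records, y, clusters)
            )
        )

    def fit(self, X, y, clusters: Sequence[str] | None = None):
        dataset = self._dataset(X, y, clusters)
        config = TrainingConfig(
            n_folds=self.n_folds,
            n_bootstrap=self.n_bootstrap,
            n_per_class=self.n_per_class,
            nm_maxiter=self.nm_maxiter,
            seed=self.random_state,
        )
        self.result_ = train_swi(dataset, _as_scale(self.initial_weights), config)
        self.weights_ = self.result_.final
        scores = [swi(s, self.weights_) for s in dataset.sequences]
        fit = fit_logistic(scores, dataset.labels)
        self.calibration_ = fit.calibration
        self.calibration_converged_ = fit.converged
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        """SWI scores under the trained weights."""
        check_is_fitted(self, "weights_")
        return np.array([swi(s, self.weights_) for s in _as_strings(X)])

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        p = np.array(
            [probability_of_solubility(s, self.calibration_) for s in scores]
        )
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
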