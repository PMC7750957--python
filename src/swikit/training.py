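"""Weight training: homology-aware folds, bootstrap resampling, and
derivative-free AUC maximization.

The pipeline refines an initial per-residue scale (normalized B-factors)
into solubility weights:

1. sequences are clustered by similarity (externally, or with the bundled
   greedy clusterer) and whole clusters are grouped into cross-validation
   folds, so that no similar sequences span the train/test boundary;
2. within each fold's training set, class-balanced bootstrap resamples are
   drawn (defaults mirror the original study: 1000 soluble + 1000 insoluble
   per resample, 1000 resamples, 10 folds);
3. each resample's weights are optimized with the Nelder–Mead simplex
   method — AUC is non-differentiable, so a derivative-free optimizer is
   required — starting from the initial scale;
4. the per-fold mean of the optimized vectors V_k is evaluated on the held
   out fold, and the final weights are W = <V_k>.

AUC is shift- and scale-invariant in the weights, so trained weights are
only identified up to a positive affine transform; they therefore travel
with a logistic calibration fitted by :func:`fit_logistic`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import rankdata

from .scales import STANDARD_AMINO_ACIDS, ResidueScale
from .scoring import LogisticCalibration
from .seqio import SequenceRecord

__all__ = [
    "LabeledDataset",
    "FoldAssignment",
    "TrainingConfig",
    "TrainedWeights",
    "LogisticFit",
    "auc",
    "build_folds",
    "bootstrap_resample",
    "composition_matrix",
    "optimize_weights",
    "train_swi",
    "fit_logistic",
    "greedy_cluster",
]

# byte -> residue index lookup for fast composition counting
_AA_LOOKUP = np.full(256, 255, dtype=np.uint8)
for _i, _aa in enumerate(STANDARD_AMINO_ACIDS):
    _AA_LOOKUP[ord(_aa)] = _i


@dataclass(frozen=True)
class LabeledDataset:
    """Sequences with binary solubility labels and cluster identifiers.

    ``records`` holds ``(SequenceRecord, label, cluster_id)`` triples with
    label 1 = soluble, 0 = insoluble.
    """

    records: tuple[tuple[SequenceRecord, int, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        for rec, label, cluster in self.records:
            if label not in (0, 1):
                raise ValueError(f"{rec.id}: label must be 0 or 1, got {label!r}")
            if not cluster:
                raise ValueError(f"{rec.id}: missing cluster_id")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [rec.residues for rec, _, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([label for _, label, _ in self.records], dtype=np.int8)

    @property
    def clusters(self) -> list[str]:
        return [cluster for _, _, cluster in self.records]

    def require_both_classes(self) -> None:
        labels = self.labels
        if labels.min() == labels.max():
            raise ValueError("dataset must contain both soluble and insoluble records")


@dataclass(frozen=True)
class FoldAssignment:
    """Whole-cluster assignment of a dataset to cross-validation folds."""

    n_folds: int
    fold_of_cluster: dict[str, int]

    def fold_indices(self, dataset: LabeledDataset) -> list[np.ndarray]:
        """Record indices of each fold, in fold order."""
        folds: list[list[int]] = [[] for _ in range(self.n_folds)]
        for i, (_, _, cluster) in enumerate(dataset.records):
            folds[self.fold_of_cluster[cluster]].append(i)
        return [np.array(ix, dtype=np.intp) for ix in folds]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the training pipeline (defaults mirror the original study)."""

    n_folds: int = 10
    n_bootstrap: int = 1000
    n_per_class: int = 1000
    nm_fatol: float = 1e-6  # simplex function-value spread at convergence
    nm_xatol: float = 1e-6
    nm_maxiter: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_folds, self.n_bootstrap, self.n_per_class) < 1:
            raise ValueError("n_folds, n_bootstrap and n_per_class must be >= 1")


@dataclass(frozen=True)
class OptimizationResult:
    weights: np.ndarray
    auc_initial: float
    auc_final: float
    converged: bool


@dataclass(frozen=True)
class TrainedWeights:
    """Per-fold mean weight vectors, their mean (the final weights), and AUCs."""

    fold_weights: np.ndarray  # (n_folds, 20), V_k
    final: ResidueScale  # W = <V_k>
    train_aucs: np.ndarray
    test_aucs: np.ndarray
    initial_train_aucs: np.ndarray
    initial_test_aucs: np.ndarray
    folds: FoldAssignment
    config: TrainingConfig

    def summary(self) -> str:
        return (
            f"train AUC {self.train_aucs.mean():.3f} ± {self.train_aucs.std():.3f}, "
            f"test AUC {self.test_aucs.mean():.3f} ± {self.test_aucs.std():.3f} "
            f"({self.config.n_folds}-fold)"
        )


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood single-feature logistic fit with its diagnostics."""

    calibration: LogisticCalibration
    converged: bool
    a_stderr: float
    b_stderr: float


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann–Whitney statistic.

    Equals (#{positive > negative} + 0.5 #ties) / (n1 * n0); ties in the
    scores receive half credit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def build_folds(dataset: LabeledDataset, n_folds: int, seed: int = 0) -> FoldAssignment:
    """Assign whole clusters to folds, balancing fold sizes.

    Greedy bin packing: clusters in decreasing size order (ties shuffled
    deterministically by ``seed``) each go to the currently smallest fold.
    No cluster ever spans folds.
    """
    sizes: dict[str, int] = {}
    for _, _, cluster in dataset.records:
        sizes[cluster] = sizes.get(cluster, 0) + 1
    if len(sizes) < n_folds:
        raise ValueError(
            f"cannot build {n_folds} folds from {len(sizes)} cluster(s); "
            "folds must not split clusters"
        )
    rng = np.random.default_rng(seed)
    names = list(sizes)
    rng.shuffle(names)  # deterministic tie-break among equal-size clusters
    names.sort(key=lambda c: -sizes[c])
    fold_sizes = np.zeros(n_folds, dtype=np.int64)
    fold_of_cluster: dict[str, int] = {}
    for name in names:
        k = int(fold_sizes.argmin())
        fold_of_cluster[name] = k
        fold_sizes[k] += sizes[name]
    return FoldAssignment(n_folds, fold_of_cluster)


def bootstrap_resample(
    labels: np.ndarray, n_per_class: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a class-balanced bootstrap resample.

    Draws ``n_per_class`` records with replacement from each class
    independently; returns ``2 * n_per_class`` indices into ``labels``.
    """
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("bootstrap resampling requires both classes to be present")
    return np.concatenate(
        [rng.choice(pos, size=n_per_class), rng.choice(neg, size=n_per_class)]
    )


def composition_matrix(sequences: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
    """Residue-count matrix (n, 20) and length vector for fast SWI scoring.

    ``counts @ w / lengths`` equals the per-sequence SWI under weight
    vector ``w`` (ordered as :data:`STANDARD_AMINO_ACIDS`).
    """
    rows, lengths = [], []
    for seq in sequences:
        codes = _AA_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if codes.max(initial=0) == 255:
            bad = sorted({c for c in seq if c not in STANDARD_AMINO_ACIDS})
            raise KeyError(f"nonstandard residue(s) {''.join(bad)!r} cannot be scored")
        rows.append(np.bincount(codes, minlength=20))
        lengths.append(len(seq))
    return np.array(rows, dtype=np.float64), np.array(lengths, dtype=np.float64)


def _swi_scores(counts: np.ndarray, lengths: np.ndarray, w: np.ndarray) -> np.ndarray:
    return counts @ w / lengths


def optimize_weights(
    counts: np.ndarray,
    lengths: np.ndarray,
    labels: np.ndarray,
    initial: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
) -> OptimizationResult:
    """Maximize AUC over the 20 residue weights with Nelder–Mead.

    The initial simplex is the initial vector plus one vertex per
    coordinate displaced by 5% of its value (floor 0.01).  The initial
    vector is itself a simplex vertex, so the returned weights never score
    a lower AUC than the initial weights on the sample.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("optimization sample must contain both classes")
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (20,) or not np.all(np.isfinite(initial)):
        raise ValueError("initial weights must be 20 finite values")

    def objective(w: np.ndarray) -> float:
        return -auc(_swi_scores(counts, lengths, w), labels)

    step = np.maximum(0.05 * np.abs(initial), 0.01)
    simplex = np.vstack([initial, initial + np.diag(step)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NM maxiter notice
        res = minimize(
            objective,
            initial,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "fatol": config.nm_fatol,
                "xatol": config.nm_xatol,
                "maxiter": config.nm_maxiter,
                "maxfev": 4 * config.nm_maxiter,
            },
        )
    return OptimizationResult(
        weights=np.asarray(res.x, dtype=float),
        auc_initial=-objective(initial),
        auc_final=-float(res.fun),
        converged=bool(res.success),
    )


def train_swi(
    dataset: LabeledDataset,
    initial: ResidueScale,
    config: TrainingConfig = TrainingConfig(),
    folds: FoldAssignment | None = None,
) -> TrainedWeights:
    """Run the full cross-validated bootstrap/optimize/average pipeline.

    For each fold k, ``n_bootstrap`` class-balanced resamples of the
    training folds are each optimized from ``initial``; their mean V_k is
    scored on the training folds and on the held-out fold k.  The final
    weights are the elementwise mean of the V_k.  Fully reproducible from
    ``config.seed``.
    """
    dataset.require_both_classes()
    if folds is None:
        folds = build_folds(dataset, config.n_folds, config.seed)
    elif folds.n_folds != config.n_folds:
        raise ValueError("fold assignment does not match config.n_folds")
    counts, lengths = composition_matrix(dataset.sequences)
    labels = dataset.labels.astype(np.int8)
    clusters = np.array(dataset.clusters)
    initial_vec = np.array(initial.as_vector())

    fold_ix = folds.fold_indices(dataset)
    root = np.random.SeedSequence(config.seed)
    fold_seeds = root.spawn(config.n_folds)

    fold_weights = np.empty((config.n_folds, 20))
    tr_auc = np.empty(config.n_folds)
    te_auc = np.empty(config.n_folds)
    tr_auc0 = np.empty(config.n_folds)
    te_auc0 = np.empty(config.n_folds)
    for k in range(config.n_folds):
        test = fold_ix[k]
        train = np.concatenate([fold_ix[j] for j in range(config.n_folds) if j != k])
        # homology leakage guard: no cluster may appear on both sides
        overlap = set(clusters[train]) & set(clusters[test])
        assert not overlap, f"cluster(s) {sorted(overlap)} span the train/test boundary"
        rng = np.random.default_rng(fold_seeds[k])
        boot_weights = np.empty((config.n_bootstrap, 20))
        for b in range(config.n_bootstrap):
            sample = train[bootstrap_resample(labels[train], config.n_per_class, rng)]
            result = optimize_weights(
                counts[sample], lengths[sample], labels[sample], initial_vec, config
            )
            boot_weights[b] = result.weights
        fold_weights[k] = boot_weights.mean(axis=0)
        for vec, tr_out, te_out in (
            (fold_weights[k], tr_auc, te_auc),
            (initial_vec, tr_auc0, te_auc0),
        ):
            tr_out[k] = auc(_swi_scores(counts[train], lengths[train], vec), labels[train])
            te_out[k] = auc(_swi_scores(counts[test], lengths[test], vec), labels[test])

    final_vec = fold_weights.mean(axis=0)
    final = ResidueScale(
        "trained",
        dict(zip(STANDARD_AMINO_ACIDS, final_vec.tolist())),
        provenance=f"trained from {initial.name!r}: {config}",
    )
    return TrainedWeights(
        fold_weights=fold_weights,
        final=final,
        train_aucs=tr_auc,
        test_aucs=te_auc,
        initial_train_aucs=tr_auc0,
        initial_test_aucs=te_auc0,
        folds=folds,
        config=config,
    )


def fit_logistic(
    swi_scores: Sequence[float], labels: Sequence[int], maxiter: int = 200
) -> LogisticFit:
    """Maximum-likelihood fit of p = 1/(1 + exp(-(a·x + b))).

    Iterations are capped; under (quasi-)complete separation the capped
    estimate is returned with ``converged=False``.
    """
    x = np.asarray(swi_scores, dtype=float)
    y = np.asarray(labels)
    if y.min() == y.max():
        raise ValueError("logistic calibration requires both classes")
    design = sm.add_constant(x)  # columns: [const, x]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, design)
        result = model.fit(method="lbfgs", maxiter=maxiter, disp=False)
        converged = bool(result.mle_retvals.get("converged", False))
        b, a = result.params
        bse = np.asarray(result.bse, dtype=float)
    # the MLE diverges under complete separation even when the capped
    # optimizer reports success at its last iterate
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        converged = False
    if not np.all(np.isfinite(bse)):
        converged = False
    return LogisticFit(
        calibration=LogisticCalibration(a=float(a), b=float(b)),
        converged=converged,
        a_stderr=float(bse[1]),
        b_stderr=float(bse[0]),
    )


def greedy_cluster(
    records: Sequence[SequenceRecord],
    identity_threshold: float = 0.4,
    word_length: int = 3,
) -> dict[str, str]:
    """Greedy centroid clustering on k-mer-estimated identity.

    Sequences are processed longest-first (ties by id); each joins the
    first centroid whose estimated identity — shared distinct words over
    the shorter sequence's distinct-word count — reaches the threshold,
    otherwise it founds a new cluster.  A deterministic, fixture-grade
    stand-in for a real clustering tool, not a replica of one.
    """
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    centroids: list[tuple[str, frozenset[str]]] = []  # (cluster_id, word set)
    assignment: dict[str, str] = {}
    for rec in order:
        words = frozenset(
            rec.residues[i : i + word_length]
            for i in range(len(rec.residues) - word_length + 1)
        )
        for cluster_id, cwords in centroids:
            denom = min(len(words), len(cwords))
            if denom and len(words & cwords) / denom >= identity_threshold:
                assignment[rec.id] = cluster_id
                break
        else:
            cluster_id = f"cluster{len(centroids) + 1}"
            centroids.append((cluster_id, words))
            assignment[rec.id] = cluster_id
    return assignment
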