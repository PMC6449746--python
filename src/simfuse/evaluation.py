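"""Hold-out evaluation of fused similarity scores.

Three evaluators:

* drug-overlap curves — does similarity in the (non-drug) fused space
  predict drug sharing?  Measured as the mean Jaccard overlap of drug sets
  among linked pairs, swept over a grid of similarity-quantile thresholds.
* ontology-class prediction — random-forest classifiers trained on each
  disease's row of pairwise similarities, evaluated by stratified
  Monte-Carlo cross-validation (AUROC averaged over runs; displayed ROC
  curves averaged over runs with the modal number of breakpoints).
* comorbidity comparison — relative risk of co-occurrence for linked vs
  non-linked disease pairs against an external patient-record table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .diseasemap import DiseaseMap
from .similarity import SimilarityMatrix, similarity_matrix
from .spaces import ClassLabels, ComorbidityTable, FeatureSpace, ValidationError

logger = logging.getLogger(__name__)

#: 100 quantile levels from 0.00 to 0.99 (step 0.01)
DEFAULT_LEVELS = tuple(np.round(np.arange(0.0, 1.0, 0.01), 2))

# Random-forest settings: 500 trees, sqrt(p) features per split, unlimited
# depth — stated numerically so results are reproducible across versions.
RF_PARAMS = dict(n_estimators=500, max_features="sqrt", max_depth=None)


@dataclass(frozen=True)
class OverlapCurve:
    """Mean drug-set Jaccard overlap among linked pairs per quantile level.

    ``mean_overlap`` is NaN where no pair is linked (undefined, not 0).
    """

    levels: tuple[float, ...]
    thresholds: tuple[float, ...]
    mean_overlap: np.ndarray
    n_links: np.ndarray
    source: str


def drug_overlap_curve(
    sim: SimilarityMatrix,
    drug_space: FeatureSpace,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> OverlapCurve:
    """Sweep similarity-quantile thresholds and measure drug sharing.

    At level ``q``, pairs whose similarity strictly exceeds the q-quantile
    of the matrix's off-diagonal values are "linked"; the curve reports the
    mean Jaccard overlap of the linked diseases' drug sets (and the link
    count) at each level.
    """
    levels = tuple(float(q) for q in levels)
    if any(not 0 <= q < 1 for q in levels):
        raise ValueError("quantile levels must lie in [0, 1)")
    missing = [d for d in sim.diseases if d not in drug_space.members]
    if missing:
        raise ValidationError(
            f"drug space lacks disease(s): {', '.join(missing[:5])}"
        )
    sim_vec = sim.pair_vector()
    drug_vec = similarity_matrix(drug_space, sim.diseases).pair_vector()
    thresholds, means, counts = [], [], []
    for q in levels:
        thr = float(np.quantile(sim_vec, q))
        linked = sim_vec > thr
        n = int(linked.sum())
        thresholds.append(thr)
        counts.append(n)
        means.append(float(drug_vec[linked].mean()) if n else float("nan"))
    return OverlapCurve(
        levels=levels,
        thresholds=tuple(thresholds),
        mean_overlap=np.array(means),
        n_links=np.array(counts),
        source=sim.space_name,
    )


@dataclass(frozen=True)
class ClassPredictionResult:
    """AUROC and averaged ROC for one binary class-membership task."""

    task: str
    auroc_mean: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_runs: int
    train_fraction: float
    seed: int | None
    aurocs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _stratified_split(
    rng: np.random.Generator, y: np.ndarray, train_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (False, True):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides populated
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


def _unique_breakpoints(fpr: np.ndarray, tpr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pts = np.column_stack([fpr, tpr])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    return pts[:, 0], pts[:, 1]


def class_prediction(
    sim: SimilarityMatrix,
    labels: ClassLabels,
    task: str,
    n_runs: int = 1000,
    train_fraction: float = 0.8,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ClassPredictionResult:
    """Predict membership of one top-level class from similarity profiles.

    Each disease's feature vector is its row of similarities to the other
    diseases (the self-similarity entry removed; similarities are computed
    without label knowledge, so no label leakage occurs).  Each run draws a
    stratified train/test split at ``train_fraction``, fits a random forest
    (500 trees, sqrt feature subset), and scores the held-out diseases.
    AUROC is averaged over all runs; the reported ROC curve is averaged
    element-wise over the runs whose curve has the modal number of unique
    (FPR, TPR) breakpoints.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = sim.n
    mask = ~np.eye(n, dtype=bool)
    X = sim.values[mask].reshape(n, n - 1)
    y = np.array([task in labels.classes_of(d) for d in sim.diseases])
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValidationError(
            f"task {task!r} needs >=2 positives and >=2 negatives "
            f"(got {n_pos}/{n_neg})"
        )
    aurocs = np.empty(n_runs)
    curves: list[tuple[np.ndarray, np.ndarray]] = []
    for run in range(n_runs):
        for _attempt in range(100):
            train, test = _stratified_split(rng, y, train_fraction)
            if len(set(y[train])) == 2 and len(set(y[test])) == 2:
                break
            logger.info("degenerate stratified split redrawn (run %d)", run)
        else:  # pragma: no cover - unreachable with >=2 per class
            raise RuntimeError("could not draw a non-degenerate stratified split")
        clf = RandomForestClassifier(
            **RF_PARAMS, random_state=int(rng.integers(2**31 - 1)), n_jobs=1
        )
        clf.fit(X[train], y[train])
        scores = clf.predict_proba(X[test])[:, list(clf.classes_).index(True)]
        aurocs[run] = roc_auc_score(y[test], scores)
        fpr, tpr, _ = roc_curve(y[test], scores, drop_intermediate=False)
        curves.append(_unique_breakpoints(fpr, tpr))
    lengths = np.array([len(c[0]) for c in curves])
    modal_len = np.bincount(lengths).argmax()
    selected = [c for c in curves if len(c[0]) == modal_len]
    roc_fpr = np.mean([c[0] for c in selected], axis=0)
    roc_tpr = np.mean([c[1] for c in selected], axis=0)
    return ClassPredictionResult(
        task=task,
        auroc_mean=float(aurocs.mean()),
        roc_fpr=roc_fpr,
        roc_tpr=roc_tpr,
        n_runs=n_runs,
        train_fraction=train_fraction,
        seed=seed,
        aurocs=aurocs,
    )


@dataclass(frozen=True)
class ComorbiditySummary:
    """Relative-risk contrast between linked and non-linked disease pairs."""

    coverage_ok: bool
    n_linked_covered: int
    n_nonlinked_covered: int
    median_rr_linked: float
    median_rr_nonlinked: float
    #: rr_threshold -> (fraction linked above, fraction non-linked above, ratio)
    fractions_above: dict[float, tuple[float, float, float]]


def comorbidity_comparison(
    dmap: DiseaseMap,
    table: ComorbidityTable,
    rr_thresholds: Sequence[float] = (1.5, 2.0, 5.0),
) -> ComorbiditySummary:
    """Compare comorbidity relative risk of linked vs non-linked pairs.

    Only pairs covered by the table enter the comparison.  With no covered
    linked pairs the summary reports a coverage failure (``coverage_ok``
    False, medians NaN).
    """
    linked_pairs = dmap.edge_pairs()
    diseases = set(dmap.diseases)
    linked_rr, nonlinked_rr = [], []
    for (a, b), rr in table.entries.items():
        if a not in diseases or b not in diseases:
            continue
        (linked_rr if (a, b) in linked_pairs else nonlinked_rr).append(rr)
    if not linked_rr:
        logger.warning("comorbidity table covers no linked pairs")
        return ComorbiditySummary(
            coverage_ok=False,
            n_linked_covered=0,
            n_nonlinked_covered=len(nonlinked_rr),
            median_rr_linked=float("nan"),
            median_rr_nonlinked=float(np.median(nonlinked_rr)) if nonlinked_rr else float("nan"),
            fractions_above={},
        )
    linked = np.array(linked_rr)
    nonlinked = np.array(nonlinked_rr)
    fractions: dict[float, tuple[float, float, float]] = {}
    for thr in rr_thresholds:
        f_link = float(np.mean(linked > thr))
        f_non = float(np.mean(nonlinked > thr)) if nonlinked.size else float("nan")
        ratio = f_link / f_non if f_non and np.isfinite(f_non) else float("inf") if f_link else float("nan")
        fractions[float(thr)] = (f_link, f_non, ratio)
    return ComorbiditySummary(
        coverage_ok=True,
        n_linked_covered=linked.size,
        n_nonlinked_covered=nonlinked.size,
        median_rr_linked=float(np.median(linked)),
        median_rr_nonlinked=float(np.median(nonlinked)) if nonlinked.size else float("nan"),
        fractions_above=fractions,
    )
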