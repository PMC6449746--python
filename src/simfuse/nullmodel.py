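"""Frequency-preserving randomization null model and significance threshold.

The significance of a fused similarity is judged against random fused
matrices built from randomized feature sets: for each disease, a random set
of the observed cardinality is drawn from the space's feature universe with
probability proportional to each feature's observed frequency.  The
randomized spaces are pushed through the same normalize-and-fuse pipeline,
the off-diagonal fused values pooled across iterations, and a high
percentile (default 99.99) of the pooled values taken as the threshold
above which two diseases are linked.

Sampling without replacement with frequency weights follows the
Plackett–Luce scheme (each successive draw renormalizes over the remaining
features), realised via the exponential-race construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .fusion import FusionConfig, normalize_and_fuse
from .similarity import similarity_matrix
from .spaces import FeatureSpace, validate_collection

logger = logging.getLogger(__name__)


def _weighted_draw(
    rng: np.random.Generator,
    weights: np.ndarray,
    k: int,
    available: np.ndarray,
) -> np.ndarray:
    """Indices of a size-k weighted sample without replacement from the
    positions where ``available`` is True (exponential race)."""
    idx = np.flatnonzero(available)
    if k > idx.size:
        raise ValueError(
            f"requested set size {k} exceeds available universe size {idx.size}"
        )
    if k == idx.size:
        return idx
    keys = rng.exponential(size=idx.size) / weights[idx]
    return idx[np.argpartition(keys, k - 1)[:k]]


def randomize_space(space: FeatureSpace, rng: np.random.Generator) -> FeatureSpace:
    """Frequency-preserving randomization of one feature space.

    Each disease receives a random feature set of its observed cardinality,
    drawn without replacement from the space's universe with probability
    proportional to feature frequency.  Signed spaces draw the up set first
    and the down set from the remaining features, preserving sizes and
    disjointness.  The returned space's universe is recomputed.
    """
    if not space.universe:
        raise ValueError(f"space {space.name!r} has an empty universe")
    features = np.array(sorted(space.universe))
    weights = np.array([space.universe[f] for f in features], dtype=float)
    members: dict = {}
    for disease in space.diseases:
        avail = np.ones(features.size, dtype=bool)
        if space.kind == "signed":
            up, down = space.members[disease]
            up_idx = _weighted_draw(rng, weights, len(up), avail)
            avail[up_idx] = False
            down_idx = _weighted_draw(rng, weights, len(down), avail)
            members[disease] = (
                frozenset(features[up_idx]),
                frozenset(features[down_idx]),
            )
        else:
            idx = _weighted_draw(rng, weights, len(space.members[disease]), avail)
            members[disease] = frozenset(features[idx])
    return FeatureSpace(
        name=space.name, kind=space.kind, members=members, allow_empty=True
    )


@dataclass(frozen=True)
class NullDistribution:
    """Pooled off-diagonal fused scores from randomized iterations."""

    values: np.ndarray  # shape (n_iterations, n_pairs)
    n_iterations: int
    seed: int | None
    config: FusionConfig

    @property
    def pooled(self) -> np.ndarray:
        return self.values.ravel()

    @property
    def n_pairs(self) -> int:
        return self.values.shape[1]


def null_distribution(
    spaces: Sequence[FeatureSpace],
    config: FusionConfig | None = None,
    n_iterations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    diseases: Sequence[str] | None = None,
    weight_rule: str = "size",
) -> NullDistribution:
    """Build the randomization null for a collection of spaces.

    Each iteration randomizes every participating space, recomputes raw
    similarity matrices, quantile-normalizes and fuses them with ``config``,
    and pools the fused off-diagonal values.  Reproducible from ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be positive")
    if config is None:
        config = FusionConfig.uniform([s.name for s in spaces])
    by_name = {s.name: s for s in spaces}
    participating = [by_name[n] for n in config.space_names]
    if diseases is None:
        diseases = validate_collection(participating).common_diseases
    diseases = tuple(diseases)
    if rng is None:
        rng = np.random.default_rng(seed)
    n_pairs = len(diseases) * (len(diseases) - 1) // 2
    values = np.empty((n_iterations, n_pairs))
    for it in range(n_iterations):
        randomized = [randomize_space(s, rng) for s in participating]
        raw = [similarity_matrix(s, diseases, weight_rule=weight_rule) for s in randomized]
        fused, _ = normalize_and_fuse(raw, config)
        values[it] = fused.pair_vector()
    return NullDistribution(
        values=values, n_iterations=n_iterations, seed=seed, config=config
    )


@dataclass(frozen=True)
class ThresholdResult:
    """Significance threshold and its per-iteration-maximum diagnostic."""

    threshold: float
    percentile: float
    #: fraction of iterations whose maximum fused value exceeds the threshold
    iteration_max_exceedance: float


def significance_threshold(
    null: NullDistribution, percentile: float = 99.99
) -> ThresholdResult:
    """Percentile of the pooled null values (linear interpolation between
    order statistics, the "type 7" convention).

    Also reports the fraction of iterations whose maximum fused value
    exceeds the threshold — a diagnostic relating the pooled percentile to
    per-matrix maxima.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    pooled = null.pooled
    if pooled.size == 0:
        raise ValueError("null distribution is empty")
    threshold = float(np.percentile(pooled, percentile))
    iter_max = null.values.max(axis=1)
    exceedance = float(np.mean(iter_max > threshold))
    return ThresholdResult(
        threshold=threshold, percentile=percentile, iteration_max_exceedance=exceedance
    )


def write_null_tsv(null: NullDistribution, path: str | Path) -> None:
    """Persist pooled null values as a single-column TSV plus metadata JSON."""
    import json

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("fused_score\n")
        for v in null.pooled:
            fh.write(format(v, ".6g") + "\n")
    meta = {
        "n_iterations": null.n_iterations,
        "n_pairs": null.n_pairs,
        "seed": null.seed,
        "spaces": list(null.config.space_names),
        "weights": list(null.config.weights),
        "percentile_convention": "linear interpolation (type 7)",
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(meta, indent=1) + "\n", encoding="utf-8"
    )
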