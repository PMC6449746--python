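"""Quantile normalization of similarity distributions and weighted-mean fusion.

Per-space similarity distributions are strongly unequal (sparse ontological
or drug spaces vs dense transcriptomic spaces), so fusing raw scores would
let high-scoring spaces dominate.  Quantile normalization forces every
space's off-diagonal pair vector onto one common distribution — the mean of
the rank-sorted vectors — after which a (weighted) mean fuses the spaces on
an equal footing.

Tied raw values are adjusted: a run of k equal values receives the mean of
the k reference values spanning their tied ranks, so equal raw scores map to
equal normalized scores.  Ties are detected by exact value equality (Jaccard
scores are exact rationals; an epsilon rule would be arbitrary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import json

import numpy as np

from .similarity import SimilarityMatrix
from .spaces import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FusionConfig:
    """Which spaces to fuse and with what weights (normalized to sum 1)."""

    space_names: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        names = tuple(self.space_names)
        if not names:
            raise ValueError("at least one space must be selected")
        if len(set(names)) != len(names):
            raise ValueError("duplicate space names in fusion config")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(names),):
            raise ValueError(
                f"weight vector length {w.shape} does not match {len(names)} spaces"
            )
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        object.__setattr__(self, "space_names", names)
        object.__setattr__(self, "weights", tuple(w / total))

    @classmethod
    def uniform(cls, space_names: Sequence[str]) -> "FusionConfig":
        names = tuple(space_names)
        return cls(names, tuple(1.0 for _ in names))

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "FusionConfig":
        """Load ``{"spaces": [...], "weights": [...]}``; omitted weights mean uniform."""
        if isinstance(source, (str, Path)):
            obj = json.loads(Path(source).read_text(encoding="utf-8"))
        else:
            obj = source
        names = obj["spaces"]
        weights = obj.get("weights")
        if weights is None:
            return cls.uniform(names)
        return cls(tuple(names), tuple(weights))


def _map_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace each value by the reference value at its rank; a run of k
    tied values gets the mean of the k reference values they span."""
    uniq, inverse, counts = np.unique(values, return_inverse=True, return_counts=True)
    # reference is sorted; group g occupies sorted positions [starts[g], starts[g]+counts[g])
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    group_means = reference[starts].copy()  # exact for untied values
    for g in np.flatnonzero(counts > 1):
        # strictly left-to-right accumulation: bit-reproducible regardless of
        # vectorized summation order
        acc = 0.0
        for v in reference[starts[g] : starts[g] + counts[g]]:
            acc += v
        group_means[g] = acc / counts[g]
    return group_means[inverse]


def quantile_normalize(
    matrices: Sequence[SimilarityMatrix],
) -> list[SimilarityMatrix]:
    """Quantile-normalize the off-diagonal pair vectors of several spaces.

    The reference distribution is the across-space mean of the rank-sorted
    pair vectors; each value is replaced by the reference value at its rank,
    with tied runs averaged over the reference values they span.  A single
    matrix is allowed (identity up to tie averaging of its own sorted
    vector, logged).
    """
    if not matrices:
        raise ValueError("no matrices given")
    diseases = matrices[0].diseases
    for m in matrices:
        if m.diseases != diseases:
            raise ValidationError("matrices cover different disease lists")
        if m.normalized:
            raise ValidationError(
                f"matrix {m.space_name!r} is already normalized"
            )
    if len(matrices) == 1:
        logger.info(
            "quantile_normalize on a single matrix: identity up to tie averaging"
        )
    vecs = np.vstack([m.pair_vector() for m in matrices])
    reference = np.sort(vecs, axis=1).mean(axis=0)
    out = []
    for m, vec in zip(matrices, vecs):
        normalized = _map_to_reference(vec, reference)
        out.append(
            SimilarityMatrix.from_pair_vector(
                diseases,
                normalized,
                space_name=m.space_name,
                normalized=True,
                meta={**m.meta, "reference_spaces": [x.space_name for x in matrices]},
            )
        )
    return out


def fuse(
    matrices: Sequence[SimilarityMatrix], config: FusionConfig
) -> SimilarityMatrix:
    """Per-pair weighted mean of quantile-normalized spaces.

    ``config`` selects a subset of the given matrices by name; weights sum
    to 1.  Selecting an unnormalized matrix is an error — fusion operates on
    a shared distribution by construction.
    """
    by_name = {m.space_name: m for m in matrices}
    missing = [n for n in config.space_names if n not in by_name]
    if missing:
        raise ValueError(f"fusion config names unknown spaces: {missing}")
    selected = [by_name[n] for n in config.space_names]
    diseases = selected[0].diseases
    for m in selected:
        if not m.normalized:
            raise ValidationError(
                f"matrix {m.space_name!r} is not quantile-normalized"
            )
        if m.diseases != diseases:
            raise ValidationError("matrices cover different disease lists")
    weights = np.asarray(config.weights)
    stacked = np.vstack([m.pair_vector() for m in selected])
    fused_vec = weights @ stacked
    return SimilarityMatrix.from_pair_vector(
        diseases,
        fused_vec,
        space_name="fused",
        normalized=True,
        meta={
            "spaces": list(config.space_names),
            "weights": list(config.weights),
        },
    )


def normalize_and_fuse(
    raw_matrices: Sequence[SimilarityMatrix],
    config: FusionConfig | None = None,
    renormalize: bool = True,
) -> tuple[SimilarityMatrix, list[SimilarityMatrix]]:
    """Convenience: quantile-normalize raw matrices and fuse a subset.

    With ``renormalize=True`` (default) the reference distribution is
    recomputed over the selected subset only — the reference depends on the
    participating spaces, so hold-out fusions (e.g. the five-space non-drug
    map) renormalize.  ``renormalize=False`` reuses the all-space
    normalization and then selects.

    Returns ``(fused, normalized_selected)``.
    """
    if config is None:
        config = FusionConfig.uniform([m.space_name for m in raw_matrices])
    if renormalize:
        by_name = {m.space_name: m for m in raw_matrices}
        selected_raw = [by_name[n] for n in config.space_names]
        normalized = quantile_normalize(selected_raw)
    else:
        all_normalized = quantile_normalize(raw_matrices)
        by_name = {m.space_name: m for m in all_normalized}
        normalized = [by_name[n] for n in config.space_names]
    return fuse(normalized, config), normalized
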