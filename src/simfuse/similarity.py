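"""Pairwise Jaccard similarity matrices over disease feature sets.

Every space is turned into a symmetric disease-by-disease matrix of Jaccard
scores; signed (gene-expression-like) spaces use a size-weighted mean of the
up-set and down-set Jaccard scores.  The diagonal is stored as 1 for display
but is excluded from every downstream vectorization, normalization,
percentile and correlation computation: the unit of analysis is the
off-diagonal pair vector of length n(n-1)/2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .spaces import FeatureSpace, ValidationError

logger = logging.getLogger(__name__)

WEIGHT_RULES = ("size", "unweighted")


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard index |a∩b| / |a∪b|; two empty sets score 0 (logged)."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        logger.debug("jaccard of two empty sets; scoring 0")
        return 0.0
    return len(a & b) / union


def signed_jaccard(
    a_up: Iterable,
    a_down: Iterable,
    b_up: Iterable,
    b_down: Iterable,
    weight_rule: str = "size",
) -> float:
    """Jaccard score for signed (up/down-regulated) feature sets.

    With the default ``"size"`` rule, each part is weighted by its combined
    set size over the two diseases: ``w_up = (|a_up|+|b_up|)/S`` with ``S``
    the total size of all four sets, so larger parts carry more signal and
    the score reduces to the unweighted mean when sizes are balanced.
    ``"unweighted"`` averages the two part scores equally.
    """
    a_up, a_down, b_up, b_down = map(set, (a_up, a_down, b_up, b_down))
    if a_up & a_down:
        raise ValidationError("up and down sets of the first disease overlap")
    if b_up & b_down:
        raise ValidationError("up and down sets of the second disease overlap")
    if weight_rule not in WEIGHT_RULES:
        raise ValueError(f"weight_rule must be one of {WEIGHT_RULES}")
    j_up = jaccard(a_up, b_up)
    j_down = jaccard(a_down, b_down)
    if weight_rule == "unweighted":
        return 0.5 * (j_up + j_down)
    total = len(a_up) + len(b_up) + len(a_down) + len(b_down)
    if total == 0:
        return 0.0
    w_up = (len(a_up) + len(b_up)) / total
    return w_up * j_up + (1.0 - w_up) * j_down


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity scores over an ordered disease list.

    ``values`` is the full n×n matrix with unit diagonal.  ``pair_vector``
    exposes the off-diagonal upper triangle (row-major, i<j), the canonical
    vector every downstream step operates on.
    """

    diseases: tuple[str, ...]
    values: np.ndarray
    space_name: str
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diseases = tuple(self.diseases)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.diseases)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.diseases)

    def pair_vector(self) -> np.ndarray:
        """Off-diagonal pairs as a length n(n-1)/2 vector (upper triangle)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu].copy()

    def pair_index(self) -> list[tuple[str, str]]:
        """Disease pairs in the order produced by :meth:`pair_vector`."""
        iu, ju = np.triu_indices(self.n, k=1)
        return [(self.diseases[i], self.diseases[j]) for i, j in zip(iu, ju)]

    @classmethod
    def from_pair_vector(
        cls,
        diseases: Sequence[str],
        vector: np.ndarray,
        space_name: str,
        normalized: bool = False,
        meta: dict | None = None,
    ) -> "SimilarityMatrix":
        n = len(diseases)
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"pair vector length {vector.shape} incompatible with {n} diseases"
            )
        values = np.eye(n)
        iu = np.triu_indices(n, k=1)
        values[iu] = vector
        values.T[iu] = vector
        return cls(
            diseases=tuple(diseases),
            values=values,
            space_name=space_name,
            normalized=normalized,
            meta=dict(meta or {}),
        )


def _indicator(diseases: Sequence[str], sets: list[frozenset]) -> np.ndarray:
    feats = sorted(set().union(*sets)) if sets else []
    idx = {f: i for i, f in enumerate(feats)}
    mat = np.zeros((len(diseases), len(feats)))
    for row, s in enumerate(sets):
        for f in s:
            mat[row, idx[f]] = 1.0
    return mat


def _jaccard_block(indicator: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs intersections and set sizes from a binary indicator matrix."""
    inter = indicator @ indicator.T
    sizes = indicator.sum(axis=1)
    return inter, sizes


def similarity_matrix(
    space: FeatureSpace,
    diseases: Sequence[str],
    weight_rule: str = "size",
) -> SimilarityMatrix:
    """Raw Jaccard similarity matrix of one space over an ordered disease list.

    Unsigned spaces use the plain Jaccard index; signed spaces the weighted
    signed Jaccard.  Pairs of empty sets score 0 (counted in the log).
    """
    missing = [d for d in diseases if d not in space.members]
    if missing:
        raise ValidationError(
            f"space {space.name!r} lacks disease(s): {', '.join(missing[:5])}"
        )
    n = len(diseases)
    if space.kind == "signed":
        ups = [space.members[d][0] for d in diseases]
        downs = [space.members[d][1] for d in diseases]
        i_up, s_up = _jaccard_block(_indicator(diseases, ups))
        i_dn, s_dn = _jaccard_block(_indicator(diseases, downs))
        u_up = s_up[:, None] + s_up[None, :] - i_up
        u_dn = s_dn[:, None] + s_dn[None, :] - i_dn
        with np.errstate(invalid="ignore", divide="ignore"):
            j_up = np.where(u_up > 0, i_up / np.maximum(u_up, 1), 0.0)
            j_dn = np.where(u_dn > 0, i_dn / np.maximum(u_dn, 1), 0.0)
        total = s_up[:, None] + s_up[None, :] + s_dn[:, None] + s_dn[None, :]
        if weight_rule == "unweighted":
            values = 0.5 * (j_up + j_dn)
        elif weight_rule == "size":
            w_up = np.where(total > 0, (s_up[:, None] + s_up[None, :]) / np.maximum(total, 1), 0.0)
            values = w_up * j_up + (1.0 - w_up) * j_dn
        else:
            raise ValueError(f"weight_rule must be one of {WEIGHT_RULES}")
        values[total == 0] = 0.0
    else:
        sets = [space.members[d] for d in diseases]
        inter, sizes = _jaccard_block(_indicator(diseases, sets))
        union = sizes[:, None] + sizes[None, :] - inter
        n_empty_pairs = int(((union == 0).sum() - (sizes == 0).sum()) // 2)
        if n_empty_pairs:
            logger.info(
                "space %r: %d empty-vs-empty pairs scored 0", space.name, n_empty_pairs
            )
        values = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        diseases=tuple(diseases),
        values=values,
        space_name=space.name,
        normalized=False,
        meta={"kind": space.kind, "weight_rule": weight_rule},
    )


def pairwise_correlations(matrices: Sequence[SimilarityMatrix]) -> pd.DataFrame:
    """Pearson correlation between the off-diagonal pair vectors of spaces.

    Returns a square DataFrame indexed by space name, unit diagonal.  A
    zero-variance pair vector yields NaN (undefined, flagged in the log)
    rather than 0.
    """
    if not matrices:
        raise ValueError("no matrices given")
    diseases = matrices[0].diseases
    for m in matrices[1:]:
        if m.diseases != diseases:
            raise ValidationError("matrices cover different disease lists")
    if len(diseases) * (len(diseases) - 1) // 2 < 3:
        raise ValidationError("need at least 3 disease pairs for correlations")
    names = [m.space_name for m in matrices]
    vecs = np.vstack([m.pair_vector() for m in matrices])
    stds = vecs.std(axis=1)
    k = len(matrices)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if stds[i] == 0 or stds[j] == 0:
                logger.warning(
                    "zero-variance pair vector (%s / %s): correlation undefined",
                    names[i],
                    names[j],
                )
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = np.corrcoef(vecs[i], vecs[j])[0, 1]
    return pd.DataFrame(out, index=names, columns=names)


# ---------------------------------------------------------------------------
# Matrix TSV round trip (sidecar JSON carries provenance)
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: SimilarityMatrix, path: str | Path) -> None:
    """Write a square TSV (header row/column of disease ids, 6 significant
    digits) plus a ``<path>.meta.json`` sidecar with provenance."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("disease_id\t" + "\t".join(matrix.diseases) + "\n")
        for i, d in enumerate(matrix.diseases):
            row = "\t".join(format(v, ".6g") for v in matrix.values[i])
            fh.write(f"{d}\t{row}\n")
    sidecar = {
        "space_name": matrix.space_name,
        "normalized": matrix.normalized,
        "meta": matrix.meta,
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=1) + "\n", encoding="utf-8"
    )


def read_matrix_tsv(path: str | Path) -> SimilarityMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    # round to the writer's precision so a written matrix is exactly symmetric
    values = 0.5 * (values + values.T)
    sidecar_path = Path(str(path) + ".meta.json")
    space_name, normalized, meta = path.stem, False, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        space_name = sidecar.get("space_name", space_name)
        normalized = bool(sidecar.get("normalized", False))
        meta = sidecar.get("meta", {})
    return SimilarityMatrix(
        diseases=tuple(frame.columns),
        values=values,
        space_name=space_name,
        normalized=normalized,
        meta=meta,
    )
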