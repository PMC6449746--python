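"""Synthetic multi-space disease collections with planted class structure.

The generator emulates the shape of a real multi-space disease dataset:
~84 diseases, six heterogeneous spaces (three omics-like spaces with
feature-set size 100, one of them signed with unequal up/down sets, a
phenotype-like space of size ~21, and a drug-like space with small variable
set sizes), with strongly unequal universe sizes so per-space similarity
distributions differ — the condition that motivates quantile normalization.

Generative model per space: the universe is partitioned into disjoint
per-class *shared pools* plus a *background pool*.  A disease of class c
with set size s draws ``m = round(shared_fraction * s)`` features uniformly
without replacement from c's pool and the remaining ``s - m`` from the
background pool.  Class pools are small — ``pool_scale`` (default 1.5)
times the largest shared draw — so within-class pairs share most of their
pool draw (the strong, frequent features real disease clusters share),
while the remaining universe forms a large sparse background.  Within-class
pairs therefore overlap in both the pool and background draws;
between-class pairs only in the background.  The expected Jaccard index is
an exact double-hypergeometric sum (:func:`expected_jaccard`) and serves as
the oracle for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .spaces import ClassLabels, FeatureSpace

SizeSpec = int | tuple[int, int]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class SpaceSpec:
    """Generative parameters for one synthetic feature space.

    ``set_size`` is either a constant or an inclusive ``(lo, hi)`` range
    sampled uniformly per disease (drug-like spaces).  ``shared_fraction``
    is the effect size: the fraction of each set drawn from the disease's
    class pool (0 = no planted structure).  Signed spaces split the universe
    and each disease's draw into disjoint up/down parts at ``up_fraction``.
    """

    name: str
    set_size: SizeSpec
    universe_size: int
    shared_fraction: float
    signed: bool = False
    up_fraction: float = 0.6
    pool_scale: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if self.pool_scale < 1.0:
            raise ValueError("pool_scale must be >= 1 (pool must hold the shared draw)")
        if isinstance(self.set_size, tuple):
            lo, hi = self.set_size
            if not (1 <= lo <= hi):
                raise ValueError("set_size range must satisfy 1 <= lo <= hi")

    def size_support(self) -> list[int]:
        if isinstance(self.set_size, tuple):
            lo, hi = self.set_size
            return list(range(lo, hi + 1))
        return [int(self.set_size)]

    def max_size(self) -> int:
        return max(self.size_support())


@dataclass(frozen=True)
class SyntheticConfig:
    """Collection-level generative parameters (defaults via :func:`default_config`)."""

    n_diseases: int
    classes: tuple[tuple[str, int], ...]
    spaces: tuple[SpaceSpec, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(count for _, count in self.classes)
        if total != self.n_diseases:
            raise ValueError(
                f"class member counts sum to {total}, expected {self.n_diseases}"
            )
        if len({name for name, _ in self.classes}) != len(self.classes):
            raise ValueError("duplicate class identifiers")

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted labels plus closed-form expected similarities per space."""

    labels: ClassLabels
    #: space name -> {"within": E[J | same class], "between": E[J | different]}
    expected: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Universe layout: small per-class pools (pool_scale x the largest shared
# draw), everything else background
# ---------------------------------------------------------------------------

def _part_layout(
    spec: SpaceSpec, n_classes: int, part_universe: int, part_max_size: int
) -> tuple[int, int]:
    """(class-pool size, background size) for one universe (or signed part)."""
    m_max = _round_half_up(spec.shared_fraction * part_max_size)
    pool = math.ceil(spec.pool_scale * m_max) if m_max else 0
    background = part_universe - n_classes * pool
    if background < part_max_size - m_max or background < 0:
        raise ValueError(
            f"space {spec.name!r}: universe size {part_universe} too small for "
            f"{n_classes} pools of {pool} plus background draws of "
            f"{part_max_size - m_max}"
        )
    return pool, background


def _signed_layouts(
    spec: SpaceSpec, n_classes: int
) -> tuple[tuple[int, int], tuple[int, int], int]:
    up_universe = _round_half_up(spec.universe_size * spec.up_fraction)
    max_up = _round_half_up(spec.up_fraction * spec.max_size())
    up_layout = _part_layout(spec, n_classes, up_universe, max_up)
    down_layout = _part_layout(
        spec, n_classes, spec.universe_size - up_universe, spec.max_size() - max_up
    )
    return up_layout, down_layout, up_universe


def _check_feasible(spec: SpaceSpec, n_classes: int) -> None:
    if spec.signed:
        _signed_layouts(spec, n_classes)
    else:
        _part_layout(spec, n_classes, spec.universe_size, spec.max_size())


def _draw_set(
    rng: np.random.Generator,
    prefix: str,
    class_idx: int,
    pool: int,
    background: int,
    size: int,
    shared_fraction: float,
) -> frozenset:
    m = min(_round_half_up(shared_fraction * size), pool)
    pool_draw = rng.choice(pool, size=m, replace=False) if m else np.empty(0, int)
    bg_draw = rng.choice(background, size=size - m, replace=False) if size - m else np.empty(0, int)
    return frozenset(
        [f"{prefix}:c{class_idx}:{int(j)}" for j in pool_draw]
        + [f"{prefix}:bg:{int(j)}" for j in bg_draw]
    )


def generate_collection(
    config: SyntheticConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[FeatureSpace], ClassLabels, SyntheticTruth]:
    """Draw a full multi-space collection from the generative model.

    Returns the feature spaces, the planted class labels, and a truth
    record with the exact expected within/between-class Jaccard per space.
    Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    for spec in config.spaces:
        _check_feasible(spec, config.n_classes)

    width = len(str(config.n_diseases))
    diseases = [f"d{i:0{width}d}" for i in range(1, config.n_diseases + 1)]
    class_of: dict[str, int] = {}
    labels: dict[str, set] = {}
    cursor = 0
    for ci, (cname, count) in enumerate(config.classes):
        for d in diseases[cursor : cursor + count]:
            class_of[d] = ci
            labels[d] = {cname}
        cursor += count

    spaces: list[FeatureSpace] = []
    for spec in config.spaces:
        sizes = {
            d: (
                int(rng.integers(spec.set_size[0], spec.set_size[1] + 1))
                if isinstance(spec.set_size, tuple)
                else int(spec.set_size)
            )
            for d in diseases
        }
        members: dict = {}
        if spec.signed:
            (up_pool, up_bg), (dn_pool, dn_bg), _ = _signed_layouts(spec, config.n_classes)
            for d in diseases:
                s_up = _round_half_up(spec.up_fraction * sizes[d])
                s_dn = sizes[d] - s_up
                ci = class_of[d]
                up = _draw_set(
                    rng, f"{spec.name}:up", ci, up_pool, up_bg, s_up, spec.shared_fraction
                )
                down = _draw_set(
                    rng, f"{spec.name}:dn", ci, dn_pool, dn_bg, s_dn, spec.shared_fraction
                )
                members[d] = (up, down)
        else:
            pool, bg = _part_layout(spec, config.n_classes, spec.universe_size, spec.max_size())
            for d in diseases:
                members[d] = _draw_set(
                    rng, spec.name, class_of[d], pool, bg, sizes[d], spec.shared_fraction
                )
        spaces.append(
            FeatureSpace(name=spec.name, kind="signed" if spec.signed else "unsigned", members=members)
        )

    expected = {
        spec.name: {
            "within": expected_jaccard(config, spec, same_class=True),
            "between": expected_jaccard(config, spec, same_class=False),
        }
        for spec in config.spaces
    }
    truth = SyntheticTruth(labels=ClassLabels(labels=labels), expected=expected)
    return spaces, truth.labels, truth


# ---------------------------------------------------------------------------
# Closed-form expected Jaccard under the generative model
# ---------------------------------------------------------------------------

def _expected_pair(
    s_a: int, s_b: int, m_a: int, m_b: int, pool: int, background: int, same_class: bool
) -> float:
    """E[(X+Y)/(s_a+s_b-X-Y)] with X, Y independent hypergeometric overlaps
    of the class-pool and background draws."""
    if s_a == 0 or s_b == 0:
        return 0.0
    if same_class and m_a and m_b:
        xs = np.arange(0, min(m_a, m_b) + 1)
        px = hypergeom.pmf(xs, pool, m_a, m_b)
    else:
        xs, px = np.array([0]), np.array([1.0])
    r_a, r_b = s_a - m_a, s_b - m_b
    if r_a and r_b:
        ys = np.arange(0, min(r_a, r_b) + 1)
        py = hypergeom.pmf(ys, background, r_a, r_b)
    else:
        ys, py = np.array([0]), np.array([1.0])
    total = s_a + s_b
    inter = xs[:, None] + ys[None, :]
    vals = inter / (total - inter)
    return float((px[:, None] * py[None, :] * vals).sum())


def expected_jaccard(
    config: SyntheticConfig, spec: SpaceSpec, same_class: bool
) -> float:
    """Exact expected Jaccard index of a disease pair under the model.

    For variable set sizes the expectation is averaged over the uniform
    size distribution of the two diseases (independent).  For signed spaces
    the expectation is the size-weighted mean of the exact expectations of
    the up and down parts (part sizes are deterministic given the set
    sizes, so the weights factor out).
    """
    support = spec.size_support()
    probs = 1.0 / len(support)
    total = 0.0
    for s_a in support:
        for s_b in support:
            if spec.signed:
                (up_pool, up_bg), (dn_pool, dn_bg), _ = _signed_layouts(spec, config.n_classes)
                su_a = _round_half_up(spec.up_fraction * s_a)
                su_b = _round_half_up(spec.up_fraction * s_b)
                sd_a, sd_b = s_a - su_a, s_b - su_b
                e_up = _expected_pair(
                    su_a,
                    su_b,
                    _round_half_up(spec.shared_fraction * su_a),
                    _round_half_up(spec.shared_fraction * su_b),
                    up_pool,
                    up_bg,
                    same_class,
                )
                e_dn = _expected_pair(
                    sd_a,
                    sd_b,
                    _round_half_up(spec.shared_fraction * sd_a),
                    _round_half_up(spec.shared_fraction * sd_b),
                    dn_pool,
                    dn_bg,
                    same_class,
                )
                grand = su_a + su_b + sd_a + sd_b
                w_up = (su_a + su_b) / grand if grand else 0.0
                e = w_up * e_up + (1.0 - w_up) * e_dn
            else:
                pool, bg = _part_layout(spec, config.n_classes, spec.universe_size, spec.max_size())
                e = _expected_pair(
                    s_a,
                    s_b,
                    _round_half_up(spec.shared_fraction * s_a),
                    _round_half_up(spec.shared_fraction * s_b),
                    pool,
                    bg,
                    same_class,
                )
            total += probs * probs * e
    return total


# ---------------------------------------------------------------------------
# Ready-made profiles
# ---------------------------------------------------------------------------

def default_config(n_diseases: int = 84, seed: int | None = None) -> SyntheticConfig:
    """Six-space profile mirroring the shape of the real dataset.

    Set sizes (100, 21, 100, 100, 100 signed 60/40, Uniform[2, 15]) with
    strongly unequal universe sizes, so that raw similarity distributions
    differ by orders of magnitude between the dense ontological-like space
    and the sparse genetic-like space.  Per-space class signal is
    heterogeneous: the "traditional" spaces (ontological, phenotypic,
    literature) carry strong class-driven sharing, while the molecular
    spaces (genetic, transcriptomic) are noisy with only a trace of class
    signal — matching the real pattern where molecular similarities
    correlate weakly with everything else.  Four planted classes in
    proportions roughly 1/3, 1/4, 1/4, 1/6.
    """
    c1 = n_diseases // 3
    c2 = n_diseases // 4
    c3 = n_diseases // 4
    c4 = n_diseases - c1 - c2 - c3
    return SyntheticConfig(
        n_diseases=n_diseases,
        classes=(
            ("disease_of_anatomical_entity", c1),
            ("disease_of_cellular_proliferation", c2),
            ("disease_by_infectious_agent", c3),
            ("disease_of_mental_health", c4),
        ),
        spaces=(
            SpaceSpec("ontological", 100, 600, 0.35),
            SpaceSpec("phenotypic", 21, 400, 0.30),
            SpaceSpec("literature", 100, 2000, 0.30),
            SpaceSpec("genetic", 100, 4000, 0.03),
            SpaceSpec("transcriptomic", 100, 3000, 0.03, signed=True, up_fraction=0.6),
            SpaceSpec("drug", (2, 15), 300, 0.40),
        ),
        seed=seed,
    )


def desk_config(n_diseases: int = 30, seed: int | None = None) -> SyntheticConfig:
    """Small four-space, three-class profile with moderate planted effect,
    sized for fast planted-structure recovery experiments."""
    base = n_diseases // 3
    classes = (
        ("class_A", base),
        ("class_B", base),
        ("class_C", n_diseases - 2 * base),
    )
    return SyntheticConfig(
        n_diseases=n_diseases,
        classes=classes,
        spaces=(
            SpaceSpec("alpha", 30, 300, 0.30),
            SpaceSpec("beta", 30, 800, 0.30),
            SpaceSpec("gamma", 30, 600, 0.30, signed=True, up_fraction=0.6),
            SpaceSpec("delta", 10, 200, 0.35),
        ),
        seed=seed,
    )


def null_config(n_diseases: int = 20, seed: int | None = None) -> SyntheticConfig:
    """Profile with no planted structure (shared_fraction 0 everywhere),
    for null-calibration experiments."""
    base = n_diseases // 2
    return SyntheticConfig(
        n_diseases=n_diseases,
        classes=(("class_A", base), ("class_B", n_diseases - base)),
        spaces=(
            SpaceSpec("alpha", 20, 300, 0.0),
            SpaceSpec("beta", 20, 800, 0.0),
            SpaceSpec("gamma", 20, 500, 0.0, signed=True, up_fraction=0.6),
            SpaceSpec("delta", 8, 150, 0.0),
        ),
        seed=seed,
    )
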