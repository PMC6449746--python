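"""Feature spaces and auxiliary tables.

A *feature space* is one data type (ontological, phenotypic, literature
co-occurrence, genetic association, gene expression, drug indication, ...)
represented as a per-disease set of opaque feature identifiers.  Gene
expression is *signed*: each disease carries disjoint up- and down-regulated
sets.  The *feature universe* of a space is the union of all features across
diseases, with their occurrence counts; it is the sampling pool for the
randomization null model.

Feature identifiers are opaque strings and are never reconciled across
spaces — spaces are compared only through the similarities they induce.
"""

from __future__ import annotations

import csv
import json
import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

logger = logging.getLogger(__name__)

FrozenPair = tuple[frozenset, frozenset]
MemberSets = Union[frozenset, FrozenPair]


class SpaceFormatError(ValueError):
    """A feature-space file violates its declared format."""


class ValidationError(ValueError):
    """Feature-space content violates a structural invariant."""


@dataclass(frozen=True)
class FeatureSpace:
    """A named collection of per-disease feature sets.

    Parameters
    ----------
    name : str
        Short identifier (e.g. ``"literature"``).
    kind : {"unsigned", "signed"}
        Signed spaces store a pair ``(up, down)`` of disjoint sets per
        disease.
    members : mapping
        ``disease_id -> frozenset`` (unsigned) or
        ``disease_id -> (up: frozenset, down: frozenset)`` (signed).
    allow_empty : bool
        Permit empty feature sets (or empty signed parts).  Off by default:
        an empty set almost always indicates an upstream data problem.

    The feature universe (``feature -> number of diseases whose set(s)
    contain it``) is derived at construction and exposed as ``universe``.
    """

    name: str
    kind: str
    members: Mapping[str, MemberSets]
    allow_empty: bool = False
    universe: Mapping[str, int] = field(default=None, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("unsigned", "signed"):
            raise ValidationError(f"unknown space kind {self.kind!r}")
        frozen: dict[str, MemberSets] = {}
        counts: Counter = Counter()
        for disease, sets in self.members.items():
            if self.kind == "signed":
                up, down = (frozenset(sets[0]), frozenset(sets[1]))
                overlap = up & down
                if overlap:
                    raise ValidationError(
                        f"space {self.name!r}: disease {disease!r} has features "
                        f"in both up and down sets: {sorted(overlap)[:5]}"
                    )
                if not self.allow_empty and (not up or not down):
                    raise ValidationError(
                        f"space {self.name!r}: disease {disease!r} has an empty "
                        "signed part (pass allow_empty=True to permit)"
                    )
                frozen[disease] = (up, down)
                counts.update(up | down)
            else:
                fset = frozenset(sets)
                if not self.allow_empty and not fset:
                    raise ValidationError(
                        f"space {self.name!r}: disease {disease!r} has an empty "
                        "feature set (pass allow_empty=True to permit)"
                    )
                frozen[disease] = fset
                counts.update(fset)
        object.__setattr__(self, "members", frozen)
        object.__setattr__(self, "universe", dict(counts))

    @property
    def diseases(self) -> list[str]:
        """Member disease identifiers, lexicographically sorted."""
        return sorted(self.members)

    def feature_set(self, disease: str) -> MemberSets:
        return self.members[disease]

    def set_size(self, disease: str) -> int:
        """Total feature-set size (up + down for signed spaces)."""
        if self.kind == "signed":
            up, down = self.members[disease]
            return len(up) + len(down)
        return len(self.members[disease])


@dataclass(frozen=True)
class ClassLabels:
    """Per-disease top-level class membership (possibly multiple or none)."""

    labels: Mapping[str, frozenset]
    vocabulary: frozenset = frozenset()

    def __post_init__(self) -> None:
        frozen = {d: frozenset(c) for d, c in self.labels.items()}
        vocab = frozenset(self.vocabulary) or frozenset(
            c for cs in frozen.values() for c in cs
        )
        unknown = {c for cs in frozen.values() for c in cs} - vocab
        if unknown:
            raise ValidationError(f"class ids outside declared vocabulary: {sorted(unknown)}")
        object.__setattr__(self, "labels", frozen)
        object.__setattr__(self, "vocabulary", vocab)

    def classes_of(self, disease: str) -> frozenset:
        return self.labels.get(disease, frozenset())


@dataclass(frozen=True)
class ComorbidityTable:
    """Unordered disease pairs mapped to comorbidity relative risk (> 0)."""

    entries: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        frozen: dict[tuple[str, str], float] = {}
        for pair, rr in self.entries.items():
            a, b = sorted(pair)
            if a == b:
                raise ValidationError(f"self-pair {a!r} in comorbidity table")
            if rr <= 0:
                raise ValidationError(f"non-positive relative risk for pair ({a}, {b})")
            if (a, b) in frozen:
                raise ValidationError(f"duplicate pair ({a}, {b})")
            frozen[(a, b)] = float(rr)
        object.__setattr__(self, "entries", frozen)

    def get(self, a: str, b: str) -> float | None:
        return self.entries.get(tuple(sorted((a, b))))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_feature_space(
    path: str | Path,
    kind: str = "unsigned",
    fmt: str | None = None,
    name: str | None = None,
    allow_empty: bool = False,
) -> FeatureSpace:
    """Read a feature space from TSV or JSON.

    TSV columns: ``disease_id<TAB>feature_id[<TAB>sign]`` with a header row;
    ``sign`` (``up``/``down``) is required for signed spaces.  JSON carries
    an object with ``name``, ``kind`` and ``members``.  Duplicate
    (disease, feature) rows collapse to one membership with a logged
    warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        return _read_space_json(path, allow_empty=allow_empty)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")

    members_unsigned: dict[str, set] = {}
    members_up: dict[str, set] = {}
    members_down: dict[str, set] = {}
    n_dupes = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SpaceFormatError(f"{path}: empty file") from None
        expected = ["disease_id", "feature_id"] + (["sign"] if kind == "signed" else [])
        if [h.strip() for h in header[: len(expected)]] != expected:
            raise SpaceFormatError(
                f"{path}: line 1: expected header {expected}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if kind == "signed":
                if len(row) < 3 or not row[2].strip():
                    raise SpaceFormatError(f"{path}: line {lineno}: signed row missing sign")
                disease, feature, sign = row[0].strip(), row[1].strip(), row[2].strip()
                if sign not in ("up", "down"):
                    raise SpaceFormatError(
                        f"{path}: line {lineno}: sign must be 'up' or 'down', got {sign!r}"
                    )
                if not disease or not feature:
                    raise SpaceFormatError(f"{path}: line {lineno}: malformed row {row!r}")
                target = members_up if sign == "up" else members_down
                bucket = target.setdefault(disease, set())
                if feature in bucket:
                    n_dupes += 1
                bucket.add(feature)
                members_up.setdefault(disease, set())
                members_down.setdefault(disease, set())
            else:
                if len(row) < 2 or not row[0].strip() or not row[1].strip():
                    raise SpaceFormatError(f"{path}: line {lineno}: malformed row {row!r}")
                disease, feature = row[0].strip(), row[1].strip()
                bucket = members_unsigned.setdefault(disease, set())
                if feature in bucket:
                    n_dupes += 1
                bucket.add(feature)
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate membership rows", path, n_dupes)

    if kind == "signed":
        members = {
            d: (frozenset(members_up.get(d, ())), frozenset(members_down.get(d, ())))
            for d in set(members_up) | set(members_down)
        }
    else:
        members = {d: frozenset(s) for d, s in members_unsigned.items()}
    return FeatureSpace(
        name=name or path.stem, kind=kind, members=members, allow_empty=allow_empty
    )


def _read_space_json(path: Path, allow_empty: bool = False) -> FeatureSpace:
    with path.open(encoding="utf-8") as fh:
        obj = json.load(fh)
    kind = obj.get("kind", "unsigned")
    raw = obj["members"]
    if kind == "signed":
        members = {
            d: (frozenset(v["up"]), frozenset(v["down"])) for d, v in raw.items()
        }
    else:
        members = {d: frozenset(v) for d, v in raw.items()}
    return FeatureSpace(
        name=obj.get("name", path.stem), kind=kind, members=members, allow_empty=allow_empty
    )


def write_feature_space(space: FeatureSpace, path: str | Path, fmt: str | None = None) -> None:
    """Write a feature space as TSV or JSON (inverse of :func:`read_feature_space`)."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        if space.kind == "signed":
            members = {
                d: {"up": sorted(up), "down": sorted(down)}
                for d, (up, down) in sorted(space.members.items())
            }
        else:
            members = {d: sorted(s) for d, s in sorted(space.members.items())}
        path.write_text(
            json.dumps({"name": space.name, "kind": space.kind, "members": members}, indent=1)
            + "\n",
            encoding="utf-8",
        )
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if space.kind == "signed":
            writer.writerow(["disease_id", "feature_id", "sign"])
            for d in space.diseases:
                up, down = space.members[d]
                for f in sorted(up):
                    writer.writerow([d, f, "up"])
                for f in sorted(down):
                    writer.writerow([d, f, "down"])
        else:
            writer.writerow(["disease_id", "feature_id"])
            for d in space.diseases:
                for f in sorted(space.members[d]):
                    writer.writerow([d, f])


def read_class_labels(path: str | Path) -> ClassLabels:
    """Read a two-column ``disease_id<TAB>class_id`` table (header row, one
    row per membership; a disease may appear several times)."""
    path = Path(path)
    labels: dict[str, set] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["disease_id", "class_id"]:
            raise SpaceFormatError(f"{path}: expected header disease_id<TAB>class_id")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise SpaceFormatError(f"{path}: line {lineno}: malformed row {row!r}")
            labels.setdefault(row[0].strip(), set()).add(row[1].strip())
    return ClassLabels(labels=labels)


def write_class_labels(labels: ClassLabels, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["disease_id", "class_id"])
        for d in sorted(labels.labels):
            for c in sorted(labels.labels[d]):
                writer.writerow([d, c])


def read_comorbidity(path: str | Path) -> ComorbidityTable:
    """Read ``disease_a<TAB>disease_b<TAB>relative_risk``.

    Duplicate unordered pairs keep the maximum relative risk (logged) —
    comorbidity sources mapped onto a different disease vocabulary can
    produce several records per pair.
    """
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}
    n_dupes = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "disease_a",
            "disease_b",
            "relative_risk",
        ]:
            raise SpaceFormatError(
                f"{path}: expected header disease_a<TAB>disease_b<TAB>relative_risk"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise SpaceFormatError(f"{path}: line {lineno}: malformed row {row!r}")
            try:
                rr = float(row[2])
            except ValueError:
                raise SpaceFormatError(
                    f"{path}: line {lineno}: relative_risk not numeric: {row[2]!r}"
                ) from None
            pair = tuple(sorted((row[0].strip(), row[1].strip())))
            if pair in entries:
                n_dupes += 1
                entries[pair] = max(entries[pair], rr)
            else:
                entries[pair] = rr
    if n_dupes:
        logger.warning("%s: %d duplicate pairs collapsed, keeping max relative risk", path, n_dupes)
    return ComorbidityTable(entries=entries)


# ---------------------------------------------------------------------------
# Collection validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CollectionReport:
    """Cross-space validation summary.

    ``common_diseases`` (lexicographic) is the disease list every downstream
    matrix uses; diseases missing from any space are excluded rather than
    imputed, and reported per space in ``missing``.
    """

    common_diseases: tuple[str, ...]
    missing: Mapping[str, tuple[str, ...]]
    size_summary: Mapping[str, Mapping[str, float]]


def validate_collection(spaces: Sequence[FeatureSpace]) -> CollectionReport:
    """Validate a collection of spaces and derive the shared disease list.

    Raises ``ValidationError`` when fewer than 3 diseases are common to all
    spaces (no meaningful pairwise analysis is possible below that).
    """
    if not spaces:
        raise ValidationError("no feature spaces given")
    all_diseases = set().union(*(set(s.members) for s in spaces))
    common = set(spaces[0].members)
    for s in spaces[1:]:
        common &= set(s.members)
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} diseases common to all spaces; need at least 3"
        )
    missing = {
        s.name: tuple(sorted(all_diseases - set(s.members))) for s in spaces
    }
    for name, absent in missing.items():
        if absent:
            logger.warning(
                "space %r lacks %d disease(s): %s%s",
                name,
                len(absent),
                ", ".join(absent[:5]),
                "..." if len(absent) > 5 else "",
            )
    summary = {}
    for s in spaces:
        sizes = [s.set_size(d) for d in s.diseases]
        summary[s.name] = {
            "n_diseases": len(sizes),
            "min": float(min(sizes)),
            "median": float(statistics.median(sizes)),
            "max": float(max(sizes)),
        }
    return CollectionReport(
        common_diseases=tuple(sorted(common)), missing=missing, size_summary=summary
    )
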