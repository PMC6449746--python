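"""Thresholded disease network ("disease map") construction and export.

Edges are disease pairs whose fused similarity is strictly above the
significance threshold; each edge carries the fused score and the per-space
normalized scores behind it.  An edge is *novel* when the two diseases
share no top-level ontology class.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .similarity import SimilarityMatrix
from .spaces import ClassLabels, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    """One above-threshold disease pair. ``novel`` is None until annotated
    (or when either disease lacks class labels)."""

    a: str
    b: str
    fused: float
    per_space: Mapping[str, float]
    novel: bool | None = None


@dataclass(frozen=True)
class DiseaseMap:
    diseases: tuple[str, ...]
    edges: tuple[Edge, ...]
    threshold: float
    provenance: dict = field(default_factory=dict)
    novel_fraction: float | None = None

    @property
    def nodes(self) -> tuple[str, ...]:
        """Diseases with at least one edge."""
        connected = {e.a for e in self.edges} | {e.b for e in self.edges}
        return tuple(d for d in self.diseases if d in connected)

    @property
    def isolated(self) -> tuple[str, ...]:
        """Diseases with no significant link to any other disease."""
        connected = set(self.nodes)
        return tuple(d for d in self.diseases if d not in connected)

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((e.a, e.b))) for e in self.edges}


def build_map(
    fused: SimilarityMatrix,
    per_space: Sequence[SimilarityMatrix],
    threshold: float,
    provenance: dict | None = None,
) -> DiseaseMap:
    """Keep disease pairs whose fused score is strictly above ``threshold``.

    ``per_space`` are the normalized single-space matrices behind the
    fusion; their scores are attached to every edge.  Isolated diseases
    (no significant link) are reported via :attr:`DiseaseMap.isolated`.
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    for m in per_space:
        if m.diseases != fused.diseases:
            raise ValidationError("per-space matrix disease list differs from fused")
    pairs = fused.pair_index()
    fused_vec = fused.pair_vector()
    space_vecs = {m.space_name: m.pair_vector() for m in per_space}
    edges = []
    for k, (a, b) in enumerate(pairs):
        if fused_vec[k] > threshold:
            edges.append(
                Edge(
                    a=a,
                    b=b,
                    fused=float(fused_vec[k]),
                    per_space={name: float(vec[k]) for name, vec in space_vecs.items()},
                )
            )
    dmap = DiseaseMap(
        diseases=fused.diseases,
        edges=tuple(edges),
        threshold=float(threshold),
        provenance=dict(provenance or {}),
    )
    if dmap.isolated:
        logger.info(
            "%d disease(s) show no significant links: %s",
            len(dmap.isolated),
            ", ".join(dmap.isolated[:5]),
        )
    return dmap


def annotate_novelty(dmap: DiseaseMap, labels: ClassLabels) -> DiseaseMap:
    """Flag edges whose diseases share no top-level class.

    Multi-label rule: an edge is novel iff the intersection of the two
    diseases' class sets is empty.  Edges where either disease has no
    label stay ``novel=None`` and are excluded from ``novel_fraction``.
    """
    uncovered = [d for d in dmap.nodes if not labels.classes_of(d)]
    if uncovered:
        logger.warning(
            "%d mapped disease(s) lack class labels: %s",
            len(uncovered),
            ", ".join(uncovered[:5]),
        )
    edges = []
    n_defined = n_novel = 0
    for e in dmap.edges:
        ca, cb = labels.classes_of(e.a), labels.classes_of(e.b)
        if not ca or not cb:
            edges.append(replace(e, novel=None))
            continue
        novel = len(ca & cb) == 0
        n_defined += 1
        n_novel += novel
        edges.append(replace(e, novel=novel))
    fraction = (n_novel / n_defined) if n_defined else None
    return replace(dmap, edges=tuple(edges), novel_fraction=fraction)


def _space_names(dmap: DiseaseMap) -> list[str]:
    names: list[str] = []
    for e in dmap.edges:
        for n in e.per_space:
            if n not in names:
                names.append(n)
    return names


def export_map(dmap: DiseaseMap, path: str | Path, fmt: str = "edge-tsv") -> None:
    """Write the map as an edge-list TSV or GraphML, plus a provenance
    sidecar JSON (threshold, fusion weights, seeds)."""
    path = Path(path)
    spaces = _space_names(dmap)
    if fmt == "edge-tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["disease_a", "disease_b", "fused_score"]
                + [f"score_{s}" for s in spaces]
                + ["novel"]
            )
            for e in dmap.edges:
                writer.writerow(
                    [e.a, e.b, format(e.fused, ".6g")]
                    + [format(e.per_space.get(s, float("nan")), ".6g") for s in spaces]
                    + ["" if e.novel is None else str(e.novel).lower()]
                )
    elif fmt == "graphml":
        graph = nx.Graph()
        graph.add_nodes_from(dmap.nodes)
        for e in dmap.edges:
            attrs = {"fused_score": e.fused}
            attrs.update({f"score_{s}": v for s, v in e.per_space.items()})
            if e.novel is not None:
                attrs["novel"] = e.novel
            graph.add_edge(e.a, e.b, **attrs)
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    sidecar = {
        "threshold": dmap.threshold,
        "n_edges": len(dmap.edges),
        "isolated": list(dmap.isolated),
        "novel_fraction": dmap.novel_fraction,
        "provenance": dmap.provenance,
    }
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=1) + "\n", encoding="utf-8"
    )


def read_edge_tsv(path: str | Path) -> list[Edge]:
    """Read back an edge-list TSV written by :func:`export_map`."""
    path = Path(path)
    edges = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        space_cols = [
            (i, h[len("score_"):]) for i, h in enumerate(header) if h.startswith("score_")
        ]
        novel_col = header.index("novel")
        for row in reader:
            if not row:
                continue
            novel_raw = row[novel_col]
            novel = None if novel_raw == "" else novel_raw == "true"
            edges.append(
                Edge(
                    a=row[0],
                    b=row[1],
                    fused=float(row[2]),
                    per_space={name: float(row[i]) for i, name in space_cols},
                    novel=novel,
                )
            )
    return edges
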