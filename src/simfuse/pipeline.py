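"""End-to-end pipeline: read → similarity → normalize → fuse → null → map → evaluate.

Driven by a *run manifest* (JSON) that pins input paths, fusion weights,
null-model parameters and the global seed, so any run is reproducible
bit-for-bit from the manifest alone.  Per-stage seeds are derived
deterministically from the global seed, so individual stages rerun
identically.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .diseasemap import annotate_novelty, build_map, export_map
from .evaluation import class_prediction, comorbidity_comparison, drug_overlap_curve
from .fusion import FusionConfig, normalize_and_fuse
from .nullmodel import null_distribution, significance_threshold, write_null_tsv
from .similarity import similarity_matrix, write_matrix_tsv
from .spaces import (
    read_class_labels,
    read_comorbidity,
    read_feature_space,
    validate_collection,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage_seed(global_seed: int | None, stage_index: int) -> int | None:
    if global_seed is None:
        return None
    ss = np.random.SeedSequence(global_seed).spawn(stage_index + 1)[stage_index]
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(manifest: dict | str | Path, outdir: str | Path) -> Path:
    """Execute the full pipeline described by a manifest.

    Manifest keys: ``spaces`` (list of ``{"name", "path", "kind", "format"}``),
    optional ``weights`` (parallel to spaces; uniform when omitted),
    ``null`` (``{"iterations", "percentile"}``), optional ``labels`` and
    ``comorbidity`` paths, optional ``holdout_drug_space`` name, and
    ``seed``.  Writes per-space raw/normalized matrices, the fused matrix,
    the null TSV and threshold, map exports, evaluation TSVs, and a result
    manifest with per-output checksums.  Halts with a stage-named
    :class:`PipelineError` on failure, leaving that stage's outputs with a
    ``.partial`` suffix.
    """
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text(encoding="utf-8"))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = manifest.get("seed")
    written: dict[str, list[Path]] = {}

    def stage(name: str):
        written[name] = []

        class _Ctx:
            def __enter__(self_inner):
                return written[name]

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    for p in written[name]:
                        if p.exists():
                            p.rename(p.with_name(p.name + ".partial"))
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    # --- read & validate -------------------------------------------------
    with stage("read"):
        space_specs = manifest["spaces"]
        spaces = [
            read_feature_space(
                s["path"], kind=s.get("kind", "unsigned"), fmt=s.get("format"), name=s["name"]
            )
            for s in space_specs
        ]
        report = validate_collection(spaces)
        diseases = report.common_diseases

    weights = manifest.get("weights")
    names = [s.name for s in spaces]
    config = (
        FusionConfig(tuple(names), tuple(weights))
        if weights is not None
        else FusionConfig.uniform(names)
    )

    # --- similarity -------------------------------------------------------
    with stage("similarity") as outputs:
        raw = [similarity_matrix(s, diseases) for s in spaces]
        for m in raw:
            p = outdir / f"raw_{m.space_name}.tsv"
            write_matrix_tsv(m, p)
            outputs.extend([p, Path(str(p) + ".meta.json")])

    # --- normalize & fuse -------------------------------------------------
    with stage("fusion") as outputs:
        fused, normalized = normalize_and_fuse(raw, config)
        for m in normalized:
            p = outdir / f"normalized_{m.space_name}.tsv"
            write_matrix_tsv(m, p)
            outputs.extend([p, Path(str(p) + ".meta.json")])
        p = outdir / "fused.tsv"
        write_matrix_tsv(fused, p)
        outputs.extend([p, Path(str(p) + ".meta.json")])

    # --- null model & threshold -------------------------------------------
    null_params = manifest.get("null", {})
    n_iter = int(null_params.get("iterations", 1000))
    percentile = float(null_params.get("percentile", 99.99))
    with stage("null") as outputs:
        null = null_distribution(
            spaces, config, n_iterations=n_iter, seed=_stage_seed(seed, 0), diseases=diseases
        )
        thr = significance_threshold(null, percentile)
        p = outdir / "null.tsv"
        write_null_tsv(null, p)
        outputs.extend([p, Path(str(p) + ".meta.json")])

    # --- disease map -------------------------------------------------------
    with stage("map") as outputs:
        provenance = {
            "threshold": thr.threshold,
            "percentile": percentile,
            "iteration_max_exceedance": thr.iteration_max_exceedance,
            "null_iterations": n_iter,
            "seed": seed,
            "spaces": list(config.space_names),
            "weights": list(config.weights),
            "version": __version__,
        }
        dmap = build_map(fused, normalized, thr.threshold, provenance=provenance)
        labels = None
        if manifest.get("labels"):
            labels = read_class_labels(manifest["labels"])
            dmap = annotate_novelty(dmap, labels)
        for fmt, fname in (("edge-tsv", "map_edges.tsv"), ("graphml", "map.graphml")):
            p = outdir / fname
            export_map(dmap, p, fmt=fmt)
            outputs.extend([p, Path(str(p) + ".meta.json")])

    # --- evaluations --------------------------------------------------------
    eval_params = manifest.get("evaluation", {})
    holdout = manifest.get("holdout_drug_space")
    if holdout:
        with stage("evaluate-drugs") as outputs:
            drug_space = next(s for s in spaces if s.name == holdout)
            non_drug = [n for n in names if n != holdout]
            sub_config = FusionConfig.uniform(non_drug)
            sub_raw = [m for m in raw if m.space_name != holdout]
            sub_fused, _ = normalize_and_fuse(sub_raw, sub_config)
            curve = drug_overlap_curve(sub_fused, drug_space)
            p = outdir / "drug_overlap.tsv"
            with p.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["level", "threshold", "mean_overlap", "n_links"])
                for q, t, mo, nl in zip(
                    curve.levels, curve.thresholds, curve.mean_overlap, curve.n_links
                ):
                    writer.writerow([q, format(t, ".6g"), format(mo, ".6g"), nl])
            outputs.append(p)
    if manifest.get("labels") and eval_params.get("class_tasks"):
        with stage("evaluate-classes") as outputs:
            rows = []
            for task in eval_params["class_tasks"]:
                result = class_prediction(
                    fused,
                    labels,
                    task,
                    n_runs=int(eval_params.get("runs", 1000)),
                    train_fraction=float(eval_params.get("train_fraction", 0.8)),
                    seed=_stage_seed(seed, 1),
                )
                rows.append((task, result.auroc_mean, result.n_runs))
            p = outdir / "class_prediction.tsv"
            with p.open("w", newline="", encoding="utf-8") as fh:
                writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
                writer.writerow(["task", "auroc_mean", "n_runs"])
                for row in rows:
                    writer.writerow(row)
            outputs.append(p)
    if manifest.get("comorbidity"):
        with stage("evaluate-comorbidity") as outputs:
            table = read_comorbidity(manifest["comorbidity"])
            summary = comorbidity_comparison(dmap, table)
            p = outdir / "comorbidity.json"
            p.write_text(
                json.dumps(
                    {
                        "coverage_ok": summary.coverage_ok,
                        "n_linked_covered": summary.n_linked_covered,
                        "n_nonlinked_covered": summary.n_nonlinked_covered,
                        "median_rr_linked": summary.median_rr_linked,
                        "median_rr_nonlinked": summary.median_rr_nonlinked,
                        "fractions_above": {
                            str(k): list(v) for k, v in summary.fractions_above.items()
                        },
                    },
                    indent=1,
                )
                + "\n",
                encoding="utf-8",
            )
            outputs.append(p)

    # --- result manifest -----------------------------------------------------
    result = {
        "version": __version__,
        "seed": seed,
        "config": {"spaces": list(config.space_names), "weights": list(config.weights)},
        "threshold": thr.threshold,
        "percentile": percentile,
        "diseases": list(diseases),
        "checksums": {
            str(p.relative_to(outdir)): _checksum(p)
            for ps in written.values()
            for p in ps
            if p.exists()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(result, indent=1) + "\n", encoding="utf-8"
    )
    return outdir
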