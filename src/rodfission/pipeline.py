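"""End-to-end orchestration: synthesize, render, measure, analyse, report.

``run_pipeline`` executes the stages in order, writes every intermediate
table under the configured output directory, and returns a manifest with
per-stage record counts.  Identical configuration and seed give
byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from rodfission import divsite, morphometry, popgen, taxmark
from rodfission.errors import ConfigurationError, RodfissionError

log = logging.getLogger("rodfission")


@dataclass
class RunConfig:
    population: popgen.PopulationConfig = field(
        default_factory=popgen.PopulationConfig
    )
    image: Optional[popgen.ImageSpec] = None
    morphometry: morphometry.MorphometryParams = field(
        default_factory=morphometry.MorphometryParams
    )
    analysis: divsite.AnalysisConfig = field(default_factory=divsite.AnalysisConfig)
    thresholds: taxmark.RankThresholds = field(default_factory=taxmark.RankThresholds)
    output_dir: str = "rodfission_out"
    seed: Optional[int] = None
    log_level: str = "INFO"


def _config_hash(config: RunConfig) -> str:
    text = repr(config).encode()
    return hashlib.sha256(text).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run synth -> render/measure -> analyse -> taxmark -> report.

    Returns the manifest (also written to ``manifest.json``): config hash,
    seed, and a per-stage status with record counts.  A missing seed is a
    configuration error raised before any stage runs.
    """
    if config.seed is None:
        raise ConfigurationError("run_pipeline: a seed is mandatory")
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
    }

    def _stage(name, fn):
        try:
            count = fn()
        except RodfissionError as exc:
            manifest["stages"].append(
                {"stage": name, "status": "failed", "error": str(exc)}
            )
            _write_manifest(manifest, out)
            raise RodfissionError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"stage": name, "status": "ok", "n": count})
        log.info("[%s] ok (n=%d)", name, count)

    state: dict = {}

    def synth():
        pop_cfg = popgen.PopulationConfig(
            **{**config.population.__dict__, "seed": config.seed}
        )
        cells = popgen.sample_population(pop_cfg)
        records = popgen.observe_measurements(cells, pop_cfg)
        popgen.write_truth_csv(cells, out / "truth.csv")
        popgen.write_measurements_csv(records, out / "measurements.csv")
        state["cells"], state["records"] = cells, records
        return len(cells)

    def measure():
        if config.image is None:
            state["shape_records"] = []
            return 0
        # render a small subset: imaging-scale scenes hold few cells each
        cells = state["cells"][: min(12, len(state["cells"]))]
        scene = popgen.render_population_image(cells, config.image,
                                               seed=config.seed)
        popgen.write_scene(scene, out / "scene.tif", out / "scene_mask.tif",
                           out / "scene_truth.csv")
        records = morphometry.measure_scene(
            scene.image, scene.pixel_size, config.morphometry
        )
        morphometry.records_to_frame(records).to_csv(
            out / "shape_records.csv", index=False
        )
        if records:
            morphometry.summarize_population(records).to_csv(
                out / "shape_summary.csv", index=False
            )
        state["shape_records"] = records
        return len(records)

    def analyse():
        if not state["records"]:
            raise RodfissionError("no dividing cells to analyse")
        model = divsite.DivisionSiteModel(state["records"], config.analysis)
        res = model.fit()
        res.records_frame().to_csv(out / "division_records.csv", index=False)
        res.class_lines.to_csv(out / "class_slopes.csv", index=False)
        res.density.to_csv(out / "density.csv", index=False)
        _dump_json(
            {
                "modes": res.modes,
                "model_comparison": _jsonable(res.model_comparison),
            },
            out / "divsite_report.json",
        )
        (out / "divsite_summary.txt").write_text(res.summary() + "\n")
        state["divsite"] = res
        return res.n_cells

    def taxmark_stage():
        features = taxmark.genome_feature_summary(
            taxmark.REFERENCE_GENOME_SUMMARIES
        )
        features.to_csv(out / "genome_features.csv", index=False)
        diffs = taxmark.genome_size_differences(
            taxmark.REFERENCE_GENOME_SUMMARIES
        )
        diffs.to_csv(out / "genome_size_differences.csv", index=False)
        return len(features)

    def report():
        n = sum(s.get("n", 0) for s in manifest["stages"])
        return n

    _stage("synth", synth)
    _stage("measure", measure)
    _stage("analyse", analyse)
    _stage("taxmark", taxmark_stage)
    _stage("report", report)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    _dump_json(manifest, out / "manifest.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _dump_json(data, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("measurements", "images", "alignment", "hits")

TOY_ALIGNMENT = {
    "taxonA": "ATGCGTACGTTAGCATGCGTACGTTAGCATGCGTACGTTAGCATGCGTACGTTAGC",
    "taxonB": "ATGCGTACGTTAGCATGCGTACGTTAGCATGCGTACGTTAGCATGCGTACGTTAGG",
    "taxonC": "ATGCGAACGTTAGCATGCGAACGTTAGCATGCGAACGTTAGCATGCGAACGTTAGC",
    "taxonD": "ATGAGTACGTAAGCATGAGTACGTAAGCATGAGTACGTAAGCATGAGTACGTAAGC",
    "taxonE": "TTGCGTACGTTACCATGCGTACGTTACCTTGCGTACGTTACCATGCGTACGTTACC",
}

# reciprocal toy hit tables: proteome A has 4 proteins (2 conserved in B),
# proteome B has 6 proteins (3 conserved in A) -> POCP = 5/10 = 50.0%
TOY_HITS_AB = [
    # conserving hits
    ("a1", "b1", 1e-30, 75.0, 200, 250),
    ("a2", "b2", 1e-12, 55.0, 180, 300),
    # rejected: identity too low / too short / e-value too high
    ("a3", "b3", 1e-40, 30.0, 200, 220),
    ("a4", "b4", 1e-20, 80.0, 90, 260),
]
TOY_HITS_BA = [
    ("b1", "a1", 1e-28, 70.0, 210, 240),
    ("b2", "a2", 1e-10, 60.0, 190, 310),
    ("b3", "a4", 1e-15, 45.0, 160, 280),
    ("b4", "a3", 1e-2, 90.0, 200, 230),   # e-value too high
]
TOY_QUERY_LENGTHS = {"a1": 250, "a2": 300, "a3": 220, "a4": 260,
                     "b1": 240, "b2": 310, "b3": 280, "b4": 230,
                     "b5": 150, "b6": 175}
TOY_PROTEOME_SIZES = {"A": 4, "B": 6}


def toy_alignment_hits():
    """The bundled toy hit tables as AlignmentHit lists (A->B, B->A)."""
    def build(rows):
        return [
            taxmark.AlignmentHit(q, s, ev, pid, al, ql)
            for q, s, ev, pid, al, ql in rows
        ]

    return build(TOY_HITS_AB), build(TOY_HITS_BA)


def make_fixtures(kind: str, seed: int = 0, out_dir: str = "fixtures") -> list[str]:
    """Write small versioned test fixtures; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    if kind == "measurements":
        cells, records = popgen.make_reference_measurements(seed=seed)
        path = out / "measurements_300.csv"
        popgen.write_measurements_csv(records, path)
        truth = out / "measurements_300_truth.csv"
        popgen.write_truth_csv(cells, truth)
        written += [str(path), str(truth)]
    elif kind == "images":
        cells = [
            popgen.TrueCell("cellA", 3.0, 0.5),
            popgen.TrueCell("cellB", 6.0, 0.5, division_fraction=1.0 / 3.0),
            popgen.TrueCell("cellC", 0.8, 0.8, is_sphere=True),
        ]
        spec = popgen.ImageSpec(noise_sigma=0.0, image_shape=(512, 512))
        scene = popgen.render_population_image(cells, spec, seed=seed)
        popgen.write_scene(scene, out / "threecell.tif",
                           out / "threecell_mask.tif",
                           out / "threecell_truth.csv")
        written += [str(out / "threecell.tif"), str(out / "threecell_mask.tif"),
                    str(out / "threecell_truth.csv")]
    elif kind == "alignment":
        path = out / "toy_alignment.fasta"
        path.write_text(
            "".join(f">{name}\n{row}\n" for name, row in TOY_ALIGNMENT.items())
        )
        written.append(str(path))
    elif kind == "hits":
        for name, rows in (("hits_ab.tsv", TOY_HITS_AB), ("hits_ba.tsv", TOY_HITS_BA)):
            path = out / name
            lines = []
            for q, s, ev, pid, al, _ in rows:
                lines.append(
                    f"{q}\t{s}\t{pid}\t{al}\t0\t0\t1\t{al}\t1\t{al}\t{ev}\t100.0"
                )
            path.write_text("\n".join(lines) + "\n")
            written.append(str(path))
        qlen = out / "query_lengths.tsv"
        qlen.write_text(
            "".join(f"{k}\t{v}\n" for k, v in TOY_QUERY_LENGTHS.items())
        )
        written.append(str(qlen))
    else:
        raise ConfigurationError(
            f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}"
        )
    return written
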