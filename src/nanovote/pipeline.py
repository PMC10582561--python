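"""End-to-end orchestration: simulate -> analyze -> pixels -> train ->
vote -> importance -> theory.

Every stage is a pure function of (inputs, config, seed); the
:class:`RunConfig` gathers all knobs and is serialised alongside each
run's outputs, so a run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import forcecurve, mapbuild, classifier, voting, importance as importance_mod
from .forcecurve import ProbeSpec
from .mapbuild import NanomechMap
from .synthdata import (
    AcquisitionSpec,
    DEFAULT_PROFILES,
    HARD_PROFILES,
    SyntheticCell,
    generate_dataset,
    synthesize_map_curves,
)

__all__ = ["RunConfig", "PipelineReport", "analyze_cell", "run_pipeline"]


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    n_per_class: int = 30
    grid: int = 32
    seed: int = 0
    profile_set: str = "default"  # "default" or "hard"
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    height_threshold: float = 200.0
    split_ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    mlp: classifier.MLPSpec = field(default_factory=classifier.MLPSpec)
    weight_params: voting.WeightParams = field(default_factory=voting.WeightParams)
    importance_rounds: int = 200
    theory_threshold: float = 0.999
    output_dir: str | None = None

    def resolved(self) -> dict:
        d = asdict(self)
        return d

    @property
    def profiles(self):
        return DEFAULT_PROFILES if self.profile_set == "default" else HARD_PROFILES


@dataclass
class PipelineReport:
    """Artifacts of one run (arrays in memory; CSV/JSON on disk when an
    output directory was configured)."""

    config: RunConfig
    pixel_table: pd.DataFrame
    splits: dict[str, list[str]]
    model: classifier.TrainedModel
    pixel_confusion: np.ndarray
    cell_confusion: np.ndarray
    outcomes: list[voting.VotingOutcome]
    importance: importance_mod.ImportanceResult | None
    theory: dict[str, dict]
    timings: dict[str, float]


def analyze_cell(
    cell: SyntheticCell,
    probe: ProbeSpec,
    acq: AcquisitionSpec,
    height_threshold: float = 200.0,
) -> NanomechMap:
    """Forward-simulate the cell's force-volume grid and run the full
    curve analysis back over it, producing a labelled channel map."""
    curves, flagged = synthesize_map_curves(cell, probe, acq)
    channels, valid = forcecurve.process_map(
        curves, cell.height.shape, probe, acq.reference_altitude
    )
    valid &= ~flagged
    nmap = NanomechMap(
        channels=channels, valid=valid, label=cell.label, cell_id=cell.cell_id
    )
    nmap.mask = mapbuild.segment_cell(nmap, height_threshold)
    return nmap


def _split_records(table: pd.DataFrame, splits: dict[str, list[str]]):
    out = {}
    for name, ids in splits.items():
        out[name] = table[table["cell_id"].isin(ids)].reset_index(drop=True)
    return out


def run_pipeline(config: RunConfig, progress: bool = False) -> PipelineReport:
    """Execute all stages on a synthetic dataset and collect the report.

    Raises ``ValueError`` before training when a split receives no cells
    or a class is missing from the training split.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    cells, manifest = generate_dataset(
        config.n_per_class, seed=config.seed, grid=config.grid,
        profiles=config.profiles,
    )
    timings["simulate"] = time.perf_counter() - t0

    t = time.perf_counter()
    maps = []
    for i, cell in enumerate(cells):
        maps.append(
            analyze_cell(cell, config.probe, config.acquisition, config.height_threshold)
        )
        if progress and (i + 1) % 10 == 0:
            print(f"analyzed {i + 1}/{len(cells)} maps")
    timings["analyze"] = time.perf_counter() - t

    t = time.perf_counter()
    table = mapbuild.build_pixel_table(maps)
    timings["pixels"] = time.perf_counter() - t

    train_ids, val_ids, test_ids = mapbuild.split_by_cell(
        [m.cell_id for m in maps], config.split_ratios, seed=config.seed
    )
    splits = {"train": train_ids, "val": val_ids, "test": test_ids}
    records = _split_records(table, splits)
    for name, recs in records.items():
        if len(recs) == 0:
            raise ValueError(f"{name} split contains no pixels")

    norm = mapbuild.fit_normalizer(records["train"])
    normed = {k: norm.transform(v) for k, v in records.items()}

    t = time.perf_counter()
    model = classifier.train(
        config.mlp, normed["train"], normed["val"], normalizer=norm
    )
    timings["train"] = time.perf_counter() - t

    t = time.perf_counter()
    test_pred = classifier.predict_pixels(model, normed["test"])
    # voting weights use the raw (nm) Morpho, not the normalized one
    test_pred["Morpho"] = records["test"]["Morpho"].to_numpy()
    pixel_conf = classifier.confusion_matrix(
        test_pred["predicted"], test_pred["Category"]
    )
    outcomes = voting.vote_cells(test_pred, weight_params=config.weight_params)
    cell_conf = classifier.confusion_matrix(
        [o.predicted for o in outcomes], [o.label for o in outcomes]
    )
    timings["vote"] = time.perf_counter() - t

    imp = None
    if config.importance_rounds > 0:
        t = time.perf_counter()
        imp = importance_mod.permutation_importance(
            model, normed["test"], rounds=config.importance_rounds, seed=config.seed
        )
        timings["importance"] = time.perf_counter() - t

    theory = {}
    for i, cls in enumerate(model.classes):
        p = voting.even_split(float(pixel_conf[i, i]))
        try:
            m_needed = voting.min_pixels_for_accuracy(*p, config.theory_threshold)
        except ValueError:
            m_needed = None
        theory[cls] = {
            "pixel_accuracy": float(pixel_conf[i, i]),
            "min_pixels": m_needed,
            "threshold": config.theory_threshold,
        }

    report = PipelineReport(
        config=config, pixel_table=table, splits=splits, model=model,
        pixel_confusion=pixel_conf, cell_confusion=cell_conf,
        outcomes=outcomes, importance=imp, theory=theory, timings=timings,
    )
    if config.output_dir:
        _write_report(report, Path(config.output_dir))
    return report


def _write_report(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    mapbuild.write_pixel_table(report.pixel_table, outdir / "pixel_table.csv",
                               provenance=True)
    (outdir / "splits.json").write_text(
        json.dumps({"seed": report.config.seed, **report.splits}, indent=1)
    )
    (outdir / "config.json").write_text(
        json.dumps(report.config.resolved(), indent=1, default=str)
    )
    np.savetxt(outdir / "pixel_confusion.csv", report.pixel_confusion,
               delimiter=",", fmt="%.6f")
    np.savetxt(outdir / "cell_confusion.csv", report.cell_confusion,
               delimiter=",", fmt="%.6f")
    pd.DataFrame(report.model.history).to_csv(
        outdir / "learning_curves.csv", index_label="epoch"
    )
    report.model.save(outdir / "model")
    if report.importance is not None:
        report.importance.as_frame().to_csv(outdir / "importance.csv", index=False)
    votes = pd.DataFrame(
        [
            {"cell_id": o.cell_id, "label": o.label, "predicted": o.predicted,
             "tie": o.tie_flag, **{f"tally_{k}": v for k, v in o.tallies.items()}}
            for o in report.outcomes
        ]
    )
    votes.to_csv(outdir / "cell_votes.csv", index=False)
    (outdir / "theory.json").write_text(json.dumps(report.theory, indent=1))
    summary = {
        "pixel_accuracy_per_class": [float(x) for x in np.diag(report.pixel_confusion)],
        "cell_accuracy_per_class": [float(x) for x in np.diag(report.cell_confusion)],
        "n_pixels": int(len(report.pixel_table)),
        "timings_s": {k: round(v, 2) for k, v in report.timings.items()},
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=1))
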