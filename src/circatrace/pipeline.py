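"""End-to-end pipeline orchestration.

``run_pipeline`` drives the stages — simulate, (optional) quantify, prep,
rhythms, respond, report — writing versioned CSV/JSON artifacts into a run
directory together with the resolved config and its hash, so any output
row is traceable to its inputs. The same config + seed always reproduces
bitwise-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, imaging, prep, report, stats, synthetic
from .config import config_hash, dump_config, resolve_config
from .trace import frame_to_traces, write_traces_csv

log = logging.getLogger("circatrace")

FLOAT_FMT = "%.10g"

# fixed per-stage offsets applied to the run seed so stages draw
# independent, reproducible streams
_SEED_OFFSETS = {"cohort": 1, "response": 2, "stacks": 3}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _SEED_OFFSETS[stage]) % (2**31 - 1)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def simulate_stage(cfg: dict, outdir: Path) -> dict:
    seed = cfg["seed"]
    cc = cfg["cohort"]
    traces, gt = synthetic.generate_cohort(
        n_cells=cc["n_cells"], class_mix=cc["class_mix"],
        rhythmic_fraction=cc["rhythmic_fraction"],
        seed=_stage_seed(seed, "cohort"),
        sampling_interval_hr=cc["sampling_interval_hr"],
        duration_hr=cc["duration_hr"],
    )
    write_traces_csv(traces, outdir / "cohort_traces.csv")
    _write_csv(gt, outdir / "cohort_ground_truth.csv")

    rc = cfg["response"]
    eff = rc["effect"]
    spec = synthetic.DrugEffectSpec(
        onset_hr=eff["onset_hr"],
        affected_groups=frozenset(eff["affected_groups"]),
        affected_classes=frozenset(eff["affected_classes"]),
        effect_shape=eff["effect_shape"], effect_size=eff["effect_size"],
        blocked_by=frozenset(eff["blocked_by"]),
    )
    experiment = synthetic.generate_response_experiment(
        spec, groups=rc["groups"], classes=rc["classes"],
        n_per_group_class=rc["n_per_group_class"],
        baseline_hr=rc["baseline_hr"], duration_hr=rc["duration_hr"],
        sampling_interval_hr=rc["sampling_interval_hr"],
        seed=_stage_seed(seed, "response"),
    )
    _write_csv(experiment, outdir / "response_experiment.csv")

    artifacts = {"cohort_traces": outdir / "cohort_traces.csv",
                 "response_experiment": outdir / "response_experiment.csv"}

    sc = cfg["stacks"]
    if sc.get("enabled"):
        artifacts.update(_simulate_stacks(cfg, traces, outdir))
    return artifacts


def _simulate_stacks(cfg: dict, traces, outdir: Path) -> dict:
    sc = cfg["stacks"]
    shape = tuple(sc["shape"])
    n_cells = min(sc["n_cells"], len(traces))
    rng = np.random.default_rng(_stage_seed(cfg["seed"], "stacks"))
    sigma = sc["radius_voxels"]
    # spread blob centers on a coarse grid, away from edges
    blobs = []
    margin = 4 * sigma
    for i in range(n_cells):
        cz = shape[0] / 2.0
        cy = margin + (shape[1] - 2 * margin) * ((i + 0.5) / n_cells)
        cx = margin + rng.uniform(0, shape[2] - 2 * margin)
        blobs.append(synthetic.BlobSpec(center=(cz, cy, cx),
                                        radius_voxels=sigma,
                                        peak_intensity=sc["peak_intensity"],
                                        neuron_class=traces[i].neuron_class))
    spec = synthetic.StackSpec(shape=shape, cells=tuple(blobs),
                               background_level=sc["background_level"])
    volumes, gt = synthetic.render_stack_series(
        spec, traces[:n_cells], seed=_stage_seed(cfg["seed"], "stacks"))
    series = imaging.StackSeries(volumes=volumes, time_hr=traces[0].time_hr)
    stack_dir = outdir / "stacks"
    imaging.write_stack_series(series, stack_dir)
    _write_csv(gt, outdir / "stack_ground_truth.csv")

    # synthetic stand-in for manual ROI drawing: disks of 3.5 sigma around
    # the projected blob centers, three background boxes near the corners
    ny, nx = shape[1], shape[2]
    yy, xx = np.mgrid[:ny, :nx]
    cell_labels = np.zeros((ny, nx), dtype=np.int32)
    for i, b in enumerate(blobs, start=1):
        _, cy, cx = b.center
        cell_labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= (3.5 * sigma) ** 2] = i
    bg_labels = np.zeros((ny, nx), dtype=np.int32)
    box = max(3, int(sigma))
    for j, (oy, ox) in enumerate([(0, 0), (0, nx - box), (ny - box, 0)], start=1):
        bg_labels[oy:oy + box, ox:ox + box] = j
    bg_labels[cell_labels > 0] = 0
    import tifffile
    tifffile.imwrite(stack_dir / "cell_rois.tif", cell_labels)
    tifffile.imwrite(stack_dir / "background_rois.tif", bg_labels)
    return {"stacks": stack_dir, "stack_ground_truth": outdir / "stack_ground_truth.csv"}


def quantify_stage(cfg: dict, outdir: Path) -> Path:
    stack_dir = outdir / "stacks"
    import tifffile
    series = imaging.read_stack_series(stack_dir)
    rois = imaging.ROISet.from_label_images(
        tifffile.imread(stack_dir / "cell_rois.tif"),
        tifffile.imread(stack_dir / "background_rois.tif"))
    records = imaging.measure_stack_series(series, rois)
    path = outdir / "cell_intensity_records.csv"
    _write_csv(records, path)
    return path


def prep_stage(cfg: dict, outdir: Path) -> Path:
    traces = frame_to_traces(pd.read_csv(outdir / "cohort_traces.csv"))
    rep = cfg["report"]
    heatmap = prep.build_heatmap(traces, window_hr=rep["heatmap_window_hr"],
                                 ceiling=rep["ceiling"])
    path = outdir / "heatmap_matrix.csv"
    heatmap.values.to_csv(path, float_format=FLOAT_FMT)
    if rep.get("render_png"):
        report.plot_heatmap(heatmap, outdir / "heatmap.png")
    return path


def rhythms_stage(cfg: dict, outdir: Path) -> dict:
    traces = frame_to_traces(pd.read_csv(outdir / "cohort_traces.csv"))
    rcfg = classify.RhythmConfig(
        band_hr=tuple(cfg["rhythms"]["band_hr"]),
        order_rule=cfg["rhythms"]["order_rule"],
        n_frequencies=cfg["rhythms"]["n_frequencies"],
    )
    calls = classify.classify_cohort(traces, rcfg)
    summaries = classify.summarize_cohort(calls, rcfg)
    calls_path = outdir / "rhythm_calls.csv"
    summary_path = outdir / "cohort_summary.csv"
    _write_csv(classify.calls_to_frame(calls), calls_path)
    _write_csv(classify.summaries_to_frame(summaries), summary_path)
    return {"calls": calls_path, "summary": summary_path}


def respond_stage(cfg: dict, outdir: Path) -> Path:
    experiment = pd.read_csv(outdir / "response_experiment.csv")
    normalized = stats.normalize_experiment(experiment)
    _write_csv(normalized, outdir / "response_normalized.csv")
    results = stats.per_timepoint_comparisons(
        normalized, reference_group=cfg["respond"]["reference_group"],
        family=cfg["respond"]["family"])
    df = stats.results_to_frame(results)
    path = outdir / "response_results.csv"
    _write_csv(df, path)
    if cfg["report"].get("render_png"):
        report.plot_response(normalized, df, outdir / "response_timecourse.png",
                             reference_group=cfg["respond"]["reference_group"],
                             alpha=cfg["respond"]["alpha"])
    return path


def run_pipeline(raw_config: dict, output_dir) -> Path:
    """Run every stage from a (raw or resolved) config dict.

    Writes all artifacts plus ``resolved_config.yaml`` and
    ``provenance.json`` (config hash, stage list) into ``output_dir`` and
    returns that path. Any stage failure is re-raised as
    :class:`StageError` naming the stage.
    """
    cfg = resolve_config(raw_config)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, outdir / "resolved_config.yaml")

    stages = [("simulate", simulate_stage)]
    if cfg["stacks"].get("enabled"):
        stages.append(("quantify", quantify_stage))
    stages += [("prep", prep_stage), ("rhythms", rhythms_stage),
               ("respond", respond_stage)]

    completed = []
    for name, fn in stages:
        log.info("running stage %s", name)
        try:
            fn(cfg, outdir)
        except Exception as err:  # noqa: BLE001 - re-raised with stage name
            raise StageError(name, err) from err
        completed.append(name)

    provenance = {"config_hash": config_hash(cfg), "stages": completed}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                       sort_keys=True) + "\n")
    return outdir
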