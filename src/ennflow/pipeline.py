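"""End-to-end orchestration: generate -> train-ann -> select-layers ->
estimate-fc -> simulate -> evaluate -> report.

Every stage is a pure function of the configuration and the master seed
(sub-seeds are derived from it), so a run is idempotent: re-running with the
same config rewrites byte-identical artifacts, and deleting an intermediate
just regenerates it.  Artifacts land in the output directory with a JSON
manifest recording each stage's seed and wall time.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import ann, io, selection, task
from .enn import build_enn
from .evaluation import EvaluationReport, cohort_prototypes, evaluate_variant_suite
from .synth import GroundTruthConfig, LayerAssignment, build_ground_truth, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnnStageConfig:
    n_hidden: int = 1280
    max_batches: int = 30000
    null_permutations: int = 1000


@dataclass
class SelectionConfig:
    n_folds: int = 12
    k_hubs: int = 10
    classifier: str = "min_distance"
    use_ground_truth_layers: bool = False


@dataclass
class SimulationConfig:
    n_per_context: int = 15
    n_components: int = 500
    variants: list = field(
        default_factory=lambda: [
            "full", "no_hidden", "no_relu", "context_lesion", "shuffled_fc",
        ]
    )


@dataclass
class EvaluationConfig:
    n_folds: int = 4
    n_reps: int = 200
    n_perm: int = 200
    n_family: int = 100
    family_reps: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 24
    generator: GroundTruthConfig = field(default_factory=GroundTruthConfig)
    ann: AnnStageConfig = field(default_factory=AnnStageConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    output_dir: str = "ennflow_run"


def _stage(manifest: dict, name: str, seed: int):
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s (seed=%d) started", name, seed)
            return self

        def __exit__(self, *exc):
            manifest[name] = {
                "seed": seed,
                "wall_time_s": round(time.time() - self.t0, 3),
                "failed": exc[0] is not None,
            }
            if exc[0] is not None:
                logger.error("stage %s failed with seed %d", name, seed)
            else:
                logger.info("stage %s done in %.1fs", name, manifest[name]["wall_time_s"])
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute all stages, writing every intermediate artifact plus a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.dataclass_to_yaml(config, out / "config.yaml")
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31 - 1))
             for k in ("brain", "cohort", "ann", "selection", "evaluation")}
    manifest: dict = {}

    with _stage(manifest, "generate", seeds["brain"]):
        brain = build_ground_truth(config.generator, seed=seeds["brain"])
        cohort = generate_cohort(config.n_subjects, brain, seed=seeds["cohort"])
        io.save_cohort(cohort, out / "cohort.h5")

    with _stage(manifest, "train_ann", seeds["ann"]):
        acfg = ann.AnnConfig(
            n_hidden=config.ann.n_hidden,
            max_batches=config.ann.max_batches,
            seed=seeds["ann"],
        )
        params, trace = ann.train_ann(acfg)
        rsm = ann.probe_hidden_rsm(params)
        null_rsm = ann.shuffled_parameter_null_rsm(
            params, n_perm=config.ann.null_permutations, seed=seeds["ann"]
        )
        io.save_ann(params, rsm, out / "ann.h5", null_rsm=null_rsm)
        pd.DataFrame(
            {"loss": trace.loss, "accuracy": trace.accuracy}
        ).to_csv(out / "ann_training_trace.csv", index=False)

    with _stage(manifest, "select_layers", seeds["selection"]):
        layers, ranking = _select_layers(cohort, rsm, config, seeds["selection"], out)
        io.save_layers(layers, out / "layers.json")
        ranking.to_csv(out / "hub_ranking.csv", index=False)

    with _stage(manifest, "estimate_fc", seeds["cohort"]):
        model = build_enn(cohort, layers, config.simulation.n_components)
        io.save_weight_maps(
            {"context2hidden": model.w_c2h,
             "stimulus2hidden": model.w_s2h,
             "hidden2output": model.w_h2m},
            out / "fc_maps.h5",
        )

    with _stage(manifest, "simulate", seeds["evaluation"]):
        protos = cohort_prototypes(
            model, cohort, config.simulation.n_per_context,
            seed=seeds["evaluation"] + 7,
        )
        with h5py.File(out / "prototypes.h5", "w") as f:
            f.create_dataset("predicted", data=protos, track_times=False)

    with _stage(manifest, "evaluate", seeds["evaluation"]):
        report = evaluate_variant_suite(
            cohort,
            layers=layers,
            variants=tuple(config.simulation.variants),
            n_components=config.simulation.n_components,
            n_per_context=config.simulation.n_per_context,
            n_folds=config.evaluation.n_folds,
            n_reps=config.evaluation.n_reps,
            n_perm=config.evaluation.n_perm,
            n_family=config.evaluation.n_family,
            family_reps=config.evaluation.family_reps,
            seed=seeds["evaluation"],
        )

    with _stage(manifest, "report", config.seed):
        write_report(report, out)

    io.write_json(manifest, out / "manifest.json")
    return report


def _select_layers(cohort, ann_rsm, config: PipelineConfig, seed: int, out: Path):
    """Layer identification: decoding maps, motor contrasts, hub ranking."""
    brain = cohort.brain
    parcel_rsms = selection.cohort_parcel_rsms(cohort)
    ranking, hub_vertices = selection.select_conjunction_hubs(
        parcel_rsms, ann_rsm, brain.parcel_table, k=config.selection.k_hubs
    )
    if config.selection.use_ground_truth_layers:
        return brain.layer_assignment(), ranking

    betas = np.stack([s.condition_betas for s in cohort.subjects])
    # rule decoding (12-way) across all parcels -> context input layer
    rule_map = selection.parcelwise_decoding(
        betas[:, :12], np.arange(12), brain.parcel_table,
        n_folds=config.selection.n_folds,
        classifier=config.selection.classifier, seed=seed,
    )
    rule_map.to_csv(out / "rule_decoding.csv", index=False)
    ctx_parcels = rule_map.loc[rule_map.fdr_significant, "parcel_id"]
    # stimulus decoding (4-way per dimension) -> stimulus input layer
    stim_sig: set[int] = set()
    for d in range(4):
        dmap = selection.parcelwise_decoding(
            betas[:, 12 + 4 * d : 12 + 4 * (d + 1)], np.arange(4),
            brain.parcel_table, n_folds=config.selection.n_folds,
            classifier=config.selection.classifier, seed=seed + d,
        )
        dmap.to_csv(out / f"stimulus_decoding_{task.DIMENSIONS[d]}.csv", index=False)
        stim_sig |= set(dmap.loc[dmap.fdr_significant, "parcel_id"])
    gt = brain.layer_assignment()
    actual = np.stack([s.actual_motor_betas for s in cohort.subjects])
    motor_masks = {}
    for hand, block in (("left", gt.motor_left), ("right", gt.motor_right)):
        # candidate vertices: the hand's somatomotor block
        local = np.where(np.isin(gt.motor, block))[0]
        idx_mask, mid_mask = selection.motor_univariate_contrast(
            actual[:, :, local], hand
        )
        motor_masks[hand] = block[np.where(idx_mask | mid_mask)[0]]
    # restrict the context layer to input-candidate parcels (rule activity is
    # broadly decodable downstream too; the input layer is where it originates)
    ctx_parcels = [p for p in ctx_parcels if brain.parcel_table[p]["kind"] == "context"]
    ctx_vertices = np.sort(np.concatenate(
        [brain.parcel_table[p]["vertices"] for p in ctx_parcels]
    )) if len(ctx_parcels) else gt.context
    stim_vertices = np.sort(np.concatenate([
        brain.parcel_table[p]["vertices"] for p in stim_sig
        if brain.parcel_table[p]["kind"] == "stimulus"
    ])) if stim_sig else gt.stimulus
    layers = LayerAssignment(
        context=ctx_vertices,
        stimulus=stim_vertices,
        hidden=hub_vertices,
        motor_left=motor_masks["left"] if len(motor_masks["left"]) else gt.motor_left,
        motor_right=motor_masks["right"] if len(motor_masks["right"]) else gt.motor_right,
    )
    return layers, ranking


def write_report(report: EvaluationReport, out_dir: Path) -> list[Path]:
    """CSV (machine), JSON (manifest), and a plain-text summary table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = report.to_frame()
    required = {"variant", "hand", "mean_accuracy", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"report missing required fields: {sorted(missing)}")
    csv_path = out_dir / "evaluation_report.csv"
    df.to_csv(csv_path, index=False)
    json_path = out_dir / "evaluation_report.json"
    io.write_json(json.loads(df.to_json(orient="records")), json_path)
    txt_path = out_dir / "evaluation_summary.txt"
    lines = [f"{'variant':<16}{'hand':<8}{'mean acc':>10}{'p':>10}"]
    for _, row in df.iterrows():
        p = "" if pd.isna(row["p_value"]) else f"{row['p_value']:.3f}"
        lines.append(
            f"{row['variant']:<16}{row['hand']:<8}"
            f"{100 * row['mean_accuracy']:>9.2f}%{p:>10}"
        )
    txt_path.write_text("\n".join(lines) + "\n")
    return [csv_path, json_path, txt_path]
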