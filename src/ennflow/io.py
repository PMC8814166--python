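"""HDF5 / YAML / CSV serialization for pipeline artifacts.

Arrays go to HDF5 (with ``track_times=False`` so identical inputs produce
byte-identical files), configs to YAML, tables to CSV, manifests to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .ann import AnnParameters
from .connectivity import VertexWeightMap
from .synth import GroundTruthConfig, LayerAssignment, SyntheticCohort

__all__ = [
    "save_cohort",
    "save_ann",
    "load_ann_parameters",
    "save_weight_maps",
    "load_weight_maps",
    "save_layers",
    "load_layers",
    "dataclass_to_yaml",
    "dataclass_from_yaml",
    "write_json",
]


def _dset(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def save_cohort(cohort: SyntheticCohort, path: Path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["seed"] = cohort.seed
        f.attrs["brain_seed"] = cohort.brain.seed
        f.attrs["config_yaml"] = yaml.safe_dump(
            dataclasses.asdict(cohort.brain.config)
        )
        _dset(f, "parcel_labels", cohort.brain.parcel_labels)
        for name in ("G_c2h", "G_s2h", "G_h2m", "rule_patterns",
                     "stimulus_patterns", "motor_templates", "actual_motor_group"):
            _dset(f, name, getattr(cohort.brain, name))
        for i, s in enumerate(cohort.subjects):
            g = f.create_group(f"subject_{i:03d}")
            g.attrs["seed"] = s.seed
            _dset(g, "rest", s.rest)
            _dset(g, "rule_betas", s.rule_betas)
            _dset(g, "stimulus_betas", s.stimulus_betas)
            _dset(g, "actual_motor_betas", s.actual_motor_betas)


def load_cohort(path: Path) -> SyntheticCohort:
    """Rebuild the ground-truth brain deterministically from its stored config
    and seed, then attach the stored subject arrays."""
    from .synth import SyntheticSubject, build_ground_truth

    with h5py.File(path, "r") as f:
        cfg = _build(GroundTruthConfig, yaml.safe_load(f.attrs["config_yaml"]))
        brain = build_ground_truth(cfg, seed=int(f.attrs["brain_seed"]))
        if not np.array_equal(brain.parcel_labels, f["parcel_labels"][...]):
            raise ValueError("stored cohort does not match its config/seed")
        subjects = []
        for name in sorted(k for k in f if k.startswith("subject_")):
            g = f[name]
            subjects.append(
                SyntheticSubject(
                    rest=g["rest"][...],
                    rule_betas=g["rule_betas"][...],
                    stimulus_betas=g["stimulus_betas"][...],
                    actual_motor_betas=g["actual_motor_betas"][...],
                    seed=int(g.attrs["seed"]),
                )
            )
        return SyntheticCohort(brain=brain, subjects=subjects, seed=int(f.attrs["seed"]))


def save_ann(params: AnnParameters, rsm: np.ndarray, path: Path,
             null_rsm: np.ndarray | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        g = f.create_group("parameters")
        for name in ("W_in", "b1", "W_h", "b2", "W_out", "b3"):
            _dset(g, name, getattr(params, name))
        _dset(f, "hidden_rsm", rsm)
        if null_rsm is not None:
            _dset(f, "null_rsm", null_rsm)


def load_ann_parameters(path: Path) -> AnnParameters:
    with h5py.File(path, "r") as f:
        g = f["parameters"]
        return AnnParameters(**{k: g[k][...] for k in
                                ("W_in", "b1", "W_h", "b2", "W_out", "b3")})


def save_weight_maps(maps: dict[str, VertexWeightMap], path: Path) -> None:
    with h5py.File(path, "w", track_order=True) as f:
        for name, m in maps.items():
            g = f.create_group(name)
            _dset(g, "W", m.W)
            g.attrs["source"] = m.source
            g.attrs["target"] = m.target
            g.attrs["provenance"] = m.provenance


def load_weight_maps(path: Path) -> dict[str, VertexWeightMap]:
    out = {}
    with h5py.File(path, "r") as f:
        for name, g in f.items():
            out[name] = VertexWeightMap(
                W=g["W"][...],
                source=g.attrs["source"],
                target=g.attrs["target"],
                provenance=g.attrs["provenance"],
            )
    return out


def save_layers(layers: LayerAssignment, path: Path) -> None:
    payload = {
        k: getattr(layers, k).tolist()
        for k in ("context", "stimulus", "hidden", "motor_left", "motor_right")
    }
    write_json(payload, path)


def load_layers(path: Path) -> LayerAssignment:
    with open(path) as f:
        payload = json.load(f)
    return LayerAssignment(**{k: np.asarray(v, dtype=np.int64)
                              for k, v in payload.items()})


def dataclass_to_yaml(obj, path: Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(dataclasses.asdict(obj), f, sort_keys=False)


def dataclass_from_yaml(cls, path: Path):
    with open(path) as f:
        payload = yaml.safe_load(f)
    return _build(cls, payload)


def _build(cls, payload):
    """Reconstruct (possibly nested) dataclasses from a plain dict."""
    import typing

    hints = typing.get_type_hints(cls)
    kwargs = {}
    for field in dataclasses.fields(cls):
        if field.name not in payload:
            continue
        value = payload[field.name]
        ftype = hints.get(field.name, field.type)
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            value = _build(ftype, value)
        kwargs[field.name] = value
    return cls(**kwargs)


def write_json(payload, path: Path) -> None:
    with open(path, "w") as f:
        json.dump(payload, f, indent=2, sort_keys=True)
        f.write("\n")
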