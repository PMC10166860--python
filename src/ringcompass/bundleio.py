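"""Session bundle storage and pipeline configuration.

A session bundle collects everything one recording needs downstream: raw
ROI fluorescence, ROI coordinates, tail (and optional gaze) traces, an
optional condition/epoch table and, for synthetic sessions, the ground
truth.  Two interchangeable on-disk dialects are supported - a single HDF5
file and a directory of CSVs with a YAML metadata file - because deposited
datasets mix both formats.  All angles are radians, all times seconds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import GazeTrace, RawFluorescence, TailTrace

__all__ = ["SessionBundle", "PipelineConfig", "save_bundle", "load_bundle",
           "bundle_from_synthetic"]


@dataclass
class SessionBundle:
    raw: RawFluorescence
    rois: pd.DataFrame
    tail: TailTrace
    gaze: GazeTrace | None = None
    conditions: pd.DataFrame | None = None  # start_s, end_s, label, gain
    truth: dict | None = None  # synthetic sessions only
    metadata: dict = field(default_factory=dict)

    def center_coordinates(self, point) -> "SessionBundle":
        """Re-reference ROI coordinates so the given (x, y, z) anatomical
        landmark sits at the origin."""
        rois = self.rois.copy()
        for col, p in zip(("x_lr", "y_rc", "z"), point):
            rois[col] = rois[col] - p
        return SessionBundle(
            raw=self.raw, rois=rois, tail=self.tail, gaze=self.gaze,
            conditions=self.conditions, truth=self.truth,
            metadata={**self.metadata, "centering_point": list(point)},
        )


def bundle_from_synthetic(session) -> SessionBundle:
    """Wrap a :class:`synthio.SyntheticSession` as a pipeline-ready bundle."""
    truth = {
        "true_phase": session.truth.true_phase,
        "true_heading": session.truth.true_heading,
        "true_alpha": session.truth.true_alpha,
        "swims": pd.DataFrame(
            [
                {
                    "onset_s": ev.onset_s,
                    "offset_s": ev.offset_s,
                    "laterality": ev.laterality,
                    "swim_class": ev.swim_class,
                }
                for ev in session.truth.swim_events
            ]
        ),
    }
    meta = {"seed": session.params.seed, "synthetic": True,
            "params": asdict(session.params)}
    return SessionBundle(
        raw=session.raw, rois=session.rois, tail=session.tail,
        gaze=session.gaze, truth=truth, metadata=meta,
    )


REQUIRED = ("raw", "rois", "tail")


def save_bundle(bundle: SessionBundle, path) -> None:
    """Write a bundle; dialect chosen by suffix (".h5"/".hdf5" vs directory)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        _save_h5(bundle, path)
    else:
        _save_csv_dir(bundle, path)


def load_bundle(path) -> SessionBundle:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return _load_h5(path)
    return _load_csv_dir(path)


def _meta_yaml(bundle: SessionBundle) -> str:
    return yaml.safe_dump(bundle.metadata, sort_keys=True)


def _save_h5(bundle: SessionBundle, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        g.create_dataset("values", data=bundle.raw.values)
        g.attrs["rate"] = bundle.raw.rate
        g.create_dataset("roi_ids", data=np.asarray(bundle.raw.roi_ids, dtype="i8"))
        f.create_dataset("tail/angle", data=bundle.tail.angle)
        f["tail"].attrs["rate"] = bundle.tail.rate
        if bundle.gaze is not None:
            f.create_dataset("gaze/angle", data=bundle.gaze.angle)
            f.create_dataset("gaze/saccade_times", data=bundle.gaze.saccade_times)
            f["gaze"].attrs["rate"] = bundle.gaze.rate
        rg = f.create_group("rois")
        for col in bundle.rois.columns:
            data = bundle.rois[col].to_numpy()
            if data.dtype == object or data.dtype.kind in "US":
                data = np.asarray(data, dtype="S")
            elif data.dtype == bool:
                data = data.astype("i1")
            rg.create_dataset(col, data=data)
        rg.attrs["columns"] = json.dumps(list(bundle.rois.columns))
        if bundle.conditions is not None:
            cg = f.create_group("conditions")
            for col in bundle.conditions.columns:
                data = bundle.conditions[col].to_numpy()
                if data.dtype == object or data.dtype.kind in "US":
                    data = np.asarray(data, dtype="S")
                cg.create_dataset(col, data=data)
            cg.attrs["columns"] = json.dumps(list(bundle.conditions.columns))
        if bundle.truth is not None:
            tg = f.create_group("truth")
            for key in ("true_phase", "true_heading", "true_alpha"):
                tg.create_dataset(key, data=np.asarray(bundle.truth[key]))
            sw = bundle.truth["swims"]
            tg.create_dataset("swims_numeric",
                              data=sw[["onset_s", "offset_s", "laterality"]].to_numpy())
            tg.create_dataset(
                "swims_class",
                data=np.asarray(sw["swim_class"].to_numpy(), dtype="S"),
            )
        f.attrs["metadata"] = _meta_yaml(bundle)


def _read_table(group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    data = {}
    for col in cols:
        arr = group[col][()]
        if arr.dtype.kind == "S":
            arr = arr.astype(str)
        data[col] = arr
    frame = pd.DataFrame(data)
    if "is_ring" in frame:
        frame["is_ring"] = frame["is_ring"].astype(bool)
    return frame


def _load_h5(path: Path) -> SessionBundle:
    with h5py.File(path, "r") as f:
        missing = [k for k in ("raw", "rois", "tail") if k not in f]
        if missing:
            raise ValueError(f"bundle missing required component(s): {missing}")
        raw = RawFluorescence(
            values=f["raw/values"][()],
            rate=float(f["raw"].attrs["rate"]),
            roi_ids=f["raw/roi_ids"][()],
        )
        tail = TailTrace(angle=f["tail/angle"][()], rate=float(f["tail"].attrs["rate"]))
        gaze = None
        if "gaze" in f:
            gaze = GazeTrace(
                angle=f["gaze/angle"][()],
                rate=float(f["gaze"].attrs["rate"]),
                saccade_times=f["gaze/saccade_times"][()],
            )
        rois = _read_table(f["rois"])
        conditions = _read_table(f["conditions"]) if "conditions" in f else None
        truth = None
        if "truth" in f:
            numeric = f["truth/swims_numeric"][()]
            swims = pd.DataFrame(
                numeric, columns=["onset_s", "offset_s", "laterality"]
            )
            swims["swim_class"] = f["truth/swims_class"][()].astype(str)
            truth = {
                "true_phase": f["truth/true_phase"][()],
                "true_heading": f["truth/true_heading"][()],
                "true_alpha": f["truth/true_alpha"][()],
                "swims": swims,
            }
        metadata = yaml.safe_load(f.attrs["metadata"]) or {}
    return SessionBundle(raw=raw, rois=rois, tail=tail, gaze=gaze,
                         conditions=conditions, truth=truth, metadata=metadata)


def _save_csv_dir(bundle: SessionBundle, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        bundle.raw.values.T, columns=[str(r) for r in bundle.raw.roi_ids]
    ).to_csv(path / "raw_fluorescence.csv", index=False)
    bundle.rois.to_csv(path / "rois.csv", index=False)
    pd.DataFrame({"angle": bundle.tail.angle}).to_csv(path / "tail.csv", index=False)
    meta = dict(bundle.metadata)
    meta["_rates"] = {"raw": bundle.raw.rate, "tail": bundle.tail.rate}
    if bundle.gaze is not None:
        pd.DataFrame({"angle": bundle.gaze.angle}).to_csv(
            path / "gaze.csv", index=False
        )
        np.savetxt(path / "gaze_saccades.txt", bundle.gaze.saccade_times)
        meta["_rates"]["gaze"] = bundle.gaze.rate
    if bundle.conditions is not None:
        bundle.conditions.to_csv(path / "conditions.csv", index=False)
    if bundle.truth is not None:
        np.savetxt(path / "truth_phase.txt", bundle.truth["true_phase"])
        np.savetxt(path / "truth_heading.txt", bundle.truth["true_heading"])
        np.savetxt(path / "truth_alpha.txt", bundle.truth["true_alpha"])
        bundle.truth["swims"].to_csv(path / "truth_swims.csv", index=False)
    (path / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def _load_csv_dir(path: Path) -> SessionBundle:
    missing = [
        name
        for name, fname in (
            ("raw", "raw_fluorescence.csv"),
            ("rois", "rois.csv"),
            ("tail", "tail.csv"),
        )
        if not (path / fname).exists()
    ]
    if missing:
        raise ValueError(f"bundle missing required component(s): {missing}")
    meta = yaml.safe_load((path / "metadata.yaml").read_text()) or {}
    rates = meta.pop("_rates")
    raw_frame = pd.read_csv(path / "raw_fluorescence.csv")
    raw = RawFluorescence(
        values=raw_frame.to_numpy().T,
        rate=rates["raw"],
        roi_ids=np.asarray([int(c) for c in raw_frame.columns]),
    )
    rois = pd.read_csv(path / "rois.csv")
    tail = TailTrace(
        angle=pd.read_csv(path / "tail.csv")["angle"].to_numpy(), rate=rates["tail"]
    )
    gaze = None
    if (path / "gaze.csv").exists():
        gaze = GazeTrace(
            angle=pd.read_csv(path / "gaze.csv")["angle"].to_numpy(),
            rate=rates["gaze"],
            saccade_times=np.atleast_1d(np.loadtxt(path / "gaze_saccades.txt")),
        )
    conditions = (
        pd.read_csv(path / "conditions.csv")
        if (path / "conditions.csv").exists()
        else None
    )
    truth = None
    if (path / "truth_phase.txt").exists():
        truth = {
            "true_phase": np.loadtxt(path / "truth_phase.txt"),
            "true_heading": np.loadtxt(path / "truth_heading.txt"),
            "true_alpha": np.loadtxt(path / "truth_alpha.txt"),
            "swims": pd.read_csv(path / "truth_swims.csv"),
        }
    return SessionBundle(raw=raw, rois=rois, tail=tail, gaze=gaze,
                         conditions=conditions, truth=truth, metadata=meta)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, addressable by field name.

    Unknown keys are rejected at construction; the full config is echoed
    into every result tree for provenance.
    """

    baseline_window_s: float = 900.0
    median_kernel_frames: int = 3
    baseline_statistic: str = "mean"
    vigor_window_ms: float = 50.0
    swim_threshold: float = 0.1
    min_gap_ms: float = 100.0
    trimodal_bins: int = 61
    fallback_class_threshold: float = 0.239
    ring_threshold: float = -0.6
    ring_scan: bool = False
    template_min_corr: float = 0.5
    clip_percentiles: tuple = (2.0, 98.0)
    clip_mode: str = "per_roi"
    profile_bins: int = 100
    coupling_window_s: float = 300.0
    coupling_step_s: float = 30.0
    delta_window_s: tuple = (15.0, 20.0)
    regressor_tau_s: float = 3.0
    motor_corr_threshold: float = 0.7
    crossval_draws: int = 500
    crossval_epoch_s: float = 300.0
    seed: int = 0

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = sorted(set(mapping) - valid)
        if unknown:
            raise ValueError(f"unknown config key(s): {unknown}")
        cfg = cls(**mapping)
        if isinstance(cfg.clip_percentiles, list):
            cfg.clip_percentiles = tuple(cfg.clip_percentiles)
        if isinstance(cfg.delta_window_s, list):
            cfg.delta_window_s = tuple(cfg.delta_window_s)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clip_percentiles"] = list(d["clip_percentiles"])
        d["delta_window_s"] = list(d["delta_window_s"])
        return d
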