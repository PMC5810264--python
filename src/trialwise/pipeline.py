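"""Config-driven pipeline orchestration.

Each stage reads files written by upstream stages and writes its own outputs
plus a manifest record, so any stage can be swapped for an external tool.
Stage order: simulate -> preprocess -> store -> cbpt -> export -> fit.
Manifests contain no timestamps; rerunning with the same config and seed
reproduces them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import cbpt as cbpt_mod
from . import erp, io_formats, lmm, simulate
from .montage import N2_ROI, P3B_ROI, standard_layout
from .preprocessing import EpochSet, PreprocessConfig, preprocess_recording
from .store import apply_analysis_filters, build_store, mean_amplitude

__all__ = ["RunConfig", "validate_config", "run_pipeline", "STAGES"]

log = logging.getLogger("trialwise.pipeline")

STAGES = ("simulate", "preprocess", "store", "cbpt", "export", "fit")

DEFAULT_ROIS = {
    "N2": {"channels": list(N2_ROI), "window_ms": [250.0, 350.0]},
    "P3b": {"channels": list(P3B_ROI), "window_ms": [400.0, 550.0]},
}


@dataclass
class RunConfig:
    """Normalized run configuration; defaults mirror the study settings."""

    out_dir: str = "trialwise_out"
    seed: int = 0
    n_participants: int = 40
    n_trials: int = 1920
    n_blocks: int = 5
    n_items: int = 4
    channels: list[str] | None = None      # None -> all scalp channels
    montage: str | None = None             # CSV path; None -> packaged layout
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cbpt_factor: str = "perceptual_certainty"
    cbpt_levels: list[str] = field(
        default_factory=lambda: ["blurred", "intact"]
    )
    cbpt_alpha: float = 0.05
    cbpt_n_permutations: int = 1000
    cbpt_neighbor_dist: float = 0.7
    rois: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_ROIS)))
    models: list[dict] = field(
        default_factory=lambda: [
            {
                "name": "rt",
                "formula": "rt_ms ~ perceptual_certainty * deviant_position"
                " | participant_id: 1 + perceptual_certainty"
                " | item_id: 1",
                "family": "gaussian",
            }
        ]
    )
    noise_sd: float = 1.0
    artifact_rate: float = 0.02

    def layout(self) -> io_formats.ChannelLayout:
        if self.montage:
            return io_formats.read_montage(self.montage)
        return standard_layout()

    def ground_truth(self) -> simulate.GroundTruth:
        return simulate.GroundTruth(
            n_participants=self.n_participants,
            n_trials=self.n_trials,
            n_blocks=self.n_blocks,
            n_items=self.n_items,
            sampling_rate=500.0,
            epoch_window_ms=self.preprocess.epoch_window_ms,
            noise_sd=self.noise_sd,
            artifact_rate=self.artifact_rate,
        )


def validate_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config, fill defaults, and report every violation at once."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    errors: list[str] = []
    known = set(RunConfig.__dataclass_fields__) | {"preprocess"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")

    pp_raw = raw.pop("preprocess", {}) or {}
    pp_known = set(PreprocessConfig.__dataclass_fields__)
    for key in pp_raw:
        if key not in pp_known:
            errors.append(f"unknown preprocess key: {key!r}")
    pp = PreprocessConfig(
        **{k: _coerce_window(k, v) for k, v in pp_raw.items() if k in pp_known}
    )
    try:
        pp.validate(500.0)
    except ValueError as err:
        errors.append(f"preprocess: {err}")

    cfg = RunConfig(
        **{k: v for k, v in raw.items() if k in known and k != "preprocess"},
        preprocess=pp,
    )
    try:
        layout = cfg.layout()
    except Exception as err:
        errors.append(f"montage: {err}")
        layout = None
    if layout is not None:
        have = set(layout.labels)
        if cfg.channels:
            unknown = sorted(set(cfg.channels) - have)
            if unknown:
                errors.append(f"channels not in montage: {unknown}")
            have = set(cfg.channels) & have
        for name, roi in cfg.rois.items():
            missing = sorted(set(roi["channels"]) - have)
            if missing:
                errors.append(f"ROI {name!r} references unknown channel(s): {missing}")
            w0, w1 = roi["window_ms"]
            if not w0 < w1:
                errors.append(f"ROI {name!r} window {roi['window_ms']} is reversed")
            e0, e1 = cfg.preprocess.epoch_window_ms
            if not (e0 <= w0 and w1 <= e1):
                errors.append(f"ROI {name!r} window outside the epoch window")
    if cfg.cbpt_n_permutations < 1:
        errors.append("cbpt_n_permutations must be >= 1")
    if not 0 < cfg.cbpt_alpha < 1:
        errors.append("cbpt_alpha must be in (0, 1)")
    if errors:
        raise ValueError(
            "invalid configuration:\n  - " + "\n  - ".join(errors)
        )
    return cfg


def _coerce_window(key: str, value):
    return tuple(value) if isinstance(value, (list, tuple)) else value


# ---------------------------------------------------------------------------
# Stage plumbing

def _manifest_path(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir) / "manifest.json"


def _load_manifest(cfg: RunConfig) -> list[dict]:
    p = _manifest_path(cfg)
    if p.exists():
        return json.loads(p.read_text())
    return []


def _append_manifest(cfg: RunConfig, record: dict) -> None:
    records = _load_manifest(cfg)
    records = [r for r in records if r["stage"] != record["stage"]]
    records.append(record)
    order = {s: i for i, s in enumerate(STAGES)}
    records.sort(key=lambda r: order[r["stage"]])
    _manifest_path(cfg).write_text(json.dumps(records, indent=2, sort_keys=True))


def _require(cfg: RunConfig, stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires {p}; run the "
                f"{_producer_of(p, cfg)!r} stage first"
            )


def _producer_of(path: Path, cfg: RunConfig) -> str:
    name = path.name
    if name == "store.h5":
        return "store"
    if name in ("epochs", "raw"):
        return {"epochs": "preprocess", "raw": "simulate"}[name]
    if name == "long.csv":
        return "export"
    return "an upstream"


def _save_epochs(path: Path, ep: EpochSet, valid: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data)
        f.create_dataset("time_ms", data=ep.time_ms)
        f.create_dataset(
            "channel_labels",
            data=np.array(ep.channel_labels, dtype=h5py.string_dtype()),
        )
        f.create_dataset("valid", data=np.asarray(valid, dtype=bool))
        f.create_dataset("dropped_events", data=np.asarray(ep.dropped_events, dtype=int))
        f.attrs["participant_id"] = str(ep.participant_id)


def _load_epochs(path: Path) -> tuple[EpochSet, np.ndarray]:
    with h5py.File(path, "r") as f:
        ep = EpochSet(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            event_codes=["S 1"] * f["data"].shape[2],
            participant_id=f.attrs["participant_id"],
            channel_labels=[
                s.decode() if isinstance(s, bytes) else s
                for s in f["channel_labels"][()]
            ],
            dropped_events=list(f["dropped_events"][()]),
        )
        valid = f["valid"][()].astype(bool)
    return ep, valid


# ---------------------------------------------------------------------------
# Stages

def _stage_simulate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir) / "raw"
    out.mkdir(parents=True, exist_ok=True)
    gt = cfg.ground_truth()
    layout = cfg.layout()
    channels = cfg.channels
    rng = np.random.default_rng(cfg.seed)
    designs = simulate.simulate_design(gt, rng)
    outputs = []
    for design in designs:
        pid = design["participant_id"].iloc[0]
        rec = simulate.simulate_continuous_recording(
            design, gt, layout=layout, channels=channels, seed=rng
        )
        # recorded-side data exclude the reference; it is recovered later
        drop = [i for i, l in enumerate(rec.channel_labels) if l == "A1"]
        if drop:
            keep = [i for i in range(len(rec.channel_labels)) if i not in drop]
            rec = io_formats.RawRecording(
                data=rec.data[keep],
                sampling_rate=rec.sampling_rate,
                channel_labels=[rec.channel_labels[i] for i in keep],
                reference_label="A1",
                events=rec.events,
            )
        beh = simulate.simulate_behavior(design, _zero_amps(gt, design), gt, seed=rng)
        vhdr, _, _ = io_formats.write_brainvision(rec, out / f"{pid}")
        beh_path = out / f"{pid}_behavior.csv"
        beh.to_csv(beh_path, index=False)
        outputs += [str(vhdr), str(beh_path)]
    return {
        "stage": "simulate",
        "seed": cfg.seed,
        "inputs": [],
        "outputs": sorted(outputs),
        "counts": {"participants": len(designs), "trials": int(cfg.n_trials)},
    }


def _zero_amps(gt: simulate.GroundTruth, design: pd.DataFrame) -> dict:
    return {c.name: np.zeros(len(design)) for c in gt.components}


def _stage_preprocess(cfg: RunConfig) -> dict:
    raw_dir = Path(cfg.out_dir) / "raw"
    _require(cfg, "preprocess", raw_dir)
    out = Path(cfg.out_dir) / "epochs"
    out.mkdir(parents=True, exist_ok=True)
    inputs, outputs = [], []
    n_trials = n_bad = 0
    for vhdr in sorted(raw_dir.glob("*.vhdr")):
        rec = io_formats.read_brainvision(vhdr)
        pid = vhdr.stem
        ep, valid = preprocess_recording(
            rec, codes=["S 1"], cfg=cfg.preprocess, participant_id=pid
        )
        path = out / f"{pid}.h5"
        _save_epochs(path, ep, valid)
        inputs.append(str(vhdr))
        outputs.append(str(path))
        n_trials += ep.n_trials
        n_bad += int((~valid).sum())
    return {
        "stage": "preprocess",
        "seed": cfg.seed,
        "inputs": inputs,
        "outputs": outputs,
        "counts": {"epochs": n_trials, "invalidated": n_bad},
    }


def _stage_store(cfg: RunConfig) -> dict:
    base = Path(cfg.out_dir)
    _require(cfg, "store", base / "epochs", base / "raw")
    epochs, behaviors, valids = [], [], []
    for path in sorted((base / "epochs").glob("*.h5")):
        ep, valid = _load_epochs(path)
        beh = pd.read_csv(base / "raw" / f"{path.stem}_behavior.csv")
        beh = beh.drop(index=ep.dropped_events, errors="ignore").reset_index(
            drop=True
        )
        epochs.append(ep)
        behaviors.append(beh)
        valids.append(valid)
    store = build_store(epochs, behaviors)
    store.meta["eeg_valid"] = np.concatenate(valids)
    out = base / "store.h5"
    io_formats.save_store(store, out)
    return {
        "stage": "store",
        "seed": cfg.seed,
        "inputs": [str(p) for p in sorted((base / "epochs").glob("*.h5"))],
        "outputs": [str(out)],
        "counts": {
            "trials": store.n_trials,
            "valid": int(store.meta["eeg_valid"].sum()),
            "channels": store.n_channels,
        },
    }


def _stage_cbpt(cfg: RunConfig) -> dict:
    base = Path(cfg.out_dir)
    _require(cfg, "cbpt", base / "store.h5")
    store = io_formats.load_store(base / "store.h5")
    layout = cfg.layout()
    scalp = [c for c in store.channel_labels if c in set(layout.scalp_labels())]
    keep = store.channel_index(scalp)
    store = type(store)(
        amplitudes=store.amplitudes[keep],
        time_ms=store.time_ms,
        channel_labels=scalp,
        meta=store.meta,
    )
    filtered = apply_analysis_filters(store, "rt_erp")
    avgs = erp.condition_averages(filtered, [cfg.cbpt_factor])
    a, b = erp.paired_condition_arrays(
        avgs, cfg.cbpt_factor, cfg.cbpt_levels[0], cfg.cbpt_levels[1]
    )
    adjacency = cbpt_mod.build_adjacency(
        layout, cfg.cbpt_neighbor_dist, labels=scalp
    )
    config = cbpt_mod.CBPTConfig(
        alpha=cfg.cbpt_alpha,
        n_permutations=cfg.cbpt_n_permutations,
        seed=cfg.seed,
    )
    results = cbpt_mod.cbpt_test(a, b, adjacency, config)
    rows, mask = [], np.zeros((store.n_channels, store.n_samples), dtype=int)
    for r in results:
        chs = sorted({c for c, _ in r.members})
        samples = sorted({s for _, s in r.members})
        rows.append(
            {
                "sign": "+" if r.sign > 0 else "-",
                "mass": r.mass,
                "p": r.p_mc,
                "significant": r.significant,
                "t_start_ms": store.time_ms[samples[0]],
                "t_end_ms": store.time_ms[samples[-1]],
                "channels": " ".join(store.channel_labels[c] for c in chs),
            }
        )
        if r.significant:
            for c, s in r.members:
                mask[c, s] = 1
    table = base / "clusters.csv"
    pd.DataFrame(
        rows, columns=["sign", "mass", "p", "significant",
                       "t_start_ms", "t_end_ms", "channels"],
    ).to_csv(table, index=False)
    mask_path = base / "cluster_mask.csv"
    pd.DataFrame(mask, index=store.channel_labels).to_csv(mask_path)
    return {
        "stage": "cbpt",
        "seed": cfg.seed,
        "inputs": [str(base / "store.h5")],
        "outputs": [str(table), str(mask_path)],
        "counts": {
            "clusters": len(results),
            "significant": int(sum(r.significant for r in results)),
            "participants": int(a.shape[0]),
        },
    }


def _stage_export(cfg: RunConfig) -> dict:
    base = Path(cfg.out_dir)
    _require(cfg, "export", base / "store.h5")
    store = io_formats.load_store(base / "store.h5")
    filtered = apply_analysis_filters(store, "rt_erp")
    for name, roi in cfg.rois.items():
        mean_amplitude(
            filtered, roi["channels"], tuple(roi["window_ms"]), column=name
        )
    out = base / "long.csv"
    filtered.meta.to_csv(out, index=False)
    return {
        "stage": "export",
        "seed": cfg.seed,
        "inputs": [str(base / "store.h5")],
        "outputs": [str(out)],
        "counts": {"rows": len(filtered.meta), "rois": len(cfg.rois)},
    }


def _stage_fit(cfg: RunConfig) -> dict:
    base = Path(cfg.out_dir)
    _require(cfg, "fit", base / "long.csv")
    data = pd.read_csv(base / "long.csv")
    outputs = []
    for model in cfg.models:
        spec = lmm.ModelSpec.from_formula(
            model["formula"], family=model.get("family", "gaussian")
        )
        spec, removed, _ = lmm.prune_singular_random_terms(spec, data)
        fit, trail = lmm.reduce_fixed_effects(spec, data)
        out = base / f"fit_{model['name']}.csv"
        table = fit.fixed_effects.copy()
        table.index.name = "term"
        table.to_csv(out)
        extras = {
            "random_sd": fit.random_sd.to_dict("records"),
            "resid_sd": fit.resid_sd,
            "logLik": fit.llf,
            "REML_deviance": fit.reml_deviance,
            "AIC": fit.aic,
            "BIC": fit.bic,
            "pruned_random_terms": removed,
            "reduction_trail": [asdict(c) for c in trail],
        }
        extra_path = base / f"fit_{model['name']}.json"
        extra_path.write_text(json.dumps(extras, indent=2, default=float))
        outputs += [str(out), str(extra_path)]
    return {
        "stage": "fit",
        "seed": cfg.seed,
        "inputs": [str(base / "long.csv")],
        "outputs": sorted(outputs),
        "counts": {"models": len(cfg.models), "rows": len(data)},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "store": _stage_store,
    "cbpt": _stage_cbpt,
    "export": _stage_export,
    "fit": _stage_fit,
}


def run_pipeline(
    cfg: RunConfig, stages: Sequence[str] | None = None
) -> list[dict]:
    """Run the requested stages in order; returns their manifest records."""
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = sorted(set(stages) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}; valid: {list(STAGES)}")
    Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
    records = []
    for stage in STAGES:
        if stage not in stages:
            continue
        log.info("running stage %s", stage)
        record = _STAGE_FUNCS[stage](cfg)
        _append_manifest(cfg, record)
        records.append(record)
    return records
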