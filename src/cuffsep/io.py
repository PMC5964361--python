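"""Persistence: recordings to HDF5/NPZ, simulator configs from YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synth import (
    SOURCE_BAND,
    CuffLayout,
    NerveSiteModel,
    StimulationProtocol,
    StimulusClass,
    RawRecording,
    build_cuff_layout,
    generate_protocol,
    make_site_model,
    proprioception_classes,
    ten_class_set,
)

__all__ = [
    "save_recording",
    "load_recording",
    "load_sim_config",
    "simulate_from_config",
]

_MARKER_DTYPE = np.dtype([("time", "f8"), ("class_id", "i8")])


def save_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording to ``.h5``/``.hdf5`` or ``.npz`` (by extension)."""
    path = Path(path)
    markers = np.array(rec.markers, dtype=_MARKER_DTYPE)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=rec.samples.astype(np.float32))
            f.create_dataset("markers", data=markers)
            if rec.fsr is not None:
                f.create_dataset("fsr", data=rec.fsr.astype(np.float32))
            f.attrs["fs"] = rec.fs
            if rec.layout is not None:
                f.attrs["layout"] = rec.layout.name
            f.attrs["meta"] = json.dumps(rec.meta)
    elif path.suffix == ".npz":
        payload = {
            "samples": rec.samples.astype(np.float32),
            "markers": markers,
            "fs": np.float64(rec.fs),
            "meta": json.dumps(rec.meta),
        }
        if rec.fsr is not None:
            payload["fsr"] = rec.fsr.astype(np.float32)
        if rec.layout is not None:
            payload["layout"] = rec.layout.name
        np.savez(path, **payload)
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .h5/.npz)")


def load_recording(path: str | Path) -> RawRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            samples = f["samples"][()].astype(float)
            markers = [(float(t), int(c)) for t, c in f["markers"][()]]
            fsr = f["fsr"][()].astype(float) if "fsr" in f else None
            fs = float(f.attrs["fs"])
            layout = (
                build_cuff_layout(str(f.attrs["layout"]))
                if "layout" in f.attrs else None
            )
            meta = json.loads(f.attrs.get("meta", "{}"))
    elif path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            samples = f["samples"].astype(float)
            markers = [(float(t), int(c)) for t, c in f["markers"]]
            fsr = f["fsr"].astype(float) if "fsr" in f.files else None
            fs = float(f["fs"])
            layout = (
                build_cuff_layout(str(f["layout"]))
                if "layout" in f.files else None
            )
            meta = json.loads(str(f["meta"]))
    else:
        raise ValueError(f"unsupported extension {path.suffix!r} (use .h5/.npz)")
    return RawRecording(
        samples=samples, fs=fs, markers=markers, fsr=fsr,
        layout=layout, meta=meta,
    )


# ---------------------------------------------------------------------------
# simulator configuration
# ---------------------------------------------------------------------------

_CLASS_SETS = {
    "proprioception6": proprioception_classes,
    "ten_class": ten_class_set,
}


def load_sim_config(path: str | Path) -> dict:
    """Parse a YAML/JSON simulator config.

    Sections: ``layout`` (cuff name), ``site`` (distal/proximal or a full
    site spec), ``classes`` (named set or explicit list), ``protocol``
    (reps_per_class_per_block, n_blocks), ``noise`` (sd), ``fs``, ``seed``.
    """
    path = Path(path)
    text = path.read_text()
    cfg = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    if not isinstance(cfg, dict):
        raise ValueError("simulator config must be a mapping")
    for key in ("layout", "site", "classes", "protocol"):
        if key not in cfg:
            raise ValueError(f"simulator config missing section {key!r}")
    return cfg


def _classes_from_config(spec) -> list[StimulusClass]:
    if isinstance(spec, str):
        if spec not in _CLASS_SETS:
            raise ValueError(
                f"unknown class set {spec!r}; valid: {', '.join(_CLASS_SETS)}"
            )
        return _CLASS_SETS[spec]()
    if isinstance(spec, dict):
        name = spec.get("set")
        if name not in _CLASS_SETS:
            raise ValueError(
                f"unknown class set {name!r}; valid: {', '.join(_CLASS_SETS)}"
            )
        kwargs = {k: v for k, v in spec.items() if k != "set"}
        return _CLASS_SETS[name](**kwargs)
    return [StimulusClass(**c) for c in spec]


def simulate_from_config(cfg: dict, seed: int | None = None) -> RawRecording:
    """Run the simulator from a parsed config; ``seed`` overrides cfg['seed']."""
    from .synth import synthesize_recording  # local to keep import cheap

    layout = build_cuff_layout(cfg["layout"])
    classes = _classes_from_config(cfg["classes"])
    proto_cfg = cfg["protocol"]
    if seed is None:
        seed = int(cfg.get("seed", 0))
    protocol = generate_protocol(
        classes,
        reps_per_class_per_block=int(proto_cfg["reps_per_class_per_block"]),
        n_blocks=int(proto_cfg.get("n_blocks", 1)),
        seed=seed,
    )
    site_cfg = cfg["site"]
    if isinstance(site_cfg, str):
        site = make_site_model(site_cfg, classes)
    else:
        site = make_site_model(
            site_cfg["name"], classes,
            **{k: v for k, v in site_cfg.items() if k != "name"},
        )
    noise_sd = float(cfg.get("noise", {}).get("sd", 0.01))
    fs = float(cfg.get("fs", 30000.0))
    band = tuple(cfg.get("source_band", SOURCE_BAND))
    has_noci = any(c.modality == "nociception" for c in classes)
    return synthesize_recording(
        protocol, layout, site, noise_sd=noise_sd, fs=fs, seed=seed,
        source_band=band, with_fsr=has_noci,
    )
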