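"""HDF5 study container, run configuration and channel-map tables.

One hierarchical container per participant/study:

    /events/ch{N}/{neg,pos}     (time, amplitude) pairs + attrs(sd, bundle, region)
    /tensors/{epoch}            (n_windows, 2, Ne, B) float32
    /labels                     250-ms multi-hot concept matrix
    /recall/vocalizations       (time_s, word, concept) table
    /activations/{model}        (n_windows, n_concepts)
    root attrs                  seed, package version, config hash, units

Configuration is one flat document whose defaults are the full-scale
analysis values; it hashes canonically so a run log can be tied to the
exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .preprocessing import AmplitudeTrain

PACKAGE_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """All tunables of the pipeline in one schema-checked document."""

    # preprocessing
    sample_rate_hz: float = 32000.0
    threshold_sds: float = 3.0
    coincident_window_ms: float = 4.0
    coincident_min_channels: int = 6
    bin_low_sd: float = 3.5
    bin_high_sd: float = 30.0
    window_s: float = 0.25
    bin_s: float = 0.005
    # model
    hidden_size: int = 396
    intermediate_size: int = 792
    depth: int = 6
    heads: int = 6
    patch_width: int = 5
    n_concepts: int = 8
    # training
    lr: float = 1e-4
    epochs: int = 49
    batch_size: int = 64
    lr_step_epochs: int = 16
    lr_decay: float = 0.5
    min_combination_screentime_s: float = 50.0
    # evaluation
    n_surrogates: int = 1500
    n_shift_permutations: int = 100
    min_shift_s: float = 60.0
    n_sign_flips: int = 1000
    min_unit_rate_hz: float = 0.5
    max_label_gap_s: float = 10.0
    # seeding: one top-level seed, split into named substreams
    seed: int = 0

    def substream(self, name: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_channel_map(path):
    """Channel-map CSV (channel, bundle, region) -> ChannelMap; a missing
    column is a schema error naming the column."""
    from .controls import ChannelMap
    df = pd.read_csv(path)
    for col in ("channel", "bundle", "region"):
        if col not in df.columns:
            raise ValueError(f"channel map missing required column {col!r}")
    return ChannelMap(bundle=dict(zip(df["channel"], df["bundle"])),
                      region=dict(zip(df["channel"], df["region"])))


# ---------------------------------------------------------------- container


def save_events(h5: h5py.Group, trains: list, bundle_of_channel=None) -> None:
    g = h5.require_group("events")
    for tr in trains:
        cg = g.require_group(f"ch{tr.channel}")
        cg.attrs["sd"] = tr.sd
        cg.attrs["discretized"] = tr.discretized
        if bundle_of_channel is not None:
            cg.attrs["bundle"] = int(bundle_of_channel[tr.channel])
        for pol, (t, a) in (("neg", (tr.neg_times, tr.neg_amps)),
                            ("pos", (tr.pos_times, tr.pos_amps))):
            if pol in cg:
                del cg[pol]
            d = cg.create_dataset(pol, data=np.column_stack(
                [t.astype(np.float64), a.astype(np.float64)]))
            d.attrs["columns"] = "time_samples,amplitude"


def load_events(h5: h5py.Group) -> list:
    trains = []
    for name in sorted(h5["events"], key=lambda s: int(s[2:])):
        cg = h5["events"][name]
        neg, pos = np.asarray(cg["neg"]), np.asarray(cg["pos"])
        neg = neg.reshape(-1, 2)
        pos = pos.reshape(-1, 2)
        trains.append(AmplitudeTrain(
            channel=int(name[2:]), sd=float(cg.attrs["sd"]),
            neg_times=neg[:, 0].astype(np.int64), neg_amps=neg[:, 1],
            pos_times=pos[:, 0].astype(np.int64), pos_amps=pos[:, 1],
            discretized=bool(cg.attrs["discretized"])))
    return trains


def save_study(path, trains=None, tensors=None, labels=None,
               vocalizations=None, activations=None,
               bundle_of_channel=None, config: RunConfig = None,
               meta: dict = None) -> None:
    """Write (or update) a study container. ``vocalizations``: iterable
    of (time_s, word, concept-or-None)."""
    with h5py.File(path, "a") as h5:
        h5.attrs["package_version"] = PACKAGE_VERSION
        if config is not None:
            h5.attrs["config_hash"] = config.hash()
            h5.attrs["config_json"] = json.dumps(dataclasses.asdict(config))
        for k, v in (meta or {}).items():
            h5.attrs[k] = v
        if trains is not None:
            save_events(h5, trains, bundle_of_channel)
        if bundle_of_channel is not None:
            if "bundle_of_channel" in h5:
                del h5["bundle_of_channel"]
            h5.create_dataset("bundle_of_channel",
                              data=np.asarray(bundle_of_channel, dtype=np.int64))
        for epoch, tensor in (tensors or {}).items():
            tg = h5.require_group("tensors")
            if epoch in tg:
                del tg[epoch]
            d = tg.create_dataset(epoch, data=np.asarray(tensor, dtype=np.float32))
            d.attrs["shape_order"] = "window,polarity,channel,bin"
        if labels is not None:
            if "labels" in h5:
                del h5["labels"]
            h5.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        if vocalizations is not None:
            rg = h5.require_group("recall")
            if "vocalizations" in rg:
                del rg["vocalizations"]
            st = h5py.string_dtype()
            dt = np.dtype([("time_s", "f8"), ("word", st), ("concept", st)])
            rows = np.array([(t, w, "" if c is None else str(c))
                             for t, w, c in vocalizations], dtype=dt)
            rg.create_dataset("vocalizations", data=rows)
        for name, act in (activations or {}).items():
            ag = h5.require_group("activations")
            if name in ag:
                del ag[name]
            ag.create_dataset(name, data=np.asarray(act, dtype=np.float32))


def load_study(path) -> dict:
    out: dict = {"tensors": {}, "activations": {}}
    with h5py.File(path, "r") as h5:
        out["attrs"] = dict(h5.attrs)
        if "events" in h5:
            out["trains"] = load_events(h5)
        if "bundle_of_channel" in h5:
            out["bundle_of_channel"] = np.asarray(h5["bundle_of_channel"])
        for epoch in h5.get("tensors", {}):
            out["tensors"][epoch] = np.asarray(h5["tensors"][epoch])
        if "labels" in h5:
            out["labels"] = np.asarray(h5["labels"])
        if "recall" in h5 and "vocalizations" in h5["recall"]:
            rows = h5["recall"]["vocalizations"][()]
            out["vocalizations"] = [
                (float(r["time_s"]),
                 r["word"].decode() if isinstance(r["word"], bytes) else r["word"],
                 (r["concept"].decode() if isinstance(r["concept"], bytes)
                  else r["concept"]) or None)
                for r in rows]
        for name in h5.get("activations", {}):
            out["activations"][name] = np.asarray(h5["activations"][name])
    return out


# ---------------------------------------------------------------- checkpoints


def save_model(path, model) -> None:
    """Self-describing checkpoint: parameter arrays in order plus the
    model config and region shapes as JSON."""
    cfg = dataclasses.asdict(model.config)
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {"config": cfg, "region_shapes": [list(s) for s in model.region_shapes],
            "kind": type(model).__name__}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path):
    from .model.network import (LogisticBaseline, ModelConfig,
                                MultiRegionTransformer)
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cls = {"MultiRegionTransformer": MultiRegionTransformer,
               "LogisticBaseline": LogisticBaseline}[meta["kind"]]
        model = cls([tuple(s) for s in meta["region_shapes"]],
                    ModelConfig(**meta["config"]))
        params = model.parameters()
        for i, p in enumerate(params):
            arr = z[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError("checkpoint incompatible with rebuilt model")
            p.data = arr.astype(p.data.dtype)
    return model


def write_run_log(path, record: dict) -> None:
    """Append one line-delimited JSON record (seed, config hash, ...)."""
    with open(path, "a") as f:
        f.write(json.dumps(record, default=str) + "\n")
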