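"""Serialization of the pipeline containers.

Recordings and feature tables round-trip through HDF5; electrode
layouts and effect maps through YAML; feature tables also export to a
long-format CSV for downstream tools.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .containers import BandTable, FeatureTable, RawRecording
from .synth import EffectMap, ElectrodeLayout

__all__ = [
    "save_recording", "load_recording",
    "save_features", "load_features", "features_to_csv",
    "save_layout", "load_layout",
    "save_effects", "load_effects",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_recording(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset("positions", data=rec.positions)
        f.create_dataset("good_mask", data=rec.good_mask)
        if rec.labels is not None:
            f.create_dataset("labels", data=np.array(rec.labels, dtype=_STR))
        f.attrs["block_duration_s"] = rec.block_duration_s
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        labels = None
        if "labels" in f:
            labels = [s.decode() if isinstance(s, bytes) else str(s)
                      for s in f["labels"][()]]
        return RawRecording(
            data=f["data"][()],
            fs=float(f["fs"][()]),
            positions=f["positions"][()],
            good_mask=f["good_mask"][()],
            block_duration_s=float(f.attrs["block_duration_s"]),
            labels=labels,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_features(table: FeatureTable, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=table.values)
        f.create_dataset("keep_mask", data=table.keep_mask)
        f.create_dataset("positions", data=table.positions)
        if table.labels is not None:
            f.create_dataset("labels",
                             data=np.array(list(table.labels), dtype=_STR))
        f.attrs["bin_s"] = table.bin_s
        f.attrs["block_duration_s"] = table.block_duration_s
        f.attrs["band_names"] = [b.name for b in table.band_table]
        f.attrs["band_lows"] = [b.low for b in table.band_table]
        f.attrs["band_highs"] = [b.high for b in table.band_table]


def load_features(path) -> FeatureTable:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["band_names"]]
        bands = BandTable.from_pairs(list(zip(
            names, f.attrs["band_lows"], f.attrs["band_highs"])))
        labels = None
        if "labels" in f:
            labels = np.array([s.decode() if isinstance(s, bytes) else str(s)
                               for s in f["labels"][()]], dtype=object)
        return FeatureTable(
            values=f["values"][()], bin_s=float(f.attrs["bin_s"]),
            band_table=bands, positions=f["positions"][()],
            labels=labels, keep_mask=f["keep_mask"][()],
            block_duration_s=float(f.attrs["block_duration_s"]),
        )


def features_to_csv(table: FeatureTable, path) -> None:
    """Long-format export: (bin, channel, band, value, label, kept)."""
    import pandas as pd
    bins, chans, bands = np.meshgrid(
        np.arange(table.n_bins), np.arange(table.n_channels),
        np.arange(len(table.band_table)), indexing="ij")
    df = pd.DataFrame({
        "bin": bins.ravel(),
        "channel": chans.ravel(),
        "band": np.array(table.band_table.names)[bands.ravel()],
        "value": table.values.ravel(),
        "label": (np.repeat(np.asarray(table.labels, dtype=object),
                            table.n_channels * len(table.band_table))
                  if table.labels is not None else ""),
        "kept": np.repeat(table.keep_mask,
                          table.n_channels * len(table.band_table)),
    })
    df.to_csv(path, index=False)


def save_layout(layout: ElectrodeLayout, path) -> None:
    doc = {
        "electrode_ids": list(layout.electrode_ids),
        "positions": [[float(x) for x in p] for p in layout.positions],
        "roi_centroids": {k: [float(x) for x in v]
                          for k, v in layout.roi_centroids.items()},
        "true_roi": list(layout.true_roi),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_layout(path) -> ElectrodeLayout:
    doc = yaml.safe_load(Path(path).read_text())
    return ElectrodeLayout(
        electrode_ids=tuple(doc["electrode_ids"]),
        positions=np.asarray(doc["positions"], dtype=float),
        roi_centroids={k: np.asarray(v, dtype=float)
                       for k, v in doc["roi_centroids"].items()},
        true_roi=tuple(doc.get("true_roi", ())),
    )


def save_effects(effects: EffectMap, path) -> None:
    doc = [{"roi": r, "band": b, "state": s, "multiplier": float(m)}
           for (r, b, s), m in effects.entries.items()]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_effects(path) -> EffectMap:
    doc = yaml.safe_load(Path(path).read_text()) or []
    return EffectMap({(e["roi"], e["band"], e["state"]): float(e["multiplier"])
                      for e in doc})
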