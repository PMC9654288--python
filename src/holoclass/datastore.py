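"""HDF5 dataset container and manifest I/O.

One file holds the whole labelled dataset: ``/samples/<id>/amplitude`` and
``/samples/<id>/phase`` as float32 planes, with label, focus and per-sample
seed as attributes, and the optics stored once at the root.  The manifest is
mirrored as a CSV with columns ``id,label,true_focus_um,split,seed`` so the
dataset remains inspectable without HDF5 tooling.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import DatasetManifest, HologramSample
from .wave_optics import AmplitudePhasePair, OpticalParams

__all__ = ["save_dataset", "load_dataset", "save_sample_tiff"]


def save_dataset(
    path: str | Path,
    manifest: DatasetManifest,
    samples: list[HologramSample],
) -> None:
    """Write samples and manifest to ``path`` (manifest CSV written alongside)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if len(manifest.records) != len(samples):
        raise ValueError("manifest and sample list lengths differ")
    with h5py.File(path, "w") as f:
        first = samples[0].params
        f.attrs["wavelength_um"] = first.wavelength_um
        f.attrs["pixel_pitch_um"] = first.pixel_pitch_um
        grp = f.create_group("samples")
        for row, sample in zip(manifest.records.itertuples(index=False), samples):
            g = grp.create_group(row.id)
            g.create_dataset("amplitude", data=sample.pair.amplitude.astype(np.float32))
            g.create_dataset("phase", data=sample.pair.phase.astype(np.float32))
            g.attrs["label"] = sample.label
            g.attrs["focus_offset_um"] = sample.focus_offset_um
            g.attrs["seed"] = int(row.seed)
    manifest.to_csv(path.with_suffix(".csv"))


def load_dataset(path: str | Path) -> tuple[DatasetManifest, list[HologramSample]]:
    """Load a dataset container written by :func:`save_dataset`."""
    path = Path(path)
    records = pd.read_csv(path.with_suffix(".csv"), keep_default_na=False)
    samples: list[HologramSample] = []
    with h5py.File(path, "r") as f:
        params = OpticalParams(
            wavelength_um=float(f.attrs["wavelength_um"]),
            pixel_pitch_um=float(f.attrs["pixel_pitch_um"]),
        )
        for row in records.itertuples(index=False):
            g = f["samples"][row.id]
            pair = AmplitudePhasePair(
                amplitude=np.asarray(g["amplitude"], dtype=np.float64),
                phase=np.asarray(g["phase"], dtype=np.float64),
            )
            samples.append(
                HologramSample(
                    pair=pair,
                    label=str(g.attrs["label"]),
                    focus_offset_um=float(g.attrs["focus_offset_um"]),
                    params=params,
                )
            )
    counts = records["label"].value_counts().to_dict()
    return DatasetManifest(records=records, class_counts=counts), samples


def save_sample_tiff(path: str | Path, sample: HologramSample) -> None:
    """Export one sample as a 2-page float32 TIFF (amplitude, then phase)."""
    import tifffile

    stack = sample.pair.as_array(dtype=np.float32)
    tifffile.imwrite(str(path), stack)
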