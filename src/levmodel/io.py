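"""Result serialization: HDF5 containers, CSV tables, JSON summaries.

Every run writes a manifest recording the configuration hash, the seed,
the package version and a checksum per emitted file, so any figure-level
artifact can be regenerated from the manifest and configuration alone.
Output directories refuse to overwrite existing results unless forced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulator import SyntheticDataset

__all__ = ["write_results", "dataset_to_hdf5", "dataset_from_hdf5",
           "pulse_train_to_csv"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    results: dict,
    out_dir: str | Path,
    *,
    config_digest: str = "",
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Write a results bundle and return its manifest.

    ``results`` maps file stems to payloads: a ``pandas.DataFrame`` becomes
    ``<stem>.csv``, a dict becomes ``<stem>.json``, a ``SyntheticDataset``
    becomes ``<stem>.h5``.  The manifest (also written as
    ``manifest.json``) lists every emitted file with its checksum.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(
            f"{out} already holds results; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    for stem, payload in results.items():
        if isinstance(payload, pd.DataFrame):
            path = out / f"{stem}.csv"
            payload.to_csv(path, index=False)
        elif isinstance(payload, SyntheticDataset):
            path = out / f"{stem}.h5"
            dataset_to_hdf5(payload, path)
        elif isinstance(payload, dict):
            path = out / f"{stem}.json"
            path.write_text(json.dumps(payload, indent=2, default=float,
                                       sort_keys=True))
        else:
            raise TypeError(f"unsupported payload type for {stem!r}: "
                            f"{type(payload).__name__}")
        files[path.name] = _sha256(path)
    from . import __version__
    manifest = {
        "config_digest": config_digest,
        "seed": seed,
        "version": __version__,
        "files": files,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def dataset_to_hdf5(dataset: SyntheticDataset, path: str | Path) -> None:
    """Serialize a synthetic dataset (groups: protocol, eeg, bold, meta)."""
    with h5py.File(path, "w") as h5:
        meta = h5.create_group("meta")
        meta.attrs["model_id"] = dataset.model_id
        meta.attrs["seed"] = dataset.seed
        meta.attrs["snr_eeg"] = dataset.snr_eeg
        meta.attrs["snr_bold"] = dataset.snr_bold
        prot = h5.create_group("protocol")
        p = dataset.protocol
        prot.attrs["stim_duration"] = p.stim_duration
        prot.attrs["rest_duration"] = p.rest_duration
        prot.attrs["tr"] = p.tr
        prot.attrs["pulse_width"] = p.pulse_width
        prot.attrs["delay"] = p.delay
        prot.attrs["amplitude"] = p.amplitude
        prot.create_dataset("frequencies", data=np.array(p.frequencies))
        prot.create_dataset(
            "luminance",
            data=np.array([p.luminance_factors[f] for f in p.frequencies]))
        for grp, series in (("eeg", dataset.eeg), ("bold", dataset.bold),
                            ("eeg_clean", dataset.eeg_clean),
                            ("bold_clean", dataset.bold_clean)):
            g = h5.create_group(grp)
            for f, arr in series.items():
                g.create_dataset(str(f), data=np.asarray(arr))


def dataset_from_hdf5(path: str | Path) -> SyntheticDataset:
    """Load a synthetic dataset written by :func:`dataset_to_hdf5`."""
    from .simulator import LEVParams
    from .stimulus import StimulusProtocol

    with h5py.File(path, "r") as h5:
        freqs = tuple(float(f) for f in h5["protocol/frequencies"][...])
        lum = {f: float(v) for f, v in
               zip(freqs, h5["protocol/luminance"][...])}
        pa = h5["protocol"].attrs
        protocol = StimulusProtocol(
            frequencies=freqs, stim_duration=float(pa["stim_duration"]),
            rest_duration=float(pa["rest_duration"]), tr=float(pa["tr"]),
            pulse_width=float(pa["pulse_width"]), delay=float(pa["delay"]),
            amplitude=float(pa["amplitude"]), luminance_factors=lum)

        def grab(name):
            return {float(k): h5[name][k][...] for k in h5[name]}

        meta = h5["meta"].attrs
        return SyntheticDataset(
            model_id=str(meta["model_id"]),
            true_params=LEVParams.priors(),  # generating record not stored
            protocol=protocol,
            eeg=grab("eeg"), bold=grab("bold"),
            eeg_clean=grab("eeg_clean"), bold_clean=grab("bold_clean"),
            snr_eeg=float(meta["snr_eeg"]), snr_bold=float(meta["snr_bold"]),
            seed=int(meta["seed"]))


def pulse_train_to_csv(train, path: str | Path) -> None:
    """Two-column (time_s, value) CSV export of a pulse train."""
    pd.DataFrame({"time_s": train.times, "value": train.values}).to_csv(
        path, index=False)
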