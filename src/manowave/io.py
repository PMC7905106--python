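"""HDF5/CSV/JSON persistence for pipeline artifacts.

Recordings travel as an HDF5 matrix (rows = channels, proximal first)
with a JSON sidecar of sampling metadata and experimental labels; spectra
and posterior draws as annotated HDF5 containers with named datasets.
CSV input (channels x time, no header) is accepted for recordings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import PressureRecording, RecordingMeta
from .wavelet import FrequencyGrid, Spectrum1D
from .cross import PhaseGrid, Spectrum2D
from .model import ModelSpec, PosteriorDraws

__all__ = [
    "save_recording", "load_recording",
    "save_spectrum", "load_spectrum",
    "save_draws", "load_draws",
]


def save_recording(rec: PressureRecording, path, meta_path=None) -> None:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("pressures", data=rec.pressures)
        f.attrs["fs_hz"] = rec.fs
        f.attrs["spacing_cm"] = rec.spacing
        if rec.mask is not None:
            f.create_dataset("mask", data=rec.mask)
        for k, v in rec.meta.as_dict().items():
            f.attrs[f"meta_{k}"] = v
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps(
            {**rec.meta.as_dict(), "fs_hz": rec.fs,
             "spacing_cm": rec.spacing}, indent=2))


def load_recording(path, meta_path=None) -> PressureRecording:
    path = Path(path)
    side = {}
    if meta_path is not None:
        side = json.loads(Path(meta_path).read_text())
    if path.suffix in (".csv", ".tsv", ".txt"):
        delim = "," if path.suffix == ".csv" else None
        p = np.loadtxt(path, delimiter=delim)
        mask = None
        attrs = {}
    else:
        import h5py

        with h5py.File(path, "r") as f:
            p = f["pressures"][...]
            mask = f["mask"][...] if "mask" in f else None
            attrs = dict(f.attrs)
    fs = side.get("fs_hz", attrs.get("fs_hz"))
    spacing = side.get("spacing_cm", attrs.get("spacing_cm", 1.0))
    if fs is None:
        raise ValueError("sampling rate fs_hz missing from file and sidecar")
    meta = RecordingMeta(
        subject=str(side.get("subject", attrs.get("meta_subject", "s0"))),
        group=str(side.get("group", attrs.get("meta_group", "healthy"))),
        region=str(side.get("region",
                            attrs.get("meta_region", "descending"))),
        meal=str(side.get("meal", attrs.get("meta_meal", "preprandial"))),
        nchan=int(side.get("nchan", attrs.get("meta_nchan", p.shape[0]))))
    return PressureRecording(p, fs=float(fs), spacing=float(spacing),
                             meta=meta, mask=mask)


def save_spectrum(spec, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        if isinstance(spec, Spectrum1D):
            f.attrs["kind"] = "spectrum1d"
            f.create_dataset("y", data=spec.y)
            f.create_dataset("freq_centers", data=spec.grid.centers)
            f.create_dataset("freq_edges", data=spec.grid.edges)
            f.attrs["meta_json"] = json.dumps(spec.meta)
        elif isinstance(spec, Spectrum2D):
            f.attrs["kind"] = "spectrum2d"
            f.create_dataset("y", data=spec.y)
            f.create_dataset("freq_centers", data=spec.fgrid.centers)
            f.create_dataset("freq_edges", data=spec.fgrid.edges)
            f.attrs["n_phase"] = spec.pgrid.n
            if spec.power is not None:
                f.create_dataset("power", data=spec.power)
            if spec.counts is not None:
                f.create_dataset("counts", data=spec.counts)
            f.attrs["meta_json"] = json.dumps(spec.meta)
        else:
            raise TypeError(f"cannot save {type(spec).__name__}")


def load_spectrum(path):
    import h5py

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        grid = FrequencyGrid(f["freq_centers"][...], f["freq_edges"][...])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        if kind == "spectrum1d":
            return Spectrum1D(f["y"][...], grid, meta)
        pgrid = PhaseGrid(int(f.attrs["n_phase"]))
        power = f["power"][...] if "power" in f else None
        counts = f["counts"][...] if "counts" in f else None
        return Spectrum2D(f["y"][...], grid, pgrid, power=power,
                          counts=counts, meta=meta)


def save_draws(draws: PosteriorDraws, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("beta", "b", "gamma"):
            f.create_dataset(name, data=getattr(draws, name))
        hg = f.create_group("hyper")
        for k, v in draws.hyper.items():
            hg.create_dataset(k, data=v)
        f.attrs["diagnostics_json"] = json.dumps(draws.diagnostics)
        f.attrs["offset"] = np.asarray(draws.offset)
        if draws.spec is not None:
            f.create_dataset("freq_centers", data=draws.spec.fgrid.centers)
            f.create_dataset("freq_edges", data=draws.spec.fgrid.edges)
            if draws.spec.pgrid is not None:
                f.attrs["n_phase"] = draws.spec.pgrid.n


def load_draws(path) -> PosteriorDraws:
    import h5py

    with h5py.File(path, "r") as f:
        spec = None
        if "freq_centers" in f:
            grid = FrequencyGrid(f["freq_centers"][...],
                                 f["freq_edges"][...])
            pgrid = PhaseGrid(int(f.attrs["n_phase"])) \
                if "n_phase" in f.attrs else None
            spec = ModelSpec(fgrid=grid, pgrid=pgrid)
        return PosteriorDraws(
            beta=f["beta"][...], b=f["b"][...], gamma=f["gamma"][...],
            hyper={k: v[...] for k, v in f["hyper"].items()},
            diagnostics=json.loads(f.attrs.get("diagnostics_json", "{}")),
            spec=spec, offset=np.asarray(f.attrs.get("offset", 0.0)))
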