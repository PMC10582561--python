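"""On-disk formats: force-curve containers, channel maps, manifests.

A force-volume map is stored either as a directory of per-curve CSV files
(columns ``segment, displacement_nm, force_nN``; segment is ``approach``
or ``retract``) with a ``metadata.json`` sidecar, or as a single HDF5 file
with ``/curves/<row>_<col>`` groups.  Channel maps are written as plain
CSV grids (one file per channel) and optionally as single-channel TIFF.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .forcecurve import ForceCurve, ProbeSpec

__all__ = [
    "write_map_dir",
    "read_map_dir",
    "write_map_hdf5",
    "read_map_hdf5",
    "write_channel_maps",
    "read_channel_maps",
    "write_nanomech_map",
    "read_nanomech_map",
]


def _metadata(probe: ProbeSpec, grid_shape, extra: dict | None) -> dict:
    meta = {"probe": asdict(probe), "grid_shape": list(grid_shape)}
    meta.update(extra or {})
    return meta


def _parse_probe(meta: dict) -> ProbeSpec:
    return ProbeSpec(**meta["probe"])


def _curve_frame(curve: ForceCurve) -> pd.DataFrame:
    seg = ["approach"] * len(curve.approach) + ["retract"] * len(curve.retract)
    data = np.vstack([curve.approach, curve.retract])
    return pd.DataFrame(
        {"segment": seg, "displacement_nm": data[:, 0], "force_nN": data[:, 1]}
    )


def write_map_dir(
    directory,
    curves: list[ForceCurve],
    probe: ProbeSpec,
    grid_shape: tuple[int, int],
    extra_metadata: dict | None = None,
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "metadata.json").write_text(
        json.dumps(_metadata(probe, grid_shape, extra_metadata), indent=1)
    )
    for curve in curves:
        r, c = curve.pixel_index
        _curve_frame(curve).to_csv(
            directory / f"curve_{r:03d}_{c:03d}.csv", index=False,
            float_format="%.8g",
        )


def read_map_dir(directory) -> tuple[list[ForceCurve], ProbeSpec, dict]:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    curves = []
    for path in sorted(directory.glob("curve_*.csv")):
        r, c = (int(s) for s in path.stem.split("_")[1:3])
        frame = pd.read_csv(path)
        app = frame[frame["segment"] == "approach"]
        ret = frame[frame["segment"] == "retract"]
        curves.append(
            ForceCurve(
                approach=app[["displacement_nm", "force_nN"]].to_numpy(),
                retract=ret[["displacement_nm", "force_nN"]].to_numpy(),
                pixel_index=(r, c),
            )
        )
    return curves, _parse_probe(meta), meta


def write_map_hdf5(
    path,
    curves: list[ForceCurve],
    probe: ProbeSpec,
    grid_shape: tuple[int, int],
    extra_metadata: dict | None = None,
) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(_metadata(probe, grid_shape, extra_metadata))
        grp = f.create_group("curves")
        for curve in curves:
            r, c = curve.pixel_index
            g = grp.create_group(f"{r}_{c}")
            g.create_dataset("approach", data=curve.approach)
            g.create_dataset("retract", data=curve.retract)


def read_map_hdf5(path) -> tuple[list[ForceCurve], ProbeSpec, dict]:
    import h5py

    curves = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        for name, g in f["curves"].items():
            r, c = (int(s) for s in name.split("_"))
            curves.append(
                ForceCurve(
                    approach=g["approach"][()],
                    retract=g["retract"][()],
                    pixel_index=(r, c),
                )
            )
    curves.sort(key=lambda cv: cv.pixel_index)
    return curves, _parse_probe(meta), meta


def write_channel_maps(
    directory, channels: dict[str, np.ndarray], prefix: str = "", tiff: bool = False
) -> None:
    """One CSV grid per channel (substrate = 0 convention for Morpho);
    optional 32-bit single-channel TIFF alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in channels.items():
        np.savetxt(directory / f"{prefix}{name}.csv", arr, delimiter=",", fmt="%.8g")
        if tiff:
            import tifffile

            tifffile.imwrite(
                directory / f"{prefix}{name}.tiff", arr.astype(np.float32)
            )


def read_channel_maps(directory, prefix: str = "") -> dict[str, np.ndarray]:
    directory = Path(directory)
    out = {}
    for name in ("Adh", "MechH", "MechL", "Morpho"):
        path = directory / f"{prefix}{name}.csv"
        if path.exists():
            out[name] = np.loadtxt(path, delimiter=",", ndmin=2)
    if not out:
        raise FileNotFoundError(f"no channel CSVs under {directory}")
    return out


def write_nanomech_map(directory, nmap) -> None:
    """Persist a processed per-cell map: channel CSV grids plus mask/valid
    grids and a map.json with label and cell id."""
    directory = Path(directory)
    write_channel_maps(directory, nmap.channels)
    np.savetxt(directory / "valid.csv", nmap.valid.astype(int), delimiter=",", fmt="%d")
    if nmap.mask is not None:
        np.savetxt(directory / "mask.csv", nmap.mask.astype(int), delimiter=",", fmt="%d")
    (directory / "map.json").write_text(
        json.dumps({"label": nmap.label, "cell_id": nmap.cell_id})
    )


def read_nanomech_map(directory):
    from .mapbuild import NanomechMap

    directory = Path(directory)
    channels = read_channel_maps(directory)
    meta = json.loads((directory / "map.json").read_text())
    valid_path = directory / "valid.csv"
    mask_path = directory / "mask.csv"
    valid = (
        np.loadtxt(valid_path, delimiter=",", ndmin=2).astype(bool)
        if valid_path.exists() else None
    )
    mask = (
        np.loadtxt(mask_path, delimiter=",", ndmin=2).astype(bool)
        if mask_path.exists() else None
    )
    return NanomechMap(channels=channels, mask=mask, valid=valid,
                       label=meta["label"], cell_id=meta["cell_id"])
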