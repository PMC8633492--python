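"""Readers and writers for the pipeline's file formats.

Label volumes go to multi-page TIFF (one page per z-slice, 8-bit labels,
voxel metadata in the image description) and to NRRD with voxel-size
metadata.  The NRRD codec is a deliberately minimal raw-encoding
implementation of the text-header format, since only detached raw headers
are needed here.  Tables are plain CSV/TSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .geometry import FibreSet, incline_summary
from .synthetic_data import LabelVolume, VolumeSpec


def write_label_volume_tiff(volume: LabelVolume, path) -> None:
    meta = {"field_of_view_mm": list(volume.spec.field_of_view),
            "labels": {"0": "background", "1": "matrix",
                       "2": "inner_bundle", "3": "outer_bundle"}}
    tifffile.imwrite(path, volume.data.astype(np.uint8),
                     description=json.dumps(meta))


def read_label_volume_tiff(path) -> LabelVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    if data.ndim == 2:
        data = data[None]
    fov = (float(data.shape[2]), float(data.shape[1]), float(data.shape[0]))
    if desc:
        try:
            fov = tuple(json.loads(desc)["field_of_view_mm"])
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
    spec = VolumeSpec(shape=(data.shape[2], data.shape[1], data.shape[0]),
                      field_of_view=fov)
    return LabelVolume(data.astype(np.uint8), spec)


def write_label_volume_nrrd(volume: LabelVolume, path) -> None:
    """Raw-encoded NRRD (version 4 header) with per-axis spacings in mm."""
    vx, vy, vz = volume.spec.voxel_size
    nx, ny, nz = volume.spec.shape
    header = "\n".join([
        "NRRD0004",
        "# culmforce label volume",
        "type: uint8",
        "dimension: 3",
        f"sizes: {nx} {ny} {nz}",
        f"spacings: {vx:.9g} {vy:.9g} {vz:.9g}",
        "encoding: raw",
        "endian: little",
        "", "",
    ])
    # sizes are fastest-to-slowest (x y z); our array is (z, y, x) C-order,
    # which serializes x fastest as required
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(volume.data, dtype=np.uint8).tobytes())


def read_label_volume_nrrd(path) -> LabelVolume:
    with open(path, "rb") as fh:
        raw = fh.read()
    head, _, body = raw.partition(b"\n\n")
    fields = {}
    for line in head.decode("ascii").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw" or fields.get("type") != "uint8":
        raise ValidationError("only raw uint8 NRRD volumes are supported")
    nx, ny, nz = (int(v) for v in fields["sizes"].split())
    vx, vy, vz = (float(v) for v in fields.get("spacings", "1 1 1").split())
    data = np.frombuffer(body[: nx * ny * nz], dtype=np.uint8).reshape(nz, ny, nx)
    spec = VolumeSpec(shape=(nx, ny, nz),
                      field_of_view=(vx * nx, vy * ny, vz * nz))
    return LabelVolume(data.copy(), spec)


def read_label_volume(path) -> LabelVolume:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_label_volume_tiff(path)
    if path.suffix.lower() == ".nrrd":
        return read_label_volume_nrrd(path)
    raise ValidationError(f"unsupported volume format: {path.suffix}")


def write_fibres_csv(fibres: FibreSet, path) -> None:
    rows = []
    for i, (f, ring) in enumerate(zip(fibres.fibres, fibres.ring_labels)):
        for x, y, z in f.points:
            rows.append({"fibre_id": i, "ring": ring,
                         "z_mm": z, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_incline_summary_csv(fibres: FibreSet, path) -> None:
    s = incline_summary(fibres)
    rows = [{"ring": ring, **s[ring]} for ring in ("outer", "inner")]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spectrum_csv(wavenumbers, absorbance, path) -> None:
    pd.DataFrame({"wavenumber_cm1": wavenumbers,
                  "absorbance": absorbance}).to_csv(path, index=False)


def read_spectrum_csv(path):
    df = pd.read_csv(path)
    missing = {"wavenumber_cm1", "absorbance"} - set(df.columns)
    if missing:
        raise ValidationError(f"spectrum CSV missing columns: {sorted(missing)}")
    return df["wavenumber_cm1"].to_numpy(float), df["absorbance"].to_numpy(float)


def read_map_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"marker_id", "chromosome", "position_cM"} - set(df.columns)
    if missing:
        raise ValidationError(f"map TSV missing columns: {sorted(missing)}")
    return df
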