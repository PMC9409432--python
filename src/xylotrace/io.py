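"""File formats: volumes (multi-page TIFF + JSON sidecar, NRRD), masks,
ground truth JSON, YAML configuration and metrics CSV.

Axis convention in every format: (z, y, x), z = trunk axial direction,
0-based voxel indices, world coordinates = index * spacing in mm.

NRRD support is a minimal self-contained reader/writer for the subset this
package emits (raw encoding, little endian, 3D, ``space directions``
diagonal): enough for interchange with common viewers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantom import GalleryTruth, RingModel
from .types import CTVolume, GalleryMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_nrrd",
    "write_nrrd",
    "write_mask",
    "read_mask",
    "write_truths",
    "read_truths",
    "write_metrics_csv",
    "load_yaml_config",
    "dump_yaml_config",
]

_NRRD_TYPES = {
    np.dtype("float32"): "float",
    np.dtype("float64"): "double",
    np.dtype("int16"): "short",
    np.dtype("int32"): "int",
    np.dtype("uint8"): "uchar",
}
_NRRD_TYPES_REV = {
    "float": np.float32,
    "double": np.float64,
    "short": np.int16,
    "int": np.int32,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
}


def write_nrrd(path, array: np.ndarray, spacing) -> None:
    """Write a 3D array as NRRD0004, raw encoding, little endian."""
    array = np.ascontiguousarray(array)
    if array.dtype not in _NRRD_TYPES:
        raise ValueError(f"unsupported dtype {array.dtype}")
    dz, dy, dx = spacing
    header = [
        "NRRD0004",
        "# produced by xylotrace",
        f"type: {_NRRD_TYPES[array.dtype]}",
        "dimension: 3",
        "space: left-posterior-superior",
        f"sizes: {array.shape[0]} {array.shape[1]} {array.shape[2]}",
        f"space directions: ({dz},0,0) (0,{dy},0) (0,0,{dx})",
        "kinds: domain domain domain",
        "endian: little",
        "encoding: raw",
        "space origin: (0,0,0)",
        "",
        "",
    ]
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode())
        data = array.astype(array.dtype.newbyteorder("<"), copy=False)
        fh.write(data.tobytes(order="C"))


def read_nrrd(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read the NRRD subset written by :func:`write_nrrd`."""
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"\n\n")
    if end < 0:
        raise ValueError(f"{path}: malformed NRRD header")
    fields: dict[str, str] = {}
    lines = raw[:end].decode().splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    for line in lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, val = line.split(":", 1)
        fields[key.strip()] = val.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw-encoded NRRD is supported")
    shape = tuple(int(s) for s in fields["sizes"].split())
    dtype = np.dtype(_NRRD_TYPES_REV[fields["type"]])
    if fields.get("endian", "little") == "big":
        dtype = dtype.newbyteorder(">")
    spacing = None
    if "space directions" in fields:
        vecs = [
            [float(x) for x in v.strip("()").split(",")]
            for v in fields["space directions"].split()
        ]
        spacing = tuple(float(np.linalg.norm(v)) for v in vecs)
    elif "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    if spacing is None:
        raise ValueError(f"{path}: NRRD carries no spacing information")
    data = np.frombuffer(raw[end + 2 :], dtype=dtype)
    if data.size != int(np.prod(shape)):
        raise ValueError(f"{path}: data size does not match header sizes")
    return data.reshape(shape).astype(dtype.newbyteorder("=")), spacing


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path, volume: CTVolume) -> None:
    """Write a volume as NRRD (.nrrd) or multi-page TIFF plus a JSON spacing
    sidecar (any other suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        write_nrrd(path, volume.voxels.astype(np.float32), volume.spacing)
        return
    tifffile.imwrite(path, volume.voxels.astype(np.float32))
    _sidecar(path).write_text(
        json.dumps({"spacing_mm": list(volume.spacing), "axes": "zyx"})
    )


def read_volume(path) -> CTVolume:
    """Read a volume written by :func:`write_volume`.

    TIFF stacks require the JSON sidecar with ``spacing_mm``; NRRD carries
    its spacing in the header.
    """
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        vox, spacing = read_nrrd(path)
        return CTVolume(vox, spacing)
    vox = tifffile.imread(path)
    if vox.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {vox.shape}")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"{path}: TIFF volumes need a spacing sidecar {side.name} "
            '({"spacing_mm": [dz, dy, dx]})'
        )
    meta = json.loads(side.read_text())
    return CTVolume(vox, tuple(meta["spacing_mm"]))


def write_mask(path_labels, path_blocked, mask: GalleryMask) -> None:
    write_nrrd(path_labels, mask.labels.astype(np.int32), mask.spacing)
    write_nrrd(path_blocked, mask.blocked.astype(np.uint8), mask.spacing)


def read_mask(path_labels, path_blocked) -> GalleryMask:
    labels, spacing = read_nrrd(path_labels)
    blocked, _ = read_nrrd(path_blocked)
    return GalleryMask(labels, blocked.astype(bool), spacing)


def _truth_dict(t: GalleryTruth) -> dict:
    return {
        "type_label": t.type_label,
        "centerline_mm": t.centerline_mm.tolist(),
        "radius_profile_mm": t.radius_profile_mm.tolist(),
        "blocked_intervals_mm": [list(iv) for iv in t.blocked_intervals_mm],
        "entrance_index": t.entrance_index,
        "emergence_index": t.emergence_index,
        "branch_mm": None if t.branch_mm is None else t.branch_mm.tolist(),
        "branch_radius_mm": None
        if t.branch_radius_mm is None
        else np.asarray(t.branch_radius_mm).tolist(),
        "branch_attach": t.branch_attach,
        "larva_present": t.larva_present,
        "larva_pose": t.larva_pose,
        "requested": t.requested,
    }


def write_truths(path, truths: list[GalleryTruth], ring: RingModel, seed=None) -> None:
    """Ground truth as JSON: centerlines in mm world coordinates, plus the
    ring model (pith axis) and the generator seed."""
    doc = {
        "seed": seed,
        "ring": {
            "pith_mm": ring.pith_mm.tolist(),
            "ring_period_mm": ring.ring_period_mm,
            "band_attenuations": list(ring.band_attenuations),
            "trunk_radius_mm": ring.trunk_radius_mm,
            "center_mm": list(ring.center_mm),
            "bark_thickness_mm": ring.bark_thickness_mm,
            "earlywood_fraction": ring.earlywood_fraction,
        },
        "galleries": [_truth_dict(t) for t in truths],
    }
    Path(path).write_text(json.dumps(doc))


def read_truths(path) -> tuple[list[GalleryTruth], RingModel, object]:
    doc = json.loads(Path(path).read_text())
    r = doc["ring"]
    ring = RingModel(
        pith_mm=np.asarray(r["pith_mm"]),
        ring_period_mm=r["ring_period_mm"],
        band_attenuations=tuple(r["band_attenuations"]),
        trunk_radius_mm=r["trunk_radius_mm"],
        center_mm=tuple(r["center_mm"]),
        bark_thickness_mm=r.get("bark_thickness_mm", 0.0),
        earlywood_fraction=r.get("earlywood_fraction", 0.6),
    )
    truths = []
    for g in doc["galleries"]:
        truths.append(
            GalleryTruth(
                type_label=g["type_label"],
                centerline_mm=np.asarray(g["centerline_mm"]),
                radius_profile_mm=np.asarray(g["radius_profile_mm"]),
                blocked_intervals_mm=[tuple(iv) for iv in g["blocked_intervals_mm"]],
                entrance_index=g["entrance_index"],
                emergence_index=g["emergence_index"],
                branch_mm=None if g["branch_mm"] is None else np.asarray(g["branch_mm"]),
                branch_radius_mm=None
                if g["branch_radius_mm"] is None
                else np.asarray(g["branch_radius_mm"]),
                branch_attach=g["branch_attach"],
                larva_present=g["larva_present"],
                larva_pose=g["larva_pose"],
                requested=g.get("requested", {}),
            )
        )
    return truths, ring, doc.get("seed")


def write_metrics_csv(path, metrics) -> None:
    """Per-gallery metrics table, one row per label, fixed column order."""
    import pandas as pd

    rows = [m.as_row() if hasattr(m, "as_row") else m for m in metrics]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return doc


def dump_yaml_config(path, config) -> None:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
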