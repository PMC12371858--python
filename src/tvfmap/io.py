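"""NIfTI-1 and CSV input/output.

Multi-echo stacks are stored as NIfTI-1 with the echo dimension last
(rows, cols, 1, echoes); since NIfTI-1 has no standard field for echo
timing, the acquisition protocol is written to a JSON sidecar next to the
image (``<stem>.protocol.json``).  Parametric maps and ROI labels are
plain 2-D NIfTI-1 images (units recorded in the header description).
Tables are CSV with a comment header recording the seed and a hash of the
generating configuration, deterministic column order, and full-precision
floats.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cartography import MultiEchoImage, ParametricMap, ROILabels
from .protocols import MESEProtocol, MGEProtocol, get_preset, protocol_from_dict

__all__ = [
    "write_multiecho_nifti",
    "read_multiecho_nifti",
    "write_map_nifti",
    "read_map_nifti",
    "write_labels_nifti",
    "read_labels_nifti",
    "write_table",
    "config_hash",
]


def _sidecar_path(path: Path) -> Path:
    stem = path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return path.with_name(stem + ".protocol.json")


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()[:12]


def write_multiecho_nifti(image: MultiEchoImage, path: str | Path) -> Path:
    """Write a multi-echo image as 4-D NIfTI-1 plus a protocol sidecar."""
    path = Path(path)
    data = image.data[:, :, None, :]  # echo as 4th dimension
    img = nib.Nifti1Image(data.astype(np.float64), affine=np.eye(4))
    img.header["descrip"] = b"multi-echo stack; echo dim 4; times in sidecar"
    nib.save(img, str(path))
    sidecar = {"protocol": image.protocol.to_dict()}
    if image.mask is not None:
        mask_img = nib.Nifti1Image(image.mask.astype(np.uint8), affine=np.eye(4))
        mask_path = path.with_name(_sidecar_path(path).name.replace(".protocol.json", ".mask.nii.gz"))
        nib.save(mask_img, str(mask_path))
        sidecar["mask_file"] = mask_path.name
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_multiecho_nifti(
    path: str | Path,
    protocol: "MESEProtocol | MGEProtocol | str | None" = None,
) -> MultiEchoImage:
    """Read a 3-D/4-D NIfTI-1 stack and attach its acquisition protocol.

    The protocol comes from the JSON sidecar unless given explicitly (an
    object or a preset name).  The echo count of the image must match the
    protocol.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        if data.shape[2] != 1:
            raise ValueError(f"expected a single slice in dim 3, got shape {data.shape}")
        data = data[:, :, 0, :]
    elif data.ndim != 3:
        raise ValueError(f"expected 3-D or 4-D NIfTI, got shape {data.shape}")

    mask = None
    if protocol is None or isinstance(protocol, str):
        sidecar_file = _sidecar_path(path)
        sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
        if isinstance(protocol, str):
            protocol = get_preset(protocol)
        elif "protocol" in sidecar:
            protocol = protocol_from_dict(sidecar["protocol"])
        else:
            raise ValueError(
                f"no protocol sidecar found at {sidecar_file} and none given"
            )
        if "mask_file" in sidecar:
            mask_img = nib.load(str(path.with_name(sidecar["mask_file"])))
            mask = np.asarray(mask_img.dataobj) > 0
    if data.shape[-1] != protocol.n_echoes:
        raise ValueError(
            f"image has {data.shape[-1]} echoes but protocol "
            f"expects {protocol.n_echoes}"
        )
    return MultiEchoImage(data=data, protocol=protocol, mask=mask)


def write_map_nifti(pmap: ParametricMap, path: str | Path) -> Path:
    """Write a parametric map (invalid voxels as NaN) as 2-D NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(pmap.masked().astype(np.float64), affine=np.eye(4))
    img.header["descrip"] = f"units={pmap.units}".encode()
    nib.save(img, str(path))
    return path


def read_map_nifti(path: str | Path) -> ParametricMap:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    units = descrip.split("units=", 1)[1] if "units=" in descrip else "a.u."
    return ParametricMap(values=values, valid=np.isfinite(values), units=units)


def write_labels_nifti(labels: ROILabels, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine=np.eye(4)), str(path))
    return path


def read_labels_nifti(path: str | Path) -> ROILabels:
    img = nib.load(str(path))
    return ROILabels(labels=np.asarray(img.dataobj).astype(np.int16))


def write_table(
    records: "pd.DataFrame | list[dict]",
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write records as CSV with a reproducibility comment header.

    Column order follows the input; floats keep full precision
    (round-trips through ``read_table`` exactly).  The header records the
    seed and a hash of the generating configuration.
    """
    path = Path(path)
    frame = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    lines = ["# tvfmap table"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        frame.to_csv(fh, index=False, float_format=None)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
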