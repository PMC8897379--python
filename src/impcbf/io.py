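"""File formats: NIfTI-1 / CSV for scans and masks, CSV for TACs, JSON results.

Canonical interchange is human-diffable text — long-format CSV for curves
and JSON for results — with 4-D NIfTI-1 (time as the 4th axis) supported
for image-shaped data.  Every results file embeds the configuration hash
and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import DynamicScan, RoiMask
from .tac import RegionTacs, Tac

__all__ = [
    "write_dynamic",
    "read_dynamic",
    "write_masks",
    "read_masks",
    "write_tacs",
    "read_tacs",
    "write_results",
]

_REGIONS = ("pulmonary_artery", "lung", "brain")


def write_dynamic(scan: DynamicScan, path) -> Path:
    """Write a scan as 4-D NIfTI-1 (.nii) or long-format CSV (.csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        nt, nr, nc = scan.counts.shape
        frames = np.repeat(np.arange(nt), nr * nc)
        rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        df = pd.DataFrame({
            "frame_index": frames,
            "time_s": (frames + 0.5) * scan.frame_duration,
            "row": np.tile(rr.ravel(), nt),
            "col": np.tile(cc.ravel(), nt),
            "counts": scan.counts.ravel(),
        })
        df.attrs = {}
        header = f"# frame_duration={scan.frame_duration} pixel_size={scan.pixel_size}\n"
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        return path
    # NIfTI: spatial axes first, time last
    img = np.moveaxis(scan.counts, 0, -1)[:, :, None, :]
    affine = np.diag([scan.pixel_size, scan.pixel_size, 1.0, 1.0])
    ni = nib.Nifti1Image(img.astype(np.float64), affine)
    ni.header["pixdim"][4] = scan.frame_duration
    nib.save(ni, str(path))
    return path


def read_dynamic(path) -> DynamicScan:
    """Read a scan written by :func:`write_dynamic`; lossless for integer counts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such scan file: {path}")
    if path.suffix == ".csv":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing protocol header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            df = pd.read_csv(fh)
        nt = int(df["frame_index"].max()) + 1
        nr = int(df["row"].max()) + 1
        nc = int(df["col"].max()) + 1
        counts = np.zeros((nt, nr, nc))
        counts[df["frame_index"], df["row"], df["col"]] = df["counts"]
        if np.allclose(counts, np.round(counts)):
            counts = counts.astype(np.int64)
        return DynamicScan(counts, frame_duration=float(meta["frame_duration"]),
                           pixel_size=float(meta["pixel_size"]))
    ni = nib.load(str(path))
    data = np.asarray(ni.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image (x, y, z, time), got {data.ndim}-D "
                         "(time must be the 4th axis)")
    counts = np.moveaxis(data[:, :, 0, :], -1, 0)
    if np.allclose(counts, np.round(counts)):
        counts = np.round(counts).astype(np.int64)
    # pixdim is float32 in the header; round off the representation noise
    return DynamicScan(counts, frame_duration=round(float(ni.header["pixdim"][4]), 6),
                       pixel_size=round(float(ni.header["pixdim"][1]), 6))


def write_masks(masks: dict[str, RoiMask], path) -> Path:
    """Write ROI masks as a CSV pixel list (label, row, col)."""
    path = Path(path)
    rows = []
    for label, mask in masks.items():
        rr, cc = np.nonzero(mask.grid)
        rows.append(pd.DataFrame({"label": label, "row": rr, "col": cc}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


def read_masks(path, shape: tuple[int, int]) -> dict[str, RoiMask]:
    df = pd.read_csv(path)
    masks = {}
    for label, sub in df.groupby("label"):
        grid = np.zeros(shape, dtype=bool)
        grid[sub["row"], sub["col"]] = True
        masks[str(label)] = RoiMask(str(label), grid)
    return masks


def write_tacs(tacs: RegionTacs, path) -> Path:
    """Long-format TAC CSV (time_s, region, counts_per_s) + JSON provenance sidecar."""
    path = Path(path)
    frames = []
    for attr, label in (("c_r", "pulmonary_artery"), ("l", "lung"), ("c_b", "brain")):
        tac = getattr(tacs, attr)
        frames.append(pd.DataFrame({"time_s": tac.times, "region": label,
                                    "counts_per_s": tac.values}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump(tacs.meta, fh, indent=2, default=str)
    return path


def read_tacs(path) -> RegionTacs:
    df = pd.read_csv(path)
    tacs = {}
    for label, sub in df.groupby("region"):
        sub = sub.sort_values("time_s")
        tacs[label] = Tac(sub["time_s"].values, sub["counts_per_s"].values, label=str(label))
    missing = set(_REGIONS) - set(tacs)
    if missing:
        raise ValueError(f"TAC file {path} is missing regions: {sorted(missing)}")
    meta = {}
    sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return RegionTacs(tacs["pulmonary_artery"], tacs["lung"], tacs["brain"], meta=meta)


def _jsonable(obj):
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(results, path, config=None, seed: int | None = None) -> Path:
    """Results JSON with reproducibility provenance (config hash, seed)."""
    path = Path(path)
    payload = {"results": _jsonable(results), "seed": seed}
    if config is not None:
        payload["config_digest"] = config.digest()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    return path
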