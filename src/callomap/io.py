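"""File I/O: PNG/TIFF images, NIfTI volumes, CSV tables, YAML specs."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .geometry import CallosalMask, RoiTemplate
from .phantom import PhantomSpec
from .sampling import ModalityMap, RoiSampleTable, TABLE_COLUMNS


def read_mask(path: str | Path, spacing: tuple[float, float] = (1.0, 1.0)) -> CallosalMask:
    """Read a binary mask from PNG/TIFF (nonzero = foreground) or 2-D NIfTI."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.squeeze(np.asanyarray(img.dataobj))
        if data.ndim != 2:
            raise DataError(f"{path}: expected a 2-D mask, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        return CallosalMask(pixels=data > 0, spacing=(float(zooms[1]), float(zooms[0])))
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return CallosalMask(pixels=arr > 0, spacing=spacing)


def write_mask_png(mask: CallosalMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.pixels * np.uint8(255)))


def read_rgb(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise DataError(f"{path}: expected an RGB image, got shape {arr.shape}")
    return arr[..., :3]


def write_rgb(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(image, dtype=np.uint8))


def read_volume(path: str | Path, name: str, midsagittal_index: int | None = None) -> ModalityMap:
    """Read a NIfTI volume as a sagittal-first ModalityMap honouring pixdim.

    The NIfTI x-axis (axis 0) is taken as sagittal; if no midline index
    is given the central slice is used.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise DataError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if midsagittal_index is None:
        midsagittal_index = data.shape[0] // 2
    return ModalityMap(
        name=name, data=data, spacing=zooms, midsagittal_index=midsagittal_index
    )


def write_volume(vol: ModalityMap, path: str | Path) -> None:
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _header_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_table_csv(
    table: RoiSampleTable, path: str | Path, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines({**(provenance or {}), "units": table.units_state}))
        table.data.to_csv(fh, index=False, columns=list(TABLE_COLUMNS))


def read_table_csv(path: str | Path) -> RoiSampleTable:
    units = "raw"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# units:"):
                units = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#", dtype={"sample": str})
    return RoiSampleTable(data=df, units_state=units)


def write_template_csv(
    template: RoiTemplate, path: str | Path, provenance: dict | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance))
        template.to_frame().to_csv(fh, index=False)


def read_template_csv(path: str | Path) -> RoiTemplate:
    return RoiTemplate.from_frame(pd.read_csv(path, comment="#"))


def read_spec_yaml(path: str | Path) -> PhantomSpec:
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: spec must be a YAML mapping")
    return PhantomSpec.from_dict(d)


def write_spec_yaml(spec: PhantomSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")
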