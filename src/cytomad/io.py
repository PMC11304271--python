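"""Dataset readers/writers and configuration I/O.

The primary container is a single HDF5 file with datasets ``/bf``, ``/qpi``,
``/mask`` (and ``/qpi_clean`` when available) aligned with a CSV or Parquet
metadata table; multi-page TIFF triplets are supported for interoperability.
"""

from __future__ import annotations

import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import Dataset, ImagePair

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_metadata",
    "read_metadata",
    "load_yaml",
    "save_yaml",
]

log = logging.getLogger("cytomad")

_META_COLS = ["cell_id", "batch_id", "cell_type", "marker_label", "split"]


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        meta.to_parquet(path, index=False)
    else:
        meta.to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_dataset(
    dataset: Dataset, image_path: str | Path, metadata_path: str | Path
) -> None:
    """Write images to HDF5 (or TIFF triplet) and the metadata table."""
    image_path = Path(image_path)
    if image_path.suffix in (".h5", ".hdf5"):
        with h5py.File(image_path, "w") as fh:
            fh.create_dataset("bf", data=dataset.bf)
            fh.create_dataset("qpi", data=dataset.qpi)
            fh.create_dataset("mask", data=dataset.masks.astype(np.uint8))
            fh.create_dataset("qpi_clean", data=dataset.qpi_clean)
    elif image_path.suffix in (".tif", ".tiff"):
        import tifffile

        stem = image_path.with_suffix("")
        tifffile.imwrite(f"{stem}_bf.tif", dataset.bf)
        tifffile.imwrite(f"{stem}_qpi.tif", dataset.qpi)
        tifffile.imwrite(f"{stem}_mask.tif", dataset.masks.astype(np.uint8))
        tifffile.imwrite(f"{stem}_qpi_clean.tif", dataset.qpi_clean)
    else:
        raise ValueError(f"unsupported image container: {image_path.suffix}")
    write_metadata(dataset.meta, metadata_path)


def _read_stacks(image_path: Path) -> dict[str, np.ndarray]:
    if image_path.suffix in (".h5", ".hdf5"):
        with h5py.File(image_path, "r") as fh:
            return {k: fh[k][...] for k in fh.keys()}
    if image_path.suffix in (".tif", ".tiff"):
        import tifffile

        stem = image_path.with_suffix("")
        out = {}
        for key in ("bf", "qpi", "mask", "qpi_clean"):
            p = Path(f"{stem}_{key}.tif")
            if p.exists():
                out[key] = tifffile.imread(p)
        return out
    raise ValueError(f"unsupported image container: {image_path.suffix}")


def read_dataset(image_path: str | Path, metadata_path: str | Path) -> Dataset:
    """Read an aligned dataset; segments masks on the fly if absent."""
    stacks = _read_stacks(Path(image_path))
    meta = read_metadata(metadata_path)
    n_img = len(stacks["bf"])
    if n_img != len(meta):
        ids = meta["cell_id"].tolist() if "cell_id" in meta else list(range(len(meta)))
        unmatched = ids[n_img:] if len(meta) > n_img else list(range(len(meta), n_img))
        raise ValueError(
            f"metadata rows ({len(meta)}) != image count ({n_img}); "
            f"unmatched ids: {unmatched}"
        )
    if "mask" not in stacks:
        from .qc import segment_cell

        log.info("no masks stored; segmenting %d cells on the fly", n_img)
        stacks["mask"] = np.stack([segment_cell(q) for q in stacks["qpi"]])
    if "qpi_clean" not in stacks:
        stacks["qpi_clean"] = stacks["qpi"].copy()
    pairs = []
    for i in range(n_img):
        row = meta.iloc[i]
        pairs.append(
            ImagePair(
                bf=stacks["bf"][i].astype(np.float32),
                qpi=stacks["qpi"][i].astype(np.float32),
                mask=stacks["mask"][i].astype(bool),
                qpi_clean=stacks["qpi_clean"][i].astype(np.float32),
                meta={k: row[k] for k in _META_COLS if k in meta.columns},
            )
        )
    return Dataset(pairs, meta)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
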