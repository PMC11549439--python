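"""File formats: TIFF section series, displacement fields, NIfTI volumes.

A series lives in a directory with one multi-page TIFF per section (pages
1-4 the fluorescence channels as float32, pages 5-10 the six structure masks
as uint8, in the canonical order) and a ``manifest.json`` recording geometry
and the included/excluded flag of every cut section.  Excluded sections may
omit their image file.  Round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from skimage.measure import block_reduce

from .phantom import CHANNELS, STRUCTURES, SectionRecord, SectionSeries

MANIFEST = "manifest.json"


class SeriesIOError(IOError):
    pass


def write_series(series: SectionSeries, directory) -> Path:
    """Write channels + masks per section and the JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sec in series.sections:
        fname = f"section_{sec.index:04d}.tif"
        pages = np.concatenate(
            [sec.channels.astype(np.float32),
             sec.masks.astype(np.float32)]
        )
        tifffile.imwrite(directory / fname, pages, photometric="minisblack")
        entries.append({"index": sec.index, "included": sec.included,
                        "filename": fname})
    manifest = {
        "n_cut": series.n_cut,
        "pixel_size_um": series.pixel_size,
        "section_thickness_um": series.section_thickness,
        "channel_pages": list(CHANNELS),
        "mask_pages": list(STRUCTURES),
        "sections": entries,
    }
    (directory / MANIFEST).write_text(json.dumps(manifest, indent=1))
    return directory


def read_series(directory) -> SectionSeries:
    """Read a series written by :func:`write_series`.

    A missing file referenced by the manifest raises, naming the section —
    unless the section is flagged excluded, in which case a placeholder
    record with empty images is created.
    """
    directory = Path(directory)
    mpath = directory / MANIFEST
    if not mpath.exists():
        raise SeriesIOError(f"no {MANIFEST} in {directory}")
    manifest = json.loads(mpath.read_text())
    sections = []
    shape = None
    for entry in manifest["sections"]:
        fpath = directory / entry["filename"]
        if not fpath.exists():
            if entry["included"]:
                raise SeriesIOError(
                    f"file for section {entry['index']} missing: {fpath.name}"
                )
            sections.append((entry, None))
            continue
        pages = tifffile.imread(fpath)
        shape = pages.shape[1:]
        sections.append((entry, pages))
    records = []
    for entry, pages in sections:
        if pages is None:
            if shape is None:
                raise SeriesIOError("cannot size placeholder sections")
            pages = np.zeros((len(CHANNELS) + len(STRUCTURES), *shape), np.float32)
        records.append(
            SectionRecord(
                index=entry["index"],
                channels=pages[: len(CHANNELS)].astype(np.float32),
                masks=pages[len(CHANNELS) :] > 0.5,
                included=entry["included"],
            )
        )
    return SectionSeries(
        sections=records,
        n_cut=manifest["n_cut"],
        pixel_size=manifest["pixel_size_um"],
        section_thickness=manifest["section_thickness_um"],
    )


# ---------------------------------------------------------------------------
# displacement fields


def write_field(field: np.ndarray, path, fixed_index=None, moving_index=None) -> None:
    """Two-page float32 TIFF (row, col displacement) with a JSON header."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(field, dtype=np.float32))
    header = {
        "units": "px",
        "shape": list(field.shape[1:]),
        "components": ["row", "col"],
        "fixed_index": fixed_index,
        "moving_index": moving_index,
    }
    path.with_suffix(".json").write_text(json.dumps(header))


def read_field(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.float32)


# ---------------------------------------------------------------------------
# NIfTI export


def export_nifti(stack: np.ndarray, geometry, path, kind: str = "mask"):
    """Write a (n_sections, H, W) stack as a 3D NIfTI with real voxel sizes.

    Axes are reordered to (H, W, n_sections) so the section axis is the
    slowest; masks become uint8, channels 16-bit integers scaled from [0,1].
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or 0 in stack.shape:
        raise ValueError("need a non-empty (n_sections, H, W) stack")
    vol = np.transpose(stack, (1, 2, 0))
    if kind == "mask":
        data = vol.astype(np.uint8)
    elif kind == "channel":
        data = np.clip(vol * np.iinfo(np.uint16).max, 0, None).astype(np.uint16)
    else:
        raise ValueError("kind must be 'mask' or 'channel'")
    affine = np.diag(
        [geometry.pixel_size, geometry.pixel_size, geometry.section_thickness, 1.0]
    )
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(
        (geometry.pixel_size, geometry.pixel_size, geometry.section_thickness)
    )
    nib.save(img, str(path))
    return path


def downsample_export(volume: np.ndarray, factor: int = 16, kind: str = "channel"):
    """In-plane block downsampling for lightweight viewing exports.

    Channels use the block mean; masks use the block majority.  Returns
    ``(reduced_volume, scaled_pixel_size_factor)`` — pixel size scales by
    ``factor`` (1.097 µm becomes 17.552 µm at 16x; the section axis keeps
    its thickness).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vol = np.asarray(volume)
    if factor > min(vol.shape[1:]):
        raise ValueError("factor larger than the image")
    if factor == 1:
        return vol.copy(), 1
    if kind == "channel":
        red = block_reduce(vol, (1, factor, factor), np.mean)
    elif kind == "mask":
        red = block_reduce(vol.astype(np.float32), (1, factor, factor), np.mean) > 0.5
    else:
        raise ValueError("kind must be 'mask' or 'channel'")
    return red, factor
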