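"""Background-corrected intensity extraction from image stacks.

Two quantification schemes are provided, mirroring how time-lapse
confocal data of clock neurons are measured in practice:

* **2-D SUM-stack ROIs** (brain explants): a z-projection summing all
  slices, manual cell ROIs plus exactly three nearby background regions;
  a cell's corrected intensity is its ROI mean minus the mean of the
  three background-region means.
* **3-D masks** (cultured neurons): voxelwise background subtraction
  (floored at 0) followed by thresholding; connected voxels
  (26-neighbourhood) above threshold form the mask and their summed
  intensity is the readout.

Conventions: arrays are indexed 0-based in (z, y, x) order with half-open
ranges; ROIs are boolean pixel masks on the projected image. Negative
corrected intensities are retained and flagged, never clipped — silently
clipping would bias downstream rhythm amplitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import measure


@dataclass(frozen=True)
class StackSeries:
    """Time-ordered 3-D volumes from one channel."""

    volumes: list  # of (z, y, x) ndarrays, all the same shape
    time_hr: np.ndarray
    channel: str = "reporter"
    voxel_spacing: tuple[float, float, float] = (2.0, 0.38, 0.38)  # microns

    def __post_init__(self):
        object.__setattr__(self, "time_hr", np.asarray(self.time_hr, dtype=float))
        if len(self.volumes) != len(self.time_hr):
            raise ValueError("one volume per timepoint required")
        if len(self.volumes) == 0:
            raise ValueError("empty stack series")
        shape = np.shape(self.volumes[0])
        for v in self.volumes:
            if np.shape(v) != shape:
                raise ValueError("all volumes must share one shape")
        if np.any(np.diff(self.time_hr) <= 0):
            raise ValueError("time_hr must be strictly increasing")


@dataclass(frozen=True)
class ROISet:
    """Cell ROIs plus exactly three background regions on a 2-D image."""

    cell_rois: dict  # cell_id -> bool mask
    background_rois: tuple  # exactly 3 bool masks

    def __post_init__(self):
        if len(self.background_rois) != 3:
            raise ValueError("exactly 3 background regions are required")
        shapes = {m.shape for m in self.cell_rois.values()}
        shapes |= {m.shape for m in self.background_rois}
        if len(shapes) > 1:
            raise ValueError("all ROI masks must share the image shape")
        for cid, m in self.cell_rois.items():
            if not m.any():
                raise ValueError(f"empty cell ROI: {cid}")
        bg_union = np.zeros_like(self.background_rois[0], dtype=bool)
        for m in self.background_rois:
            if not m.any():
                raise ValueError("empty background region")
            bg_union |= m
        for cid, m in self.cell_rois.items():
            if (m & bg_union).any():
                raise ValueError(f"cell ROI {cid} overlaps a background region")

    @classmethod
    def from_label_images(cls, cell_labels: np.ndarray, background_labels: np.ndarray) -> "ROISet":
        """Build from integer label images (0 = outside)."""
        cells = {f"cell{int(v)}": cell_labels == v
                 for v in np.unique(cell_labels) if v != 0}
        bgs = tuple(background_labels == v
                    for v in np.unique(background_labels) if v != 0)
        return cls(cell_rois=cells, background_rois=bgs)


def sum_project(volume: np.ndarray) -> np.ndarray:
    """SUM-stack z-projection: pixel (y, x) = sum over z.

    Integer inputs are widened to int64 so large stacks cannot overflow;
    total intensity is conserved exactly.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError("need a non-empty (z, y, x) volume")
    dtype = np.int64 if np.issubdtype(volume.dtype, np.integer) else np.float64
    return volume.sum(axis=0, dtype=dtype)


def background_mean(image: np.ndarray, rois: ROISet) -> float:
    """Mean of the three background-region means."""
    return float(np.mean([image[m].mean() for m in rois.background_rois]))


def corrected_intensity(image: np.ndarray, rois: ROISet, cell_id: str) -> float:
    """Cell ROI mean minus the mean of the three background-region means.

    May be negative (the caller flags, never clips).
    """
    if cell_id not in rois.cell_rois:
        raise KeyError(f"no ROI for cell {cell_id!r}")
    image = np.asarray(image, dtype=float)
    return float(image[rois.cell_rois[cell_id]].mean() - background_mean(image, rois))


def measure_stack_series(stacks: StackSeries, rois: ROISet) -> pd.DataFrame:
    """Quantify every cell ROI at every timepoint on SUM projections.

    Returns a table with columns ``cell_id, time_hr, raw_mean,
    background_mean, corrected_intensity, negative_flag``.
    """
    rows = []
    for vol, t in zip(stacks.volumes, stacks.time_hr):
        img = sum_project(vol).astype(float)
        bg = background_mean(img, rois)
        for cid in sorted(rois.cell_rois):
            raw = float(img[rois.cell_rois[cid]].mean())
            corr = raw - bg
            rows.append({"cell_id": cid, "time_hr": float(t), "raw_mean": raw,
                         "background_mean": bg, "corrected_intensity": corr,
                         "negative_flag": corr < 0})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MaskResult:
    """Outcome of 3-D mask quantification of one volume."""

    mask: np.ndarray  # bool, voxels in any component
    labels: np.ndarray  # int, connected components (0 = outside)
    total_sum: float  # summed background-subtracted intensity in mask
    component_sums: dict  # label -> sum
    empty: bool


def mask_intensity_sum(volume: np.ndarray, threshold: float,
                       background: float) -> MaskResult:
    """Threshold a background-subtracted volume into 3-D cell masks.

    Background is subtracted voxelwise and floored at 0; voxels strictly
    above ``threshold`` are grouped into 26-connected components, and the
    background-subtracted intensity is summed per component and overall.
    An empty mask is returned flagged with sum 0, not raised.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("need a (z, y, x) volume")
    sub = np.maximum(vol - background, 0.0)
    above = sub > threshold
    labels = measure.label(above, connectivity=3)  # 26-neighbourhood
    comp_sums = {}
    for lab in range(1, labels.max() + 1):
        comp_sums[lab] = float(sub[labels == lab].sum())
    total = float(sub[above].sum())
    return MaskResult(mask=above, labels=labels, total_sum=total,
                      component_sums=comp_sums, empty=not above.any())


def nuclear_cytoplasmic_ratio(image: np.ndarray, nuclear_roi: np.ndarray,
                              cytoplasmic_roi: np.ndarray,
                              background_mean: float) -> float:
    """Background-corrected nuclear / cytoplasmic mean-intensity ratio."""
    if (np.asarray(nuclear_roi) & np.asarray(cytoplasmic_roi)).any():
        raise ValueError("nuclear and cytoplasmic ROIs must be disjoint")
    img = np.asarray(image, dtype=float)
    nuc = img[nuclear_roi].mean() - background_mean
    cyt = img[cytoplasmic_roi].mean() - background_mean
    if cyt <= 0:
        raise ValueError("corrected cytoplasmic mean is non-positive; ratio undefined")
    return float(nuc / cyt)


# ---------------------------------------------------------------------------
# TIFF + manifest I/O
# ---------------------------------------------------------------------------

def write_stack_series(stacks: StackSeries, directory) -> None:
    """Write one multi-page TIFF per timepoint plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, (vol, t) in enumerate(zip(stacks.volumes, stacks.time_hr)):
        name = f"t{k:03d}.tif"
        tifffile.imwrite(directory / name, np.asarray(vol, dtype=np.float32),
                         photometric="minisblack")
        entries.append({"file": name, "time_hr": float(t)})
    manifest = {
        "channel": stacks.channel,
        "voxel_spacing_um": list(stacks.voxel_spacing),
        "timepoints": entries,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def read_stack_series(directory) -> StackSeries:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    volumes, times = [], []
    for entry in manifest["timepoints"]:
        volumes.append(tifffile.imread(directory / entry["file"]).astype(np.float64))
        times.append(entry["time_hr"])
    return StackSeries(volumes=volumes, time_hr=np.array(times),
                       channel=manifest.get("channel", "reporter"),
                       voxel_spacing=tuple(manifest.get("voxel_spacing_um", (2.0, 0.38, 0.38))))
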