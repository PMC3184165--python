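"""Ion images, composites, and substantia-nigra ROI geometry.

The SN is delineated manually (an ordered spot set per hemisphere) and
split into medial and lateral halves by the perpendicular bisector of the
segment joining its ventromedial and dorsolateral corners; spots exactly on
the bisector go medial (fixed tie rule). ROI-level readouts are arithmetic
means of spot peak areas, and lesion effects are reported as percent of the
intact-side mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IMSSection, PeakBinTable, ROIMask

__all__ = [
    "IonImage",
    "make_ion_image",
    "composite_rgb",
    "split_sn_medial_lateral",
    "summarize_roi",
    "percent_of_intact",
]


@dataclass
class IonImage:
    """2-D masked intensity grid for one m/z bin.

    ``grid[row, col]`` holds the spot's peak area; ``mask`` is True where
    no spot exists (never imputed). ``origin`` is the (col, row) offset of
    the grid's top-left cell in section coordinates.
    """

    bin_center: float
    grid: np.ndarray
    mask: np.ndarray
    origin: tuple[int, int]

    @property
    def values(self) -> np.ndarray:
        """Masked array view (missing spots masked out)."""
        return np.ma.MaskedArray(self.grid, mask=self.mask)


def make_ion_image(table: PeakBinTable, bin_center: float, section: IMSSection | None = None) -> IonImage:
    """Place one bin's per-spot areas onto the section grid.

    Values are copied unchanged (no smoothing or interpolation). Unknown
    bin centers raise a ``KeyError`` listing the nearest available centers.
    """
    j = table.bin_index(bin_center)
    coords = table.coords
    c0, r0 = coords[:, 0].min(), coords[:, 1].min()
    ncol = coords[:, 0].max() - c0 + 1
    nrow = coords[:, 1].max() - r0 + 1
    grid = np.zeros((nrow, ncol))
    mask = np.ones((nrow, ncol), dtype=bool)
    for i, (c, r) in enumerate(coords):
        grid[r - r0, c - c0] = table.areas[i, j]
        mask[r - r0, c - c0] = False
    return IonImage(bin_center=float(table.bin_centers[j]), grid=grid, mask=mask, origin=(int(c0), int(r0)))


def composite_rgb(
    images: list[IonImage | None], channels: tuple[str, ...] = ("R", "G", "B")
) -> tuple[np.ndarray, dict]:
    """Merge up to three ion images into an RGB composite.

    Each channel is min-max scaled per image to [0, 1] before merging; a
    constant image renders at mid-intensity 0.5 (degenerate-range guard).
    Returns ``(rgb, metadata)`` where metadata records the per-channel
    scaling bounds. Masked cells render black in all channels.
    """
    imgs = [im for im in images if im is not None]
    if not imgs:
        raise ValueError("at least one ion image required")
    if len(images) > 3:
        raise ValueError("at most 3 channels")
    shape = imgs[0].grid.shape
    for im in imgs[1:]:
        if im.grid.shape != shape or im.origin != imgs[0].origin:
            raise ValueError("composite channels must share section geometry")
    order = {"R": 0, "G": 1, "B": 2}
    rgb = np.zeros(shape + (3,))
    meta: dict = {"channels": {}}
    for im, ch in zip(images, channels):
        if im is None:
            continue
        vals = im.grid[~im.mask]
        lo, hi = float(vals.min()), float(vals.max())
        if hi > lo:
            scaled = (im.grid - lo) / (hi - lo)
        else:
            scaled = np.full_like(im.grid, 0.5)
        scaled = np.where(im.mask, 0.0, scaled)
        rgb[:, :, order[ch]] = scaled
        meta["channels"][ch] = {"bin_center": im.bin_center, "min": lo, "max": hi}
    return rgb, meta


def split_sn_medial_lateral(
    roi_spots: np.ndarray,
    vm_corner: tuple[int, int],
    dl_corner: tuple[int, int],
    hemisphere: str,
    section_id: str = "",
) -> ROIMask:
    """Split an SN spot set into medial and lateral halves.

    The split is the perpendicular bisector of the segment from the
    ventromedial (VM) to the dorsolateral (DL) corner: spots on the VM side
    of the bisector are ``SN_medial``, those on the DL side ``SN_lateral``,
    and spots exactly on the bisector go medial. Swapping the corner inputs
    swaps the two labels exactly.
    """
    spots = np.asarray(roi_spots, dtype=float)
    vm = np.asarray(vm_corner, dtype=float)
    dl = np.asarray(dl_corner, dtype=float)
    keys = {tuple(map(int, s)) for s in spots}
    if tuple(map(int, vm)) not in keys or tuple(map(int, dl)) not in keys:
        raise ValueError("both corner spots must belong to the ROI spot set")
    if np.allclose(vm, dl):
        raise ValueError("ventromedial and dorsolateral corners coincide")
    axis = dl - vm
    mid = (vm + dl) / 2
    signed = (spots - mid) @ axis  # <0: VM side, >0: DL side, 0: boundary
    rows = []
    for (c, r), d in zip(np.asarray(roi_spots, dtype=int), signed):
        region = "SN_medial" if d <= 0 else "SN_lateral"
        rows.append({"col": int(c), "row": int(r), "hemisphere": hemisphere, "region": region})
    return ROIMask(section_id=section_id, table=pd.DataFrame(rows))


def summarize_roi(table: PeakBinTable, mask: ROIMask) -> pd.DataFrame:
    """Arithmetic mean of spot areas per (region, hemisphere, bin).

    Returns a long DataFrame with columns ``section_id, hemisphere, region,
    bin_mz, mean_area, n_spots``. Regions with no labeled spot in the table
    are omitted (a warning is not an error: counts make imbalance visible).
    NaN areas (bins outside a spectrum's range) are excluded from means.
    """
    lookup = mask.region_of()
    rows = []
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (c, r) in enumerate(table.coords):
        lab = lookup.get((int(c), int(r)))
        if lab is None or lab[1] == "other":
            continue
        groups.setdefault((lab[0], lab[1]), []).append(i)
    for (hemi, region), idx in sorted(groups.items()):
        sub = table.areas[idx, :]
        with np.errstate(invalid="ignore"):
            means = np.nanmean(sub, axis=0)
        counts = np.sum(~np.isnan(sub), axis=0)
        for j, center in enumerate(table.bin_centers):
            if counts[j] == 0:
                continue
            rows.append(
                {
                    "section_id": table.section_id,
                    "hemisphere": hemi,
                    "region": region,
                    "bin_mz": float(center),
                    "mean_area": float(means[j]),
                    "n_spots": int(counts[j]),
                }
            )
    return pd.DataFrame(rows)


def percent_of_intact(lesioned_mean: float, intact_mean: float) -> float:
    """Lesioned-side mean expressed as percent of the intact-side mean."""
    if intact_mean <= 0:
        raise ValueError("intact-side mean must be positive")
    return 100.0 * lesioned_mean / intact_mean
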