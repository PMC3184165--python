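"""Core imaging-MS data model.

One MALDI-TOF imaging run yields one :class:`IMSSection`: a 250-µm grid of
matrix spots over the ventral midbrain, each spot carrying one mass
spectrum, each spot assigned to the hemisphere ipsilateral (lesioned) or
contralateral (intact) to the 6-OHDA injection. Downstream stages attach an
ROI mask (substantia nigra medial/lateral halves) and a spots × m/z-bins
peak-area table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "IMSSection",
    "ROIMask",
    "PeakBinTable",
    "HEMISPHERES",
    "REGIONS",
]

HEMISPHERES = ("intact", "lesioned")
REGIONS = ("SN_medial", "SN_lateral", "other")


@dataclass
class Spectrum:
    """Paired m/z and intensity arrays for one matrix spot.

    m/z must be strictly increasing; intensities non-negative. The study's
    acquisition window is 500–3500 Da, but the container accepts any valid
    axis so narrow test fixtures remain representable.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        if not np.all(np.diff(self.mz) > 0):
            raise ValueError("mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def tic(self) -> float:
        """Total ion current: sum of all intensities."""
        return float(self.intensity.sum())

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy())


@dataclass
class IMSSection:
    """Grid of spots + spectra + metadata for one tissue section / run.

    ``coords`` is an (n_spots, 2) integer array of 0-based (column, row)
    grid positions at ``spacing_um`` pitch; ``hemispheres`` labels each spot
    ``"intact"`` or ``"lesioned"``. Spots are stored (and exported) in
    column-major order.
    """

    section_id: str
    animal_id: str
    run_id: int
    coords: np.ndarray
    spectra: list[Spectrum]
    hemispheres: list[str]
    spacing_um: float = 250.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.run_id not in (1, 2):
            raise ValueError("run_id must be 1 or 2 (duplicate experiments)")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (col, row)")
        n = self.coords.shape[0]
        if len(self.spectra) != n or len(self.hemispheres) != n:
            raise ValueError("coords, spectra and hemispheres must align 1:1")
        keys = {tuple(c) for c in self.coords}
        if len(keys) != n:
            raise ValueError("spot coordinates must be unique")
        bad = set(self.hemispheres) - set(HEMISPHERES)
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")
        # canonical column-major spot order
        order = np.lexsort((self.coords[:, 1], self.coords[:, 0]))
        self.coords = self.coords[order]
        self.spectra = [self.spectra[i] for i in order]
        self.hemispheres = [self.hemispheres[i] for i in order]

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def spot_ids(self) -> list[str]:
        """Stable per-spot identifiers ``"c{col}r{row}"``."""
        return [f"c{c}r{r}" for c, r in self.coords]

    def with_spectra(self, spectra: list[Spectrum]) -> "IMSSection":
        """Copy of the section with spectra replaced (same geometry)."""
        return IMSSection(
            section_id=self.section_id,
            animal_id=self.animal_id,
            run_id=self.run_id,
            coords=self.coords.copy(),
            spectra=spectra,
            hemispheres=list(self.hemispheres),
            spacing_um=self.spacing_um,
        )


@dataclass
class ROIMask:
    """Spot → (hemisphere, region) labels for one section.

    ``table`` columns: ``col, row, hemisphere, region`` with region in
    ``{"SN_medial", "SN_lateral", "other"}``. Only spots present in the
    section may be labeled; unlabeled spots are implicitly ``other``.
    """

    section_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"col", "row", "hemisphere", "region"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI mask missing columns: {sorted(missing)}")
        bad = set(self.table["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"unknown ROI region labels: {sorted(bad)}")
        bad_h = set(self.table["hemisphere"]) - set(HEMISPHERES)
        if bad_h:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_h)}")
        if self.table.duplicated(subset=["col", "row"]).any():
            raise ValueError("duplicate spot labels in ROI mask")

    def validate_against(self, section: IMSSection) -> None:
        spots = {tuple(c) for c in section.coords}
        labeled = {(int(r.col), int(r.row)) for r in self.table.itertuples()}
        orphans = labeled - spots
        if orphans:
            raise ValueError(f"ROI mask labels spots absent from section: {sorted(orphans)}")

    def region_of(self) -> dict[tuple[int, int], tuple[str, str]]:
        """Mapping (col, row) -> (hemisphere, region)."""
        return {
            (int(r.col), int(r.row)): (r.hemisphere, r.region)
            for r in self.table.itertuples()
        }


@dataclass
class PeakBinTable:
    """Per-section matrix of AUC peak areas: spots × m/z bins.

    ``areas[i, j]`` is the trapezoidal peak area of spot ``i`` in bin ``j``;
    NaN marks a bin window outside that spectrum's m/z range (missing, not
    zero). Provenance flags record whether the source spectra were TIC
    normalized and m/z aligned.
    """

    section_id: str
    bin_centers: np.ndarray
    areas: np.ndarray
    coords: np.ndarray
    hemispheres: list[str] = field(default_factory=list)
    normalized: bool = False
    aligned: bool = False

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        self.coords = np.asarray(self.coords, dtype=int)
        if self.bin_centers.size and not np.all(np.diff(self.bin_centers) > 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.areas.shape != (self.coords.shape[0], self.bin_centers.size):
            raise ValueError(
                f"area matrix shape {self.areas.shape} does not match "
                f"{self.coords.shape[0]} spots x {self.bin_centers.size} bins"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.areas[~np.isnan(self.areas)] < 0):
                raise ValueError("peak areas must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Long/wide DataFrame: one row per spot, one column per bin center."""
        df = pd.DataFrame(self.areas, columns=[f"{c:.4f}" for c in self.bin_centers])
        df.insert(0, "col", self.coords[:, 0])
        df.insert(1, "row", self.coords[:, 1])
        if self.hemispheres:
            df.insert(2, "hemisphere", self.hemispheres)
        return df

    def bin_index(self, center: float, atol: float = 1e-6) -> int:
        """Index of the bin matching ``center`` within ``atol``."""
        idx = int(np.argmin(np.abs(self.bin_centers - center)))
        if abs(self.bin_centers[idx] - center) > atol:
            near = ", ".join(f"{c:.4f}" for c in _nearest(self.bin_centers, center))
            raise KeyError(f"no bin at m/z {center}; nearest centers: {near}")
        return idx


def _nearest(centers: np.ndarray, value: float, k: int = 3) -> np.ndarray:
    order = np.argsort(np.abs(centers - value))
    return centers[order[:k]]
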