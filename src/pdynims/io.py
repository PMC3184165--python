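"""Readers/writers for imaging-MS sections and section-level quality control.

Two dialects:

* ``csvjson`` — a human-readable fixture format: ``<base>.json`` holds the
  section metadata and spot list, ``<base>.csv`` holds ``spot, mz,
  intensity`` triples. Round-trips bit-consistently (floats serialized with
  ``repr``).
* ``imzml`` — minimal imzML (continuous mode) via :mod:`pyimzml` for
  interoperability with instrument-adjacent tooling. Hemisphere labels have
  no imzML slot and travel in a ``<base>.hemispheres.csv`` sidecar when
  written by this package; absent a sidecar all spots read back ``intact``.

QC follows the study's exclusion rule: sections whose raw (pre-
normalization) total ion current is uneven across spots are dropped.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IMSSection, ROIMask, Spectrum

__all__ = [
    "read_section",
    "write_section",
    "read_roi_mask",
    "write_roi_mask",
    "QCResult",
    "qc_section",
]


@dataclass(frozen=True)
class QCResult:
    """Verdict of section-level quality control."""

    passed: bool
    reason: str
    tic_cv: float


def write_section(section: IMSSection, base_path: str, dialect: str = "csvjson") -> None:
    """Write a section in the named dialect.

    ``csvjson``: writes ``<base_path>.json`` + ``<base_path>.csv``.
    ``imzml``: writes ``<base_path>.imzML`` + ``.ibd`` + hemisphere sidecar.
    """
    if dialect == "csvjson":
        _write_csvjson(section, base_path)
    elif dialect == "imzml":
        _write_imzml(section, base_path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_section(base_path: str, dialect: str = "csvjson") -> IMSSection:
    """Read a section written in the named dialect."""
    if dialect == "csvjson":
        return _read_csvjson(base_path)
    if dialect == "imzml":
        return _read_imzml(base_path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_csvjson(section: IMSSection, base_path: str) -> None:
    spot_ids = section.spot_ids()
    meta = {
        "section_id": section.section_id,
        "animal_id": section.animal_id,
        "run_id": section.run_id,
        "spacing_um": section.spacing_um,
        "spots": [
            {"id": sid, "col": int(c), "row": int(r), "hemisphere": h}
            for sid, (c, r), h in zip(spot_ids, section.coords, section.hemispheres)
        ],
    }
    with open(base_path + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
    with open(base_path + ".csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["spot", "mz", "intensity"])
        for sid, spec in zip(spot_ids, section.spectra):
            for mz, inten in zip(spec.mz, spec.intensity):
                writer.writerow([sid, repr(float(mz)), repr(float(inten))])


def _read_csvjson(base_path: str) -> IMSSection:
    with open(base_path + ".json") as fh:
        meta = json.load(fh)
    declared = {s["id"]: s for s in meta["spots"]}
    data: dict[str, tuple[list, list]] = {sid: ([], []) for sid in declared}
    with open(base_path + ".csv", newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["spot"]
            if sid not in data:
                raise ValueError(f"spectrum data for undeclared spot {sid!r}")
            data[sid][0].append(float(row["mz"]))
            data[sid][1].append(float(row["intensity"]))
    coords, spectra, hemis = [], [], []
    for sid, s in declared.items():
        mzs, ints = data[sid]
        if not mzs:
            raise ValueError(f"missing spectrum for declared spot {sid!r}")
        if not all(b > a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"non-monotone m/z axis in spot {sid!r}")
        coords.append((s["col"], s["row"]))
        spectra.append(Spectrum(np.array(mzs), np.array(ints)))
        hemis.append(s["hemisphere"])
    return IMSSection(
        section_id=meta["section_id"],
        animal_id=meta["animal_id"],
        run_id=int(meta["run_id"]),
        coords=np.array(coords),
        spectra=spectra,
        hemispheres=hemis,
        spacing_um=float(meta.get("spacing_um", 250.0)),
    )


def _write_imzml(section: IMSSection, base_path: str) -> None:
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = base_path + ".imzML"
    with ImzMLWriter(path, mode="continuous") as writer:
        for (c, r), spec in zip(section.coords, section.spectra):
            # imzML coordinates are 1-based
            writer.addSpectrum(spec.mz, spec.intensity, (int(c) + 1, int(r) + 1, 1))
    side = pd.DataFrame(
        {
            "col": section.coords[:, 0],
            "row": section.coords[:, 1],
            "hemisphere": section.hemispheres,
        }
    )
    side.to_csv(base_path + ".hemispheres.csv", index=False)
    meta = {
        "section_id": section.section_id,
        "animal_id": section.animal_id,
        "run_id": section.run_id,
        "spacing_um": section.spacing_um,
    }
    with open(base_path + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def _read_imzml(base_path: str) -> IMSSection:
    from pyimzml.ImzMLParser import ImzMLParser

    path = base_path if base_path.lower().endswith(".imzml") else base_path + ".imzML"
    stem = path[: -len(".imzML")]
    parser = ImzMLParser(path)
    coords, spectra = [], []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        if not np.all(np.diff(mzs) > 0):
            raise ValueError(f"non-monotone m/z axis in spot index {i} at ({x}, {y})")
        coords.append((int(x) - 1, int(y) - 1))
        spectra.append(Spectrum(mzs, ints))
    hemis = ["intact"] * len(coords)
    side_path = stem + ".hemispheres.csv"
    if os.path.exists(side_path):
        side = pd.read_csv(side_path)
        lookup = {
            (int(r.col), int(r.row)): str(r.hemisphere) for r in side.itertuples()
        }
        hemis = [lookup.get(c, "intact") for c in coords]
    meta = {"section_id": os.path.basename(stem), "animal_id": "", "run_id": 1, "spacing_um": 250.0}
    meta_path = stem + ".meta.json"
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta.update(json.load(fh))
    return IMSSection(
        section_id=str(meta["section_id"]),
        animal_id=str(meta["animal_id"]),
        run_id=int(meta["run_id"]),
        coords=np.array(coords),
        spectra=spectra,
        hemispheres=hemis,
        spacing_um=float(meta["spacing_um"]),
    )


def write_roi_mask(mask: ROIMask, path: str) -> None:
    """ROI mask as CSV with columns col, row, hemisphere, region."""
    mask.table.to_csv(path, index=False)


def read_roi_mask(path: str, section_id: str | None = None) -> ROIMask:
    table = pd.read_csv(path)
    return ROIMask(section_id=section_id or os.path.basename(path), table=table)


def qc_section(section: IMSSection, cv_threshold: float = 0.5) -> QCResult:
    """Section QC on raw (pre-normalization) total ion current.

    Fails when any spot has zero TIC (empty spectrum — freeze damage or a
    missed matrix droplet) or when the coefficient of variation of TIC
    across spots exceeds ``cv_threshold`` (uneven TIC). Scale-invariant:
    multiplying all spectra by one positive constant leaves the verdict
    unchanged.
    """
    if section.n_spots == 0:
        raise ValueError("section has no spots")
    tics = np.array([s.tic for s in section.spectra])
    if np.any(tics == 0):
        return QCResult(passed=False, reason="empty spectrum", tic_cv=float("nan"))
    cv = float(np.std(tics, ddof=1) / np.mean(tics)) if tics.size > 1 else 0.0
    if cv > cv_threshold:
        return QCResult(passed=False, reason=f"uneven TIC (CV {cv:.2f} > {cv_threshold})", tic_cv=cv)
    return QCResult(passed=True, reason="", tic_cv=cv)
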