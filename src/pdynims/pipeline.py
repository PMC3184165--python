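"""End-to-end orchestration: simulate -> QC -> preprocess -> ROI -> stats
-> behavior -> report.

Stages communicate through plain-text artifacts in a working directory
(sections in the csvjson dialect, CSV tables, JSON/YAML metadata) so each
stage can be run separately from the CLI or composed via
:func:`run_pipeline`. A run manifest records the configuration snapshot,
seeds, QC verdicts and a SHA-256 checksum per artifact; re-running with the
same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import cohort as chr
from . import io as pio
from . import roi as proi
from . import stats as pstats
from .chem import annotate_peaks, default_catalog
from .model import PeakBinTable
from .preprocess import (
    ConvexHullBaseline,
    PeakBinner,
    SpectrumAligner,
    TICNormalizer,
    bin_peaks,
    integrate_areas,
)

__all__ = [
    "ValidationError",
    "load_config",
    "run_pipeline",
    "analyze_cohort",
    "DEFAULT_CONFIG",
]


class ValidationError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,
    "cohort": {},  # overrides for cohort.CohortConfig fields
    "qc": {"cv_threshold": 0.5},
    "preprocess": {
        "snr_min": 3.0,
        "bin_tol": 0.3,
        "halfwidth_floor": 0.25,
        "noise_window": 101,
        "max_shift": 1.0,
    },
    "stats": {
        "contrast": "HD",
        "reference": "LC",
        "alpha": 0.05,
        "region": "SN_lateral",
        "average_runs": True,
        "annotation_tol": 0.3,
    },
}


def _merge_validate(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, val in override.items():
        if path == "" and key == "cohort":
            # free-form here; validated against the CohortConfig fields later
            merged = dict(defaults.get(key, {}))
            merged.update(val or {})
            out[key] = merged
            continue
        if key not in defaults:
            raise ValidationError(f"unknown config key {path + key!r}")
        if isinstance(defaults.get(key), dict) and isinstance(val, dict):
            out[key] = _merge_validate(defaults[key], val, path=f"{key}.")
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides, rejecting unknown keys."""
    import copy

    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError("config file must contain a mapping")
        cfg = _merge_validate(cfg, user)
    if overrides:
        cfg = _merge_validate(cfg, overrides)
    if "cohort" in cfg and cfg["cohort"]:
        valid = {f.name for f in dataclasses.fields(chr.CohortConfig)}
        bad = set(cfg["cohort"]) - valid
        if bad:
            raise ValidationError(f"unknown cohort config keys: {sorted(bad)}")
    return cfg


def _log(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[pdynims] stage={stage} elapsed={time.time() - t0:.2f}s {extras}", file=sys.stderr)


def _jsonable(obj):
    """Best-effort JSON view of a config snapshot (tuple keys, dataclasses)."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (str, bool)) or obj is None:
        return obj
    if isinstance(obj, (int, float, np.integer, np.floating)):
        return float(obj) if isinstance(obj, (float, np.floating)) else int(obj)
    return str(obj)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_config(cfg: dict) -> chr.CohortConfig:
    return chr.CohortConfig(**cfg.get("cohort", {}), master_seed=cfg["seed"]) if (
        "master_seed" not in cfg.get("cohort", {})
    ) else chr.CohortConfig(**cfg["cohort"])


# ----------------------------------------------------------------- stages


def stage_simulate(cfg: dict, outdir: str) -> chr.CohortBundle:
    t0 = time.time()
    bundle = chr.generate_cohort(_cohort_config(cfg))
    secdir = os.path.join(outdir, "sections")
    os.makedirs(secdir, exist_ok=True)
    for section, mask in bundle.sections:
        base = os.path.join(secdir, section.section_id)
        pio.write_section(section, base, dialect="csvjson")
        pio.write_roi_mask(mask, base + ".roi.csv")
    animals = pd.DataFrame(
        {"animal_id": [a.animal_id for a in bundle.animals], "group": [a.group for a in bundle.animals]}
    )
    animals.to_csv(os.path.join(outdir, "animals.csv"), index=False)
    aim = pd.concat([bhv.sessions_to_frame(a.sessions) for a in bundle.animals], ignore_index=True)
    aim.to_csv(os.path.join(outdir, "aim_scores.csv"), index=False)
    cyl = pd.DataFrame(
        [
            {"animal_id": a.animal_id, "occasion": t.occasion, "left": t.left, "right": t.right}
            for a in bundle.animals
            for t in (a.cylinder_pre, a.cylinder_post)
        ]
    )
    cyl.to_csv(os.path.join(outdir, "cylinder.csv"), index=False)
    bundle.truth.spot_areas.to_csv(os.path.join(outdir, "ground_truth_areas.csv"), index=False)
    bundle.truth.animal_truth.to_csv(os.path.join(outdir, "ground_truth_animals.csv"), index=False)
    bundle.truth.species_truth.to_csv(os.path.join(outdir, "ground_truth_species.csv"), index=False)
    _log("simulate", t0, animals=len(bundle.animals), sections=len(bundle.sections))
    return bundle


def load_sections(outdir: str):
    secdir = os.path.join(outdir, "sections")
    out = []
    for name in sorted(os.listdir(secdir)):
        if not name.endswith(".json") or name.endswith(".roi.csv"):
            continue
        base = os.path.join(secdir, name[: -len(".json")])
        section = pio.read_section(base, dialect="csvjson")
        mask = pio.read_roi_mask(base + ".roi.csv", section_id=section.section_id)
        out.append((section, mask))
    return out


def stage_qc(cfg: dict, outdir: str) -> pd.DataFrame:
    t0 = time.time()
    rows = []
    for section, _mask in load_sections(outdir):
        res = pio.qc_section(section, cv_threshold=cfg["qc"]["cv_threshold"])
        rows.append(
            {
                "section_id": section.section_id,
                "passed": res.passed,
                "reason": res.reason,
                "tic_cv": res.tic_cv,
            }
        )
    qc = pd.DataFrame(rows)
    qc.to_csv(os.path.join(outdir, "qc.csv"), index=False)
    _log("qc", t0, sections=len(qc), excluded=int((~qc["passed"]).sum()))
    return qc


def _qc_passed_ids(outdir: str) -> set:
    qc_path = os.path.join(outdir, "qc.csv")
    if not os.path.exists(qc_path):
        return set()
    qc = pd.read_csv(qc_path)
    return set(qc.loc[qc["passed"], "section_id"])


def stage_preprocess(cfg: dict, outdir: str) -> dict[str, PeakBinTable]:
    """Baseline, normalize and align every passing section; pool peaks
    across all sections into one common bin set; integrate AUC areas."""
    t0 = time.time()
    p = cfg["preprocess"]
    passed = _qc_passed_ids(outdir)
    sections = [(s, m) for s, m in load_sections(outdir) if not passed or s.section_id in passed]
    if not sections:
        raise RuntimeError("no section passed QC")
    refs = np.array([pep.mh for pep in default_catalog()])
    processed = []
    all_peaklists = []
    binner = PeakBinner(
        snr_min=p["snr_min"],
        tol=p["bin_tol"],
        halfwidth_floor=p["halfwidth_floor"],
        noise_window=p["noise_window"],
    )
    for section, _mask in sections:
        spectra = ConvexHullBaseline().fit_transform(section.spectra)
        spectra = TICNormalizer().fit_transform(spectra)
        aligner = SpectrumAligner(reference_mz=refs, max_shift=p["max_shift"])
        spectra = aligner.fit_transform(spectra)
        binner.fit(spectra)
        all_peaklists.extend(binner.peaklists_)
        processed.append(section.with_spectra(spectra))
    bins = bin_peaks(all_peaklists, tol=p["bin_tol"])
    peakdir = os.path.join(outdir, "peaks")
    os.makedirs(peakdir, exist_ok=True)
    tables = {}
    for section in processed:
        table = integrate_areas(
            section, bins, halfwidth_floor=p["halfwidth_floor"], normalized=True, aligned=True
        )
        tables[section.section_id] = table
        table.to_frame().to_csv(os.path.join(peakdir, f"{section.section_id}.csv"), index=False)
    pd.DataFrame(
        {
            "center": [b.center for b in bins],
            "half_width": [b.half_width for b in bins],
            "count": [b.count for b in bins],
        }
    ).to_csv(os.path.join(outdir, "bins.csv"), index=False)
    _log(
        "preprocess",
        t0,
        sections=len(processed),
        peaks=sum(len(pl) for pl in all_peaklists),
        bins=len(bins),
    )
    return tables


def _load_peak_tables(outdir: str) -> dict[str, PeakBinTable]:
    peakdir = os.path.join(outdir, "peaks")
    tables = {}
    for name in sorted(os.listdir(peakdir)):
        if not name.endswith(".csv"):
            continue
        df = pd.read_csv(os.path.join(peakdir, name))
        meta_cols = [c for c in ("col", "row", "hemisphere") if c in df.columns]
        bin_cols = [c for c in df.columns if c not in meta_cols]
        tables[name[:-4]] = PeakBinTable(
            section_id=name[:-4],
            bin_centers=np.array([float(c) for c in bin_cols]),
            areas=df[bin_cols].to_numpy(float),
            coords=df[["col", "row"]].to_numpy(int),
            hemispheres=list(df["hemisphere"]) if "hemisphere" in df else [],
            normalized=True,
            aligned=True,
        )
    return tables


def stage_roi(cfg: dict, outdir: str) -> pd.DataFrame:
    t0 = time.time()
    tables = _load_peak_tables(outdir)
    frames = []
    for section, mask in load_sections(outdir):
        if section.section_id not in tables:
            continue
        summary = proi.summarize_roi(tables[section.section_id], mask)
        summary["animal_id"] = section.animal_id
        summary["run_id"] = section.run_id
        frames.append(summary)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(os.path.join(outdir, "roi_summaries.csv"), index=False)
    _log("roi", t0, rows=len(out))
    return out


def stage_stats(cfg: dict, outdir: str) -> pd.DataFrame:
    t0 = time.time()
    s = cfg["stats"]
    summaries = pd.read_csv(os.path.join(outdir, "roi_summaries.csv"))
    animals = pd.read_csv(os.path.join(outdir, "animals.csv"))
    design = pstats.build_design(summaries, animals, region=s["region"])
    results = pstats.fit_all_bins(design, contrast=s["contrast"], reference=s["reference"])
    catalog = default_catalog()
    notes = []
    for b in results["bin_mz"]:
        hits = annotate_peaks([b], catalog, tolerance=s["annotation_tol"])[0]
        notes.append(hits[0].peptide_name if hits else "")
    results["annotation"] = notes
    results["significant"] = results["p_adj"] < s["alpha"]
    results.to_csv(os.path.join(outdir, "bin_results.csv"), index=False)
    _log("stats", t0, bins=len(results), significant=int(results["significant"].sum()))
    return results


def stage_behavior(cfg: dict, outdir: str) -> dict:
    t0 = time.time()
    aim = pd.read_csv(os.path.join(outdir, "aim_scores.csv"))
    animals = pd.read_csv(os.path.join(outdir, "animals.csv"))
    session_totals = (
        aim.groupby(["animal_id", "session"])["score"].sum().unstack("session").sort_index()
    )
    groups = animals.set_index("animal_id").loc[session_totals.index, "group"]
    treated = groups.isin(["LD", "HD"]).to_numpy()
    out: dict = {}
    if treated.sum() >= 4 and groups[treated].nunique() == 2:
        rm = pstats.repeated_measures_anova(
            session_totals.to_numpy()[treated], groups[treated].to_numpy()
        )
        out["rm_anova"] = {k: v for k, v in rm.items() if k != "posthoc"}
        rm["posthoc"].to_csv(os.path.join(outdir, "behavior_posthoc.csv"), index=False)
    days = np.array(bhv.SESSION_DAYS)
    traj_rows = []
    for g in ("LD", "HD"):
        ids = groups[groups == g].index
        if len(ids) == 0:
            continue
        mean_scores = session_totals.loc[ids].mean(axis=0).to_numpy()
        tr = bhv.fit_trajectory(days, mean_scores)
        traj_rows.append(
            {"group": g, "slope": tr.slope, "intercept": tr.intercept, "residual_sd": tr.residual_sd}
        )
    traj = pd.DataFrame(traj_rows)
    traj.to_csv(os.path.join(outdir, "trajectories.csv"), index=False)
    cyl = pd.read_csv(os.path.join(outdir, "cylinder.csv"))
    asym_rows = []
    for aid, sub in cyl.groupby("animal_id"):
        tests = {
            r.occasion: bhv.CylinderTest(aid, r.occasion, int(r.left), int(r.right))
            for r in sub.itertuples()
        }
        if "pre" in tests and "post" in tests:
            pct, include = bhv.percent_left_use(tests["pre"])
            asym_rows.append(
                {
                    "animal_id": aid,
                    "pre_pct_left": pct,
                    "included": include,
                    "asymmetry_change": bhv.asymmetry_change(tests["pre"], tests["post"]),
                }
            )
    pd.DataFrame(asym_rows).to_csv(os.path.join(outdir, "cylinder_changes.csv"), index=False)
    with open(os.path.join(outdir, "behavior_stats.json"), "w") as fh:
        json.dump(out, fh, indent=1, default=float)
    _log("behavior", t0, animals=len(session_totals))
    return out


def stage_report(cfg: dict, outdir: str) -> dict:
    """Peak-behavior correlations, ion images, composite, manifest."""
    t0 = time.time()
    s = cfg["stats"]
    summaries = pd.read_csv(os.path.join(outdir, "roi_summaries.csv"))
    animals = pd.read_csv(os.path.join(outdir, "animals.csv"))
    aim = pd.read_csv(os.path.join(outdir, "aim_scores.csv"))
    cum = aim.groupby("animal_id")["score"].sum()
    design = pstats.build_design(
        summaries, animals, region=s["region"], average_runs=s["average_runs"]
    )
    catalog = default_catalog()
    corr_rows = []
    for b in sorted(design["bin_mz"].unique()):
        hits = annotate_peaks([b], catalog, tolerance=s["annotation_tol"])[0]
        if not hits:
            continue
        sub = design[np.isclose(design["bin_mz"], b) & design["group"].isin(["LD", "HD"])]
        merged = sub.merge(cum.rename("cumulative"), left_on="animal_id", right_index=True)
        if len(merged) < 3 or merged["log2_ratio"].nunique() < 2:
            continue
        ratio_pct = 100.0 * 2 ** merged["log2_ratio"]
        try:
            res = pstats.correlate_with_behavior(ratio_pct, merged["cumulative"])
        except ValueError:
            continue
        corr_rows.append(
            {
                "bin_mz": b,
                "annotation": hits[0].peptide_name,
                "r": res.r,
                "p": res.p,
                "slope": res.slope,
                "intercept": res.intercept,
                "n": res.n,
            }
        )
    corr = pd.DataFrame(corr_rows)
    corr.to_csv(os.path.join(outdir, "behavior_correlations.csv"), index=False)

    # ion images + composite for the headline peptides, first section
    tables = _load_peak_tables(outdir)
    img_meta = {}
    if tables:
        first = sorted(tables)[0]
        table = tables[first]
        import matplotlib

        matplotlib.use("Agg")
        from matplotlib import image as mpimg

        targets = {"Dyn B": "G", "Leu-Enk-Arg": "R"}
        chans: dict[str, object] = {}
        for pep in catalog:
            if pep.name not in targets:
                continue
            try:
                j = table.bin_index(pep.mh, atol=s["annotation_tol"])
            except KeyError:
                continue
            img = proi.make_ion_image(table, float(table.bin_centers[j]))
            grid = np.where(img.mask, 0.0, img.grid)
            hi = grid.max() or 1.0
            mpimg.imsave(
                os.path.join(outdir, f"ion_{pep.name.replace(' ', '_')}.png"),
                grid / hi,
                cmap="viridis",
                vmin=0,
                vmax=1,
            )
            pd.DataFrame(img.grid).to_csv(
                os.path.join(outdir, f"ion_{pep.name.replace(' ', '_')}.csv"), index=False
            )
            chans[targets[pep.name]] = img
        if {"R", "G"} <= set(chans):
            rgb, meta = proi.composite_rgb([chans["R"], chans["G"], None], ("R", "G", "B"))
            mpimg.imsave(os.path.join(outdir, "composite_dynb_lea.png"), rgb)
            img_meta = meta
            with open(os.path.join(outdir, "composite_meta.json"), "w") as fh:
                json.dump(meta, fh, indent=1)

    manifest = {
        "config": _jsonable(cfg),
        "seed": cfg["seed"],
        "qc": pd.read_csv(os.path.join(outdir, "qc.csv")).to_dict("records")
        if os.path.exists(os.path.join(outdir, "qc.csv"))
        else [],
        "artifacts": {},
        "composite": img_meta,
    }
    for root, _dirs, files in os.walk(outdir):
        for name in sorted(files):
            if name == "manifest.json":
                continue
            path = os.path.join(root, name)
            rel = os.path.relpath(path, outdir)
            manifest["artifacts"][rel] = _sha256(path)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    _log("report", t0, artifacts=len(manifest["artifacts"]))
    return manifest


def analyze_cohort(
    bundle: chr.CohortBundle,
    snr_min: float = 3.0,
    bin_tol: float = 0.3,
    halfwidth_floor: float = 0.25,
    noise_window: int = 101,
    max_shift: float = 1.0,
    min_bin_count: int = 1,
    region: str = "SN_lateral",
    contrast: str = "HD",
    reference: str = "LC",
    average_runs: bool = True,
    cv_threshold: float = 0.5,
) -> dict:
    """Run the full analysis on an in-memory cohort bundle (no file I/O).

    QC-filters sections, runs the spectral chain per section with bins
    pooled across the whole study (bins backed by fewer than
    ``min_bin_count`` detected peaks are dropped), summarizes ROIs, builds
    the log2 side-ratio design for ``region`` and tests the ``contrast`` vs
    ``reference`` treatment coefficient per bin with BH correction, and
    correlates annotated per-animal side ratios with cumulative AIM scores.

    Returns a dict with ``qc``, ``bins``, ``summaries``, ``design``,
    ``results`` and ``correlations``.
    """
    refs = np.array([pep.mh for pep in default_catalog()])
    kept, qc_rows = [], []
    for section, mask in bundle.sections:
        res = pio.qc_section(section, cv_threshold=cv_threshold)
        qc_rows.append({"section_id": section.section_id, "passed": res.passed, "reason": res.reason})
        if res.passed:
            kept.append((section, mask))
    if not kept:
        raise RuntimeError("QC excluded every section")
    binner = PeakBinner(
        snr_min=snr_min, tol=bin_tol, halfwidth_floor=halfwidth_floor, noise_window=noise_window
    )
    processed, all_peaklists = [], []
    for section, mask in kept:
        spectra = ConvexHullBaseline().fit_transform(section.spectra)
        spectra = TICNormalizer().fit_transform(spectra)
        spectra = SpectrumAligner(reference_mz=refs, max_shift=max_shift).fit_transform(spectra)
        binner.fit(spectra)
        all_peaklists.extend(binner.peaklists_)
        processed.append((section.with_spectra(spectra), mask))
    bins = [b for b in bin_peaks(all_peaklists, tol=bin_tol) if b.count >= min_bin_count]
    frames = []
    for section, mask in processed:
        table = integrate_areas(
            section, bins, halfwidth_floor=halfwidth_floor, normalized=True, aligned=True
        )
        summary = proi.summarize_roi(table, mask)
        summary["animal_id"] = section.animal_id
        summary["run_id"] = section.run_id
        frames.append(summary)
    summaries = pd.concat(frames, ignore_index=True)
    animals = pd.DataFrame(
        {"animal_id": [a.animal_id for a in bundle.animals], "group": [a.group for a in bundle.animals]}
    )
    design = pstats.build_design(summaries, animals, region=region)
    results = pstats.fit_all_bins(design, contrast=contrast, reference=reference)
    catalog = default_catalog()
    if len(results):
        results["annotation"] = [
            hits[0].peptide_name if hits else ""
            for hits in annotate_peaks(list(results["bin_mz"]), catalog, tolerance=0.3)
        ]
    else:
        results["annotation"] = []
    cum = {a.animal_id: bhv.cumulative_score(a.sessions) for a in bundle.animals}
    corr_design = pstats.build_design(summaries, animals, region=region, average_runs=average_runs)
    corr_rows = []
    for b in sorted(corr_design["bin_mz"].unique()):
        hits = annotate_peaks([b], catalog, tolerance=0.3)[0]
        if not hits:
            continue
        sub = corr_design[
            np.isclose(corr_design["bin_mz"], b) & corr_design["group"].isin(["LD", "HD"])
        ]
        if len(sub) < 3:
            continue
        x = 100.0 * 2 ** sub["log2_ratio"].to_numpy()
        y = np.array([cum[a] for a in sub["animal_id"]])
        try:
            res = pstats.correlate_with_behavior(x, y)
        except ValueError:
            continue
        corr_rows.append(
            {"bin_mz": b, "annotation": hits[0].peptide_name, "r": res.r, "p": res.p, "n": res.n}
        )
    return {
        "qc": pd.DataFrame(qc_rows),
        "bins": bins,
        "summaries": summaries,
        "design": design,
        "results": results,
        "correlations": pd.DataFrame(corr_rows),
    }


STAGES = ("simulate", "qc", "preprocess", "roi", "stats", "behavior", "report")


def run_pipeline(config: dict | str | None = None, outdir: str = "pdynims_out") -> dict:
    """Run every stage in order; returns the manifest.

    Raises :class:`ValidationError` on bad configuration; raises
    ``RuntimeError`` when QC excludes every section.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    os.makedirs(outdir, exist_ok=True)
    if cfg["simulate"]:
        stage_simulate(cfg, outdir)
    qc = stage_qc(cfg, outdir)
    if not qc["passed"].any():
        raise RuntimeError("QC excluded every section")
    stage_preprocess(cfg, outdir)
    stage_roi(cfg, outdir)
    stage_stats(cfg, outdir)
    stage_behavior(cfg, outdir)
    return stage_report(cfg, outdir)
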