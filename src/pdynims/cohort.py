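"""Synthetic study generator with ground truth.

Emulates the study design end to end: 14 unilaterally lesioned rats (4
lesion-only controls, 5 low-dyskinetic, 5 high-dyskinetic), duplicate
imaging runs per animal on consecutive sections, a 250-µm spot grid over
the ventral midbrain with the substantia nigra split into balanced medial
and lateral halves per hemisphere, ~30% CV multiplicative peak-area noise,
group- and region-dependent lesion-side fold changes on the prodynorphin
peptides, and linear two-group dyskinesia trajectories. Every generated
observable has a ground-truth twin so parameter recovery is testable.

Severity coupling: each treated animal carries a latent standard-normal
severity; with coupling strength rho, the behavioral severity component and
the peak-fold severity component are each ``sqrt(rho)*z + sqrt(1-rho)*e``
for the shared ``z`` and independent ``e``, so their correlation is exactly
``rho``. Those two components shift the animal's cumulative AIM score and
its lesion-lateral log2 fold changes, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import AIM_CATEGORIES, SESSION_DAYS, AIMSession, CylinderTest, cumulative_score
from .chem import default_catalog
from .model import IMSSection, ROIMask, Spectrum
from .roi import split_sn_medial_lateral

__all__ = [
    "SpeciesSpec",
    "CohortConfig",
    "AnimalRecord",
    "GroundTruth",
    "CohortBundle",
    "default_panel",
    "draw_severity_pairs",
    "generate_behavior",
    "generate_section",
    "generate_cohort",
]

GROUPS = ("LC", "LD", "HD")


@dataclass(frozen=True)
class SpeciesSpec:
    """One planted molecular species.

    ``localized`` species follow the nigral dynorphin pattern (enriched in
    the SN ROI, ventromedially weighted, faint elsewhere); non-localized
    ("background") species are spatially uniform and carry most of the
    total ion current, as the ~1000 unrelated species do in real sections.
    """

    name: str
    mz: float
    base: float
    localized: bool = True


def default_panel() -> list[SpeciesSpec]:
    """Default ~24-species panel: the peptide catalog + 10 background ions."""
    bases = {
        "Dyn B": 120.0,
        "aNeo": 120.0,
        "Leu-Enk-Arg": 80.0,
        "Leu-Enk-Arg-Arg": 60.0,
        "aNeo(1-7)": 60.0,
        "bNeo": 60.0,
        "Dyn A(1-8)": 50.0,
        "Dyn A(1-17)": 40.0,
        "Dyn A(10-17)": 40.0,
        "Leu-Enk": 30.0,
        "Substance P": 100.0,
        "Dyn A(2-8)": 30.0,
        "aNeo(2-10)": 30.0,
        "Dyn B(2-13)": 30.0,
    }
    panel = [
        SpeciesSpec(p.name, p.mh, bases[p.name], localized=(p.name != "Substance P"))
        for p in default_catalog()
    ]
    background_mz = [575.0, 650.0, 760.0, 905.0, 1150.0, 1290.0, 1480.0, 1660.0, 1800.0, 2000.0]
    panel += [
        SpeciesSpec(f"bg_{int(m)}", m, 5000.0, localized=False) for m in background_mz
    ]
    return panel


def _default_effects() -> dict:
    # lesioned-hemisphere fold changes by (peptide, group) -> {region: fold}
    return {
        ("Dyn B", "HD"): {"SN_lateral": 1.75, "SN_medial": 1.13},
        ("aNeo", "HD"): {"SN_lateral": 1.54, "SN_medial": 0.98},
        ("Leu-Enk-Arg", "HD"): {"SN_lateral": 1.50},
        ("Leu-Enk-Arg-Arg", "HD"): {"SN_lateral": 1.70},
        ("Leu-Enk-Arg-Arg", "LD"): {"SN_lateral": 1.10},
        ("aNeo(1-7)", "HD"): {"SN_lateral": 1.48},
        ("aNeo(1-7)", "LD"): {"SN_lateral": 1.02},
    }


@dataclass
class CohortConfig:
    """All study-condition knobs, with the emulated design as defaults."""

    group_sizes: dict = field(default_factory=lambda: {"LC": 4, "LD": 5, "HD": 5})
    runs_per_animal: int = 2
    # section geometry: two hemispheres side by side, 250 um pitch
    hemi_cols: int = 8
    n_rows: int = 4
    spacing_um: float = 250.0
    # per-hemisphere SN ROI: a 6 x 2 block whose VM-DL diagonal bisector
    # yields a balanced 6/6 medial/lateral split
    roi_col_offset: int = 1
    roi_row_offset: int = 1
    roi_cols: int = 6
    roi_rows: int = 2
    # spectra
    mz_range: tuple = (500.0, 2200.0)
    mz_step: float = 0.04
    peak_sigma: float = 0.08
    baseline_amp: float = 50.0
    baseline_decay: float = 800.0
    white_noise_sd: float = 1.0
    tic_scale_sd: float = 0.10
    mz_jitter_sd: float = 0.02
    noise_cv: float = 0.30
    # biology
    panel: list = field(default_factory=default_panel)
    effect_map: dict = field(default_factory=_default_effects)
    medial_boost: float = 1.3
    outside_level: float = 0.25
    correlated_peptides: tuple = ("Dyn B", "aNeo", "Leu-Enk-Arg")
    severity_rho: float = 0.8
    severity_fold_sd: float = 0.25  # log2 units on lesion-lateral folds
    conversion_patch: bool = True
    patch_dynb_factor: float = 0.4
    patch_lea_factor: float = 2.5
    knockout: bool = False  # zero all prodynorphin-derived species
    # behavior
    trajectories: dict = field(default_factory=lambda: {"LD": (0.68, 0.41), "HD": (0.81, 29.94)})
    n_timepoints: int = 9
    score_noise_sd: float = 2.0
    severity_score_scale: float = 2.0  # per-session score shift per unit severity
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for eff in self.effect_map.values() for f in eff.values()):
            raise ValueError("all fold changes must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        if not 0 <= self.severity_rho <= 1:
            raise ValueError("severity_rho must lie in [0, 1]")


@dataclass
class AnimalRecord:
    """One animal: group, behavior, and latent severity components."""

    animal_id: str
    group: str
    sessions: list = field(default_factory=list)
    cylinder_pre: CylinderTest | None = None
    cylinder_post: CylinderTest | None = None
    severity_behavior: float = 0.0
    severity_fold: float = 0.0
    planted_cumulative: float = 0.0


@dataclass
class GroundTruth:
    """Ground-truth twins of every generated observable.

    ``spot_areas``: planted noiseless AUC per section/spot/species (folds
    and patches included, multiplicative noise excluded). ``animal_truth``:
    latent severity components and planted cumulative score per animal.
    ``species_truth``: per species, the nominal HD lesion-lateral fold and
    the true null/alternative label.
    """

    spot_areas: pd.DataFrame
    animal_truth: pd.DataFrame
    species_truth: pd.DataFrame
    seeds: dict = field(default_factory=dict)


@dataclass
class CohortBundle:
    config: CohortConfig
    animals: list
    sections: list  # list of (IMSSection, ROIMask)
    truth: GroundTruth


def draw_severity_pairs(n: int, rho: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw n latent (behavior, fold) severity pairs with correlation rho."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    a = np.sqrt(rho)
    b = np.sqrt(1 - rho)
    z = rng.standard_normal(n)
    c = a * z + b * rng.standard_normal(n)
    l = a * z + b * rng.standard_normal(n)
    return c, l


def _distribute_session_score(total: int, n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    """Spread a session total over (timepoints x 4 categories), each cell 0-4."""
    n_cells = n_timepoints * len(AIM_CATEGORIES)
    total = int(min(total, 4 * n_cells))
    # exact scheme: repeatedly add one point to a random cell still below 4
    flat = np.zeros(n_cells, dtype=int)
    remaining = total
    while remaining > 0:
        open_cells = np.where(flat < 4)[0]
        pick = open_cells[rng.integers(open_cells.size)]
        flat[pick] += 1
        remaining -= 1
    return flat.reshape(n_timepoints, len(AIM_CATEGORIES))


def generate_behavior(
    config: CohortConfig,
    group: str,
    rng: np.random.Generator,
    animal_id: str = "a1",
    severity: float = 0.0,
) -> tuple[list[AIMSession], tuple[CylinderTest, CylinderTest], float]:
    """Draw AIM sessions and cylinder tests for one animal.

    Session totals follow ``round(max(0, m*day + b + shift + noise))`` with
    the group's trajectory (m, b), a severity-proportional shift, and
    Gaussian score noise; lesion-only controls score zero throughout.
    Pre-treatment cylinder tests always satisfy the <30% left-use inclusion
    criterion; post-treatment left use improves in LD, is unchanged in HD,
    and worsens in LC. Returns (sessions, (pre, post), planted_cumulative).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    sessions = []
    planted = 0.0
    for k, day in enumerate(SESSION_DAYS, start=1):
        if group == "LC":
            total = 0
        else:
            m, b = config.trajectories[group]
            mean = m * day + b + config.severity_score_scale * severity
            planted += max(0.0, mean)
            total = int(round(max(0.0, mean + config.score_noise_sd * rng.standard_normal())))
        scores = _distribute_session_score(total, config.n_timepoints, rng)
        sessions.append(AIMSession(animal_id=animal_id, index=k, scores=scores))
    left_pre = int(rng.integers(0, 6))  # <=25% of 20 touches: always included
    pre = CylinderTest(animal_id, "pre", left_pre, 20 - left_pre)
    pct_pre = 100.0 * left_pre / 20
    delta = {"LD": 10.0, "HD": 0.0, "LC": -5.0}[group]
    pct_post = float(np.clip(pct_pre + delta + 3.0 * rng.standard_normal(), 0.0, 100.0))
    left_post = int(round(pct_post / 100 * 20))
    post = CylinderTest(animal_id, "post", left_post, 20 - left_post)
    return sessions, (pre, post), planted


def _roi_mask_for(config: CohortConfig, section_id: str) -> ROIMask:
    """Both hemispheres' SN masks: medial toward the midline."""
    hc, co, ro = config.hemi_cols, config.roi_col_offset, config.roi_row_offset
    rc, rr = config.roi_cols, config.roi_rows
    tables = []
    for hemi in ("intact", "lesioned"):
        c0 = co if hemi == "intact" else hc + (hc - co - rc)
        spots = np.array([(c, r) for c in range(c0, c0 + rc) for r in range(ro, ro + rr)])
        if hemi == "intact":  # midline on the right: medial = high columns
            vm = (c0 + rc - 1, ro + rr - 1)
            dl = (c0, ro)
        else:  # midline on the left: medial = low columns
            vm = (c0, ro + rr - 1)
            dl = (c0 + rc - 1, ro)
        mask = split_sn_medial_lateral(spots, vm, dl, hemisphere=hemi, section_id=section_id)
        tables.append(mask.table)
    return ROIMask(section_id=section_id, table=pd.concat(tables, ignore_index=True))


def _is_prodynorphin(name: str) -> bool:
    return not name.startswith("bg_") and name != "Substance P"


def generate_section(
    config: CohortConfig,
    animal: AnimalRecord,
    run: int,
    rng: np.random.Generator,
) -> tuple[IMSSection, ROIMask, pd.DataFrame]:
    """Build one synthetic imaging section with its ROI mask and truth.

    Each spot's spectrum is a sum of Gaussian peaks at the panel's m/z
    values (amplitude = base x spatial pattern x group/hemisphere fold x
    lognormal CV noise), on a decaying-exponential chemical baseline, with
    additive white noise, one lognormal TIC scale factor and one rigid m/z
    jitter per spectrum. Returns the planted noiseless per-spot areas as a
    long DataFrame.
    """
    names = {s.name for s in config.panel}
    for (pep, _g) in config.effect_map:
        if pep not in names:
            raise ValueError(f"effect map names species absent from panel: {pep!r}")
    section_id = f"{animal.animal_id}_run{run}"
    mask = _roi_mask_for(config, section_id)
    region_lookup = mask.region_of()
    ncols = 2 * config.hemi_cols
    coords = np.array([(c, r) for c in range(ncols) for r in range(config.n_rows)])
    hemis = ["intact" if c < config.hemi_cols else "lesioned" for c, _r in coords]

    lo, hi = config.mz_range
    mz = np.arange(lo, hi + config.mz_step / 2, config.mz_step)
    sigma = config.peak_sigma
    cv_sigma = np.sqrt(np.log(1 + config.noise_cv**2)) if config.noise_cv > 0 else 0.0
    patch_spots: set = set()
    if config.conversion_patch and animal.group == "HD":
        # dorsolateral corner of the lesioned SN + its ventral neighbor
        hc, co, ro = config.hemi_cols, config.roi_col_offset, config.roi_row_offset
        c0 = hc + (hc - co - config.roi_cols)
        dl_col = c0 + config.roi_cols - 1
        patch_spots = {(dl_col, ro), (dl_col - 1, ro)}

    spectra = []
    truth_rows = []
    for (c, r), hemi in zip(coords, hemis):
        y = config.baseline_amp * np.exp(-(mz - lo) / config.baseline_decay)
        jitter = rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd > 0 else 0.0
        _hemi, region = region_lookup.get((c, r), (hemi, "other"))
        for sp in config.panel:
            amp = sp.base
            if config.knockout and _is_prodynorphin(sp.name):
                amp = 0.0
            if sp.localized:
                if region == "other":
                    amp *= config.outside_level
                elif region == "SN_medial":
                    amp *= config.medial_boost
            fold = 1.0
            if hemi == "lesioned" and region != "other":
                fold = config.effect_map.get((sp.name, animal.group), {}).get(region, 1.0)
                if (
                    sp.name in config.correlated_peptides
                    and region == "SN_lateral"
                    and animal.group in ("LD", "HD")
                ):
                    fold *= 2.0 ** (config.severity_fold_sd * animal.severity_fold)
                if (c, r) in patch_spots and region == "SN_lateral":
                    if sp.name == "Dyn B":
                        fold *= config.patch_dynb_factor
                    elif sp.name == "Leu-Enk-Arg":
                        fold *= config.patch_lea_factor
            amp_clean = amp * fold
            noise_factor = (
                np.exp(rng.normal(0.0, cv_sigma) - cv_sigma**2 / 2) if cv_sigma > 0 else 1.0
            )
            amp_noisy = amp_clean * noise_factor
            if amp_noisy > 0:
                center = sp.mz + jitter
                sel = slice(
                    np.searchsorted(mz, center - 6 * sigma),
                    np.searchsorted(mz, center + 6 * sigma),
                )
                y[sel] += amp_noisy * np.exp(-0.5 * ((mz[sel] - center) / sigma) ** 2)
            truth_rows.append(
                {
                    "section_id": section_id,
                    "col": int(c),
                    "row": int(r),
                    "hemisphere": hemi,
                    "region": region,
                    "species": sp.name,
                    "planted_area": amp_clean * sigma * np.sqrt(2 * np.pi),
                }
            )
        if config.white_noise_sd > 0:
            y = y + rng.normal(0.0, config.white_noise_sd, size=mz.size)
        if config.tic_scale_sd > 0:
            y = y * np.exp(rng.normal(0.0, config.tic_scale_sd))
        spectra.append(Spectrum(mz.copy(), np.clip(y, 0.0, None)))

    section = IMSSection(
        section_id=section_id,
        animal_id=animal.animal_id,
        run_id=run,
        coords=coords,
        spectra=spectra,
        hemispheres=hemis,
        spacing_um=config.spacing_um,
    )
    return section, mask, pd.DataFrame(truth_rows)


def generate_cohort(config: CohortConfig | None = None, master_seed: int | None = None) -> CohortBundle:
    """Generate the full study bundle: animals, behavior, sections, truth.

    Per-animal and per-section random streams are spawned deterministically
    from the master seed, so the bundle is bit-identical under a fixed
    seed.
    """
    config = config if config is not None else CohortConfig()
    seed = config.master_seed if master_seed is None else master_seed
    root = np.random.SeedSequence(seed)
    animal_ids = []
    for g in GROUPS:
        for i in range(config.group_sizes.get(g, 0)):
            animal_ids.append((f"{g}{i + 1}", g))

    treated = [(aid, g) for aid, g in animal_ids if g != "LC"]
    sev_rng = np.random.default_rng(root.spawn(1)[0])
    c_sev, l_sev = draw_severity_pairs(len(treated), config.severity_rho, sev_rng)
    severity = {aid: (c, l) for (aid, _g), c, l in zip(treated, c_sev, l_sev)}

    animals: list[AnimalRecord] = []
    sections = []
    truth_frames = []
    child_seeds = root.spawn(1 + len(animal_ids))[1:]
    for (aid, g), child in zip(animal_ids, child_seeds):
        sub = child.spawn(1 + config.runs_per_animal)
        rng_b = np.random.default_rng(sub[0])
        sev_b, sev_f = severity.get(aid, (0.0, 0.0))
        rec = AnimalRecord(animal_id=aid, group=g, severity_behavior=sev_b, severity_fold=sev_f)
        rec.sessions, (rec.cylinder_pre, rec.cylinder_post), rec.planted_cumulative = (
            generate_behavior(config, g, rng_b, animal_id=aid, severity=sev_b)
        )
        animals.append(rec)
        for run in range(1, config.runs_per_animal + 1):
            rng_s = np.random.default_rng(sub[run])
            sec, mask, truth = generate_section(config, rec, run, rng_s)
            sections.append((sec, mask))
            truth_frames.append(truth)

    animal_truth = pd.DataFrame(
        {
            "animal_id": [a.animal_id for a in animals],
            "group": [a.group for a in animals],
            "severity_behavior": [a.severity_behavior for a in animals],
            "severity_fold": [a.severity_fold for a in animals],
            "planted_cumulative": [a.planted_cumulative for a in animals],
            "cumulative_score": [cumulative_score(a.sessions) for a in animals],
        }
    )
    species_truth = _species_truth(config)
    truth = GroundTruth(
        spot_areas=pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame(),
        animal_truth=animal_truth,
        species_truth=species_truth,
        seeds={"master_seed": seed},
    )
    return CohortBundle(config=config, animals=animals, sections=sections, truth=truth)


def _species_truth(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for sp in config.panel:
        eff = config.effect_map.get((sp.name, "HD"), {})
        lateral = eff.get("SN_lateral", 1.0)
        rows.append(
            {
                "species": sp.name,
                "mz": sp.mz,
                "hd_lateral_fold": lateral,
                "is_null": all(
                    f == 1.0
                    for g in GROUPS
                    for f in config.effect_map.get((sp.name, g), {"_": 1.0}).values()
                ),
            }
        )
    return pd.DataFrame(rows)
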