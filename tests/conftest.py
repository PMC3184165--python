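"""Shared fixtures: reduced synthetic study configurations.

All fixtures build cohorts programmatically; nothing is read from disk.
The reduced configurations keep the study's structure (groups, duplicate
runs, balanced medial/lateral ROI, 30% CV noise) while shrinking the m/z
axis and spot grid so the suite stays desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from pdynims import cohort as chr


def make_tiny_config(max_mz: float = 900.0, **overrides) -> chr.CohortConfig:
    """A reduced cohort config: narrow m/z axis, panel restricted to it."""
    panel = [s for s in chr.default_panel() if s.mz < max_mz - 10]
    names = {s.name for s in panel}
    effects = {k: v for k, v in chr._default_effects().items() if k[0] in names}
    defaults = dict(
        group_sizes={"LC": 2, "LD": 2, "HD": 3},
        runs_per_animal=1,
        mz_range=(500.0, max_mz),
        mz_step=0.05,
        panel=panel,
        effect_map=effects,
        correlated_peptides=tuple(
            n for n in ("Dyn B", "aNeo", "Leu-Enk-Arg") if n in names
        ),
        master_seed=0,
    )
    defaults.update(overrides)
    return chr.CohortConfig(**defaults)


def make_null_micro_config(seed: int = 0, **overrides) -> chr.CohortConfig:
    """Fully null micro-study: no planted effects, minimal grid and axis."""
    panel = [s for s in chr.default_panel() if s.mz < 890.0]
    defaults = dict(
        group_sizes={"LC": 3, "LD": 0, "HD": 3},
        runs_per_animal=1,
        hemi_cols=4,
        n_rows=2,
        roi_col_offset=0,
        roi_row_offset=0,
        roi_cols=4,
        roi_rows=2,
        mz_range=(500.0, 900.0),
        mz_step=0.1,
        panel=panel,
        effect_map={},
        correlated_peptides=(),
        conversion_patch=False,
        master_seed=seed,
    )
    defaults.update(overrides)
    return chr.CohortConfig(**defaults)


def make_noiseless_config(**overrides) -> chr.CohortConfig:
    """Noise-free study conditions (for exact parameter recovery)."""
    return make_tiny_config(
        noise_cv=0.0,
        white_noise_sd=0.0,
        tic_scale_sd=0.0,
        mz_jitter_sd=0.0,
        baseline_amp=0.0,
        severity_fold_sd=0.0,
        conversion_patch=False,
        **overrides,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_bundle() -> chr.CohortBundle:
    return chr.generate_cohort(make_tiny_config(master_seed=7))
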