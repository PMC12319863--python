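"""Synthetic cohorts with the representational structure the analysis assumes.

Generates per-subject run x condition x voxel beta patterns with a
three-category cluster geometry over the 8 body-part conditions, trait
tables matching the study population's score distributions, head-motion
traces, and (through :mod:`bodyrep.design`) full voxel time series. Every
generator is a pure function of (config, seed, subject index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .conditions import (
    BODY_PARTS,
    CATEGORY_LABELS,
    CONDITIONS,
    HYPOTHESIZED_CATEGORIES,
)

TD_LABEL = "TD-like"
ASD_LABEL = "ASD-like"

#: Trait score distributions per group: trait -> (TD mean, TD sd, ASD mean, ASD sd).
#: Means/SDs follow the study population's demographic summary.
TRAIT_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "age": (31.0, 10.2, 30.4, 5.3),
    "fsiq": (111.0, 14.4, 109.0, 12.0),
    "srs_total": (54.9, 21.2, 106.0, 28.9),
    "aq_total": (16.0, 7.0, 33.0, 5.0),
    "sp_low_registration": (27.4, 7.5, 33.7, 8.7),
    "sp_sensory_seeking": (38.1, 6.4, 30.7, 6.6),
    "sp_sensory_sensitivity": (33.9, 6.9, 40.2, 9.7),
    "sp_sensation_avoiding": (34.7, 6.3, 40.9, 11.4),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-group cohort.

    category_separation scales the distance between the three category
    mean patterns; condition_separation the spread of individual
    conditions around their category mean; run_noise_sd the i.i.d.
    run-level noise; group_shift a uniform mean-pattern offset added to
    ASD-like subjects.
    """

    n_per_group: int = 23
    n_voxels: int = 33
    n_runs: int = 4
    n_conditions: int = 10
    category_separation: float = 1.0
    condition_separation: float = 0.5
    run_noise_sd: float = 0.5
    group_shift: float = 0.0
    seed: int = 0
    conditions: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        if self.n_runs < 2 or self.n_runs % 2:
            raise ValueError("n_runs must be even and >= 2 (odd/even split)")
        if self.n_voxels < 2:
            raise ValueError("n_voxels must be >= 2")
        if self.n_conditions != len(self.conditions):
            raise ValueError("n_conditions must match the condition list")
        if min(self.category_separation, self.condition_separation, self.run_noise_sd) < 0:
            raise ValueError("separations and noise SD must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_per_group


@dataclass
class VoxelPatternSet:
    """Per-subject condition beta patterns, indexed [run][condition][voxel]."""

    subject: str
    group: str
    betas: np.ndarray  # (n_runs, n_conditions, n_voxels)
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (runs, conditions, voxels)")
        if self.betas.shape[1] != len(self.conditions):
            raise ValueError("condition axis does not match condition list")
        if not np.isfinite(self.betas).all():
            raise ValueError("betas must be finite")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def condition_index(self, name: str) -> int:
        return self.conditions.index(name)


def _subject_rng(config: CohortConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 7919, subject_index])


def subject_group(config: CohortConfig, subject_index: int) -> str:
    """Subjects 0..n_per_group-1 are TD-like, the rest ASD-like."""
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    return TD_LABEL if subject_index < config.n_per_group else ASD_LABEL


def generate_pattern_set(config: CohortConfig, subject_index: int) -> VoxelPatternSet:
    """Draw one subject's run x condition x voxel beta array.

    Per subject: each of the three body-part categories (and the whole-body
    localizer condition) receives a standard-normal mean pattern over voxels
    scaled by ``category_separation``; the chair pattern is the negated
    whole-body pattern so the localizer contrast is maximal. Each condition
    adds its own normal offset scaled by ``condition_separation``; each run
    adds i.i.d. N(0, run_noise_sd) noise; ASD-like subjects add
    ``group_shift`` to every beta.
    """
    group = subject_group(config, subject_index)
    rng = _subject_rng(config, subject_index)

    cat_means = {
        label: config.category_separation * rng.standard_normal(config.n_voxels)
        for label in CATEGORY_LABELS
    }
    whole_body = config.category_separation * rng.standard_normal(config.n_voxels)
    cat_means["whole body"] = whole_body
    cat_means["chair"] = -whole_body  # maximally anticorrelated localizer foil

    mean_pattern = np.empty((config.n_conditions, config.n_voxels))
    for c, cond in enumerate(config.conditions):
        key = HYPOTHESIZED_CATEGORIES.get(cond, cond)
        if key not in cat_means:  # non-canonical condition: own mean pattern
            cat_means[key] = config.category_separation * rng.standard_normal(
                config.n_voxels
            )
        offset = config.condition_separation * rng.standard_normal(config.n_voxels)
        mean_pattern[c] = cat_means[key] + offset

    noise = config.run_noise_sd * rng.standard_normal(
        (config.n_runs, config.n_conditions, config.n_voxels)
    )
    betas = mean_pattern[None, :, :] + noise
    if group == ASD_LABEL:
        betas = betas + config.group_shift
    return VoxelPatternSet(
        subject=f"sub-{subject_index:03d}",
        group=group,
        betas=betas,
        conditions=config.conditions,
    )


def generate_cohort(config: CohortConfig) -> list[VoxelPatternSet]:
    """All 2 * n_per_group subjects, TD-like first."""
    return [generate_pattern_set(config, i) for i in range(config.n_subjects)]


def generate_traits(
    config: CohortConfig,
    coupling: float = 0.0,
    neural_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject trait table with group-specific normal score distributions.

    Traits are independent of the neural patterns by default. A nonzero
    ``coupling`` mixes standardized per-subject ``neural_scores`` into every
    trait (trait := trait + coupling * sd_trait * z(neural)), creating a
    recoverable brain-trait association for testing.
    """
    # seed stream independent of group_shift and separations by construction
    rng = np.random.default_rng([config.seed, 104729])
    n = config.n_subjects
    groups = [subject_group(config, i) for i in range(n)]
    data: dict[str, object] = {
        "subject": [f"sub-{i:03d}" for i in range(n)],
        "group": groups,
    }
    td_mask = np.array([g == TD_LABEL for g in groups])
    for trait, (m_td, sd_td, m_asd, sd_asd) in TRAIT_DISTRIBUTIONS.items():
        z = rng.standard_normal(n)
        mean = np.where(td_mask, m_td, m_asd)
        sd = np.where(td_mask, sd_td, sd_asd)
        data[trait] = mean + sd * z
    df = pd.DataFrame(data)
    if coupling != 0.0:
        if neural_scores is None or len(neural_scores) != n:
            raise ValueError("coupling requires one neural score per subject")
        zs = (neural_scores - np.mean(neural_scores)) / np.std(neural_scores)
        for trait, (_, sd_td, _, sd_asd) in TRAIT_DISTRIBUTIONS.items():
            sd = np.where(td_mask, sd_td, sd_asd)
            df[trait] = df[trait] + coupling * sd * zs
    return df


def generate_motion_params(
    n_volumes: int, amplitude: float, seed: int
) -> np.ndarray:
    """Random-walk motion trace, (n_volumes, 6): translations mm, rotations rad.

    Step increments are N(0, amplitude); amplitude 0 gives constant traces.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng([seed, 15485863])
    steps = amplitude * rng.standard_normal((n_volumes, 6))
    steps[0] = 0.0
    # rotations drift an order of magnitude less than translations
    steps[:, 3:] *= 0.1
    return np.cumsum(steps, axis=0)


def generate_timeseries(
    patterns: VoxelPatternSet,
    design: "RunDesign",
    ar_coefficient: float = 0.0,
    drift_amplitude: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Forward-model voxel time series, (n_runs, n_volumes, n_voxels).

    Per voxel: sum over conditions of beta x HRF-convolved boxcar, plus a
    low-frequency cosine drift of the given amplitude, plus AR(1) noise
    with the stated lag-1 coefficient and innovation SD ``noise_sd``.
    """
    from .design import HRFSpec, condition_regressors

    if not 0 <= abs(ar_coefficient) < 1:
        raise ValueError("ar_coefficient must satisfy |a| < 1")
    missing = [c for c, _ in design.blocks if c not in patterns.conditions]
    if missing:
        raise ValueError(f"design conditions absent from patterns: {missing}")

    X = condition_regressors(design, HRFSpec(), conditions=patterns.conditions)
    n_vol = design.n_volumes
    t = np.arange(n_vol) * design.tr
    drift = drift_amplitude * np.cos(np.pi * t / t[-1])
    rng = np.random.default_rng([seed, 32452843])
    runs = []
    for r in range(patterns.n_runs):
        signal = X @ patterns.betas[r]  # (n_vol, n_voxels)
        eps = noise_sd * rng.standard_normal((n_vol, patterns.n_voxels))
        if ar_coefficient != 0.0 and noise_sd > 0:
            noise = np.empty_like(eps)
            noise[0] = eps[0] / np.sqrt(1 - ar_coefficient**2)
            for k in range(1, n_vol):
                noise[k] = ar_coefficient * noise[k - 1] + eps[k]
        else:
            noise = eps
        runs.append(signal + drift[:, None] + noise)
    return np.stack(runs)


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    """Copy of the config with a new master seed."""
    return replace(config, seed=seed)
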