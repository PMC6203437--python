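"""Synthetic enrichment-cohort generator.

Emulates the statistical structure of a two-group individualization study
in isogenic mice: a control group (CTRL, standard cages) and an enriched
group (ENR) of 40 animals each, phenotyped for a wide panel of
morphometric, behavioral, neurogenic and metabolic traits.  Group effects
are expressed per trait as an additive mean shift and a variance ratio
(ENR variance / CTRL variance) — the variance ratio being the effect size
of interest for individualization.  Trait blocks can be given a target
pairwise Spearman correlation (Gaussian copula), marginals may be normal
or lognormal, and records go missing completely at random at a per-trait
rate, mirroring the technical losses of real cohorts.

Open-field trajectories are generated by a reflected Gaussian random walk
with a drift toward the nearest wall (thigmotaxis) and a repulsion from
one designated corner (where the light source sits), which reproduces the
peripheral occupancy pattern of real open-field heat maps.  Trial-to-trial
habituation enters as a multiplicative shrinkage of the exploratory step
dispersion on re-exposure, which lowers roaming entropy on trial 2.

All generators take explicit seeds; there is no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .trajectory import Trajectory

logger = logging.getLogger(__name__)

GROUPS = ("CTRL", "ENR")


class SimulationConfigError(ValueError):
    """Raised for invalid generator configurations."""


# ---------------------------------------------------------------------------
# phenotype cohort


@dataclass(frozen=True)
class TraitSpec:
    """One trait's marginal distribution and its group effects.

    ``ctrl_mean`` and ``ctrl_sd`` are the CTRL-group mean and standard
    deviation on the trait's natural (data) scale, for lognormal families
    included: the underlying log-scale parameters are solved by moment
    matching.  ``enr_mean_shift`` is additive on that same scale and
    ``enr_var_ratio`` is the ENR/CTRL variance ratio, so the realized
    group variances converge to ``ctrl_sd**2`` and
    ``ctrl_sd**2 * enr_var_ratio``.
    """

    name: str
    family: str = "normal"  # "normal" | "lognormal"
    ctrl_mean: float = 0.0
    ctrl_sd: float = 1.0
    enr_mean_shift: float = 0.0
    enr_var_ratio: float = 1.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise SimulationConfigError(f"unknown family {self.family!r}")
        if self.ctrl_sd < 0:
            raise SimulationConfigError(f"{self.name}: ctrl_sd must be >= 0")
        if self.enr_var_ratio <= 0:
            raise SimulationConfigError(f"{self.name}: enr_var_ratio must be > 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise SimulationConfigError(f"{self.name}: missing_rate must lie in [0, 1]")
        if self.family == "lognormal":
            for label, m in (("CTRL", self.ctrl_mean), ("ENR", self.ctrl_mean + self.enr_mean_shift)):
                if m <= 0:
                    raise SimulationConfigError(
                        f"{self.name}: lognormal {label} mean must be > 0, got {m}"
                    )

    def group_moments(self, group: str) -> tuple[float, float]:
        """(mean, sd) of this trait in ``group`` on the data scale."""
        if group == "CTRL":
            return self.ctrl_mean, self.ctrl_sd
        return self.ctrl_mean + self.enr_mean_shift, self.ctrl_sd * np.sqrt(self.enr_var_ratio)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a two-group synthetic cohort."""

    n_per_group: int = 40
    traits: tuple[TraitSpec, ...] = ()
    #: (trait-name tuple, target pairwise Spearman rho) per correlated block
    correlation_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise SimulationConfigError("n_per_group must be >= 2")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise SimulationConfigError("duplicate trait names")
        for members, rho in self.correlation_blocks:
            if not abs(rho) < 1:
                raise SimulationConfigError(f"block rho must satisfy |rho| < 1, got {rho}")
            unknown = set(members) - set(names)
            if unknown:
                raise SimulationConfigError(f"correlation block names not in traits: {unknown}")


def _latent_correlation(config: CohortConfig) -> np.ndarray:
    """Latent Gaussian correlation matrix hitting the target Spearman rhos.

    For a bivariate Gaussian copula, Spearman's rho relates to the latent
    correlation r by rho_S = (6/pi) * arcsin(r/2); inverting gives
    r = 2 sin(pi rho_S / 6), which also survives any monotone marginal
    transform (hence holds for the lognormal marginals too).
    """
    names = [t.name for t in config.traits]
    idx = {n: i for i, n in enumerate(names)}
    corr = np.eye(len(names))
    for members, rho_s in config.correlation_blocks:
        r = 2.0 * np.sin(np.pi * rho_s / 6.0)
        for a in members:
            for b in members:
                if a != b:
                    corr[idx[a], idx[b]] = r
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise SimulationConfigError(
            "assembled block correlation matrix is not positive-definite; "
            "check for overlapping blocks or extreme rho values"
        )
    return corr


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given data-scale moments."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic two-group phenotype table.

    Returns a wide table with one row per animal: ``animal_id``,
    ``group`` (CTRL/ENR) and one column per trait, NaN where a record went
    missing.  Identical config and seed give an identical table.
    """
    if not config.traits:
        raise SimulationConfigError("cohort needs at least one trait")
    corr = _latent_correlation(config)
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng(config.seed)
    n, m = config.n_per_group, len(config.traits)

    frames = []
    for group in GROUPS:
        z = rng.standard_normal((n, m)) @ chol.T
        cols: dict[str, np.ndarray] = {}
        for j, spec in enumerate(config.traits):
            mean, sd = spec.group_moments(group)
            if spec.family == "normal":
                v = mean + sd * z[:, j]
            else:
                mu, sigma = _lognormal_params(mean, sd)
                v = np.exp(mu + sigma * z[:, j])
            if spec.missing_rate > 0:
                v = v.copy()
                v[rng.random(n) < spec.missing_rate] = np.nan
            cols[spec.name] = v
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        df.insert(0, "animal_id", [f"{group}_{i + 1:03d}" for i in range(n)])
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    logger.info(
        "simulated cohort: %d animals x %d traits (seed=%d)", len(table), m, config.seed
    )
    return table


# ---------------------------------------------------------------------------
# open-field trajectories


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the thigmotactic random-walk trajectory generator.

    ``step_scale`` is the per-step Gaussian step dispersion (length units),
    ``wall_bias`` an outward drift magnitude pulling the animal toward the
    nearest wall, ``avoided_corner_bias`` a short-range repulsion from the
    brightly lit corner at (arena_side, arena_side), and
    ``habituation_factor`` multiplies the step dispersion on the second
    trial (values < 1 shrink exploration on re-exposure).
    """

    arena_side: float = 60.0  # cm
    duration: float = 300.0  # s
    dt: float = 0.2  # s
    step_scale: float = 4.0  # cm per step
    wall_bias: float = 1.0  # cm per step, >= 0
    avoided_corner_bias: float = 0.5  # cm per step at the corner
    habituation_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arena_side <= 0:
            raise SimulationConfigError("arena_side must be > 0")
        if self.dt <= 0:
            raise SimulationConfigError("dt must be > 0")
        if self.duration < self.dt:
            raise SimulationConfigError("duration must be >= dt")
        if self.step_scale < 0 or self.wall_bias < 0:
            raise SimulationConfigError("step_scale and wall_bias must be >= 0")
        if not 0.0 <= self.habituation_factor <= 1.0:
            raise SimulationConfigError("habituation_factor must lie in [0, 1]")


def _reflect(v: np.ndarray, side: float) -> np.ndarray:
    v = np.mod(v, 2.0 * side)
    return np.where(v > side, 2.0 * side - v, v)


def simulate_trajectory(
    walk: WalkConfig, trial: int = 1, animal_id: str = "sim", trial_id: str | None = None
) -> Trajectory:
    """One open-field trial as a reflected biased Gaussian random walk.

    The animal starts at the arena center.  Each step adds an isotropic
    Gaussian displacement (dispersion ``step_scale``, shrunk by
    ``habituation_factor`` on trial >= 2), a drift of magnitude
    ``wall_bias`` away from the arena center (toward the nearest wall),
    and a repulsion from the lit corner that decays linearly to zero at
    half the arena diagonal.  Positions are reflected at the walls, so the
    walk stays inside [0, arena_side]^2.
    """
    if trial < 1:
        raise SimulationConfigError("trial must be >= 1")
    rng = np.random.default_rng([walk.seed, trial])
    n_steps = int(round(walk.duration / walk.dt))
    scale = walk.step_scale * (walk.habituation_factor if trial >= 2 else 1.0)
    side = walk.arena_side
    center = np.array([side / 2.0, side / 2.0])
    corner = np.array([side, side])
    corner_range = side * np.sqrt(2.0) / 2.0

    pos = np.empty((n_steps + 1, 2))
    pos[0] = center
    steps = scale * rng.standard_normal((n_steps, 2))
    p = center.copy()
    for i in range(n_steps):
        d = p - center
        norm = np.hypot(d[0], d[1])
        drift = walk.wall_bias * d / norm if norm > 0 else np.zeros(2)
        dc = p - corner
        cnorm = np.hypot(dc[0], dc[1])
        if cnorm > 0 and cnorm < corner_range and walk.avoided_corner_bias != 0:
            drift = drift + walk.avoided_corner_bias * (1.0 - cnorm / corner_range) * dc / cnorm
        p = _reflect(p + steps[i] + drift, side)
        pos[i + 1] = p

    t = np.arange(n_steps + 1) * walk.dt
    return Trajectory(
        animal_id=animal_id,
        trial_id=trial_id if trial_id is not None else str(trial),
        t=t,
        x=pos[:, 0],
        y=pos[:, 1],
        arena_side=side,
    )


def simulate_cohort_trajectories(
    walk: WalkConfig,
    n_per_group: int = 40,
    seed: int = 0,
    enr_step_shrink: float = 0.85,
    ctrl_habituation: tuple[float, float] = (0.85, 0.05),
    enr_habituation: tuple[float, float] = (0.70, 0.12),
    n_lost_trial2_ctrl: int = 8,
) -> list[Trajectory]:
    """Two open-field trials for every animal of a two-group cohort.

    Per-animal individuality enters through an animal-specific step scale
    (lognormal jitter around the group base) and habituation factor
    (group-specific (mean, sd), clipped to [0, 1]); the enriched group
    explores with smaller steps (lower roaming entropy) but habituates
    more strongly and more variably.  ``n_lost_trial2_ctrl`` CTRL animals
    lose their second-trial recording, emulating technical data loss.
    """
    rng = np.random.default_rng(seed)
    lost = set(rng.choice(n_per_group, size=min(n_lost_trial2_ctrl, n_per_group), replace=False))
    out: list[Trajectory] = []
    for group in GROUPS:
        base_scale = walk.step_scale * (enr_step_shrink if group == "ENR" else 1.0)
        hab_mean, hab_sd = enr_habituation if group == "ENR" else ctrl_habituation
        for i in range(n_per_group):
            animal = f"{group}_{i + 1:03d}"
            step = base_scale * float(np.exp(0.15 * rng.standard_normal()))
            hab = float(np.clip(rng.normal(hab_mean, hab_sd), 0.05, 1.0))
            w = replace(
                walk,
                step_scale=step,
                habituation_factor=hab,
                seed=int(rng.integers(2**31)),
            )
            out.append(simulate_trajectory(w, trial=1, animal_id=animal))
            if group == "CTRL" and i in lost:
                continue
            out.append(simulate_trajectory(w, trial=2, animal_id=animal))
    logger.info(
        "simulated %d trajectories (%d animals/group, %d CTRL trial-2 records lost)",
        len(out), n_per_group, min(n_lost_trial2_ctrl, n_per_group),
    )
    return out


# ---------------------------------------------------------------------------
# raw behavioral records (novel object recognition, rotarod)


def simulate_nor_records(
    n_per_group: int = 40,
    seed: int = 0,
    zero_exploration_rate: float = 0.06,
    enr_exploration_var_ratio: float = 2.5,
) -> pd.DataFrame:
    """Raw novel-object-recognition exploration times, three trials/animal.

    Exploration times are lognormal (enriched animals more variable); with
    probability ``zero_exploration_rate`` an animal ignores object A in
    both early trials or ignores both objects in trial 3, producing the
    animals that the exclusion rule must remove.  Columns:
    ``animal_id, trial, time_object_A, time_object_B`` (trial 3: new, old).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        sigma = 0.4 * (np.sqrt(enr_exploration_var_ratio) if group == "ENR" else 1.0)
        for i in range(n_per_group):
            animal = f"{group}_{i + 1:03d}"
            base = float(np.exp(np.log(12.0) + sigma * rng.standard_normal()))
            skip = rng.random() < zero_exploration_rate
            skip_trial3 = skip and rng.random() < 0.5
            for trial in (1, 2, 3):
                ta = float(base * rng.gamma(4.0, 0.25))
                tb = float(base * rng.gamma(4.0, 0.25))
                if skip and not skip_trial3 and trial in (1, 2):
                    ta = 0.0
                if skip and skip_trial3 and trial == 3:
                    ta = tb = 0.0
                rows.append(
                    {"animal_id": animal, "trial": trial,
                     "time_object_A": ta, "time_object_B": tb}
                )
    return pd.DataFrame(rows)


def simulate_rotarod_records(
    n_per_group: int = 40, seed: int = 0, n_trials: int = 9
) -> pd.DataFrame:
    """Raw rotarod fall latencies, ``n_trials`` accelerating trials/animal.

    Latencies improve across trials and are capped at the 300 s ceiling;
    enriched animals perform better on average.  Columns:
    ``animal_id, trial, latency_s``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in GROUPS:
        base_mean = 150.0 if group == "ENR" else 110.0
        for i in range(n_per_group):
            animal = f"{group}_{i + 1:03d}"
            ability = rng.normal(base_mean, 30.0)
            for trial in range(1, n_trials + 1):
                lat = ability + 6.0 * trial + rng.normal(0.0, 25.0)
                rows.append(
                    {"animal_id": animal, "trial": trial,
                     "latency_s": float(np.clip(lat, 0.0, 300.0))}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# default cohort: the illustrative phenotype panel

#: traits whose raw values are log-transformed before testing
DEFAULT_LOG_TRAITS = frozenset({"triglycerides_mg_dl", "corticosterone_ng_ml"})


def default_trait_specs() -> tuple[TraitSpec, ...]:
    """Illustrative phenotype panel for a two-group enrichment cohort.

    Mirrors the composition of a broad individualization screen — gross
    morphology, open-field and object behavior, adult-neurogenesis counts,
    regional brain volumetry, cortical thickness and plasma metabolites —
    with variance-ratio effects (2.5) confined to behavior- and
    brain-plasticity-related traits, mean shifts on body size and
    metabolism, lognormal right-skewed traits, and occasional technical
    missingness.  Effect sizes are illustrative defaults, not estimates
    from any specific animal cohort.
    """
    return (
        TraitSpec("body_weight_g", "normal", 25.0, 1.5, -2.0, 1.0),
        TraitSpec("body_length_cm", "normal", 9.5, 0.3, -0.3, 1.0),
        TraitSpec("brain_weight_g", "normal", 0.48, 0.02, 0.0, 1.0),
        TraitSpec("adrenal_weight_mg", "normal", 5.5, 0.8, -0.8, 1.0),
        TraitSpec("liver_weight_g", "normal", 1.30, 0.12, -0.15, 1.0),
        TraitSpec("distance_of1_cm", "normal", 2500.0, 400.0, 300.0, 1.0),
        TraitSpec("distance_of2_cm", "normal", 2400.0, 400.0, -300.0, 1.0),
        TraitSpec("distance_nor_cm", "normal", 1400.0, 250.0, -150.0, 1.0),
        TraitSpec("object_exploration_s", "lognormal", 20.0, 8.0, 0.0, 2.5),
        TraitSpec("rotarod_mean_s", "normal", 120.0, 30.0, 40.0, 1.0),
        TraitSpec("ki67_cells", "normal", 2800.0, 500.0, 150.0, 1.0),
        TraitSpec("brdu_cells", "lognormal", 1200.0, 300.0, 400.0, 2.5),
        TraitSpec("new_neurons", "lognormal", 950.0, 250.0, 350.0, 2.5),
        TraitSpec("new_astrocytes", "lognormal", 120.0, 35.0, 0.0, 2.5),
        TraitSpec("hippocampus_volume_mm3", "normal", 22.0, 1.5, 0.0, 1.0),
        TraitSpec("dg_volume_mm3", "normal", 4.4, 0.35, 0.3, 1.0),
        TraitSpec("imf_volume_mm3", "normal", 0.50, 0.06, 0.05, 1.0),
        TraitSpec("smf_volume_mm3", "normal", 1.10, 0.10, 0.0, 1.0),
        TraitSpec("hilus_volume_mm3", "normal", 1.60, 0.15, 0.10, 1.0),
        TraitSpec("motor_cortex_thickness_um", "normal", 1250.0, 60.0, 0.0, 2.5, 0.05),
        TraitSpec("entorhinal_cortex_thickness_um", "normal", 900.0, 50.0, 0.0, 1.0, 0.04),
        TraitSpec("cingulate_cortex_thickness_um", "normal", 1100.0, 55.0, 0.0, 1.0, 0.04),
        TraitSpec("glucose_mg_dl", "normal", 160.0, 25.0, 0.0, 1.0),
        TraitSpec("cholesterol_mg_dl", "normal", 95.0, 12.0, -10.0, 1.0),
        TraitSpec("triglycerides_mg_dl", "lognormal", 90.0, 25.0, 0.0, 1.0),
        TraitSpec("corticosterone_ng_ml", "lognormal", 60.0, 30.0, 0.0, 1.0, 0.02),
    )


def default_cohort_config(seed: int = 0, n_per_group: int = 40) -> CohortConfig:
    """Default two-group cohort: 40 animals/group, correlated trait blocks."""
    return CohortConfig(
        n_per_group=n_per_group,
        traits=default_trait_specs(),
        correlation_blocks=(
            (("glucose_mg_dl", "cholesterol_mg_dl", "triglycerides_mg_dl"), 0.5),
            (("brdu_cells", "new_neurons", "new_astrocytes"), 0.8),
            (("body_weight_g", "body_length_cm", "liver_weight_g"), 0.6),
        ),
        seed=seed,
    )
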