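"""Simulated localisation experiment: design, world, trial loop, sweeps.

The default design mirrors the behavioural protocol: 33 source directions
spread over the full sphere at 30-degree lateral/polar spacing, 20
repetitions per direction in each of three movement conditions (passive,
active-left, active-right), eight virtual listeners.  Passive stimuli last
500 ms; active stimuli are gated off after 10 degrees of yaw rotation, so
their duration follows the drawn rotation speed.  A +/-2.5 dB level roving
is applied between trials.  Trials violating the movement gates (passive:
any-axis movement above 2 degrees; active: total yaw outside [7, 13]
degrees or pitch above 6 degrees, boundaries kept) are flagged excluded.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .frontend import ErbBank, build_template, gammatone_spectrum
from .geometry import DirectionGrid, LateralPolar, cart_to_latpolar, latpolar_to_cart, make_direction_grid
from .observer import NoiseConfig, build_sigma_A, run_observer, spatial_prior
from .synth import (
    SourcePrior,
    SphericalHeadParams,
    TrajectoryJitter,
    draw_rotation_speed,
    fit_source_prior,
    synth_head_trajectory,
    synth_hrir_set,
    synth_source_corpus,
)

__all__ = [
    "CONDITIONS",
    "ExperimentDesign",
    "World",
    "default_source_directions",
    "make_design",
    "build_world",
    "exclusion_filter",
    "run_experiment",
    "parameter_sweep",
]

CONDITIONS = ("passive", "active-left", "active-right")

PASSIVE_MOVEMENT_LIMIT_DEG = 2.0
ACTIVE_YAW_RANGE_DEG = (7.0, 13.0)
ACTIVE_PITCH_LIMIT_DEG = 6.0


def default_source_directions() -> np.ndarray:
    """The 33 source directions of the default design (unit vectors).

    Lateral rings at 0, +/-30 and +/-60 degrees with polar spacing in
    multiples of 30 degrees, coarsened on the higher rings where the rings
    shrink (12, 6 and 4 points per ring), plus the left interaural pole:
    12 + 2*6 + 2*4 + 1 = 33 points over the full sphere.
    """
    specs: list[tuple[float, float]] = []
    specs += [(0.0, p) for p in range(-150, 181, 30)]
    for lat in (30.0, -30.0):
        specs += [(lat, p) for p in (-120, -60, 0, 60, 120, 180)]
    for lat in (60.0, -60.0):
        specs += [(lat, p) for p in (-90, 0, 90, 180)]
    specs.append((90.0, 0.0))
    return np.array([latpolar_to_cart(LateralPolar(lat, pol)) for lat, pol in specs])


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout and stimulus parameters of one simulated study."""

    directions: np.ndarray = field(default_factory=default_source_directions)
    repetitions: int = 20
    conditions: tuple = CONDITIONS
    n_subjects: int = 8
    passive_duration: float = 0.5  # s
    target_yaw: float = 10.0  # deg, rotation gate in active conditions
    rove_db: float = 2.5  # +/- level roving between trials
    speed_median: float = 15.75  # deg/s, median of the rotation-speed draw
    speed_sigma_log: float = 0.5
    grid_n: int = 2042
    fs: float = 48000.0
    ir_length: int = 256
    jitter: TrajectoryJitter = field(default_factory=TrajectoryJitter)
    subject_radius_jitter: float = 0.05  # fractional SD over subjects
    subject_notch_jitter: float = 0.10

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValueError("directions must be an (m, 3) array")
        if np.any(np.abs(np.linalg.norm(dirs, axis=1) - 1.0) > 1e-9):
            raise ValueError("source directions must be unit vectors")
        object.__setattr__(self, "directions", dirs)
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    def trials_per_subject(self, condition: str) -> int:
        return self.n_directions * self.repetitions

    def trial_specs(self):
        """Deterministic full-factorial trial list.

        Yields ``(subject, condition, direction index, repetition)``; the
        per-trial random substream is derived from these indices and the
        master seed, so the schedule order never affects the draws.
        """
        for subject in range(self.n_subjects):
            for ci, condition in enumerate(self.conditions):
                for di in range(self.n_directions):
                    for rep in range(self.repetitions):
                        yield subject, ci, condition, di, rep


def make_design(**overrides) -> ExperimentDesign:
    """Build the default design with keyword overrides."""
    return ExperimentDesign(**overrides)


@dataclass
class World:
    """Everything the observer and the generative world share."""

    design: ExperimentDesign
    grid: DirectionGrid
    bank: ErbBank
    head_params: list
    templates: list  # one AcousticTemplate per subject
    source_prior: SourcePrior
    stimulus_spectrum: np.ndarray  # white-noise burst through the front end
    master_seed: int


def _subject_head_params(design: ExperimentDesign, rng: np.random.Generator) -> list:
    base = SphericalHeadParams()
    out = []
    for _ in range(design.n_subjects):
        out.append(
            dataclasses.replace(
                base,
                radius=base.radius * (1.0 + design.subject_radius_jitter * rng.standard_normal()),
                notch_f0=base.notch_f0 * (1.0 + design.subject_notch_jitter * rng.standard_normal()),
            )
        )
    return out


def build_world(design: ExperimentDesign, master_seed: int = 0) -> World:
    """Synthesize grids, listener templates, source prior and stimulus.

    Deterministic in ``master_seed``; independent of the noise
    configuration, so one world serves a whole parameter sweep.
    """
    rng = np.random.default_rng([int(master_seed), 2042])
    grid = make_direction_grid(design.grid_n)
    bank = ErbBank(fs=design.fs)
    head_params = _subject_head_params(design, rng)
    templates = []
    for p in head_params:
        hrirs = synth_hrir_set(grid, p, fs=design.fs, length=design.ir_length)
        templates.append(build_template(hrirs, grid, bank))
    corpus = synth_source_corpus(seed=rng, cfs=bank.cfs)
    prior = fit_source_prior(corpus)
    noise_burst = rng.standard_normal(int(round(design.fs * design.passive_duration)))
    stimulus = gammatone_spectrum(noise_burst, design.fs, bank)
    return World(
        design=design,
        grid=grid,
        bank=bank,
        head_params=head_params,
        templates=templates,
        source_prior=prior,
        stimulus_spectrum=stimulus,
        master_seed=int(master_seed),
    )


def exclusion_filter(summary: dict, condition: str) -> tuple[bool, str]:
    """Movement-gate check on a trajectory summary.

    Passive trials are excluded when any axis moved more than 2 degrees;
    active trials when the total yaw fell outside [7, 13] degrees or the
    pitch exceeded 6 degrees.  Boundary values are kept (the stated limits
    are strict inequalities).
    """
    if condition == "passive":
        if summary["max_any_axis"] > PASSIVE_MOVEMENT_LIMIT_DEG:
            return True, "passive-movement"
        return False, ""
    lo, hi = ACTIVE_YAW_RANGE_DEG
    if summary["total_yaw"] < lo or summary["total_yaw"] > hi:
        return True, "active-yaw"
    if summary["max_abs_pitch"] > ACTIVE_PITCH_LIMIT_DEG:
        return True, "active-pitch"
    return False, ""


def _trial_rng(master_seed: int, subject: int, ci: int, di: int, rep: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed), subject, ci, di, rep])


def run_experiment(
    design: ExperimentDesign,
    noise: NoiseConfig | None = None,
    rule: str = "PM",
    master_seed: int = 0,
    world: World | None = None,
    keep_excluded: bool = True,
) -> pd.DataFrame:
    """Simulate the full factorial experiment; returns a tidy trial table.

    One row per trial with the true and response directions (cartesian,
    lateral-polar and elevation), the trajectory summary and the exclusion
    flag.  Bit-identical across runs with the same master seed and design.
    """
    noise = noise or NoiseConfig()
    if world is None:
        world = build_world(design, master_seed)
    sigma_A = build_sigma_A(noise, world.source_prior)
    prior = spatial_prior(world.grid, noise.sigma_p)
    rows = []
    for subject, ci, condition, di, rep in design.trial_specs():
        rng = _trial_rng(master_seed, subject, ci, di, rep)
        # the world renders sources at template resolution: each nominal
        # target is realised as its nearest template-grid direction
        true_dir = world.grid.points[world.grid.nearest_many(design.directions[di][None, :])[0]]
        speed = draw_rotation_speed(rng, design.speed_median, design.speed_sigma_log)
        traj = synth_head_trajectory(
            condition,
            target_yaw=design.target_yaw,
            speed=speed,
            jitter=design.jitter,
            dt=noise.dt,
            seed=rng,
            passive_duration=design.passive_duration,
        )
        gain_db = float(rng.uniform(-design.rove_db, design.rove_db))
        result = run_observer(
            true_dir,
            traj,
            world.templates[subject],
            sigma_A,
            world.source_prior,
            prior,
            noise,
            rule,
            rng,
            world.stimulus_spectrum,
            gain_db=gain_db,
        )
        summary = traj.summary()
        excluded, reason = exclusion_filter(summary, condition)
        if excluded and not keep_excluded:
            continue
        t_lp = cart_to_latpolar(true_dir)
        r_lp = cart_to_latpolar(result.response_dir)
        rows.append(
            {
                "subject": subject,
                "condition": condition,
                "direction_index": di,
                "repetition": rep,
                "true_x": true_dir[0],
                "true_y": true_dir[1],
                "true_z": true_dir[2],
                "resp_x": result.response_dir[0],
                "resp_y": result.response_dir[1],
                "resp_z": result.response_dir[2],
                "true_lateral": t_lp.lateral,
                "true_polar": t_lp.polar,
                "resp_lateral": r_lp.lateral,
                "resp_polar": r_lp.polar,
                "true_elevation": float(np.degrees(np.arcsin(np.clip(true_dir[2], -1, 1)))),
                "resp_elevation": float(np.degrees(np.arcsin(np.clip(result.response_dir[2], -1, 1)))),
                "n_looks": result.n_looks,
                "duration": summary["duration"],
                "total_yaw": summary["total_yaw"],
                "max_abs_pitch": summary["max_abs_pitch"],
                "excluded": excluded,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


SWEEPABLE = {"sigma_itd", "sigma_H", "sigma_u", "sigma_p", "dt"}


def parameter_sweep(
    param: str,
    values,
    design: ExperimentDesign,
    noise: NoiseConfig | None = None,
    rule: str = "PM",
    master_seed: int = 0,
    world: World | None = None,
) -> pd.DataFrame:
    """Re-run the experiment for each value of one noise parameter.

    Returns one row per (value, condition) with subject-mean and -SD of the
    localisation metrics.  The synthetic world (templates, source prior) is
    shared across values; only the observer/noise configuration changes.
    """
    if param not in SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {param!r}; choose from {sorted(SWEEPABLE)}")
    noise = noise or NoiseConfig()
    if world is None:
        world = build_world(design, master_seed)
    frames = []
    for v in values:
        nz = replace(noise, **{param: float(v)})
        df = run_experiment(design, nz, rule=rule, master_seed=master_seed, world=world)
        kept = df[~df["excluded"]]
        per_sc = _metrics.summarize(kept)
        agg = (
            per_sc.groupby("condition")
            .agg(
                lateral_rmse_mean=("lateral_rmse", "mean"),
                lateral_rmse_sd=("lateral_rmse", "std"),
                polar_rmse_mean=("polar_rmse", "mean"),
                polar_rmse_sd=("polar_rmse", "std"),
                qe_pct_mean=("qe_pct", "mean"),
                qe_pct_sd=("qe_pct", "std"),
                elevation_gain_mean=("elevation_gain", "mean"),
                elevation_gain_sd=("elevation_gain", "std"),
                n_trials=("n_trials", "sum"),
            )
            .reset_index()
        )
        agg.insert(0, "value", float(v))
        agg.insert(0, "param", param)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
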