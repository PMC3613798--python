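"""Synthetic multi-subject BOLD datasets with known ground truth.

Emulates the grouping experiment's event design and effect structure on a
toy 20 x 20 x 20 voxel volume so the whole analysis stack is testable
without scanner data:

* trials at a fixed 8 s pitch (5 s stimulus + 3 s blank), TR 3.264 s,
  seven discarded equilibration volumes simulated then dropped;
* semi-random category order from a six-state Markov chain (the six
  analysis categories) with an elevated self-transition probability that
  favours short runs of the same category;
* spherical effect regions whose responses are linear in the number of
  groupings: a colour-slope region (V4-like), a motion-slope region
  (V5-like), two contiguous non-overlapping parietal-like compartments,
  and one shared region carrying both slopes (cerebellum-like);
* AR(1) noise, slow sinusoidal drift (periods >= 160 s, beyond the 120 s
  high-pass cutoff), and Normal between-subject variation of the effects;
* simulated keypress responses/RTs and nuisance series (6 motion
  parameters + keypress regressor), plus synthetic 500 Hz gaze logs.

Defaults describe a 16-subject, two-sessions-per-subject cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import FOUR_CONDITIONS, build_design
from .hrf import HRFSpec

__all__ = [
    "CATEGORIES",
    "ScanProtocol",
    "EffectRegion",
    "GroundTruth",
    "Session",
    "SubjectDataset",
    "default_ground_truth",
    "schedule_events",
    "simulate_session",
    "simulate_subject",
    "simulate_cohort",
    "simulate_gaze",
    "sphere_mask",
]

#: The six analysis categories (the study's six main contrast vectors).
CATEGORIES = (
    "moving_colour_grouped",
    "moving_colour_ungrouped",
    "moving_greyscale_grouped",
    "moving_greyscale_ungrouped",
    "static_colour",
    "static_greyscale",
)

#: Behavioural emulation: accuracy and mean RT (ms) by true grouping count.
DEFAULT_ACCURACY = {0: 0.85, 1: 0.80, 2: 0.89, 3: 0.85}
DEFAULT_RT_MS = {0: 2900.0, 1: 2926.0, 2: 2923.0, 3: 2790.0}
RT_SD_MS = 300.0


@dataclass(frozen=True)
class ScanProtocol:
    """Event/scan timing for one session."""

    tr_s: float = 3.264
    n_trials: int = 54
    event_duration_s: float = 5.0
    gap_s: float = 3.0
    discard_volumes: int = 7
    n_volumes: int | None = None  # post-discard; derived if None
    stay_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not 0.0 <= self.stay_probability < 1.0:
            raise ValueError("stay_probability must be in [0, 1)")
        if self.n_volumes is not None and self.trial_pitch_s * self.n_trials > (
            self.n_volumes * self.tr_s
        ):
            raise ValueError("event schedule does not fit within n_volumes")

    @property
    def trial_pitch_s(self) -> float:
        return self.event_duration_s + self.gap_s

    @property
    def volumes(self) -> int:
        """Retained volume count: schedule plus a 16 s tail for HRF decay."""
        if self.n_volumes is not None:
            return self.n_volumes
        return int(np.ceil((self.n_trials * self.trial_pitch_s + 16.0) / self.tr_s))

    @property
    def duration_s(self) -> float:
        return self.volumes * self.tr_s


def _category_to_trial(category: str) -> tuple[str, bool]:
    if category.startswith("static"):
        return category, False
    trial_type = category.rsplit("_", 1)[0]
    return trial_type, category.endswith("_grouped")


def schedule_events(protocol: ScanProtocol, rng: np.random.Generator) -> pd.DataFrame:
    """Semi-random trial schedule at a fixed 8 s pitch.

    Categories follow a first-order Markov chain over the six analysis
    categories whose self-transition probability (default 0.3, vs 1/6
    under uniform sampling) favours short runs of the same category.
    Grouped categories draw 1-3 groupings uniformly; ungrouped and static
    trials have zero.  Simulated keypresses use the study-level accuracy
    and RT profile.
    """
    n_cat = len(CATEGORIES)
    p_stay = protocol.stay_probability
    p_move = (1.0 - p_stay) / (n_cat - 1)
    state = int(rng.integers(n_cat))
    rows = []
    for trial in range(protocol.n_trials):
        if trial > 0:
            if rng.random() >= p_stay:
                others = [k for k in range(n_cat) if k != state]
                state = others[int(rng.integers(n_cat - 1))]
        category = CATEGORIES[state]
        trial_type, grouped = _category_to_trial(category)
        n_groups = int(rng.integers(1, 4)) if grouped else 0
        correct = rng.random() < DEFAULT_ACCURACY[n_groups]
        if correct:
            response = n_groups
        else:
            options = [k for k in range(4) if k != n_groups]
            response = options[int(rng.integers(3))]
        rt = float(np.clip(rng.normal(DEFAULT_RT_MS[n_groups], RT_SD_MS), 300.0, 4900.0))
        rows.append(
            {
                "onset": trial * protocol.trial_pitch_s,
                "duration": protocol.event_duration_s,
                "trial_type": trial_type,
                "n_groups": n_groups,
                "response": response,
                "rt": rt,
            }
        )
    return pd.DataFrame(rows)


def sphere_mask(shape: tuple[int, int, int], centre, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, centre))
    return dist2 <= radius**2


@dataclass(frozen=True)
class EffectRegion:
    """One spherical effect region of the ground truth.

    ``category_amplitudes`` are BOLD responses (arbitrary units) to each
    trial type; ``colour_slope``/``motion_slope`` are the response gains
    per additional grouping in the corresponding moving condition.
    """

    name: str
    centre: tuple[int, int, int]
    radius: float
    category_amplitudes: dict = field(
        default_factory=lambda: {
            "moving_colour": 1.0,
            "moving_greyscale": 1.0,
            "static_colour": 0.5,
            "static_greyscale": 0.5,
        }
    )
    colour_slope: float = 0.0
    motion_slope: float = 0.0

    def mask(self, shape) -> np.ndarray:
        return sphere_mask(shape, self.centre, self.radius)


@dataclass(frozen=True)
class GroundTruth:
    """Full generative specification of a synthetic cohort."""

    shape: tuple[int, int, int] = (20, 20, 20)
    regions: tuple[EffectRegion, ...] = ()
    baseline: float = 100.0
    noise_sd: float = 1.0
    ar1: float = 0.3
    drift_amplitudes: tuple[float, ...] = (2.0, 2.0)
    drift_periods_s: tuple[float, ...] = (160.0, 320.0)
    between_subject_sd: float = 0.1

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if any(p < 160.0 for p in self.drift_periods_s):
            raise ValueError("drift periods must be >= 160 s (beyond the high-pass)")
        for region in self.regions:
            lo = np.array(region.centre) - region.radius
            hi = np.array(region.centre) + region.radius
            if (lo < 0).any() or (hi >= np.array(self.shape)).any():
                raise ValueError(f"region {region.name} exceeds the volume bounds")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def region(self, name: str) -> EffectRegion:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(name)


def default_ground_truth(slope: float = 0.5) -> GroundTruth:
    """The default dissociation truth on the 20^3 toy volume.

    Colour-slope-only and motion-slope-only regions stand in for the V4
    and V5 complexes, two contiguous non-overlapping compartments for the
    intraparietal cortex, and one region carrying both slopes for the
    shared cerebellar site.
    """
    return GroundTruth(
        regions=(
            EffectRegion("v4_like", (5, 10, 10), 2.2, colour_slope=slope),
            EffectRegion("v5_like", (15, 10, 10), 2.2, motion_slope=slope),
            EffectRegion("ips_colour", (8, 15, 10), 1.6, colour_slope=slope),
            EffectRegion("ips_motion", (12, 15, 10), 1.6, motion_slope=slope),
            EffectRegion(
                "cerebellum_like",
                (10, 4, 10),
                2.2,
                colour_slope=slope,
                motion_slope=slope,
            ),
        )
    )


@dataclass
class Session:
    """One scanning session: 4-D data (as time x voxels), events, nuisance."""

    data: np.ndarray
    events: pd.DataFrame
    nuisance: pd.DataFrame
    tr: float
    shape: tuple[int, int, int]
    session_id: int = 0

    def volume4d(self) -> np.ndarray:
        """Reshape to (x, y, z, t) for NIfTI export."""
        return np.moveaxis(self.data.reshape((-1,) + self.shape), 0, -1)


@dataclass
class SubjectDataset:
    """All sessions of one subject plus the subject-level effect draws."""

    subject_id: int
    sessions: list[Session]
    effects: dict  # region name -> {"colour_slope": ..., "motion_slope": ..., "amplitudes": {...}}


def _subject_effects(
    truth: GroundTruth, rng: np.random.Generator
) -> dict[str, dict]:
    """Draw one subject's region effects around the group means."""
    sd = truth.between_subject_sd
    effects = {}
    for region in truth.regions:
        effects[region.name] = {
            "colour_slope": region.colour_slope
            + (rng.normal(0.0, sd) if region.colour_slope != 0.0 else 0.0),
            "motion_slope": region.motion_slope
            + (rng.normal(0.0, sd) if region.motion_slope != 0.0 else 0.0),
            "amplitudes": {
                cat: amp + rng.normal(0.0, sd)
                for cat, amp in region.category_amplitudes.items()
            },
        }
    return effects


def _nuisance_series(
    events: pd.DataFrame, n_volumes: int, tr: float, rng: np.random.Generator
) -> pd.DataFrame:
    motion = np.cumsum(rng.normal(0.0, 0.02, size=(n_volumes, 6)), axis=0)
    keypress = np.zeros(n_volumes)
    press_times = events["onset"].to_numpy() + events["rt"].to_numpy() / 1000.0
    vol_idx = np.clip(np.round(press_times / tr).astype(int), 0, n_volumes - 1)
    keypress[vol_idx] = 1.0
    cols = {f"motion_{i}": motion[:, i] for i in range(6)}
    cols["keypress"] = keypress
    return pd.DataFrame(cols)


def simulate_session(
    protocol: ScanProtocol,
    truth: GroundTruth,
    effects: dict,
    rng: np.random.Generator,
    session_id: int = 0,
    hrf_spec: HRFSpec | None = None,
) -> Session:
    """Forward-model one session.

    Voxel signal = sum over condition boxcars of amplitude x (boxcar
    convolved with the HRF) + slope x (mean-centred grouping modulator
    convolved with the HRF), plus baseline, slow sinusoidal drift and
    AR(1) noise with the configured marginal SD.  The equilibration
    volumes are simulated at the start and then dropped.
    """
    events = schedule_events(protocol, rng)
    n_vol = protocol.volumes
    n_total = n_vol + protocol.discard_volumes
    v = truth.n_voxels

    dm = build_design(
        events,
        n_volumes=n_vol,
        tr=protocol.tr_s,
        variant="four_condition_parametric",
        nuisance=None,
        hrf_spec=hrf_spec,
        add_derivatives=False,
        add_intercept=False,
    )
    amp = np.zeros((dm.n_regressors, v))
    for region in truth.regions:
        mask = region.mask(truth.shape).ravel()
        eff = effects[region.name]
        for j, (name, role) in enumerate(zip(dm.names, dm.roles)):
            if role == "condition":
                amp[j, mask] += eff["amplitudes"].get(name, 0.0)
            elif name == "moving_colour_x_n_groups":
                amp[j, mask] += eff["colour_slope"]
            elif name == "moving_greyscale_x_n_groups":
                amp[j, mask] += eff["motion_slope"]
    signal = dm.matrix @ amp  # (n_vol, v)

    t = np.arange(n_total) * protocol.tr_s
    drift = np.zeros(n_total)
    for a, period in zip(truth.drift_amplitudes, truth.drift_periods_s):
        drift += a * np.sin(2.0 * np.pi * t / period + rng.uniform(0.0, 2.0 * np.pi))

    innov_sd = truth.noise_sd * np.sqrt(1.0 - truth.ar1**2)
    innovations = rng.normal(0.0, innov_sd, size=(n_total, v))
    noise = lfilter([1.0], [1.0, -truth.ar1], innovations, axis=0)

    data = truth.baseline + drift[:, None] + noise
    data[protocol.discard_volumes :] += signal
    data = data[protocol.discard_volumes :]

    nuisance = _nuisance_series(events, n_vol, protocol.tr_s, rng)
    return Session(
        data=data,
        events=events,
        nuisance=nuisance,
        tr=protocol.tr_s,
        shape=truth.shape,
        session_id=session_id,
    )


def simulate_subject(
    protocol: ScanProtocol,
    truth: GroundTruth,
    seed: int | np.random.SeedSequence,
    subject_id: int = 0,
    n_sessions: int = 2,
    hrf_spec: HRFSpec | None = None,
) -> SubjectDataset:
    """Simulate one subject: shared effect draws, per-session event orders."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    eff_seed, *sess_seeds = ss.spawn(1 + n_sessions)
    effects = _subject_effects(truth, np.random.default_rng(eff_seed))
    sessions = [
        simulate_session(
            protocol,
            truth,
            effects,
            np.random.default_rng(s),
            session_id=k,
            hrf_spec=hrf_spec,
        )
        for k, s in enumerate(sess_seeds)
    ]
    return SubjectDataset(subject_id=subject_id, sessions=sessions, effects=effects)


def simulate_cohort(
    n_subjects: int = 16,
    protocol: ScanProtocol | None = None,
    truth: GroundTruth | None = None,
    seed: int = 0,
    n_sessions: int = 2,
    hrf_spec: HRFSpec | None = None,
) -> list[SubjectDataset]:
    """Simulate the full cohort (default 16 subjects x 2 sessions)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    protocol = protocol or ScanProtocol()
    truth = truth if truth is not None else default_ground_truth()
    root = np.random.SeedSequence(seed)
    return [
        simulate_subject(
            protocol, truth, child, subject_id=i, n_sessions=n_sessions, hrf_spec=hrf_spec
        )
        for i, child in enumerate(root.spawn(n_subjects))
    ]


def simulate_null_maps(
    n_subjects: int,
    shape: tuple[int, int, int] = (20, 20, 20),
    fwhm_vox: float = 3.0,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Null second-level input: smooth Gaussian subject maps, no effect.

    Real subject contrast images are spatially smooth (acquisition blur
    plus the smoothing kernel applied before group analysis); the default
    FWHM of 3 voxels corresponds to ~9 mm at 3 mm voxels.  Smoothness also
    gives the max-cluster-size null a usable dynamic range — on spatially
    independent noise nearly every cluster is a single voxel and
    cluster-extent inference degenerates.  Returns (n_subjects, n_voxels).
    """
    from scipy.ndimage import gaussian_filter

    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    sigma = fwhm_vox / np.sqrt(8.0 * np.log(2.0))
    maps = rng.normal(size=(n_subjects,) + tuple(shape))
    smoothed = gaussian_filter(maps, (0.0, sigma, sigma, sigma), mode="constant")
    return smoothed.reshape(n_subjects, -1)


def simulate_gaze(
    events: pd.DataFrame,
    duration_s: float,
    rng: np.random.Generator,
    rate_hz: float = 500.0,
    centre: tuple[float, float] = (512.0, 384.0),
    dispersion_px: float = 15.0,
    grouping_dispersion_gain: float = 1.0,
    valid_fraction: float = 0.92,
) -> pd.DataFrame:
    """Synthetic fixation gaze log (t, x, y, valid) at 500 Hz.

    Gaze scatters isotropically around the fixation cross; during grouping
    epochs the scatter SD is multiplied by ``grouping_dispersion_gain``
    (1.0 = the null relationship the study reports).  Invalid samples
    (blinks/track losses) occur in short runs with the configured overall
    fraction of valid samples.
    """
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    sd = np.full(n, dispersion_px)
    for _, ev in events.iterrows():
        if ev["n_groups"] > 0:
            sel = (t >= ev["onset"]) & (t < ev["onset"] + ev["duration"])
            sd[sel] *= grouping_dispersion_gain
    x = centre[0] + rng.normal(0.0, 1.0, n) * sd
    y = centre[1] + rng.normal(0.0, 1.0, n) * sd
    valid = np.ones(n, dtype=bool)
    # blink-like invalid runs of ~100 ms until the target fraction is met
    run = int(0.1 * rate_hz)
    n_bad = int(round((1.0 - valid_fraction) * n))
    while valid.sum() > n - n_bad:
        start = int(rng.integers(0, max(n - run, 1)))
        valid[start : start + run] = False
    return pd.DataFrame({"t": t, "x": x, "y": y, "valid": valid})
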