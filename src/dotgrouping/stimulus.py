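"""Random-dot grouping stimulus simulator.

Generates the six stimulus categories used in the colour/motion grouping
experiment: fields of 680 moving dots (coloured or greyscale) containing
0-3 circular grouping regions, plus static colour and static greyscale
frames.  Groupings are defined either chromatically (dots inside static
circular regions take a single shared colour) or kinetically (dots
initialised inside the regions share one common random-walk direction).

All kinematic rules operate in pixel units on a 1024 x 768 field:

* ungrouped dots rotate their heading by a uniform jitter of up to
  ±0.2 rad per frame, receive a rightward bias of 1.5 px/frame, and are
  renormalised to move exactly 1.7 px per frame, wrapping toroidally;
* grouped dots share a single jittered heading with no rightward bias and
  reverse direction (180°) instead of wrapping when they meet an edge.

The public surface is vectorised: dot state lives in a :class:`DotField`
(struct-of-arrays), and the per-frame update functions accept and return
whole fields.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "MOVING_CONDITIONS",
    "STATIC_CONDITIONS",
    "ConfigurationError",
    "PlacementError",
    "SimConfig",
    "DotField",
    "GroupingRegion",
    "GroupMotionState",
    "StepResult",
    "StimulusSequence",
    "rng_streams",
    "init_dot_field",
    "assign_colours",
    "rgb_to_grey_level",
    "place_regions",
    "region_membership",
    "step_ungrouped",
    "step_groups",
    "wrap_position",
    "recolour_in_regions",
    "generate_sequence",
    "displacement_norms",
    "frame_displacements",
]

CONDITIONS = ("moving_colour", "moving_greyscale", "static_colour", "static_greyscale")
MOVING_CONDITIONS = ("moving_colour", "moving_greyscale")
STATIC_CONDITIONS = ("static_colour", "static_greyscale")

#: Named substreams spawned from the root seed.  Each component draws from
#: its own stream so that changing the draw count of one component never
#: perturbs the others.
RNG_STREAMS = ("positions", "colours", "regions", "directions", "group", "static")


class ConfigurationError(ValueError):
    """Raised for invalid stimulus configurations."""


class PlacementError(RuntimeError):
    """Raised when grouping-region rejection sampling exceeds its cap."""


@dataclass(frozen=True)
class SimConfig:
    """All numeric stimulus parameters, with experiment defaults.

    Lengths are in pixels, durations in seconds, angles in radians.
    ``speed_px_per_frame`` is the exact post-normalisation displacement of
    every dot on every frame; ``x_bias_px_per_frame`` is the rightward
    vector added to ungrouped dots before renormalisation.
    """

    n_dots: int = 680
    dot_diameter_px: float = 10.0
    field_w_px: float = 1024.0
    field_h_px: float = 768.0
    jitter_px: float = 10.0
    region_diameter_px: float = 100.0
    n_groups: int = 0
    dir_jitter_rad: float = 0.2
    x_bias_px_per_frame: float = 1.5
    speed_px_per_frame: float = 1.7
    burn_in_frames: int = 100
    stim_duration_s: float = 5.0
    blank_duration_s: float = 3.0
    frame_rate_hz: float = 50.0
    condition: str = "moving_colour"
    seed: int = 0
    grid_cols: int = 34
    grid_rows: int = 20

    def __post_init__(self) -> None:
        for name in (
            "n_dots",
            "dot_diameter_px",
            "field_w_px",
            "field_h_px",
            "region_diameter_px",
            "speed_px_per_frame",
            "stim_duration_s",
            "frame_rate_hz",
            "grid_cols",
            "grid_rows",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("jitter_px", "dir_jitter_rad", "x_bias_px_per_frame", "burn_in_frames"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if not 0 <= self.n_groups <= 3:
            raise ConfigurationError("n_groups must be between 0 and 3")
        if self.condition in STATIC_CONDITIONS and self.n_groups != 0:
            raise ConfigurationError("static conditions have no groups (n_groups must be 0)")
        if self.grid_cols * self.grid_rows != self.n_dots:
            raise ConfigurationError(
                f"n_dots={self.n_dots} is not expressible as the configured "
                f"{self.grid_cols} x {self.grid_rows} grid"
            )

    @property
    def region_radius_px(self) -> float:
        return self.region_diameter_px / 2.0

    @property
    def n_display_frames(self) -> int:
        """Exported frame count: 5 s of motion, or a single static frame."""
        if self.condition in STATIC_CONDITIONS:
            return 1
        return round(self.stim_duration_s * self.frame_rate_hz)

    @property
    def is_greyscale(self) -> bool:
        return self.condition in ("moving_greyscale", "static_greyscale")


def rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """Spawn one independent generator per named component from a root seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(RNG_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(RNG_STREAMS, children)}


@dataclass
class DotField:
    """Struct-of-arrays dot state for one stimulus.

    ``group_ids`` holds the region index a dot belongs to (fixed at
    initialisation for motion grouping; dynamic containment for colour
    grouping) or -1 for ungrouped dots.
    """

    positions: np.ndarray  # (n, 2) float64, px
    directions: np.ndarray  # (n,) float64, rad
    base_colours: np.ndarray  # (n, 3) uint8
    display_colours: np.ndarray  # (n, 3) uint8
    group_ids: np.ndarray  # (n,) int64, -1 = none

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "DotField":
        return DotField(*(getattr(self, f.name).copy() for f in dataclasses.fields(self)))


@dataclass(frozen=True)
class GroupingRegion:
    """A circular grouping region, fully inside the visible field."""

    centre: tuple[float, float]
    radius: float


@dataclass(frozen=True)
class GroupMotionState:
    """Shared heading of all kinetically grouped dots (one per stimulus)."""

    shared_direction: float


class StepResult(NamedTuple):
    positions: np.ndarray
    directions: np.ndarray
    displacement: np.ndarray
    jitter: np.ndarray


def grid_positions(config: SimConfig) -> np.ndarray:
    """Cell-centred regular grid filling the field (col-major x fastest)."""
    xs = (np.arange(config.grid_cols) + 0.5) * (config.field_w_px / config.grid_cols)
    ys = (np.arange(config.grid_rows) + 0.5) * (config.field_h_px / config.grid_rows)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def init_dot_field(config: SimConfig, rng: np.random.Generator) -> DotField:
    """Place dots on the jittered grid.

    Each dot starts at its grid cell centre plus an independent uniform
    offset in [-jitter_px, +jitter_px] on each axis; offsets that push a
    dot over the field edge are wrapped immediately, consistent with the
    running wrap rule.  Initial headings are uniform on [0, 2*pi).
    """
    grid = grid_positions(config)
    offsets = rng.uniform(-config.jitter_px, config.jitter_px, size=(config.n_dots, 2))
    positions = wrap_position(grid + offsets, config)
    directions = rng.uniform(0.0, 2.0 * np.pi, size=config.n_dots)
    n = config.n_dots
    zeros = np.zeros((n, 3), dtype=np.uint8)
    return DotField(
        positions=positions,
        directions=directions,
        base_colours=zeros.copy(),
        display_colours=zeros.copy(),
        group_ids=np.full(n, -1, dtype=np.int64),
    )


def rgb_to_grey_level(rgb: np.ndarray) -> np.ndarray:
    """Map 8-bit sRGB colours to the 8-bit encoding of their CIELAB L*.

    Uses the standard sRGB transfer function with the D65 white point;
    the grey level is ``round(255 * L* / 100)`` so that black maps to 0
    and white to 255.
    """
    from skimage.color import rgb2lab

    arr = np.asarray(rgb, dtype=np.float64).reshape(-1, 1, 3) / 255.0
    lab = rgb2lab(arr)
    lightness = lab[:, 0, 0]
    return np.clip(np.round(255.0 * lightness / 100.0), 0, 255).astype(np.uint8)


def assign_colours(dots: DotField, condition: str, rng: np.random.Generator) -> DotField:
    """Draw base colours uniformly from the full 8-bit RGB cube.

    Greyscale conditions draw the same random colours and replace each by
    the grey whose level equals the colour's CIELAB lightness, so the
    greyscale palette is the lightness distribution of the colour palette.
    """
    colours = rng.integers(0, 256, size=(dots.n_dots, 3), dtype=np.uint8)
    if condition in ("moving_greyscale", "static_greyscale"):
        grey = rgb_to_grey_level(colours)
        colours = np.repeat(grey[:, None], 3, axis=1)
    out = dots.copy()
    out.base_colours = colours
    out.display_colours = colours.copy()
    return out


def place_regions(
    n_groups: int, config: SimConfig, rng: np.random.Generator, max_iter: int = 10_000
) -> list[GroupingRegion]:
    """Rejection-sample non-overlapping region centres, discs fully in-field.

    Centres are uniform over the admissible rectangle; a candidate is
    rejected if its centre lies closer than one region diameter to an
    already accepted centre (non-overlap reading of "no two regions should
    be coincident").
    """
    if not 0 <= n_groups <= 3:
        raise ConfigurationError("n_groups must be between 0 and 3")
    r = config.region_radius_px
    if config.field_w_px < 2 * r or config.field_h_px < 2 * r:
        raise PlacementError("region diameter exceeds the field")
    centres: list[np.ndarray] = []
    for _ in range(max_iter):
        if len(centres) == n_groups:
            break
        cand = rng.uniform(
            [r, r], [config.field_w_px - r, config.field_h_px - r], size=2
        )
        if all(np.hypot(*(cand - c)) >= config.region_diameter_px for c in centres):
            centres.append(cand)
    else:
        raise PlacementError(
            f"could not place {n_groups} regions in {max_iter} iterations"
        )
    return [GroupingRegion(centre=(float(c[0]), float(c[1])), radius=r) for c in centres]


def _region_arrays(regions: Sequence[GroupingRegion]) -> tuple[np.ndarray, np.ndarray]:
    if not regions:
        return np.empty((0, 2)), np.empty((0,))
    centres = np.array([reg.centre for reg in regions], dtype=np.float64)
    radii = np.array([reg.radius for reg in regions], dtype=np.float64)
    return centres, radii


def region_membership(
    positions: np.ndarray, regions: Sequence[GroupingRegion]
) -> np.ndarray:
    """Index of the region containing each dot centre, or -1.

    Membership is a disc test on the dot centre (dot radius ignored); a
    centre exactly on the rim counts as inside.  Regions do not overlap,
    so the first match is the only match.
    """
    out = np.full(positions.shape[0], -1, dtype=np.int64)
    centres, radii = _region_arrays(regions)
    for idx in range(len(radii) - 1, -1, -1):
        dist = np.hypot(
            positions[:, 0] - centres[idx, 0], positions[:, 1] - centres[idx, 1]
        )
        out[dist <= radii[idx]] = idx
    return out


def wrap_position(positions: np.ndarray, config: SimConfig) -> np.ndarray:
    """Wrap positions toroidally into [0, field_w) x [0, field_h)."""
    out = np.array(positions, dtype=np.float64, copy=True)
    out[..., 0] %= config.field_w_px
    out[..., 1] %= config.field_h_px
    # float modulo of a tiny negative value can round up to the bound itself
    out[..., 0][out[..., 0] >= config.field_w_px] = 0.0
    out[..., 1][out[..., 1] >= config.field_h_px] = 0.0
    return out


def step_ungrouped(
    positions: np.ndarray,
    directions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> StepResult:
    """One kinematic update of ungrouped dots (positions not yet wrapped).

    heading' = heading + U(-j, j); the raw velocity is the nominal-speed
    heading vector plus the rightward bias (x_bias, 0); the displacement is
    that raw velocity renormalised to exactly ``speed_px_per_frame``.  The
    stored heading becomes the direction of the realised displacement.
    """
    m = positions.shape[0]
    jitter = rng.uniform(-config.dir_jitter_rad, config.dir_jitter_rad, size=m)
    theta = directions + jitter
    speed = config.speed_px_per_frame
    raw = np.column_stack(
        [speed * np.cos(theta) + config.x_bias_px_per_frame, speed * np.sin(theta)]
    )
    norm = np.hypot(raw[:, 0], raw[:, 1])
    # exact cancellation cannot occur when x_bias != speed; guard anyway
    degenerate = norm == 0.0
    if degenerate.any():
        raw[degenerate] = np.column_stack(
            [np.cos(theta[degenerate]), np.sin(theta[degenerate])]
        )
        norm[degenerate] = 1.0
    displacement = speed * raw / norm[:, None]
    new_dirs = np.arctan2(displacement[:, 1], displacement[:, 0])
    return StepResult(positions + displacement, new_dirs, displacement, jitter)


def step_groups(
    state: GroupMotionState,
    positions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[GroupMotionState, np.ndarray, np.ndarray]:
    """One shared update of all kinetically grouped dots.

    A single jitter draw updates the shared heading; every grouped dot
    receives the identical displacement of length ``speed_px_per_frame``
    with no rightward bias.  If any grouped dot would leave the field this
    frame the shared heading is reversed by 180° before moving; if (in
    pathological geometries) the reversed move would also exit, the group
    holds position for the frame.

    Returns the new state, new positions and the shared displacement.
    """
    jitter = rng.uniform(-config.dir_jitter_rad, config.dir_jitter_rad)
    theta = state.shared_direction + jitter
    speed = config.speed_px_per_frame

    def _disp(angle: float) -> np.ndarray:
        return np.array([speed * math.cos(angle), speed * math.sin(angle)])

    def _exits(new_pos: np.ndarray) -> bool:
        return bool(
            (new_pos[:, 0] < 0).any()
            or (new_pos[:, 0] >= config.field_w_px).any()
            or (new_pos[:, 1] < 0).any()
            or (new_pos[:, 1] >= config.field_h_px).any()
        )

    disp = _disp(theta)
    new_positions = positions + disp
    if positions.size and _exits(new_positions):
        theta = math.remainder(theta + math.pi, 2.0 * math.pi)
        disp = _disp(theta)
        new_positions = positions + disp
        if _exits(new_positions):  # cannot occur at experiment geometry
            disp = np.zeros(2)
            new_positions = positions.copy()
    return GroupMotionState(shared_direction=float(theta)), new_positions, disp


def recolour_in_regions(
    dots: DotField,
    regions: Sequence[GroupingRegion],
    group_colour: np.ndarray,
    condition: str,
) -> DotField:
    """Apply the chromatic grouping rule for the current frame.

    Dots whose centres lie inside any (static) grouping region display the
    single shared group colour; all others display their base colour, so a
    dot's colour reverts exactly when it leaves a region.
    """
    if condition not in ("moving_colour", "static_colour"):
        raise ConfigurationError("recolour_in_regions applies to colour conditions only")
    out = dots.copy()
    member = region_membership(out.positions, regions)
    out.group_ids = member
    out.display_colours = out.base_colours.copy()
    inside = member >= 0
    out.display_colours[inside] = np.asarray(group_colour, dtype=np.uint8)
    return out


@dataclass
class StimulusSequence:
    """Per-frame dot snapshots plus region/group metadata for one stimulus.

    ``positions`` has shape (frames, n_dots, 2); ``colours`` the displayed
    8-bit colours, (frames, n_dots, 3); ``group_ids`` the per-frame region
    membership (fixed initial membership for motion grouping, dynamic
    containment for colour grouping).  ``group_displacements`` logs the
    shared displacement applied between consecutive displayed frames in the
    motion-grouping condition.
    """

    config: SimConfig
    positions: np.ndarray
    colours: np.ndarray
    group_ids: np.ndarray
    regions: list[GroupingRegion] = field(default_factory=list)
    group_colour: np.ndarray | None = None
    group_displacements: np.ndarray | None = None
    n_simulated_frames: int = 0

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dots(self) -> int:
        return self.positions.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StimulusSequence):
            return NotImplemented

        def _arr_eq(a, b):
            if a is None or b is None:
                return a is None and b is None
            return np.array_equal(a, b)

        return (
            self.config == other.config
            and _arr_eq(self.positions, other.positions)
            and _arr_eq(self.colours, other.colours)
            and _arr_eq(self.group_ids, other.group_ids)
            and self.regions == other.regions
            and _arr_eq(self.group_colour, other.group_colour)
            and self.n_simulated_frames == other.n_simulated_frames
        )


def _moving_sequence(config: SimConfig, rngs: dict[str, np.random.Generator]) -> StimulusSequence:
    dots = init_dot_field(config, rngs["positions"])
    dots = assign_colours(dots, config.condition, rngs["colours"])
    regions = place_regions(config.n_groups, config, rngs["regions"])

    colour_grouping = config.condition == "moving_colour" and config.n_groups > 0
    motion_grouping = config.condition == "moving_greyscale" and config.n_groups > 0

    group_colour: np.ndarray | None = None
    if colour_grouping:
        group_colour = rngs["group"].integers(0, 256, size=3, dtype=np.uint8)

    grouped = np.zeros(config.n_dots, dtype=bool)
    state = GroupMotionState(0.0)
    if motion_grouping:
        # membership is frozen at initialisation, before the burn-in
        member = region_membership(dots.positions, regions)
        dots.group_ids = member
        grouped = member >= 0
        state = GroupMotionState(float(rngs["group"].uniform(0.0, 2.0 * np.pi)))

    n_frames = config.n_display_frames
    burn_in = config.burn_in_frames if motion_grouping else 0

    positions = np.empty((n_frames, config.n_dots, 2))
    colours = np.empty((n_frames, config.n_dots, 3), dtype=np.uint8)
    group_ids = np.empty((n_frames, config.n_dots), dtype=np.int64)
    group_disp = np.zeros((n_frames, 2)) if motion_grouping else None

    def _record(frame: int) -> None:
        if colour_grouping:
            current = recolour_in_regions(dots, regions, group_colour, config.condition)
        else:
            current = dots
        positions[frame] = current.positions
        colours[frame] = current.display_colours
        group_ids[frame] = current.group_ids

    def _advance() -> np.ndarray:
        nonlocal state
        free = ~grouped
        res = step_ungrouped(
            dots.positions[free], dots.directions[free], config, rngs["directions"]
        )
        dots.positions[free] = wrap_position(res.positions, config)
        dots.directions[free] = res.directions
        disp = np.zeros(2)
        if grouped.any():
            state, new_pos, disp = step_groups(
                state, dots.positions[grouped], config, rngs["group"]
            )
            dots.positions[grouped] = new_pos
        return disp

    for _ in range(burn_in):
        _advance()

    _record(0)
    for frame in range(1, n_frames):
        disp = _advance()
        if group_disp is not None:
            group_disp[frame] = disp
        _record(frame)

    return StimulusSequence(
        config=config,
        positions=positions,
        colours=colours,
        group_ids=group_ids,
        regions=list(regions),
        group_colour=group_colour,
        group_displacements=group_disp,
        n_simulated_frames=burn_in + n_frames,
    )


def generate_sequence(config: SimConfig) -> StimulusSequence:
    """Generate one full stimulus, deterministically from ``config.seed``.

    Moving conditions run the complete pipeline (grid init, colours,
    regions, optional 100-frame non-displayed burn-in for motion grouping,
    then 5 s of displayed frames).  Static conditions return a single frame
    drawn at random from a zero-group moving sequence of the matching
    palette.
    """
    rngs = rng_streams(config.seed)
    if config.condition in MOVING_CONDITIONS:
        return _moving_sequence(config, rngs)

    # static: sample one frame of a zero-group moving sequence
    moving_condition = (
        "moving_colour" if config.condition == "static_colour" else "moving_greyscale"
    )
    source_cfg = dataclasses.replace(config, condition=moving_condition, n_groups=0)
    source = _moving_sequence(source_cfg, rngs)
    idx = int(rngs["static"].integers(0, source.n_frames))
    return StimulusSequence(
        config=config,
        positions=source.positions[idx : idx + 1].copy(),
        colours=source.colours[idx : idx + 1].copy(),
        group_ids=source.group_ids[idx : idx + 1].copy(),
        regions=[],
        group_colour=None,
        group_displacements=None,
        n_simulated_frames=source.n_simulated_frames,
    )


def frame_displacements(seq: StimulusSequence) -> np.ndarray:
    """Per-dot displacement between consecutive frames, unwrapping the torus.

    Displacements are far smaller than half the field, so the minimal-image
    difference recovers the true step even across a wrap.
    """
    diff = np.diff(seq.positions, axis=0)
    w, h = seq.config.field_w_px, seq.config.field_h_px
    diff[..., 0] = (diff[..., 0] + w / 2.0) % w - w / 2.0
    diff[..., 1] = (diff[..., 1] + h / 2.0) % h - h / 2.0
    return diff


def displacement_norms(seq: StimulusSequence) -> np.ndarray:
    """Norm of every per-dot per-frame displacement, shape (frames-1, n_dots)."""
    diff = frame_displacements(seq)
    return np.hypot(diff[..., 0], diff[..., 1])
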