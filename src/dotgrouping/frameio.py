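"""Frame-dump text format for stimulus sequences.

The dump is UTF-8, tab-separated, losslessly round-trippable:

* ``#``-prefixed metadata header holding every configuration field
  (including the seed) as ``key=value`` pairs, the optional group colour
  and the total simulated frame count;
* a region block, one ``# region`` line per grouping region
  (index, cx, cy, radius);
* one data row per dot per frame:
  ``frame_index  dot_index  x  y  r  g  b  group_id`` with ``group_id``
  -1 for ungrouped dots.  Positions are printed with full (shortest
  round-trip) precision.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .stimulus import GroupingRegion, SimConfig, StimulusSequence

__all__ = ["FrameDumpError", "export_frames", "import_frames"]

MAGIC = "# dotgrouping frame dump v1"

_INT_FIELDS = {"n_dots", "n_groups", "burn_in_frames", "seed", "grid_cols", "grid_rows"}
_STR_FIELDS = {"condition"}


class FrameDumpError(ValueError):
    """Malformed frame dump; the message names the offending line."""


def export_frames(seq: StimulusSequence, path: str | Path) -> Path:
    """Write a stimulus sequence to a frame-dump text file."""
    path = Path(path)
    lines: list[str] = [MAGIC]
    for f in dataclasses.fields(SimConfig):
        lines.append(f"# config\t{f.name}={getattr(seq.config, f.name)!r}")
    lines.append(f"# n_simulated_frames={seq.n_simulated_frames}")
    if seq.group_colour is not None:
        r, g, b = (int(v) for v in seq.group_colour)
        lines.append(f"# group_colour\t{r}\t{g}\t{b}")
    for idx, reg in enumerate(seq.regions):
        lines.append(
            f"# region\t{idx}\t{reg.centre[0]!r}\t{reg.centre[1]!r}\t{reg.radius!r}"
        )
    lines.append("frame\tdot\tx\ty\tr\tg\tb\tgroup")
    for frame in range(seq.n_frames):
        pos = seq.positions[frame]
        col = seq.colours[frame]
        gid = seq.group_ids[frame]
        for dot in range(seq.n_dots):
            x, y = float(pos[dot, 0]), float(pos[dot, 1])
            lines.append(
                f"{frame}\t{dot}\t{x!r}\t{y!r}\t"
                f"{col[dot, 0]}\t{col[dot, 1]}\t{col[dot, 2]}\t{gid[dot]}"
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _parse_config(pairs: dict[str, str], lineno: int) -> SimConfig:
    kwargs: dict[str, object] = {}
    for f in dataclasses.fields(SimConfig):
        if f.name not in pairs:
            raise FrameDumpError(f"line {lineno}: missing config field {f.name!r}")
        raw = pairs[f.name]
        if f.name in _STR_FIELDS:
            kwargs[f.name] = raw.strip("'\"")
        elif f.name in _INT_FIELDS:
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = float(raw)
    return SimConfig(**kwargs)


def import_frames(path: str | Path) -> StimulusSequence:
    """Read a frame-dump file back into a :class:`StimulusSequence`."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != MAGIC:
        raise FrameDumpError("line 1: not a dotgrouping frame dump")

    config_pairs: dict[str, str] = {}
    regions: list[GroupingRegion] = []
    group_colour: np.ndarray | None = None
    n_simulated = 0
    rows: list[tuple[int, int, float, float, int, int, int, int]] = []
    header_seen = False

    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            if line.startswith("# config\t"):
                key, _, value = line.split("\t", 1)[1].partition("=")
                config_pairs[key] = value
            elif line.startswith("# n_simulated_frames="):
                n_simulated = int(line.partition("=")[2])
            elif line.startswith("# group_colour\t"):
                parts = line.split("\t")[1:]
                group_colour = np.array([int(p) for p in parts], dtype=np.uint8)
            elif line.startswith("# region\t"):
                _, _, cx, cy, radius = line.split("\t")
                regions.append(GroupingRegion(centre=(float(cx), float(cy)), radius=float(radius)))
            elif line.startswith("#"):
                continue
            elif line.startswith("frame\t"):
                header_seen = True
            else:
                if not header_seen:
                    raise ValueError("data row before column header")
                parts = line.split("\t")
                if len(parts) != 8:
                    raise ValueError(f"expected 8 columns, got {len(parts)}")
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        int(parts[4]),
                        int(parts[5]),
                        int(parts[6]),
                        int(parts[7]),
                    )
                )
        except FrameDumpError:
            raise
        except ValueError as exc:
            raise FrameDumpError(f"line {lineno}: {exc}") from exc

    config = _parse_config(config_pairs, lineno=2)
    n_dots = config.n_dots
    if not rows or len(rows) % n_dots != 0:
        raise FrameDumpError(
            f"line {len(lines)}: row count {len(rows)} is not a multiple of n_dots={n_dots}"
        )
    n_frames = len(rows) // n_dots
    positions = np.empty((n_frames, n_dots, 2))
    colours = np.empty((n_frames, n_dots, 3), dtype=np.uint8)
    group_ids = np.empty((n_frames, n_dots), dtype=np.int64)
    for frame, dot, x, y, r, g, b, gid in rows:
        if not (0 <= frame < n_frames and 0 <= dot < n_dots):
            raise FrameDumpError(f"row with out-of-range indices frame={frame} dot={dot}")
        positions[frame, dot] = (x, y)
        colours[frame, dot] = (r, g, b)
        group_ids[frame, dot] = gid

    return StimulusSequence(
        config=config,
        positions=positions,
        colours=colours,
        group_ids=group_ids,
        regions=regions,
        group_colour=group_colour,
        group_displacements=None,
        n_simulated_frames=n_simulated,
    )
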