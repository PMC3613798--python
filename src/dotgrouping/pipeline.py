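"""End-to-end pipeline: stimuli -> synthetic BOLD -> GLM -> inference ->
behaviour/eye, driven by one YAML configuration and one root seed.

Every output is regenerable from config + seed alone; a JSON manifest
records per-file SHA-256 checksums, the derived stage seeds and the
package version, so identical configs yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import accuracy_rt_by_groups, gaze_grouping_correlation, session_validity
from .bold import (
    GroundTruth,
    ScanProtocol,
    default_ground_truth,
    simulate_cohort,
    simulate_gaze,
)
from .dataio import save_nifti, write_tsv
from .frameio import export_frames
from .glm import contrast_t, fit_subject, second_level
from .inference import cluster_inference, conjunction_by_masking
from .stimulus import SimConfig, generate_sequence

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

#: Stimulus categories generated in the stimulus stage (condition, n_groups).
STIMULUS_CATEGORIES = (
    ("moving_colour", 2),
    ("moving_colour", 0),
    ("moving_greyscale", 2),
    ("moving_greyscale", 0),
    ("static_colour", 0),
    ("static_greyscale", 0),
)


@dataclasses.dataclass
class PipelineConfig:
    """Nested pipeline options; section contents mirror the stage types."""

    seed: int = 0
    n_subjects: int = 4
    n_sessions: int = 2
    stimulus: dict = dataclasses.field(default_factory=dict)
    protocol: dict = dataclasses.field(default_factory=dict)
    truth: dict | None = None
    glm: dict = dataclasses.field(
        default_factory=lambda: {"highpass_cutoff_s": 120.0}
    )
    inference: dict = dataclasses.field(
        default_factory=lambda: {
            "voxel_p": 0.001,
            "cluster_alpha": 0.05,
            "n_perm": 200,
            "connectivity": 18,
        }
    )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown pipeline config sections: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage and write the manifest; returns the out dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    # --- stimuli ---------------------------------------------------------
    stim_dir = out / "stimuli"
    stim_dir.mkdir(exist_ok=True)
    stim_seed = _stage_seed(config.seed, "stimuli")
    categories = []
    for k, (condition, n_groups) in enumerate(STIMULUS_CATEGORIES):
        cfg = SimConfig(
            condition=condition,
            n_groups=n_groups,
            seed=stim_seed + k,
            **config.stimulus,
        )
        seq = generate_sequence(cfg)
        name = f"{condition}_{n_groups}groups.tsv"
        files.append(export_frames(seq, stim_dir / name))
        categories.append(name)
    manifest["stages"]["stimuli"] = {"seed": stim_seed, "categories": categories}

    # --- synthetic BOLD --------------------------------------------------
    bold_dir = out / "bold"
    bold_dir.mkdir(exist_ok=True)
    protocol = ScanProtocol(**config.protocol)
    truth = (
        default_ground_truth()
        if config.truth is None
        else GroundTruth(**config.truth)
    )
    bold_seed = _stage_seed(config.seed, "bold")
    cohort = simulate_cohort(
        n_subjects=config.n_subjects,
        protocol=protocol,
        truth=truth,
        seed=bold_seed,
        n_sessions=config.n_sessions,
    )
    gaze_rng = np.random.default_rng(_stage_seed(config.seed, "gaze"))
    gaze_tables = {}
    for subj in cohort:
        for sess in subj.sessions:
            stem = f"sub-{subj.subject_id:02d}_ses-{sess.session_id}"
            files.append(save_nifti(sess.volume4d(), bold_dir / f"{stem}_bold.nii"))
            files.append(write_tsv(sess.events, bold_dir / f"{stem}_events.tsv"))
            files.append(write_tsv(sess.nuisance, bold_dir / f"{stem}_nuisance.tsv"))
            gaze = simulate_gaze(sess.events, sess.data.shape[0] * sess.tr, gaze_rng)
            files.append(write_tsv(gaze, bold_dir / f"{stem}_gaze.tsv"))
            gaze_tables[(subj.subject_id, sess.session_id)] = gaze
    manifest["stages"]["bold"] = {"seed": bold_seed, "n_subjects": config.n_subjects}

    # --- GLM (both variants) + second level ------------------------------
    glm_dir = out / "glm"
    glm_dir.mkdir(exist_ok=True)
    cutoff = config.glm.get("highpass_cutoff_s", 120.0)
    subject_maps: dict[str, list[np.ndarray]] = {}
    for variant in ("six_condition", "four_condition_parametric"):
        for subj in cohort:
            result, contrasts = fit_subject(
                subj.sessions, variant=variant, highpass_cutoff_s=cutoff
            )
            for cname, weights in contrasts.items():
                smap = contrast_t(result, weights, shape=truth.shape)
                subject_maps.setdefault(cname, []).append(smap.effect)
    group_maps = {}
    for cname, maps in subject_maps.items():
        gmap = second_level(np.vstack(maps), shape=truth.shape)
        group_maps[cname] = gmap
        vol = np.where(gmap.defined, gmap.t, 0.0).reshape(truth.shape)
        files.append(save_nifti(vol[..., None], glm_dir / f"group_{cname}_t.nii"))
    manifest["stages"]["glm"] = {"contrasts": sorted(subject_maps)}

    # --- cluster inference on the parametric slopes -----------------------
    inf_dir = out / "inference"
    inf_dir.mkdir(exist_ok=True)
    inf_seed = _stage_seed(config.seed, "inference")
    cluster_tables = {}
    for cname in ("colour_slope", "motion_slope"):
        if cname not in subject_maps:
            continue
        res = cluster_inference(
            np.vstack(subject_maps[cname]),
            shape=truth.shape,
            voxel_p=config.inference.get("voxel_p", 0.001),
            cluster_alpha=config.inference.get("cluster_alpha", 0.05),
            n_perm=config.inference.get("n_perm", 200),
            connectivity=config.inference.get("connectivity", 18),
            seed=inf_seed,
        )
        files.append(write_tsv(res.table, inf_dir / f"clusters_{cname}.tsv"))
        cluster_tables[cname] = int(len(res.table))
    manifest["stages"]["inference"] = {"seed": inf_seed, "clusters": cluster_tables}

    # --- conjunction of the two slopes ------------------------------------
    if "colour_slope" in group_maps and "motion_slope" in group_maps:
        conj = conjunction_by_masking(
            group_maps["colour_slope"], group_maps["motion_slope"]
        )
        conj_df = pd.DataFrame(conj.overlap_indices, columns=["x", "y", "z"])
        files.append(write_tsv(conj_df, inf_dir / "conjunction_voxels.tsv"))
        manifest["stages"]["conjunction"] = {"n_overlap": conj.n_overlap}

    # --- behaviour / eye ---------------------------------------------------
    beh_dir = out / "behaviour"
    beh_dir.mkdir(exist_ok=True)
    all_events = []
    for subj in cohort:
        for sess in subj.sessions:
            ev = sess.events.copy()
            ev["subject"] = subj.subject_id
            all_events.append(ev)
    responses = pd.concat(all_events, ignore_index=True)
    acc = accuracy_rt_by_groups(responses)
    files.append(write_tsv(acc.summary.reset_index(), beh_dir / "accuracy_rt.tsv"))
    eye_rows = []
    for (sid, sess_id), gaze in gaze_tables.items():
        validity = session_validity(gaze["valid"].to_numpy())
        row = {
            "subject": sid,
            "session": sess_id,
            "fraction_valid": validity.fraction_valid,
            "keep": validity.keep,
            "r": np.nan,
        }
        if validity.keep:
            events = next(
                s.events
                for subj in cohort
                if subj.subject_id == sid
                for s in subj.sessions
                if s.session_id == sess_id
            )
            corr = gaze_grouping_correlation(gaze, events)
            row["r"] = corr.r if corr.defined else np.nan
        eye_rows.append(row)
    files.append(write_tsv(pd.DataFrame(eye_rows), beh_dir / "eye_summary.tsv"))
    manifest["stages"]["behaviour"] = {
        "n_sessions_kept": int(sum(r["keep"] for r in eye_rows))
    }

    manifest["checksums"] = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(files)
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
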