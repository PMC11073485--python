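"""End-to-end pipeline stages: synthesize, extract, screen.

Each stage is a pure function of (inputs, config, seed): re-running with
the same configuration produces byte-identical outputs.  Subjects whose
recordings yield no usable cycles are excluded with machine-parsable
reason codes, mirroring a screening study's enrollment attrition.

Configuration is one YAML document with a block per stage::

    seed: 7
    cohort:   {n: 50, prevalence: 0.32, ...}
    segmentation: {hr_min: 40, hr_max: 220, ...}
    if_fit:   {omega1_range: [40, 300], omega2_range: [20, 200], ...}
    features: {phi_circular: false}
    screening: {predictors: [omega1_bpm, omegai1], fixed_trees: [A, B]}
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import if_core, screening, synthetic, waveform_io

log = logging.getLogger(__name__)


def _version() -> str:
    from ifscreen import __version__
    return __version__

# exclusion reason codes
REASON_NO_BEATS = "no_beats_detected"
REASON_NO_CYCLES = "no_valid_cycles"
REASON_ALL_FITS_FAILED = "all_fits_failed"


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a configuration mapping (canonical JSON)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _manifest(config: Mapping[str, Any], seed: int) -> dict:
    return {"config_hash": config_hash(config), "seed": int(seed),
            "package_version": _version()}


def _cohort_config(config: Mapping[str, Any], seed: int | None = None) -> synthetic.CohortConfig:
    block = dict(config.get("cohort", {}))
    if seed is not None:
        block["seed"] = int(seed)
    for key in ("age_group_weights", "hr_means", "omega2_range"):
        if key in block:
            block[key] = tuple(block[key])
    return synthetic.CohortConfig(**block)


def _fit_config(config: Mapping[str, Any]) -> if_core.FitConfig:
    block = dict(config.get("if_fit", {}))
    for key in ("omega1_range", "omega2_range"):
        if key in block:
            block[key] = tuple(block[key])
    return if_core.FitConfig(**block)


def _seg_config(config: Mapping[str, Any]) -> waveform_io.SegmentationConfig:
    block = dict(config.get("segmentation", {}))
    if "notch_window" in block:
        block["notch_window"] = tuple(block["notch_window"])
    return waveform_io.SegmentationConfig(**block)


def run_synth(config: Mapping[str, Any], outdir: str | Path, seed: int | None = None) -> Path:
    """Generate a cohort and write recordings, truth table and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = _cohort_config(config, seed)
    recordings, truths = synthetic.gen_cohort(cfg)
    wavedir = outdir / "waveforms"
    wavedir.mkdir(exist_ok=True)
    for w in recordings:
        waveform_io.write_waveform(w, wavedir / f"{w.subject_id}.csv")
    table = synthetic.truth_table(truths)
    table.to_csv(outdir / "truth.csv", index=False, float_format="%.12g")
    manifest = _manifest(dict(config), cfg.seed)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    log.info("wrote %d recordings to %s", len(recordings), wavedir)
    return outdir


def extract_subject(
    w: waveform_io.Waveform,
    age: float,
    lvef: float,
    seg_cfg: waveform_io.SegmentationConfig,
    fit_cfg: if_core.FitConfig,
    phi_circular: bool = False,
) -> feat.SubjectFeatures | None:
    """Segment -> select -> fit -> aggregate for one subject.

    Returns ``None`` (with a logged reason code) when the recording
    yields nothing usable.
    """
    onsets = waveform_io.detect_beats(w, seg_cfg)
    if onsets.size < 2:
        log.warning("exclude subject=%s reason=%s", w.subject_id, REASON_NO_BEATS)
        return None
    cycles = waveform_io.segment_cycles(w, onsets, seg_cfg)
    if not cycles:
        log.warning("exclude subject=%s reason=%s", w.subject_id, REASON_NO_CYCLES)
        return None
    selection = waveform_io.select_cycles(cycles)
    cycle_feats = []
    for c in selection.cycles:
        try:
            fit = if_core.fit_if(c, fit_cfg)
        except RuntimeError:
            continue
        cycle_feats.append(feat.cycle_features(fit, c))
    if not cycle_feats:
        log.warning("exclude subject=%s reason=%s", w.subject_id, REASON_ALL_FITS_FAILED)
        return None
    return feat.aggregate_subject(
        cycle_feats, w.subject_id, age, lvef,
        phi_circular=phi_circular, insufficient=selection.insufficient,
    )


def run_extract(config: Mapping[str, Any], datadir: str | Path, outdir: str | Path) -> Path:
    """Build the per-subject feature table from recordings + metadata.

    ``datadir`` must contain ``waveforms/<subject_id>.csv`` and a
    metadata table ``truth.csv`` with at least subject_id, age, lvef.
    """
    datadir, outdir = Path(datadir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(datadir / "truth.csv")
    seg_cfg = _seg_config(config)
    fit_cfg = _fit_config(config)
    phi_circ = bool(config.get("features", {}).get("phi_circular", False))
    subjects, excluded = [], []
    for row in meta.itertuples(index=False):
        path = datadir / "waveforms" / f"{row.subject_id}.csv"
        w = waveform_io.read_waveform(path, str(row.subject_id))
        s = extract_subject(w, row.age, row.lvef, seg_cfg, fit_cfg, phi_circ)
        if s is None:
            excluded.append(str(row.subject_id))
        else:
            subjects.append(s)
    table = feat.features_table(subjects)
    table.to_csv(outdir / "features.csv", index=False, float_format="%.12g")
    (outdir / "exclusions.json").write_text(json.dumps(excluded, indent=1) + "\n")
    seed = int(config.get("seed", 0))
    (outdir / "manifest.json").write_text(json.dumps(_manifest(dict(config), seed), indent=1) + "\n")
    return outdir


def _subjects_from_table(df: pd.DataFrame) -> list[feat.SubjectFeatures]:
    subjects = []
    for row in df.itertuples(index=False):
        subjects.append(feat.SubjectFeatures(
            subject_id=str(row.subject_id), age=float(row.age), lvef=float(row.lvef),
            label=bool(row.label), omega1_bpm=float(row.omega1_bpm), phi1=float(row.phi1),
            HR=float(row.HR), omegai1=float(row.omegai1), omega2_bpm=float(row.omega2_bpm),
            phi2=float(row.phi2), Rs=float(row.Rs), Rd=float(row.Rd),
            n_cycles=int(row.n_cycles), age_group=feat.age_group(float(row.age)),
        ))
    return subjects


def run_screen(config: Mapping[str, Any], features_csv: str | Path, outdir: str | Path) -> dict:
    """Classify and evaluate; writes report JSON and ROC CSV.

    Fixed published rules always run; CART training + LOOCV runs when
    both classes are present (otherwise it is skipped with a warning).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.read_csv(features_csv)
    subjects = _subjects_from_table(df)
    block = config.get("screening", {})
    predictors = list(block.get("predictors", ["omega1_bpm", "omegai1"]))
    report: dict[str, Any] = {"n_subjects": len(subjects)}

    fixed: dict[str, Any] = {}
    for s in subjects:
        la, _ = screening.classify_fixed_tree_A(s.omega1_bpm, s.age, s.phi1)
        lb, _ = screening.classify_fixed_tree_B(s.omega1_bpm, s.omegai1)
        fixed[s.subject_id] = {"tree_A": bool(la), "tree_B": bool(lb)}
    report["fixed_trees"] = fixed

    labels = {s.label for s in subjects}
    if len(labels) == 2:
        loocv_report = screening.evaluate_loocv(subjects, predictors)
        report["loocv"] = loocv_report.to_dict()
        tree = screening.train_cart(subjects, predictors)
        report["trained_tree"] = json.loads(tree.to_json())
        (outdir / "roc.csv").write_text(
            "fpr,tpr,threshold\n" + "\n".join(
                f"{fpr:.10g},{tpr:.10g},{'' if not np.isfinite(thr) else f'{thr:.10g}'}"
                for fpr, tpr, thr in loocv_report.roc_points
            ) + "\n"
        )
    else:
        log.warning("single-class feature table: CART training and ROC skipped")
        report["loocv"] = None
    seed = int(config.get("seed", 0))
    report["manifest"] = _manifest(dict(config), seed)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report


def run_all(config: Mapping[str, Any], outdir: str | Path, seed: int | None = None) -> dict:
    """synth -> extract -> screen in one call."""
    outdir = Path(outdir)
    run_synth(config, outdir, seed)
    run_extract(config, outdir, outdir)
    return run_screen(config, outdir / "features.csv", outdir)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg
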