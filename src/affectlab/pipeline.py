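"""End-to-end orchestration: signals -> features -> fusion -> models -> reports.

`extract_features` turns one study's recordings into the 206-column stimulus
record table; `run_all` evaluates the four emotion models (arousal/valence in
the real and virtual museum, each over analysis cases 1-3) plus the
real-vs-virtual classifier, and writes report CSVs with a provenance log.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, eeg_features, eeg_preprocess, fusion, hrv, synthetic

__all__ = ["PipelineConfig", "extract_features", "run_all"]


@dataclass
class PipelineConfig:
    """All tunable analysis settings in one auditable place."""

    seed: int = 0
    n_subjects_per_phase: int = 6
    fs: float = 256.0
    stages: tuple[str, ...] = ("iaps", "rooms360", "museum")
    iaps_block_duration: float = 10.0
    museum_duration: float = 60.0
    n_iaps_blocks: int = 13
    effect_scale: float = 1.0
    # HRV
    detrend_lambda: float = 500.0
    ectopic_threshold: float = 0.25
    hf_band_conventional: bool = False
    # EEG
    ica_mode: str = "none"            # none | auto | manual
    amp_threshold_uv: float = 100.0
    grad_threshold_uv: float = 70.0
    kurtosis_z: float = 5.0
    channel_qc: bool = True
    # classifier
    pca_variance: float = 0.95
    grid_n: int = 15
    grid_lo: float = 0.1
    grid_hi: float = 1000.0
    balance_min: float = 60.0
    feature_selection: bool = True
    corr_threshold: float = 0.85
    cases: tuple[int, ...] = (1, 2, 3)

    def grid(self) -> np.ndarray:
        return classify.make_grid(self.grid_n, self.grid_lo, self.grid_hi)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(_as_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "cases"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_as_plain(asdict(self)), fh, sort_keys=True)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _preprocess_eeg(raw: eeg_preprocess.RawEEG,
                    cfg: PipelineConfig, log: dict) -> eeg_preprocess.EpochedEEG | None:
    if cfg.channel_qc and raw.duration >= 60.0:
        bad, verdict = eeg_preprocess.detect_bad_channels(raw, cfg.kurtosis_z)
        log["bad_channels"] = bad
        if verdict == "reject-subject":
            return None
        if verdict == "interpolate":
            raw = eeg_preprocess.interpolate_channel(raw, bad[0], tuple(bad))
    raw = eeg_preprocess.filter_and_center(raw)
    ep = eeg_preprocess.epoch(raw)
    ep = eeg_preprocess.reject_artifact_epochs(
        ep, cfg.amp_threshold_uv, cfg.grad_threshold_uv)
    if ep.rejection_log.get("subject_rejected"):
        return None
    if cfg.ica_mode != "none" and ep.valid_mask.sum() >= 9 * ep.epochs.shape[0]:
        ep = eeg_preprocess.ica_clean(ep, mode=cfg.ica_mode)
    return ep


def extract_features(study: synthetic.SyntheticStudy,
                     cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-stimulus 206-feature records for every usable subject-stage.

    Rejected subjects/stages and windows without valid epochs are dropped
    with a log entry (`df.attrs["log"]`), never silently.
    """
    cfg = cfg or PipelineConfig()
    hf_band = (hrv.HF_BAND_CONVENTIONAL if cfg.hf_band_conventional
               else hrv.HF_BAND)
    rows = []
    log: dict[str, list] = {"rejected_stages": [], "dropped_stimuli": []}
    sam_idx = study.sam.set_index(["subject_id", "stimulus_id"])
    for rec in study.recordings:
        stage_log: dict = {}
        ep = _preprocess_eeg(rec.eeg, cfg, stage_log)
        if ep is None:
            log["rejected_stages"].append((rec.subject_id, rec.stage))
            continue
        try:
            rr = hrv.detect_r_peaks(rec.ecg, rec.fs)
            rr = hrv.correct_ectopics(rr, cfg.ectopic_threshold)
        except (hrv.DetectionError, RuntimeError, ValueError):
            log["rejected_stages"].append((rec.subject_id, rec.stage))
            continue
        ev = study.events
        ev = ev[(ev["subject_id"] == rec.subject_id) & (ev["stage"] == rec.stage)]
        for _, event in ev.iterrows():
            window = (event["onset_s"], event["onset_s"] + event["duration_s"])
            eeg_feats = eeg_features.aggregate_stimulus(ep, window)
            if eeg_feats is None:
                log["dropped_stimuli"].append(
                    (rec.subject_id, event["stimulus_id"], "no valid epochs"))
                continue
            rr_win = rr.window(*window)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                hrv_feats = hrv.hrv_features(rr_win, lam=cfg.detrend_lambda,
                                             hf_band=hf_band)
            key = (rec.subject_id, event["stimulus_id"])
            arousal, valence = sam_idx.loc[key, ["arousal", "valence"]]
            row = {"subject_id": rec.subject_id, "stage": rec.stage,
                   "condition": rec.condition,
                   "stimulus_id": event["stimulus_id"],
                   "arousal": float(arousal), "valence": float(valence)}
            row.update({f"hrv_{k}": v for k, v in hrv_feats.items()})
            row.update(eeg_feats)
            rows.append(row)
    df = pd.DataFrame(rows, columns=fusion.META_COLUMNS + fusion.feature_columns())
    df.attrs["log"] = log
    return df


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig, outdir=None,
            study: synthetic.SyntheticStudy | None = None) -> dict:
    """Run the whole analysis and return (optionally write) all reports.

    Returns ``{"records", "psychometrics", "models", "nature", "tables"}``:
    four emotion model groups (target x condition, cases per config) plus the
    real-vs-virtual model, each as an :class:`~affectlab.classify.EvaluationReport`.
    """
    if study is None:
        scfg = synthetic.StudyConfig(
            n_subjects_per_phase=cfg.n_subjects_per_phase, fs=cfg.fs,
            stages=tuple(cfg.stages), n_iaps_blocks=cfg.n_iaps_blocks,
            iaps_block_duration=cfg.iaps_block_duration,
            museum_duration=cfg.museum_duration, ica_mode=cfg.ica_mode)
        effects = synthetic.EffectModel().scaled(cfg.effect_scale)
        study = synthetic.generate_study(cfg.n_subjects_per_phase, effects,
                                         seed=cfg.seed, config=scfg)
    records = extract_features(study, cfg)
    psych = fusion.compare_conditions(
        study.sam[study.sam["stage"] == "museum"])

    grid = cfg.grid()
    models: dict[tuple[str, str], list[classify.EvaluationReport]] = {}
    for target in ("arousal", "valence"):
        for condition in ("real", "virtual"):
            reports = []
            for case in cfg.cases:
                if case != 1 and _CASE_STAGE[case] not in set(records["stage"]):
                    continue
                ds = fusion.build_case(records, case, target, condition)
                reports.append(classify.loso_evaluate(
                    ds, grid=grid, var_target=cfg.pca_variance,
                    balance_min=cfg.balance_min,
                    feature_selection=cfg.feature_selection,
                    corr_threshold=cfg.corr_threshold))
            models[(target, condition)] = reports
    nature = classify.classify_nature(
        records, grid=grid, var_target=cfg.pca_variance,
        balance_min=cfg.balance_min, feature_selection=cfg.feature_selection,
        corr_threshold=cfg.corr_threshold)

    tables = {f"{t}_{c}": classify.report(reps)
              for (t, c), reps in models.items()}
    tables["nature"] = classify.report([nature])

    result = {"records": records, "psychometrics": psych, "models": models,
              "nature": nature, "tables": tables,
              "config_hash": cfg.config_hash()}
    if outdir is not None:
        _write_outputs(result, cfg, Path(outdir))
    return result


_CASE_STAGE = {2: "iaps", 3: "rooms360"}


def _write_outputs(result: dict, cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    h = result["config_hash"]
    result["records"].to_csv(out / f"records_{h}.csv", index=False)
    result["psychometrics"].to_csv(out / f"psychometrics_{h}.csv", index=False)
    for name, table in result["tables"].items():
        table.to_csv(out / f"report_{name}_{h}.csv", index=False)
    preds = []
    for (t, c), reps in result["models"].items():
        for r in reps:
            p = r.predictions.copy()
            p["model"], p["case"] = f"{t}_{c}", r.case
            preds.append(p)
    p = result["nature"].predictions.copy()
    p["model"], p["case"] = "nature", 1
    preds.append(p)
    pd.concat(preds, ignore_index=True).to_csv(
        out / f"predictions_{h}.csv", index=False)
    prov = {"config_hash": h, "seed": cfg.seed,
            "config": _as_plain(asdict(cfg))}
    with open(out / f"provenance_{h}.json", "w") as fh:
        json.dump(prov, fh, indent=2)
    cfg.to_yaml(out / f"config_{h}.yaml")
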