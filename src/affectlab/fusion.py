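"""Stimulus-record assembly, psychometric screening and analysis-case datasets.

Each stimulus record carries 206 features in three tagged blocks -- HRV (26),
band power (36) and MPC connectivity (144) -- plus its SAM arousal/valence
labels in [-4, 4] and study metadata.  Three analysis cases are supported:

* Case 1: museum stimuli only;
* Case 2: museum + 2D affective picture (IAPS) stimuli;
* Case 3: museum + 360-degree emotional-room stimuli.

Validation rows are always museum stimuli; calibration-stage rows are
training-only extras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .eeg_features import band_power_names, mpc_names
from .hrv import HRV_FEATURE_NAMES

__all__ = [
    "META_COLUMNS",
    "BLOCKS",
    "CaseDataset",
    "feature_columns",
    "block_of",
    "bipolarize",
    "screen_outliers",
    "compare_conditions",
    "build_case",
]

META_COLUMNS = ["subject_id", "stage", "condition", "stimulus_id",
                "arousal", "valence"]

#: Ordered feature blocks: name -> column list (26 / 36 / 144).
BLOCKS: dict[str, list[str]] = {
    "HRV": [f"hrv_{name}" for name in HRV_FEATURE_NAMES],
    "BAND": band_power_names(),
    "MPC": mpc_names(),
}


def feature_columns() -> list[str]:
    """All 206 feature columns in canonical block order."""
    return BLOCKS["HRV"] + BLOCKS["BAND"] + BLOCKS["MPC"]


def block_of(column: str) -> str:
    """Block tag (HRV | BAND | MPC) of a feature column."""
    if column.startswith("hrv_"):
        return "HRV"
    if column.startswith("bp_"):
        return "BAND"
    if column.startswith("mpc_"):
        return "MPC"
    raise ValueError(f"not a feature column: {column!r}")


# ---------------------------------------------------------------------------
# Psychometrics
# ---------------------------------------------------------------------------

def bipolarize(score):
    """Threshold an affect score: > 0 -> ``"high"``, <= 0 -> ``"low"``."""
    arr = np.asarray(score, dtype=float)
    out = np.where(arr > 0, "high", "low")
    return out.item() if np.isscalar(score) or arr.ndim == 0 else out


def screen_outliers(sam_scores: pd.DataFrame, norms: pd.DataFrame,
                    z_limit: float = 2.58) -> tuple[list[str], list[str], pd.DataFrame]:
    """Z-score subjects' picture ratings against published norms.

    ``sam_scores`` columns: subject_id, picture_id, arousal, valence.
    ``norms`` columns: picture_id, arousal_mean, arousal_sd, valence_mean,
    valence_sd.  A subject is excluded when any |z| strictly exceeds
    ``z_limit`` (evaluations exactly on the boundary are kept).  Returns
    (kept_subjects, excluded_subjects, z_table).
    """
    missing = set(sam_scores["picture_id"]) - set(norms["picture_id"])
    if missing:
        raise ValueError(f"no norms for pictures: {sorted(missing)}")
    merged = sam_scores.merge(norms, on="picture_id", how="left")
    for dim in ("arousal", "valence"):
        sd = merged[f"{dim}_sd"]
        if (sd <= 0).any():
            raise ValueError(f"non-positive norm SD for {dim}")
        merged[f"z_{dim}"] = (merged[dim] - merged[f"{dim}_mean"]) / sd
    z = merged[["subject_id", "picture_id", "z_arousal", "z_valence"]]
    outlier = (z[["z_arousal", "z_valence"]].abs() > z_limit).any(axis=1)
    excluded = sorted(z.loc[outlier, "subject_id"].unique())
    kept = sorted(set(z["subject_id"]) - set(excluded))
    return kept, excluded, z


def compare_conditions(museum_sam: pd.DataFrame,
                       alpha: float = 0.05,
                       alpha_lenient: float = 0.10) -> pd.DataFrame:
    """Real-vs-virtual comparison of museum SAM scores, per stimulus/dimension.

    Normality is probed per group with Shapiro-Wilk; group location is
    compared with the two-sided Mann-Whitney U test.  Also reports the
    proportion of bipolarized high/positive ratings per condition.
    Degenerate (all-tied) groups are marked not applicable.
    """
    rows = []
    for stim, g in museum_sam.groupby("stimulus_id"):
        for dim in ("arousal", "valence"):
            real = g.loc[g["condition"] == "real", dim].to_numpy(dtype=float)
            virt = g.loc[g["condition"] == "virtual", dim].to_numpy(dtype=float)
            row = {"stimulus_id": stim, "dimension": dim,
                   "n_real": len(real), "n_virtual": len(virt),
                   "prop_high_real": float(np.mean(real > 0)) if len(real) else np.nan,
                   "prop_high_virtual": float(np.mean(virt > 0)) if len(virt) else np.nan}
            applicable = (len(real) >= 3 and len(virt) >= 3
                          and (np.ptp(real) > 0 or np.ptp(virt) > 0))
            row["applicable"] = applicable
            if applicable:
                row["shapiro_p_real"] = (float(stats.shapiro(real).pvalue)
                                         if np.ptp(real) > 0 else np.nan)
                row["shapiro_p_virtual"] = (float(stats.shapiro(virt).pvalue)
                                            if np.ptp(virt) > 0 else np.nan)
                u = stats.mannwhitneyu(real, virt, alternative="two-sided")
                row["u_stat"] = float(u.statistic)
                row["p_value"] = float(u.pvalue)
                row["significant_05"] = bool(u.pvalue < alpha)
                row["significant_10"] = bool(u.pvalue < alpha_lenient)
            else:
                row.update({"shapiro_p_real": np.nan, "shapiro_p_virtual": np.nan,
                            "u_stat": np.nan, "p_value": np.nan,
                            "significant_05": False, "significant_10": False})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Case datasets
# ---------------------------------------------------------------------------

_CASE_EXTRA_STAGE = {1: None, 2: "iaps", 3: "rooms360"}


@dataclass
class CaseDataset:
    """Labeled analysis dataset for one case and target."""

    case: int
    target: str                       # "arousal" | "valence" | "nature"
    df: pd.DataFrame                  # records + 'role' + 'label' columns

    @property
    def museum(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "museum"]

    @property
    def subjects(self) -> list[str]:
        return sorted(self.museum["subject_id"].unique())


def build_case(records: pd.DataFrame, case: int, target: str,
               condition: str | None = None) -> CaseDataset:
    """Assemble a :class:`CaseDataset` from a stimulus-record table.

    For emotion targets (``arousal``/``valence``) records are restricted to
    one phase's ``condition`` and labels are the bipolarized SAM scores; for
    ``target="nature"`` records are the museum stimuli of both phases and
    labels are the condition itself.
    """
    if case not in _CASE_EXTRA_STAGE:
        raise ValueError("case must be 1, 2 or 3")
    if target not in ("arousal", "valence", "nature"):
        raise ValueError("target must be arousal, valence or nature")

    if target == "nature":
        df = records[records["stage"] == "museum"].copy()
        df["role"] = "museum"
        df["label"] = df["condition"].to_numpy()
    else:
        if condition is None:
            raise ValueError("emotion targets need a condition (real|virtual)")
        sub = records[records["condition"] == condition]
        museum = sub[sub["stage"] == "museum"].copy()
        museum["role"] = "museum"
        parts = [museum]
        extra_stage = _CASE_EXTRA_STAGE[case]
        if extra_stage is not None:
            extra = sub[sub["stage"] == extra_stage].copy()
            extra["role"] = "train-extra"
            parts.append(extra)
        df = pd.concat(parts, ignore_index=True)
        df["label"] = bipolarize(df[target].to_numpy())
    if (df["role"] == "museum").sum() == 0:
        raise ValueError("empty validation set: no museum records")
    return CaseDataset(case=case, target=target, df=df.reset_index(drop=True))
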