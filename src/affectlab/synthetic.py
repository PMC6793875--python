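"""Synthetic two-phase museum study: ECG + 9-channel EEG with known structure.

The generator emulates the experiment the analysis chain expects: two cohorts
(one exploring a real museum, one its immersive-virtual twin), each subject
recorded through up to three stages -- 2D affective picture blocks, four 90-s
360-degree emotional rooms, and eight museum stimuli (five rooms plus three
artworks) -- with a 1-lead ECG and nine EEG channels at a nominal 256 Hz.

Label-dependent physiological structure is injected through an
:class:`EffectModel`: arousal modulates mean RR, the LF/HF balance, beta and
gamma band power, and inter-channel phase coupling; valence modulates frontal
alpha asymmetry (F4 vs F3); the real-vs-virtual condition shifts phase
coupling globally.  A zero effect model produces signals independent of the
labels, which downstream classifiers must read as chance.

All generators are deterministic in their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_preprocess import MONTAGE, RawEEG
from .hrv import RRSeries

__all__ = [
    "SubjectSpec",
    "StimulusSpec",
    "EffectModel",
    "StudyConfig",
    "StageRecording",
    "SyntheticStudy",
    "generate_rr_series",
    "render_ecg",
    "generate_eeg",
    "generate_study",
]

LF_FREQ = 0.10   # Hz, centre of the LF band
HF_FREQ = 0.25   # Hz, centre of the HF band


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectSpec:
    """Stable per-subject physiology and identity."""

    subject_id: str
    condition: str                    # "real" | "virtual"
    baseline_mean_rr: float = 900.0   # ms
    baseline_sdnn: float = 50.0       # ms
    baseline_lf_hf: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 600.0 <= self.baseline_mean_rr <= 1200.0:
            raise ValueError("baseline_mean_rr must lie in [600, 1200] ms")
        if self.condition not in ("real", "virtual"):
            raise ValueError("condition must be 'real' or 'virtual'")


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus presentation with its design labels."""

    stimulus_id: str
    stage: str                        # "iaps" | "rooms360" | "museum"
    onset: float                      # s
    duration: float                   # s
    arousal_label: float              # [-4, 4]
    valence_label: float              # [-4, 4]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        for v in (self.arousal_label, self.valence_label):
            if not -4.0 <= v <= 4.0:
                raise ValueError("labels must lie in [-4, 4]")


@dataclass(frozen=True)
class EffectModel:
    """Per-label-unit physiological effects injected by the generator.

    Units: mean RR in ms per arousal unit; LF/HF in ratio units per arousal
    unit; band powers in dB per label unit; coupling in MPC units per arousal
    unit and as a global real-vs-virtual offset.
    """

    arousal_mean_rr: float = -15.0
    arousal_lf_hf: float = 0.15
    arousal_beta_gamma_db: float = 0.75
    arousal_coupling: float = 0.06
    valence_frontal_alpha_db: float = 0.6
    condition_coupling: float = 0.15     # added for the virtual condition
    eeg_noise_db: float = 0.0            # extra broadband noise floor, dB
    ecg_noise_sd: float = 0.0            # mV

    @classmethod
    def zero(cls) -> "EffectModel":
        """Null world: labels carry no physiological information."""
        return cls(arousal_mean_rr=0.0, arousal_lf_hf=0.0,
                   arousal_beta_gamma_db=0.0, arousal_coupling=0.0,
                   valence_frontal_alpha_db=0.0, condition_coupling=0.0)

    def scaled(self, factor: float) -> "EffectModel":
        """Uniformly scale all label effects (for dose-response checks)."""
        return replace(self,
                       arousal_mean_rr=self.arousal_mean_rr * factor,
                       arousal_lf_hf=self.arousal_lf_hf * factor,
                       arousal_beta_gamma_db=self.arousal_beta_gamma_db * factor,
                       arousal_coupling=self.arousal_coupling * factor,
                       valence_frontal_alpha_db=self.valence_frontal_alpha_db * factor,
                       condition_coupling=self.condition_coupling * factor)


#: Baseline EEG band powers, dB re 1 uV^2 (alpha-dominant resting profile).
BASE_BAND_DB = {"theta": 10.0, "alpha": 12.0, "beta": 9.0, "gamma": 7.0}
#: Baseline inter-channel phase coupling per band.
BASE_COUPLING = 0.30

#: Design labels for the four 360-degree emotional rooms (arousal, valence).
ROOM_DESIGN = {
    "room360_1": (1.2, -1.1),
    "room360_2": (2.1, 1.5),
    "room360_3": (0.0, -0.4),
    "room360_4": (-0.6, 2.6),
}

#: Design labels for the eight museum stimuli: five rooms + three artworks.
MUSEUM_DESIGN = {
    "mus_room1": (1.5, -1.5),
    "mus_room2": (2.5, 1.5),
    "mus_room3": (-1.5, -0.5),
    "mus_room4": (-1.0, 2.5),
    "mus_room5": (3.0, -2.5),
    "mus_art1": (2.0, -1.0),
    "mus_art2": (-0.5, 2.0),
    "mus_art3": (-1.0, 0.5),
}


@dataclass(frozen=True)
class StudyConfig:
    """Shape of the generated study (cohort sizes, schedules, noise)."""

    n_subjects_per_phase: int = 30
    fs: float = 256.0
    stages: tuple[str, ...] = ("iaps", "rooms360", "museum")
    n_iaps_blocks: int = 13              # 1 neutral + 12 affective blocks
    iaps_block_duration: float = 10.0    # s (one 10-s picture block)
    room_duration: float = 90.0          # s, fixed by design (1.5 min per room)
    museum_duration: float = 60.0        # s per museum room / artwork
    sam_noise_sd: float = 0.8            # subject scatter around design labels
    condition_sam_offset: float = 0.3    # virtual condition rates slightly higher
    ica_mode: str = "none"

    def __post_init__(self) -> None:
        if self.n_subjects_per_phase < 2:
            raise ValueError("need at least 2 subjects per phase")
        unknown = set(self.stages) - {"iaps", "rooms360", "museum"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


@dataclass
class StageRecording:
    """One subject-stage recording: ECG trace plus raw EEG."""

    subject_id: str
    stage: str
    condition: str
    ecg: np.ndarray
    eeg: RawEEG
    fs: float


@dataclass
class SyntheticStudy:
    """Recordings + event annotations + SAM tables for a whole study."""

    recordings: list[StageRecording]
    events: pd.DataFrame
    sam: pd.DataFrame
    subjects: list[SubjectSpec]
    config: StudyConfig
    effects: EffectModel

    def recording(self, subject_id: str, stage: str) -> StageRecording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.stage == stage:
                return rec
        raise KeyError(f"no recording for {subject_id}/{stage}")


# ---------------------------------------------------------------------------
# RR / ECG generation
# ---------------------------------------------------------------------------

def generate_rr_series(mean_rr: float, sdnn: float, lf_hf: float,
                       n_beats: int, seed: int | np.random.Generator = 0,
                       modulation_fraction: float = 0.9) -> RRSeries:
    """RR series with sinusoidal LF (0.10 Hz) and HF (0.25 Hz) modulation.

    ``RR(t) = mean_rr + a_LF sin(2 pi 0.10 t + p1) + a_HF sin(2 pi 0.25 t + p2)
    + noise`` where the sinusoid amplitudes satisfy ``a_LF^2 / a_HF^2 = lf_hf``
    and the modulation carries ``modulation_fraction`` of the total variance
    ``sdnn^2`` (white per-beat noise carries the rest).  The default keeps the
    broadband share small so the spectral LF/HF of the generated tachogram
    tracks the requested ratio instead of being diluted toward 1.
    """
    if mean_rr <= 0:
        raise ValueError("mean_rr must be positive")
    if sdnn < 0 or lf_hf <= 0:
        raise ValueError("sdnn must be >= 0 and lf_hf > 0")
    if n_beats < 16:
        raise ValueError("need at least 16 beats")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if sdnn == 0:
        return RRSeries.from_intervals(np.full(n_beats, mean_rr))

    mod_var = modulation_fraction * sdnn ** 2
    a_hf = np.sqrt(2.0 * mod_var / (1.0 + lf_hf))
    a_lf = np.sqrt(lf_hf) * a_hf
    noise_sd = np.sqrt((1.0 - modulation_fraction)) * sdnn
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)

    intervals = np.empty(n_beats)
    t = 0.0
    for i in range(n_beats):
        rr = (mean_rr
              + a_lf * np.sin(2 * np.pi * LF_FREQ * t + p1)
              + a_hf * np.sin(2 * np.pi * HF_FREQ * t + p2)
              + noise_sd * rng.standard_normal())
        rr = max(rr, 0.3 * mean_rr)   # physiological floor
        intervals[i] = rr
        t += rr / 1000.0
    return RRSeries.from_intervals(intervals)


#: Stylized PQRST template: (time offset s, amplitude mV, Gaussian sigma s).
_ECG_WAVES = (
    (-0.200, 0.12, 0.025),   # P
    (-0.028, -0.10, 0.010),  # Q
    (0.000, 1.00, 0.010),    # R
    (0.030, -0.18, 0.010),   # S
    (0.260, 0.30, 0.045),    # T
)


def render_ecg(rr: RRSeries, fs: float, noise_sd: float = 0.0,
               baseline_wander: float = 0.0,
               seed: int | np.random.Generator = 0) -> np.ndarray:
    """Template PQRST waveform with R peaks at the RR-series beat times (mV)."""
    if fs < 128:
        raise ValueError("sampling rate must be >= 128 Hz")
    if len(rr.beat_times) == 0 or rr.duration == 0:
        raise ValueError("empty RR series cannot be rendered")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t_end = rr.beat_times[-1] + 0.4
    n = int(np.ceil(t_end * fs))
    t0 = rr.beat_times[0]
    out = np.zeros(n)
    for b in rr.beat_times:
        for off, amp, sig in _ECG_WAVES:
            c = b + off
            lo = max(int((c - 4 * sig) * fs), 0)
            hi = min(int((c + 4 * sig) * fs) + 1, n)
            if hi <= lo:
                continue
            tt = np.arange(lo, hi) / fs
            out[lo:hi] += amp * np.exp(-0.5 * ((tt - c) / sig) ** 2)
    if baseline_wander > 0:
        tt = np.arange(n) / fs
        ph = rng.uniform(0, 2 * np.pi)
        out += baseline_wander * np.sin(2 * np.pi * 0.25 * tt + ph)
    if noise_sd > 0:
        out += noise_sd * rng.standard_normal(n)
    return out


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

_BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0),
               "beta": (13.0, 25.0), "gamma": (25.0, 40.0)}


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise.

    Band limiting uses a frequency-domain brick wall with the same band
    edges (and convention) as the feature extractor, so generated bands do
    not leak into each other's analysis masks.
    """
    spec = np.fft.fft(rng.standard_normal(n))
    freqs = np.abs(np.fft.fftfreq(n, d=1.0 / fs))
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    x = np.fft.ifft(spec).real
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_eeg(montage: tuple[str, ...], fs: float, duration: float,
                 band_power_targets: dict[str, np.ndarray | float],
                 coupling: dict[str, np.ndarray | float],
                 seed: int | np.random.Generator = 0) -> RawEEG:
    """Coupled band-limited-noise EEG with controlled power and phase coupling.

    Per band each channel is ``sqrt(1 - c^2) * independent + c * shared``
    (both unit-variance band-limited noise) scaled to the target band power;
    larger coupling ``c`` monotonically raises the expected MPC of every
    channel pair in that band.  Powers are given in dB re 1 uV^2; coupling
    entries must lie in [0, 1].
    """
    unknown = set(montage) - set(MONTAGE)
    if unknown:
        raise ValueError(f"unknown montage labels: {sorted(unknown)}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = int(round(duration * fs))
    n_ch = len(montage)
    out = np.zeros((n_ch, n))
    for band, (lo, hi) in _BAND_EDGES.items():
        if band not in band_power_targets:
            continue
        p_db = np.broadcast_to(np.asarray(band_power_targets[band], dtype=float),
                               (n_ch,))
        c = np.broadcast_to(np.asarray(coupling.get(band, 0.0), dtype=float),
                            (n_ch,))
        if np.any((c < 0) | (c > 1)):
            raise ValueError("coupling entries must lie in [0, 1]")
        shared = _band_noise(rng, n, fs, lo, hi)
        amp = np.sqrt(10.0 ** (p_db / 10.0))
        for ci in range(n_ch):
            indep = _band_noise(rng, n, fs, lo, hi)
            out[ci] += amp[ci] * (np.sqrt(1.0 - c[ci] ** 2) * indep
                                  + c[ci] * shared)
    return RawEEG(out, fs, tuple(montage))


# ---------------------------------------------------------------------------
# Whole-study generation
# ---------------------------------------------------------------------------

def _iaps_design(n_blocks: int) -> list[tuple[str, float, float]]:
    """Alternating neutral / affective picture blocks spanning the label plane."""
    affective = [(2.5, -3.0), (2.5, 0.0), (2.5, 3.0),
                 (3.0, -2.0), (3.0, 2.0), (2.0, -1.0),
                 (2.0, 1.0), (3.5, -3.0), (3.5, 3.0),
                 (1.5, -2.0), (1.5, 2.0), (3.0, 0.0)]
    design = [("iaps_neutral", -2.5, 0.0)]
    for i in range(n_blocks - 1):
        a, v = affective[i % len(affective)]
        design.append((f"iaps_block{i + 1}", a, v))
    return design[:n_blocks]


def _stage_stimuli(stage: str, cfg: StudyConfig) -> list[StimulusSpec]:
    specs: list[StimulusSpec] = []
    t = 0.0
    if stage == "iaps":
        for sid, a, v in _iaps_design(cfg.n_iaps_blocks):
            specs.append(StimulusSpec(sid, "iaps", t, cfg.iaps_block_duration, a, v))
            t += cfg.iaps_block_duration
    elif stage == "rooms360":
        for sid, (a, v) in ROOM_DESIGN.items():
            specs.append(StimulusSpec(sid, "rooms360", t, cfg.room_duration, a, v))
            t += cfg.room_duration
    elif stage == "museum":
        for sid, (a, v) in MUSEUM_DESIGN.items():
            specs.append(StimulusSpec(sid, "museum", t, cfg.museum_duration, a, v))
            t += cfg.museum_duration
    return specs


def _subject_sam(spec: SubjectSpec, stim: StimulusSpec, cfg: StudyConfig,
                 rng: np.random.Generator) -> tuple[float, float]:
    """Subject-reported (arousal, valence), noisy around the design labels."""
    if stim.stage == "iaps":
        # Stage-1 labels come from published norms downstream; no scatter.
        return stim.arousal_label, stim.valence_label
    off = cfg.condition_sam_offset if spec.condition == "virtual" else 0.0
    a = np.clip(stim.arousal_label + off + rng.normal(0, cfg.sam_noise_sd), -4, 4)
    v = np.clip(stim.valence_label + off + rng.normal(0, cfg.sam_noise_sd), -4, 4)
    return float(a), float(v)


def _stimulus_physiology(spec: SubjectSpec, arousal: float, valence: float,
                         effects: EffectModel):
    """Map labels to per-stimulus generator parameters."""
    mean_rr = float(np.clip(spec.baseline_mean_rr
                            + effects.arousal_mean_rr * arousal, 450, 1500))
    lf_hf = float(np.clip(spec.baseline_lf_hf
                          + effects.arousal_lf_hf * arousal, 0.2, 8.0))
    band_db = dict(BASE_BAND_DB)
    band_db = {b: np.full(len(MONTAGE), v) for b, v in band_db.items()}
    for b in ("beta", "gamma"):
        band_db[b] = band_db[b] + effects.arousal_beta_gamma_db * arousal
    # frontal alpha asymmetry: valence raises F4 alpha relative to F3
    f3, f4 = MONTAGE.index("F3"), MONTAGE.index("F4")
    band_db["alpha"] = band_db["alpha"].copy()
    band_db["alpha"][f4] += 0.5 * effects.valence_frontal_alpha_db * valence
    band_db["alpha"][f3] -= 0.5 * effects.valence_frontal_alpha_db * valence
    cond_off = effects.condition_coupling if spec.condition == "virtual" else 0.0
    coup = float(np.clip(BASE_COUPLING + effects.arousal_coupling * arousal
                         + cond_off, 0.0, 0.98))
    coupling = {b: coup for b in band_db}
    return mean_rr, lf_hf, band_db, coupling


def _fit_intervals(intervals: np.ndarray, duration_s: float) -> np.ndarray:
    """Trim/stretch an interval block so it spans exactly ``duration_s``.

    Keeps the beat clock aligned with the stimulus event clock across a
    stage; the boundary beat absorbs the residual (a mild, realistic
    irregularity).
    """
    target = duration_s * 1000.0
    cum = np.cumsum(intervals)
    k = int(np.searchsorted(cum, target))
    if k >= len(intervals):
        k = len(intervals) - 1
    block = intervals[: k + 1].copy()
    prev = cum[k - 1] if k > 0 else 0.0
    last = target - prev
    if last < 300.0 and len(block) > 1:   # avoid implausibly short beats
        block = block[:-1]
        block[-1] = target - (cum[k - 2] if k > 1 else 0.0)
    else:
        block[-1] = last
    return block


def _render_stage(spec: SubjectSpec, stage: str, cfg: StudyConfig,
                  effects: EffectModel, rng: np.random.Generator,
                  sam_rows: list, event_rows: list) -> StageRecording:
    stimuli = _stage_stimuli(stage, cfg)
    eeg_parts: list[np.ndarray] = []
    all_intervals: list[np.ndarray] = []
    for stim in stimuli:
        a, v = _subject_sam(spec, stim, cfg, rng)
        sam_rows.append({"subject_id": spec.subject_id, "stimulus_id": stim.stimulus_id,
                         "stage": stage, "condition": spec.condition,
                         "arousal": a, "valence": v})
        event_rows.append({"subject_id": spec.subject_id, "stage": stage,
                           "stimulus_id": stim.stimulus_id, "onset_s": stim.onset,
                           "duration_s": stim.duration,
                           "condition": spec.condition})
        mean_rr, lf_hf, band_db, coupling = _stimulus_physiology(spec, a, v, effects)
        n_beats = max(int(np.ceil(stim.duration / (mean_rr / 1000.0))) + 3, 16)
        rr = generate_rr_series(mean_rr, spec.baseline_sdnn, lf_hf, n_beats, rng)
        all_intervals.append(_fit_intervals(rr.intervals, stim.duration))
        eeg = generate_eeg(MONTAGE, cfg.fs, stim.duration, band_db, coupling, rng)
        eeg_parts.append(eeg.samples)
    total_dur = sum(s.duration for s in stimuli)
    full_rr = RRSeries.from_intervals(np.concatenate(all_intervals))
    ecg = render_ecg(full_rr, cfg.fs, noise_sd=effects.ecg_noise_sd, seed=rng)
    n = int(round(total_dur * cfg.fs))
    ecg = ecg[:n] if len(ecg) >= n else np.pad(ecg, (0, n - len(ecg)))
    eeg = RawEEG(np.concatenate(eeg_parts, axis=1)[:, :n], cfg.fs, MONTAGE)
    return StageRecording(spec.subject_id, stage, spec.condition, ecg, eeg, cfg.fs)


def generate_study(n_subjects_per_phase: int = 30,
                   effects: EffectModel | None = None,
                   seed: int = 0,
                   config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a full two-phase study: recordings, events and SAM tables.

    Phase 1 subjects explore the real museum, phase 2 the virtual one; every
    subject also passes through the configured calibration stages.  Output is
    byte-identical for a fixed seed.
    """
    cfg = config or StudyConfig(n_subjects_per_phase=n_subjects_per_phase)
    if cfg.n_subjects_per_phase != n_subjects_per_phase:
        cfg = replace(cfg, n_subjects_per_phase=n_subjects_per_phase)
    effects = EffectModel() if effects is None else effects

    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(2 * cfg.n_subjects_per_phase)
    subjects: list[SubjectSpec] = []
    recordings: list[StageRecording] = []
    sam_rows: list[dict] = []
    event_rows: list[dict] = []
    k = 0
    for phase, condition in ((1, "real"), (2, "virtual")):
        for i in range(cfg.n_subjects_per_phase):
            ss = subject_seeds[k]
            k += 1
            rng = np.random.default_rng(ss)
            spec = SubjectSpec(
                subject_id=f"s{phase}{i + 1:02d}",
                condition=condition,
                baseline_mean_rr=float(np.clip(rng.normal(900, 60), 600, 1200)),
                baseline_sdnn=float(np.clip(rng.normal(50, 10), 20, 120)),
                baseline_lf_hf=float(np.clip(rng.normal(1.5, 0.3), 0.5, 4.0)),
                seed=int(ss.generate_state(1)[0] % (2 ** 31)),
            )
            subjects.append(spec)
            for stage in cfg.stages:
                recordings.append(_render_stage(spec, stage, cfg, effects, rng,
                                                sam_rows, event_rows))
    return SyntheticStudy(
        recordings=recordings,
        events=pd.DataFrame(event_rows),
        sam=pd.DataFrame(sam_rows),
        subjects=subjects,
        config=cfg,
        effects=effects,
    )


# ---------------------------------------------------------------------------
# Disk round trip (long-format CSV)
# ---------------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir) -> None:
    """Write signals (one CSV per subject-stage), events.csv and sam.csv."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in study.recordings:
        df = pd.DataFrame(rec.eeg.samples.T, columns=list(rec.eeg.montage))
        df["ECG"] = rec.ecg
        df.insert(0, "sample", np.arange(len(df)))
        df.to_csv(out / f"{rec.subject_id}_{rec.stage}.csv", index=False,
                  float_format="%.4f")
    study.events.to_csv(out / "events.csv", index=False)
    study.sam.to_csv(out / "sam.csv", index=False)
    manifest = pd.DataFrame([{"fs": study.config.fs,
                              "n_subjects_per_phase": study.config.n_subjects_per_phase}])
    manifest.to_csv(out / "manifest.csv", index=False)


def read_signals_csv(path, fs: float) -> tuple[RawEEG, np.ndarray]:
    """Read one subject-stage signals CSV back into (RawEEG, ecg)."""
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c in MONTAGE]
    eeg = RawEEG(df[channels].to_numpy().T, fs, tuple(channels))
    return eeg, df["ECG"].to_numpy()
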