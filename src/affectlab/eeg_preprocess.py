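"""EEG cleaning: bad-channel QC, filtering, epoching, artifact rejection, ICA.

The pipeline order is fixed: corrupted-channel detection (kurtosis + flatness)
with single-channel interpolation, mean subtraction + 0.5-40 Hz zero-phase
band-pass, segmentation into 1-s epochs, threshold/gradient artifact
rejection, and optional ICA-based removal of blink and muscle components.
Every stage logs its counts so rejection decisions are auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "MONTAGE",
    "NEIGHBOURS",
    "RawEEG",
    "EpochedEEG",
    "detect_bad_channels",
    "interpolate_channel",
    "filter_and_center",
    "epoch",
    "reject_artifact_epochs",
    "ica_clean",
]

#: 10-20 montage used throughout: frontal, central and parietal rows.
MONTAGE = ("Fz", "F3", "F4", "Cz", "C3", "C4", "POz", "P3", "P4")

#: Fixed adjacency used for single-channel interpolation.
NEIGHBOURS: dict[str, tuple[str, ...]] = {
    "Fz": ("F3", "F4", "Cz"),
    "F3": ("Fz", "C3"),
    "F4": ("Fz", "C4"),
    "Cz": ("Fz", "C3", "C4", "POz"),
    "C3": ("F3", "Cz", "P3"),
    "C4": ("F4", "Cz", "P4"),
    "POz": ("Cz", "P3", "P4"),
    "P3": ("C3", "POz"),
    "P4": ("C4", "POz"),
}


@dataclass
class RawEEG:
    """Continuous multichannel EEG in microvolts (channels x samples)."""

    samples: np.ndarray
    fs: float
    montage: tuple[str, ...] = MONTAGE
    reference: str = "linked mastoids"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.montage = tuple(self.montage)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.montage):
            raise ValueError("samples must be (n_channels, n_samples) matching montage")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochedEEG:
    """Channels x epochs x samples tensor with a per-epoch validity mask."""

    epochs: np.ndarray
    fs: float
    montage: tuple[str, ...] = MONTAGE
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    interpolated_channels: tuple[str, ...] = ()
    rejection_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (channels, epochs, samples)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.epochs.shape[1], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.valid_mask) != self.epochs.shape[1]:
            raise ValueError("valid_mask length must equal epoch count")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[1]


# ---------------------------------------------------------------------------
# Channel quality control
# ---------------------------------------------------------------------------

def detect_bad_channels(raw: RawEEG, kurtosis_z: float = 5.0,
                        flat_eps: float = 0.01,
                        flat_fraction: float = 0.10) -> tuple[list[str], str]:
    """Flag corrupted channels by excess kurtosis or flatness.

    A channel is corrupted when the robust z-score of its excess kurtosis
    across channels exceeds ``kurtosis_z``, or when its absolute successive
    difference stays below ``flat_eps`` microvolts for more than
    ``flat_fraction`` of the recording.  Verdict: ``"ok"`` (none),
    ``"interpolate"`` (exactly one), ``"reject-subject"`` (more than one).
    """
    if raw.duration < 60.0:
        raise ValueError("need at least 60 s of signal for channel QC")
    x = raw.samples
    kurt = stats.kurtosis(x, axis=1, fisher=True, bias=True)
    finite = np.isfinite(kurt)   # flat channels yield NaN; the flat rule catches them
    kz = np.zeros_like(kurt)
    if finite.sum() >= 3:
        med = np.median(kurt[finite])
        mad = np.median(np.abs(kurt[finite] - med))
        if mad > 0:
            kz[finite] = (kurt[finite] - med) / (1.4826 * mad)
    flat = np.mean(np.abs(np.diff(x, axis=1)) < flat_eps, axis=1) > flat_fraction

    bad = [raw.montage[i] for i in range(len(raw.montage))
           if abs(kz[i]) > kurtosis_z or flat[i]]
    if not bad:
        verdict = "ok"
    elif len(bad) == 1:
        verdict = "interpolate"
    else:
        verdict = "reject-subject"
    return bad, verdict


def interpolate_channel(raw: RawEEG, label: str,
                        corrupted: tuple[str, ...] = ()) -> RawEEG:
    """Replace ``label`` by the unweighted mean of its montage neighbours."""
    if label not in raw.montage:
        raise ValueError(f"unknown channel {label!r}")
    neigh = NEIGHBOURS[label]
    bad_neigh = [n for n in neigh if n in corrupted]
    if bad_neigh:
        raise RuntimeError(
            f"cannot interpolate {label}: neighbour(s) {bad_neigh} also corrupted")
    idx = {ch: i for i, ch in enumerate(raw.montage)}
    out = raw.samples.copy()
    out[idx[label]] = np.mean([raw.samples[idx[n]] for n in neigh], axis=0)
    return RawEEG(out, raw.fs, raw.montage, raw.reference)


# ---------------------------------------------------------------------------
# Filtering and epoching
# ---------------------------------------------------------------------------

def filter_and_center(raw: RawEEG, band: tuple[float, float] = (0.5, 40.0),
                      order: int = 4) -> RawEEG:
    """Per-channel mean subtraction then zero-phase band-pass (0.5-40 Hz)."""
    if raw.fs <= 80:
        raise ValueError("sampling rate must exceed 80 Hz")
    x = raw.samples - raw.samples.mean(axis=1, keepdims=True)
    sos = signal.butter(order, band, btype="band", fs=raw.fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    return RawEEG(y, raw.fs, raw.montage, raw.reference)


def epoch(raw: RawEEG, length_s: float = 1.0) -> EpochedEEG:
    """Cut into consecutive non-overlapping epochs; trailing partial discarded."""
    nsamp = int(round(length_s * raw.fs))
    n_ep = raw.samples.shape[1] // nsamp
    if n_ep == 0:
        warnings.warn("signal shorter than one epoch; zero epochs returned",
                      RuntimeWarning, stacklevel=2)
    cut = raw.samples[:, : n_ep * nsamp]
    ep = cut.reshape(raw.samples.shape[0], n_ep, nsamp)
    return EpochedEEG(ep.copy(), raw.fs, raw.montage)


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

def reject_artifact_epochs(ep: EpochedEEG, amp_thresh: float = 100.0,
                           grad_thresh: float = 70.0,
                           max_bad_channels: int = 2,
                           reject_fraction: float = 1.0 / 3.0,
                           rule: str = "or") -> EpochedEEG:
    """Invalidate epochs where more than ``max_bad_channels`` channels violate.

    A channel violates when its absolute amplitude exceeds ``amp_thresh`` uV
    or its sample-to-sample gradient exceeds ``grad_thresh`` uV (``rule="or"``,
    default) -- ``rule="and"`` requires both.  The subject-level flag
    ``rejection_log["subject_rejected"]`` is set when the invalid fraction
    exceeds ``reject_fraction``.  Idempotent.
    """
    x = ep.epochs
    amp_bad = np.max(np.abs(x), axis=2) > amp_thresh            # (C, E)
    grad_bad = np.max(np.abs(np.diff(x, axis=2)), axis=2) > grad_thresh
    if rule == "or":
        ch_bad = amp_bad | grad_bad
    elif rule == "and":
        ch_bad = amp_bad & grad_bad
    else:
        raise ValueError("rule must be 'or' or 'and'")
    epoch_bad = ch_bad.sum(axis=0) > max_bad_channels
    valid = ep.valid_mask & ~epoch_bad
    frac_bad = 1.0 - valid.mean() if ep.n_epochs else 0.0
    log = dict(ep.rejection_log)
    log.update({
        "epochs_total": ep.n_epochs,
        "epochs_rejected": int((~valid).sum()),
        "subject_rejected": bool(frac_bad > reject_fraction),
    })
    return EpochedEEG(ep.epochs, ep.fs, ep.montage, valid_mask=valid,
                      interpolated_channels=ep.interpolated_channels,
                      rejection_log=log)


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

_FRONTAL = ("Fz", "F3", "F4")


def ica_clean(ep: EpochedEEG, mode: str = "auto",
              manual_components: list[int] | None = None,
              blink_lowfreq_fraction: float = 0.5,
              muscle_gamma_fraction: float = 0.5,
              muscle_kurtosis: float = 5.0,
              random_state: int = 0) -> EpochedEEG:
    """ICA decomposition of valid epochs with artifact-component removal.

    ``mode="auto"`` removes components that look like blinks (frontal
    topography dominance AND <4 Hz power fraction above threshold) or muscle
    activity (gamma-band power fraction above threshold AND heavy-tailed
    sample distribution).  ``mode="manual"`` removes the supplied component
    indices; an empty list reconstructs the input unchanged.
    """
    n_ch = ep.epochs.shape[0]
    valid_idx = np.flatnonzero(ep.valid_mask)
    if len(valid_idx) < 9 * n_ch:
        raise ValueError("need at least 9x more valid epochs than channels for ICA")
    data = ep.epochs[:, valid_idx, :].reshape(n_ch, -1)   # (C, T)

    ica = FastICA(n_components=n_ch, whiten="unit-variance",
                  random_state=random_state, max_iter=1000, tol=1e-3)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sources = ica.fit_transform(data.T)               # (T, C)
    converged = not any(issubclass(w.category, ConvergenceWarning)
                        for w in caught)
    mixing = ica.mixing_                                   # (C, C)
    if not np.all(np.isfinite(mixing)) or not np.all(np.isfinite(sources)):
        # genuinely degenerate decomposition: pass through with a log entry
        warnings.warn("ICA decomposition degenerate; passing data through",
                      RuntimeWarning, stacklevel=2)
        log = dict(ep.rejection_log, ica_components_removed=[],
                   ica_converged=False)
        return EpochedEEG(ep.epochs, ep.fs, ep.montage, ep.valid_mask.copy(),
                          ep.interpolated_channels, log)

    if mode == "manual":
        remove = sorted(set(manual_components or []))
    elif mode == "auto":
        remove = _auto_components(sources, mixing, ep, blink_lowfreq_fraction,
                                  muscle_gamma_fraction, muscle_kurtosis)
    else:
        raise ValueError("mode must be 'auto' or 'manual'")

    out = ep.epochs.copy()
    if remove:
        keep = [i for i in range(n_ch) if i not in remove]
        clean = (sources[:, keep] @ mixing[:, keep].T).T + ica.mean_[:, None]
        out[:, valid_idx, :] = clean.reshape(n_ch, len(valid_idx), -1)
    log = dict(ep.rejection_log, ica_components_removed=list(remove),
               ica_converged=converged)
    return EpochedEEG(out, ep.fs, ep.montage, ep.valid_mask.copy(),
                      ep.interpolated_channels, log)


def _auto_components(sources: np.ndarray, mixing: np.ndarray, ep: EpochedEEG,
                     blink_frac: float, gamma_frac: float,
                     kurt_thresh: float) -> list[int]:
    """Deterministic blink/muscle heuristics on ICA components."""
    fs = ep.fs
    frontal_idx = [i for i, ch in enumerate(ep.montage) if ch in _FRONTAL]
    other_idx = [i for i, ch in enumerate(ep.montage) if ch not in _FRONTAL]
    remove = []
    for k in range(sources.shape[1]):
        s = sources[:, k]
        f, psd = signal.welch(s, fs=fs, nperseg=min(len(s), int(2 * fs)))
        total = np.trapezoid(psd, f) or 1.0
        low = np.trapezoid(psd[f < 4.0], f[f < 4.0]) / total
        gmask = (f >= 25.0) & (f < 40.0)
        gamma = np.trapezoid(psd[gmask], f[gmask]) / total
        topo = np.abs(mixing[:, k])
        frontal_dom = topo[frontal_idx].mean() > 1.5 * (topo[other_idx].mean() + 1e-12)
        heavy = stats.kurtosis(s, fisher=True) > kurt_thresh
        if (frontal_dom and low > blink_frac) or (gamma > gamma_frac and heavy):
            remove.append(k)
    return remove
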