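"""Band power and mean-phase-coherence (MPC) features from cleaned epochs.

Four bands are analysed: theta (4-8 Hz), alpha (8-12 Hz), beta (13-25 Hz) and
gamma (25-40 Hz); delta is deliberately excluded.  Per stimulus the extractor
emits 36 band-power features (9 channels x 4 bands) and 144 MPC features
(36 channel pairs x 4 bands).

MPC between channels i and j is the phase-locking statistic

    R = sqrt( E[cos(dphi)]^2 + E[sin(dphi)]^2 ),   dphi = phi_i - phi_j,

with instantaneous phases from the Hilbert analytic signal of the
band-filtered channels and the expectation taken over within-epoch samples
(10% trimmed at each edge to suppress Hilbert transients), then averaged over
valid epochs.  R lies in [0, 1]: 1 for perfectly phase-locked channels, near
0 for independent ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

from .eeg_preprocess import MONTAGE, EpochedEEG

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "band_power",
    "mpc",
    "aggregate_stimulus",
    "band_power_names",
    "mpc_names",
]


@dataclass(frozen=True)
class BandScheme:
    """Ordered (name, low Hz, high Hz) frequency bands."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        for name, lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band {name}: need low < high")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __len__(self) -> int:
        return len(self.bands)


DEFAULT_BANDS = BandScheme((
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 13.0, 25.0),
    ("gamma", 25.0, 40.0),
))


def band_power_names(montage=MONTAGE, scheme: BandScheme = DEFAULT_BANDS) -> list[str]:
    """Column names ``bp_<band>_<channel>`` in canonical order (36 values)."""
    return [f"bp_{band}_{ch}" for band, _, _ in scheme for ch in montage]


def mpc_names(montage=MONTAGE, scheme: BandScheme = DEFAULT_BANDS) -> list[str]:
    """Column names ``mpc_<band>_<chA>_<chB>`` in canonical order (144 values)."""
    return [f"mpc_{band}_{a}_{b}" for band, _, _ in scheme
            for a, b in combinations(montage, 2)]


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

def band_power(ep: EpochedEEG, scheme: BandScheme = DEFAULT_BANDS,
               segment_s: float = 0.5) -> np.ndarray:
    """Welch band powers per epoch: returns (n_epochs, n_channels, n_bands), uV^2.

    PSD per channel and epoch with Hann segments of ``segment_s`` seconds and
    50% overlap; band power is the PSD integral over the band.  Invalid
    epochs are returned as NaN rows.
    """
    fs = ep.fs
    for name, lo, hi in scheme:
        if hi > fs / 2:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist {fs / 2} Hz")
    nper = min(int(round(segment_s * fs)), ep.epochs.shape[2])
    f, psd = signal.welch(ep.epochs, fs=fs, window="hann", nperseg=nper,
                          noverlap=nper // 2, axis=2)
    df = f[1] - f[0]
    n_c, n_e = ep.epochs.shape[:2]
    out = np.full((n_e, n_c, len(scheme)), np.nan)
    for bi, (_, lo, hi) in enumerate(scheme):
        # sum of PSD bins whose centre lies in the band, times the bin width:
        # avoids the edge truncation a trapezoid over the coarse grid suffers
        mask = (f >= lo) & (f < hi)
        out[:, :, bi] = (psd[:, :, mask].sum(axis=2) * df).T
    out[~ep.valid_mask, :, :] = np.nan
    return out


# ---------------------------------------------------------------------------
# Mean phase coherence
# ---------------------------------------------------------------------------

def _band_analytic(ep: EpochedEEG, lo: float, hi: float) -> np.ndarray:
    """Per-epoch band-limited analytic signal, (channels, epochs, samples).

    Band selection and the Hilbert transform are combined in the frequency
    domain: positive-frequency bins inside [lo, hi) are kept (doubled, as in
    the analytic-signal construction), everything else is zeroed.  This is
    zero-phase by construction and exact for in-band bin-frequency sinusoids,
    which an IIR band-pass applied to 1-s epochs is not (its edge transients
    leave phase ripple well above numerical precision).
    """
    n = ep.epochs.shape[2]
    freqs = np.fft.fftfreq(n, d=1.0 / ep.fs)
    mult = np.zeros(n)
    pos = (freqs >= lo) & (freqs < hi) & (freqs > 0)
    mult[pos] = 2.0
    if n % 2 == 0 and ep.fs / 2 >= lo and ep.fs / 2 < hi:
        mult[n // 2] = 1.0  # Nyquist bin is its own conjugate
    spec = np.fft.fft(ep.epochs, axis=2)
    return np.fft.ifft(spec * mult, axis=2)


def mpc(ep: EpochedEEG, scheme: BandScheme = DEFAULT_BANDS,
        edge_trim: float = 0.10, squared: bool = False,
        epoch_aggregate: str = "vector") -> dict[str, np.ndarray]:
    """Mean phase coherence matrices per band over the valid epochs.

    Returns ``{band_name: (9, 9) symmetric matrix}`` with unit diagonal and
    values in [0, 1] (or R^2 when ``squared=True``).  Channels with zero
    variance in a band yield NaN for their pairs.

    With ``epoch_aggregate="vector"`` (default) the expectation pools the
    per-epoch complex phase-difference vectors before taking the magnitude,
    so genuinely unsynchronized channels average toward 0 as epochs
    accumulate; ``"magnitude"`` instead averages per-epoch scalar R values,
    which carries a strong positive bias for narrow bands on 1-s epochs
    (few independent phase samples per epoch).
    """
    valid = np.flatnonzero(ep.valid_mask)
    if len(valid) == 0:
        raise ValueError("no valid epochs")
    n_c = ep.epochs.shape[0]
    out: dict[str, np.ndarray] = {}
    for band, lo, hi in scheme:
        analytic = _band_analytic(ep, lo, hi)[:, valid, :]
        n = analytic.shape[2]
        trim = int(round(edge_trim * n))
        analytic = analytic[:, :, trim: n - trim] if trim else analytic
        band_var = np.mean(np.abs(analytic) ** 2, axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = analytic / np.abs(analytic)                   # (C, E, S)
        z = np.nan_to_num(z)
        n_s = z.shape[2]
        # per epoch and pair: mean_t z_i conj(z_j)
        cross = np.einsum("aes,bes->abe", z, np.conj(z)) / n_s
        if epoch_aggregate == "vector":
            m = np.abs(cross.mean(axis=2))
            if squared:
                m = m ** 2
        elif epoch_aggregate == "magnitude":
            r = np.abs(cross)                                 # (C, C, E)
            if squared:
                r = r ** 2
            m = r.mean(axis=2)
        else:
            raise ValueError("epoch_aggregate must be 'vector' or 'magnitude'")
        m = 0.5 * (m + m.T)
        np.fill_diagonal(m, 1.0)
        # zero-variance channels carry no phase information
        dead = band_var < 1e-18
        for i in np.flatnonzero(dead):
            m[i, :] = np.nan
            m[:, i] = np.nan
            m[i, i] = 1.0
        nanmask = np.isnan(m)
        m[~nanmask] = np.clip(m[~nanmask], 0.0, 1.0)
        out[band] = m
    return out


# ---------------------------------------------------------------------------
# Per-stimulus aggregation
# ---------------------------------------------------------------------------

def aggregate_stimulus(ep: EpochedEEG, window: tuple[float, float],
                       scheme: BandScheme = DEFAULT_BANDS,
                       montage=None) -> dict[str, float] | None:
    """Mean feature vector over the valid epochs inside a stimulus window.

    ``window`` is (onset_s, offset_s) relative to the recording start; epochs
    are 1 s, so the window is mapped to whole epoch indices.  Returns the
    36 + 144 named features, or None when the window holds no valid epoch.
    """
    montage = tuple(montage or ep.montage)
    lo = int(np.floor(window[0]))
    hi = int(np.ceil(window[1]))
    idx = np.arange(max(lo, 0), min(hi, ep.n_epochs))
    idx = idx[ep.valid_mask[idx]] if len(idx) else idx
    if len(idx) == 0:
        return None
    sub = EpochedEEG(ep.epochs[:, idx, :], ep.fs, ep.montage)
    bp = band_power(sub, scheme)                              # (E, C, B)
    bp_mean = np.nanmean(bp, axis=0)                          # (C, B)
    feats: dict[str, float] = {}
    for bi, (band, _, _) in enumerate(scheme):
        for ci, ch in enumerate(montage):
            feats[f"bp_{band}_{ch}"] = float(bp_mean[ci, bi])
    mats = mpc(sub, scheme)
    ch_index = {ch: i for i, ch in enumerate(montage)}
    for band, _, _ in scheme:
        m = mats[band]
        for a, b in combinations(montage, 2):
            feats[f"mpc_{band}_{a}_{b}"] = float(m[ch_index[a], ch_index[b]])
    return feats
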