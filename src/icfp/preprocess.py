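"""Pre-processing and ICA decomposition of multichannel EEG.

The feature extraction stage expects EEG that has been band-pass filtered
(0.3-100 Hz Butterworth, zero phase), notch filtered at the line frequency,
downsampled to a common rate, vetted for dead/saturated channels, and
decomposed by PCA pre-whitening followed by extended-Infomax ICA into a
fixed number of independent components (typically 20, 50 or 80).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import ElectrodeMontage

__all__ = [
    "EEGRecording",
    "ICDecomposition",
    "ChannelVettingReport",
    "bandpass_notch",
    "downsample",
    "vet_channels",
    "decompose",
    "fastica_unmixing",
]


@dataclass
class EEGRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    montage: ElectrodeMontage
    bad_channels: frozenset[str] = frozenset()
    trimmed_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"{self.data.shape[0]} data rows but montage has "
                f"{len(self.montage)} electrodes"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def good_channel_indices(self) -> np.ndarray:
        return np.array(
            [i for i, lab in enumerate(self.montage.labels) if lab not in self.bad_channels],
            dtype=int,
        )

    def drop_bad(self) -> "EEGRecording":
        """Recording restricted to good channels (montage updated to match)."""
        if not self.bad_channels:
            return self
        keep = self.good_channel_indices()
        return EEGRecording(
            data=self.data[keep],
            fs=self.fs,
            montage=self.montage.subset(keep),
            bad_channels=frozenset(),
            trimmed_segments=self.trimmed_segments,
        )


@dataclass
class ICDecomposition:
    """ICA result: ``weights`` (electrodes x n_ics) and IC ``timecourses``.

    ``weights[:, j]`` is the scalp projection (mixing column) of component
    ``j`` — the vector the spatial features operate on; ``timecourses[j]``
    is its activation.  ``weights @ timecourses`` reconstructs the
    (possibly PCA-reduced) channel data.
    """

    weights: np.ndarray
    timecourses: np.ndarray
    fs: float
    montage: ElectrodeMontage | None = None
    dataset_id: str = "dataset"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.timecourses = np.asarray(self.timecourses, dtype=float)
        if self.weights.ndim != 2 or self.timecourses.ndim != 2:
            raise ValueError("weights and timecourses must be 2-D")
        if self.weights.shape[1] != self.timecourses.shape[0]:
            raise ValueError(
                "weights column count must equal timecourse row count "
                f"({self.weights.shape[1]} != {self.timecourses.shape[0]})"
            )

    @property
    def n_ics(self) -> int:
        return self.weights.shape[1]

    @property
    def n_samples(self) -> int:
        return self.timecourses.shape[1]

    def reconstruct(self, exclude: "list[int] | None" = None) -> np.ndarray:
        """Channel data rebuilt from the ICs, optionally zeroing some."""
        keep = np.ones(self.n_ics, dtype=bool)
        if exclude:
            exclude = list(exclude)
            if min(exclude) < 0 or max(exclude) >= self.n_ics:
                raise IndexError(f"IC index out of range 0..{self.n_ics - 1}")
            keep[exclude] = False
        return self.weights[:, keep] @ self.timecourses[keep]


def bandpass_notch_array(
    data: np.ndarray,
    fs: float,
    lo: float = 0.3,
    hi: float = 100.0,
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> np.ndarray:
    """Array-level zero-phase Butterworth band-pass + optional notch."""
    nyq = fs / 2.0
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)
    if notch is not None:
        if notch >= nyq:
            raise ValueError(f"notch {notch} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(notch, notch_q, fs=fs)
        out = signal.filtfilt(b, a, out, axis=-1)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite samples after filtering")
    return out


def bandpass_notch(
    rec: EEGRecording,
    lo: float = 0.3,
    hi: float = 100.0,
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass plus optional mains notch filter."""
    data = bandpass_notch_array(rec.data, rec.fs, lo, hi, notch, order, notch_q)
    return replace(rec, data=data)


def downsample(rec: EEGRecording, target_fs: float = 1024.0) -> EEGRecording:
    """Anti-aliased (polyphase) resampling to ``target_fs``; no-op if equal."""
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the current rate")
    if target_fs == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=data, fs=target_fs)


@dataclass
class ChannelVettingReport:
    bad_channels: tuple[str, ...]
    reasons: dict[str, str] = field(default_factory=dict)
    trimmed_segments: tuple[tuple[int, int], ...] = ()
    dataset_usable: bool = True


def vet_channels(
    rec: EEGRecording,
    max_bad_fraction: float = 0.20,
    window_bad_fraction: float = 0.50,
    saturation_uv: float = 500.0,
    flat_std_uv: float = 0.05,
    noise_std_factor: float = 8.0,
    window_seconds: float = 1.0,
) -> tuple[EEGRecording, ChannelVettingReport]:
    """Automated channel screening for flatline/saturation/excess noise.

    A channel is marked bad when its standard deviation is below
    ``flat_std_uv`` (isoelectric/flat), when more than 5% of its samples
    exceed ``saturation_uv`` in magnitude (saturation), or when its standard
    deviation exceeds ``noise_std_factor`` times the median channel standard
    deviation (excessive noise).  When more than ``max_bad_fraction`` of
    channels are bad the whole dataset is flagged unusable.  Time windows in
    which more than ``window_bad_fraction`` of channels exceed the
    saturation bound are trimmed from the data.
    """
    if not (0 < max_bad_fraction <= 1) or not (0 < window_bad_fraction <= 1):
        raise ValueError("fractions must lie in (0, 1]")
    stds = rec.data.std(axis=1)
    med = np.median(stds[stds > 0]) if np.any(stds > 0) else 0.0
    reasons: dict[str, str] = {}
    for i, lab in enumerate(rec.montage.labels):
        if stds[i] < flat_std_uv:
            reasons[lab] = "flatline"
        elif np.mean(np.abs(rec.data[i]) > saturation_uv) > 0.05:
            reasons[lab] = "saturation"
        elif med > 0 and stds[i] > noise_std_factor * med:
            reasons[lab] = "noise"
    bad = frozenset(reasons)
    usable = len(bad) <= max_bad_fraction * rec.n_channels

    # window-level trimming on the good channels
    good = [i for i, lab in enumerate(rec.montage.labels) if lab not in bad]
    win = max(1, int(round(window_seconds * rec.fs)))
    n_win = rec.n_samples // win
    trimmed: list[tuple[int, int]] = []
    if n_win and good:
        seg = rec.data[good, : n_win * win].reshape(len(good), n_win, win)
        frac_bad = np.mean(np.max(np.abs(seg), axis=2) > saturation_uv, axis=0)
        for w in np.flatnonzero(frac_bad > window_bad_fraction):
            trimmed.append((w * win, (w + 1) * win))
    if trimmed:
        keep_mask = np.ones(rec.n_samples, dtype=bool)
        for a, b in trimmed:
            keep_mask[a:b] = False
        data = rec.data[:, keep_mask]
    else:
        data = rec.data
    out = EEGRecording(
        data=data,
        fs=rec.fs,
        montage=rec.montage,
        bad_channels=bad,
        trimmed_segments=tuple(trimmed),
    )
    report = ChannelVettingReport(
        bad_channels=tuple(sorted(bad)),
        reasons=reasons,
        trimmed_segments=tuple(trimmed),
        dataset_usable=usable,
    )
    if not usable:
        warnings.warn(
            f"{len(bad)}/{rec.n_channels} channels bad exceeds "
            f"{max_bad_fraction:.0%}: dataset flagged unusable",
            stacklevel=2,
        )
    return out, report


def _extended_infomax_unmixing(white: np.ndarray, seed: int) -> np.ndarray:
    """Extended-Infomax unmixing matrix for pre-whitened data.

    ``white`` is components x samples.  Thin wrapper so the ICA backend is
    swappable; any callable returning an unmixing matrix of matching shape
    satisfies the contract.
    """
    from mne.preprocessing import infomax

    rng = np.random.RandomState(seed % (2**32))
    return infomax(white.T, extended=True, rng=rng, verbose="error")


def fastica_unmixing(white: np.ndarray, seed: int) -> np.ndarray:
    """FastICA unmixing backend — much faster, useful for large sweeps."""
    import warnings as _warnings

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    fica = FastICA(whiten=False, random_state=seed % (2**32), max_iter=500, tol=1e-6)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        fica.fit(white.T)
    return fica.components_


def decompose(
    rec: EEGRecording,
    n_ics: int,
    seed: int = 0,
    ica_fun=_extended_infomax_unmixing,
    dataset_id: str = "dataset",
) -> ICDecomposition:
    """PCA pre-whitening followed by extended-Infomax ICA.

    The data are mean-centred per channel, reduced to ``n_ics`` principal
    components, whitened, and unmixed.  Components are canonicalized by
    descending explained variance of their back-projection and their sign is
    fixed so each scalp map's largest-|weight| entry is positive, removing
    ICA's permutation/sign ambiguity so feature tables are reproducible.
    """
    rec = rec.drop_bad()
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    n_ch, n_samp = x.shape
    if n_ics > n_ch:
        raise ValueError(f"n_ics={n_ics} exceeds channel count {n_ch}")
    # PCA via SVD of the centred data
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_ics > rank:
        raise ValueError(f"n_ics={n_ics} exceeds data rank {rank}")
    u, s, vt = u[:, :n_ics], s[:n_ics], vt[:n_ics]
    # whitened sources: unit variance per row
    white = vt * np.sqrt(n_samp)
    w = ica_fun(white, seed)  # (n_ics, n_ics) unmixing on whitened rows
    sources = w @ white
    # mixing back to electrode space: x ≈ A_pca @ white, white ≈ pinv(w) @ sources
    a_pca = u * (s / np.sqrt(n_samp))
    mixing = a_pca @ np.linalg.pinv(w)
    # canonical scaling: unit-variance sources, amplitude in the weights
    sd = sources.std(axis=1)
    sd[sd == 0] = 1.0
    sources = sources / sd[:, None]
    mixing = mixing * sd[None, :]
    # canonical order: descending explained variance of back-projection
    ev = (mixing**2).sum(axis=0)  # sources have unit variance
    order = np.argsort(-ev, kind="stable")
    mixing, sources = mixing[:, order], sources[order]
    # canonical sign: largest-|weight| electrode positive
    for j in range(n_ics):
        k = int(np.argmax(np.abs(mixing[:, j])))
        if mixing[k, j] < 0:
            mixing[:, j] = -mixing[:, j]
            sources[j] = -sources[j]
    return ICDecomposition(
        weights=mixing,
        timecourses=sources,
        fs=rec.fs,
        montage=rec.montage,
        dataset_id=dataset_id,
    )
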