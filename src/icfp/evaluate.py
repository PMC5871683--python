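"""Classifier scoring and signal-to-noise assessment of artifact removal.

Classification output is scored against reference labels with five metrics:

* accuracy      = (TP + TN) / total
* precision     = TP / (TP + FP)        — P(true artifact | labeled artifact)
* false omission rate = FN / (FN + TN)  — P(true artifact | labeled clean)
* sensitivity   = TP / (TP + FN)
* specificity   = TN / (TN + FP)

Artifact removal is quantified by reconstructing the EEG without the
classified artifactual ICs and comparing amplitude SNR around each artifact
event: signal is the maximum |v| in a 200 ms window centred on the event,
noise the maximum |v| in the immediately preceding 200 ms baseline,
SNR_dB = 20 log10(signal / noise).  Successful removal lowers the SNR
(the "signal", i.e. the artifact, shrinks while baseline brain activity
remains).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EEGRecording, ICDecomposition

__all__ = [
    "EvaluationReport",
    "SNRReport",
    "score",
    "metrics_from_counts",
    "reconstruct_without",
    "snr_change",
]


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float | None  # None when TP + FP == 0 (no artifact labels issued)
    false_omission_rate: float | None
    sensitivity: float | None
    specificity: float | None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> EvaluationReport:
    """All five metrics from confusion counts; undefined ratios become None."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("confusion counts sum to zero")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / total,
        precision=ratio(tp, tp + fp),
        false_omission_rate=ratio(fn, fn + tn),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
    )


def score(predicted, reference) -> EvaluationReport:
    """Score predicted binary labels (1 = artifact) against reference labels."""
    predicted = np.asarray(predicted, dtype=int)
    reference = np.asarray(reference, dtype=int)
    if predicted.shape != reference.shape:
        raise ValueError("predicted and reference label lengths differ")
    tp = int(np.sum((predicted == 1) & (reference == 1)))
    tn = int(np.sum((predicted == 0) & (reference == 0)))
    fp = int(np.sum((predicted == 1) & (reference == 0)))
    fn = int(np.sum((predicted == 0) & (reference == 1)))
    return metrics_from_counts(tp, tn, fp, fn)


def reconstruct_without(decomp: ICDecomposition, removed_ics) -> EEGRecording:
    """EEG rebuilt from the decomposition with the given ICs zeroed out."""
    data = decomp.reconstruct(exclude=list(removed_ics))
    if decomp.montage is None:
        raise ValueError("decomposition carries no montage; cannot build a recording")
    return EEGRecording(data=data, fs=decomp.fs, montage=decomp.montage)


@dataclass(frozen=True)
class SNRReport:
    channel: str
    n_events: int
    signal_amplitudes: np.ndarray = field(repr=False)
    noise_amplitudes: np.ndarray = field(repr=False)
    snr_db_original: float
    snr_db_reconstructed: float

    @property
    def snr_db_change(self) -> float:
        return self.snr_db_reconstructed - self.snr_db_original


def _event_snrs(
    data: np.ndarray,
    fs: float,
    events_s: np.ndarray,
    window_s: float,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    half = int(round(window_s * fs / 2))
    win = int(round(window_s * fs))
    sig, noi, db = [], [], []
    for t in events_s:
        c = int(round(t * fs))
        sig_lo, sig_hi = c - half, c - half + win
        noi_lo = sig_lo - win
        if noi_lo < 0 or sig_hi > data.size:
            warnings.warn(f"event at {t:.3f} s too close to the segment edge; skipped",
                          stacklevel=3)
            continue
        s = float(np.max(np.abs(data[sig_lo:sig_hi])))
        n = float(np.max(np.abs(data[noi_lo:sig_lo])))
        if n <= 0:
            warnings.warn(f"zero baseline amplitude at event {t:.3f} s; skipped",
                          stacklevel=3)
            continue
        sig.append(s)
        noi.append(n)
        factor = 20.0 if mode == "amplitude" else 10.0
        db.append(factor * math.log10(s / n))
    return np.asarray(sig), np.asarray(noi), np.asarray(db)


def snr_change(
    original: EEGRecording,
    reconstructed: EEGRecording,
    channel: str,
    event_times_s,
    segment: tuple[float, float] | None = None,
    window_s: float = 0.2,
    mode: str = "amplitude",
) -> SNRReport:
    """Amplitude SNR around artifact events, before vs after IC removal.

    ``event_times_s`` are artifact event centres in seconds (ground truth or
    user supplied).  Per event the signal is the max |v| in the ``window_s``
    window centred on it, the noise the max |v| of the preceding baseline
    window of the same length; per-event dB values are averaged.  With
    ``mode='power'`` the ratio is treated as a power ratio
    (10 log10 instead of 20 log10).
    """
    if original.fs != reconstructed.fs:
        raise ValueError("recordings must share a sampling rate")
    ch = original.montage.index(channel)
    ch_rec = reconstructed.montage.index(channel)
    events = np.asarray(list(event_times_s), dtype=float)
    if segment is not None:
        lo, hi = segment
        events = events[(events >= lo) & (events <= hi)]
    if events.size == 0:
        raise ValueError("no artifact events inside the analysis segment")
    sig_o, noi_o, db_o = _event_snrs(original.data[ch], original.fs, events, window_s, mode)
    _, _, db_r = _event_snrs(reconstructed.data[ch_rec], reconstructed.fs, events, window_s, mode)
    if db_o.size == 0 or db_r.size == 0:
        raise ValueError("no scorable artifact events (all skipped)")
    return SNRReport(
        channel=channel,
        n_events=int(db_o.size),
        signal_amplitudes=sig_o,
        noise_amplitudes=noi_o,
        snr_db_original=float(db_o.mean()),
        snr_db_reconstructed=float(db_r.mean()),
    )
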