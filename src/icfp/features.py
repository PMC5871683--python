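"""The 14 per-IC fingerprint features.

Each independent component (IC) of an EEG decomposition is summarized by an
ordered 14-value "fingerprint" spanning temporal, spatial, spectral and
statistical domains:

========== =====================================================
K          temporal kurtosis (mean excess kurtosis over 5 s epochs)
MEV        maximum epoch variance over mean epoch variance
SAD        spatial average difference, frontal vs posterior |weights|
SED        spatial eye difference, left vs right fronto-temporal weights
PSD_*      fraction of spectral power in delta/theta/alpha/beta/gamma
CIF        cardiac identification: found beats over expected beats
MIF        myogenic identification: high-band power dominance
EM_CORR    sliding correlation with a horizontal eye-movement template
EB_CORR    sliding correlation with an eyeblink template
EF         entropy feature: fraction of segments with extreme entropy
========== =====================================================

K, MEV, SAD and SED are normalized to the per-dataset maximum, so their
values are only comparable within one dataset; the remaining features are
absolute.  Thresholds (correlation floor 0.65, entropy z-floor 1.64,
entropy fraction floor 0.2, myogenic 20/21 Hz split, cardiac band
0.8-3.0 Hz) are configurable and default to the method's published values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .montage import ElectrodeMontage, region_indices
from .preprocess import ICDecomposition

__all__ = [
    "FEATURE_NAMES",
    "EpochPlan",
    "ArtifactTemplate",
    "FeatureConfig",
    "temporal_kurtosis",
    "max_epoch_variance",
    "spatial_average_difference",
    "spatial_eye_difference",
    "normalize_within_dataset",
    "band_power_fractions",
    "cardiac_identification",
    "myogenic_identification",
    "template_correlation",
    "build_template",
    "eyeblink_template",
    "eye_movement_template",
    "entropy_feature",
    "fingerprint_dataset",
]

#: fixed feature order of the fingerprint vector
FEATURE_NAMES: tuple[str, ...] = (
    "K",
    "MEV",
    "SAD",
    "SED",
    "PSD_DELTA",
    "PSD_THETA",
    "PSD_ALPHA",
    "PSD_BETA",
    "PSD_GAMMA",
    "CIF",
    "MIF",
    "EM_CORR",
    "EB_CORR",
    "EF",
)

#: canonical EEG band edges in Hz, half-open [lo, hi)
BANDS: tuple[tuple[str, float, float], ...] = (
    ("PSD_DELTA", 0.3, 4.0),
    ("PSD_THETA", 4.0, 8.0),
    ("PSD_ALPHA", 8.0, 12.0),
    ("PSD_BETA", 12.0, 40.0),
    ("PSD_GAMMA", 40.0, 100.0),
)


@dataclass(frozen=True)
class EpochPlan:
    """Epoching scheme for the temporal features.

    Defaults to consecutive 5 s epochs with 1 s overlap (4 s hop);
    trailing samples shorter than one epoch are discarded.
    """

    length: float = 5.0
    overlap: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length > self.overlap >= 0):
            raise ValueError("need length > overlap >= 0")

    def slices(self, n_samples: int, fs: float) -> list[slice]:
        n = int(round(self.length * fs))
        hop = int(round((self.length - self.overlap) * fs))
        if n < 2 or hop < 1:
            raise ValueError("epoch too short for the sampling rate")
        return [slice(s, s + n) for s in range(0, n_samples - n + 1, hop)]


@dataclass(frozen=True)
class ArtifactTemplate:
    """A canonical 4 s artifact waveform at a declared sampling rate."""

    waveform: np.ndarray
    fs: float
    kind: str = "eyeblink"
    duration: float = 4.0

    def __post_init__(self) -> None:
        w = np.asarray(self.waveform, dtype=float)
        object.__setattr__(self, "waveform", w - w.mean())
        n_expected = int(round(self.duration * self.fs))
        if w.size != n_expected:
            raise ValueError(
                f"template must span {self.duration} s at {self.fs} Hz "
                f"({n_expected} samples), got {w.size}"
            )

    def resampled(self, fs: float) -> "ArtifactTemplate":
        if fs == self.fs:
            return self
        n_new = int(round(self.duration * fs))
        w = signal.resample(self.waveform, n_new)
        return ArtifactTemplate(waveform=w, fs=fs, kind=self.kind, duration=self.duration)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable thresholds of the fingerprint features (published defaults)."""

    corr_threshold: float = 0.65
    entropy_z_threshold: float = 1.64
    entropy_floor: float = 0.2
    entropy_bins: int = 100
    mif_low: tuple[float, float] = (0.0, 20.0)
    mif_high: tuple[float, float] = (21.0, 100.0)
    cif_band: tuple[float, float] = (0.8, 3.0)
    cif_spacing_tol: float = 0.2
    cif_peak_floor: float = 5.0  # PSD peak must exceed this x band median
    cif_welch_window_s: float = 8.0  # long window: 0.125 Hz beat-rate resolution
    welch_window_s: float = 2.0
    psd_lo: float = 0.3
    psd_hi: float = 100.0
    band_mode: str = "mean"  # "mean" PSD per band or "integral" power


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# temporal features


def temporal_kurtosis(tc: np.ndarray, fs: float, plan: EpochPlan = EpochPlan()) -> float:
    """Raw temporal kurtosis K: mean excess kurtosis over epochs.

    Each epoch is mean-subtracted; its excess kurtosis is the fourth central
    moment over the squared variance, minus 3.  Zero-variance epochs
    contribute 0.  Negative averages are clamped to 0.
    """
    tc = np.asarray(tc, dtype=float)
    sls = plan.slices(tc.size, fs)
    if not sls:
        raise ValueError("time course shorter than one epoch")
    ks = []
    for sl in sls:
        e = tc[sl]
        e = e - e.mean()
        m2 = np.mean(e**2)
        if m2 == 0:
            ks.append(0.0)
        else:
            ks.append(np.mean(e**4) / m2**2 - 3.0)
    return float(max(0.0, np.mean(ks)))


def max_epoch_variance(tc: np.ndarray, fs: float, plan: EpochPlan = EpochPlan()) -> float:
    """Raw MEV: maximum epoch variance over the mean epoch variance."""
    tc = np.asarray(tc, dtype=float)
    sls = plan.slices(tc.size, fs)
    if len(sls) < 2:
        raise ValueError("need at least two epochs for MEV")
    v = np.array([np.mean(tc[sl] ** 2) - np.mean(tc[sl]) ** 2 for sl in sls])
    mean_v = v.mean()
    if mean_v == 0:
        return 0.0
    return float(v.max() / mean_v)


# ---------------------------------------------------------------------------
# spatial features


def _region_mean(weights: np.ndarray, idx: np.ndarray) -> float:
    return float(weights[idx].mean()) if idx.size else 0.0


def spatial_average_difference(
    weights: np.ndarray, montage: ElectrodeMontage, regions: dict | None = None
) -> float:
    """Raw SAD: |mean FA weight| - |mean PA weight|, with posterior guards.

    Returns 0 when variance(FA) - variance(PA) <= 0 (the frontal contrast is
    attributed to a posterior source), when the LE and RE mean weights have
    opposite sign (blink topographies are bilaterally symmetric), or when a
    required region is empty.  Negative differences are clamped to 0.
    """
    weights = np.asarray(weights, dtype=float)
    reg = regions if regions is not None else region_indices(montage)
    fa, pa, le, re_ = reg["FA"], reg["PA"], reg["LE"], reg["RE"]
    if fa.size == 0 or pa.size == 0:
        warnings.warn("empty FA/PA region: SAD set to 0", stacklevel=2)
        return 0.0
    var_fa = float(weights[fa].var())
    var_pa = float(weights[pa].var())
    if var_fa - var_pa <= 0:
        return 0.0
    if le.size and re_.size:
        if _region_mean(weights, le) * _region_mean(weights, re_) < 0:
            return 0.0
    sad = abs(_region_mean(weights, fa)) - abs(_region_mean(weights, pa))
    return float(max(0.0, sad))


def spatial_eye_difference(
    weights: np.ndarray, montage: ElectrodeMontage, regions: dict | None = None
) -> float:
    """Raw SED: |mean LE - mean RE| weight, 0 when both means share a sign.

    A common sign means no net horizontal eye-movement dipole.  Empty LE or
    RE regions degrade to 0 with a warning.
    """
    weights = np.asarray(weights, dtype=float)
    reg = regions if regions is not None else region_indices(montage)
    le, re_ = reg["LE"], reg["RE"]
    if le.size == 0 or re_.size == 0:
        warnings.warn("empty LE/RE region: SED set to 0", stacklevel=2)
        return 0.0
    m_le, m_re = _region_mean(weights, le), _region_mean(weights, re_)
    if m_le * m_re > 0:
        return 0.0
    return float(abs(m_le - m_re))


def normalize_within_dataset(raw: np.ndarray) -> np.ndarray:
    """Scale raw scores of one dataset by their maximum (all-zero stays zero)."""
    raw = np.asarray(raw, dtype=float)
    m = raw.max() if raw.size else 0.0
    return raw / m if m > 0 else np.zeros_like(raw)


# ---------------------------------------------------------------------------
# spectral features


def _welch(tc: np.ndarray, fs: float, cfg: FeatureConfig):
    nper = min(int(round(cfg.welch_window_s * fs)), tc.size)
    f, pxx = signal.welch(tc, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    return f, pxx


def band_power_fractions(
    tc: np.ndarray, fs: float, cfg: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Fractions of spectral power in the five canonical EEG bands.

    Welch PSD over ``[psd_lo, psd_hi)``; per band the mean PSD (or the
    integrated power when ``band_mode='integral'``) is taken, and the five
    band values are normalized to sum to 1.  A zero-power time course maps
    to all-zero fractions.
    """
    tc = np.asarray(tc, dtype=float)
    f, pxx = _welch(tc, fs, cfg)
    vals = {}
    for name, lo, hi in BANDS:
        m = (f >= lo) & (f < hi)
        if not np.any(m):
            vals[name] = 0.0
        elif cfg.band_mode == "integral":
            vals[name] = float(np.trapezoid(pxx[m], f[m])) if m.sum() > 1 else float(pxx[m].sum())
        else:
            vals[name] = float(pxx[m].mean())
    total = sum(vals.values())
    if total <= 0:
        return {name: 0.0 for name, *_ in BANDS}
    return {k: v / total for k, v in vals.items()}


def myogenic_identification(
    tc: np.ndarray, fs: float, cfg: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """MIF: high-frequency power dominance indicative of muscle activity.

    0 when the 0-20 Hz integrated PSD exceeds the 21-100 Hz PSD; otherwise
    the high-band power over the two-band total, which therefore lies in
    (0.5, 1] whenever nonzero.
    """
    tc = np.asarray(tc, dtype=float)
    f, pxx = _welch(tc, fs, cfg)
    lo_m = (f >= cfg.mif_low[0]) & (f <= cfg.mif_low[1])
    hi_m = (f >= cfg.mif_high[0]) & (f <= cfg.mif_high[1])
    p_lo, p_hi = float(pxx[lo_m].sum()), float(pxx[hi_m].sum())
    if p_lo + p_hi == 0 or p_lo > p_hi:
        return 0.0
    return p_hi / (p_lo + p_hi)


def cardiac_identification(
    tc: np.ndarray, fs: float, cfg: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """CIF: found cardiac peaks over expected beats at the dominant rate.

    The dominant spectral peak in the cardiac band (0.8-3.0 Hz, i.e.
    48-180 bpm) sets the expected beat rate; if the band holds no peak above
    ``cif_peak_floor`` times the band's median PSD, the score is 0.
    Time-course local maxima above half the mean peak amplitude are
    retained, then thinned so consecutive kept peaks are at least
    ``(1 - cif_spacing_tol)`` expected inter-beat intervals apart.  The
    score is found peaks over ``floor(duration x rate)`` and may exceed 1
    when extra peaks survive the spacing filter.  The PSD uses a longer
    Welch window than the band features so beat rates resolve to 1/8 Hz.
    """
    tc = np.asarray(tc, dtype=float)
    nper = min(int(round(cfg.cif_welch_window_s * fs)), tc.size)
    f, pxx = signal.welch(tc, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    band = (f >= cfg.cif_band[0]) & (f <= cfg.cif_band[1])
    if not np.any(band) or pxx[band].max() <= 0:
        return 0.0
    med = np.median(pxx[band])
    if med > 0 and pxx[band].max() < cfg.cif_peak_floor * med:
        return 0.0  # no distinct cardiac-band peak
    f_peak = float(f[band][np.argmax(pxx[band])])
    expected_ibi = fs / f_peak  # samples per beat
    n_expected = int(np.floor(tc.size / fs * f_peak))
    if n_expected == 0:
        return 0.0
    prominence = 0.5 * tc.std()
    peaks, props = signal.find_peaks(tc, prominence=prominence or None)
    if peaks.size == 0:
        return 0.0
    amps = tc[peaks]
    keep = amps > 0.5 * amps.mean()
    peaks = peaks[keep]
    # spacing filter: drop peaks closer than (1 - tol) x expected interval
    min_gap = (1.0 - cfg.cif_spacing_tol) * expected_ibi
    found: list[int] = []
    for p in peaks:
        if not found or p - found[-1] >= min_gap:
            found.append(p)
    return len(found) / n_expected


# ---------------------------------------------------------------------------
# template correlation


def _blink_waveform(fs: float, duration: float = 4.0) -> np.ndarray:
    """Stereotyped biphasic eyeblink pulse (~300 ms) centred in the window."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs - duration / 2.0
    # dominant positive lobe ~150 ms wide with a shallow negative rebound
    pulse = np.exp(-0.5 * (t / 0.06) ** 2) - 0.35 * np.exp(-0.5 * ((t - 0.18) / 0.10) ** 2)
    return pulse


def _saccade_waveform(fs: float, duration: float = 4.0) -> np.ndarray:
    """Step-and-return horizontal eye-movement profile (step at 1.5 s, 0.5 s hold)."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    rise = 1.0 / (1.0 + np.exp(-(t - 1.5) / 0.015))
    fall = 1.0 / (1.0 + np.exp(-(t - 2.0) / 0.015))
    return rise - fall


def eyeblink_template(fs: float) -> ArtifactTemplate:
    """Canonical parametric eyeblink template (4 s, zero mean)."""
    return ArtifactTemplate(waveform=_blink_waveform(fs), fs=fs, kind="eyeblink")


def eye_movement_template(fs: float) -> ArtifactTemplate:
    """Canonical parametric step-and-hold saccade template (4 s, zero mean)."""
    return ArtifactTemplate(waveform=_saccade_waveform(fs), fs=fs, kind="eye-movement")


def build_template(
    exemplars: list[np.ndarray], fs: float, kind: str = "eyeblink"
) -> ArtifactTemplate:
    """Average peak-aligned 4 s exemplar segments into a template.

    Exemplars of a different length are resampled to 4 s at ``fs``; each is
    circularly shifted so its absolute peak aligns with the first exemplar's
    before averaging, then the average is zero-meaned.
    """
    if not exemplars:
        raise ValueError("need at least one exemplar segment")
    n = int(round(4.0 * fs))
    aligned = []
    ref_peak = None
    for ex in exemplars:
        ex = np.asarray(ex, dtype=float)
        if ex.size != n:
            ex = signal.resample(ex, n)
        peak = int(np.argmax(np.abs(ex)))
        if ref_peak is None:
            ref_peak = peak
        aligned.append(np.roll(ex, ref_peak - peak))
    return ArtifactTemplate(waveform=np.mean(aligned, axis=0), fs=fs, kind=kind)


def sliding_correlation(tc: np.ndarray, template: ArtifactTemplate, fs: float) -> np.ndarray:
    """|Pearson r| between the template and every one-sample-step window.

    Vectorized over windows via FFT cross-correlation and cumulative sums;
    windows with zero variance yield 0 (their correlation is undefined and
    they can never pass the retention threshold).
    """
    tc = np.asarray(tc, dtype=float)
    tmpl = template.resampled(fs).waveform
    n = tmpl.size
    if tc.size < n:
        raise ValueError("time course shorter than the template")
    t0 = tmpl - tmpl.mean()
    st = t0.std()
    if st == 0:
        raise ValueError("template has zero variance")
    # dot products of t0 with every window, via correlation
    dots = signal.fftconvolve(tc, t0[::-1], mode="valid")
    c1 = np.concatenate(([0.0], np.cumsum(tc)))
    c2 = np.concatenate(([0.0], np.cumsum(tc**2)))
    w_sum = c1[n:] - c1[:-n]
    w_sq = c2[n:] - c2[:-n]
    w_var = w_sq / n - (w_sum / n) ** 2
    w_var = np.maximum(w_var, 0.0)
    denom = n * np.sqrt(w_var) * st
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, dots / denom, 0.0)
    return np.clip(np.abs(r), 0.0, 1.0)


def template_correlation(
    tc: np.ndarray,
    fs: float,
    template: ArtifactTemplate,
    cfg: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """EM-CORR / EB-CORR: mean of retained sliding |r| >= 0.65, else 0."""
    r = sliding_correlation(tc, template, fs)
    retained = r[r >= cfg.corr_threshold]
    return float(retained.mean()) if retained.size else 0.0


# ---------------------------------------------------------------------------
# entropy feature


def segment_entropies(
    timecourses: np.ndarray,
    fs: float,
    cfg: FeatureConfig = DEFAULT_CONFIG,
    segment_s: float = 5.0,
) -> np.ndarray:
    """Shannon entropy of each IC's amplitude distribution per 5 s segment.

    Returns an (n_ics, n_segments) array.  Each segment's amplitudes are
    binned into ``cfg.entropy_bins`` equal-width bins over that segment's own
    range; zero-probability bins are skipped; natural logarithm.
    """
    x = np.asarray(timecourses, dtype=float)
    n = int(round(segment_s * fs))
    n_seg = x.shape[1] // n
    if n_seg < 1:
        raise ValueError("time courses shorter than one 5 s segment")
    out = np.empty((x.shape[0], n_seg))
    for i in range(x.shape[0]):
        for j in range(n_seg):
            seg = x[i, j * n : (j + 1) * n]
            counts, _ = np.histogram(seg, bins=cfg.entropy_bins)
            p = counts[counts > 0] / seg.size
            out[i, j] = -np.sum(p * np.log(p))
    return out


def entropy_feature(
    timecourses: np.ndarray, fs: float, cfg: FeatureConfig = DEFAULT_CONFIG
) -> np.ndarray:
    """EF per IC: fraction of segments with extreme relative entropy.

    Segment entropies are z-scored across ICs at each segment index; EF is
    the fraction of an IC's segments with ``|z| >= 1.64``, floored to 0 when
    ``<= 0.2``.  Needs at least two ICs (z is undefined otherwise).
    """
    h = segment_entropies(timecourses, fs, cfg)
    n_ics, n_seg = h.shape
    if n_ics < 2:
        warnings.warn("entropy feature needs >= 2 ICs; returning 0", stacklevel=2)
        return np.zeros(n_ics)
    mu = h.mean(axis=0, keepdims=True)
    sd = h.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (h - mu) / sd, 0.0)
    ef = np.mean(np.abs(z) >= cfg.entropy_z_threshold, axis=1)
    ef[ef <= cfg.entropy_floor] = 0.0
    return ef


# ---------------------------------------------------------------------------
# full fingerprint table


def fingerprint_dataset(
    decomp: ICDecomposition,
    montage: ElectrodeMontage | None = None,
    templates: "dict[str, ArtifactTemplate] | None" = None,
    plan: EpochPlan = EpochPlan(),
    cfg: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One 14-feature fingerprint per IC, normalized within the dataset.

    Returns a DataFrame with the fixed :data:`FEATURE_NAMES` columns plus
    ``ic_id`` and ``dataset_id``.  K/MEV/SAD/SED are scaled by the dataset
    maximum; all other features are absolute.
    """
    montage = montage if montage is not None else decomp.montage
    if montage is None:
        raise ValueError("a montage is required for the spatial features")
    fs = decomp.fs
    if templates is None:
        templates = {
            "eyeblink": eyeblink_template(fs),
            "eye-movement": eye_movement_template(fs),
        }
    reg = region_indices(montage)
    n = decomp.n_ics
    raw = {name: np.zeros(n) for name in ("K", "MEV", "SAD", "SED")}
    rows = np.zeros((n, len(FEATURE_NAMES)))
    col = {name: i for i, name in enumerate(FEATURE_NAMES)}
    for j in range(n):
        tc = decomp.timecourses[j]
        w = decomp.weights[:, j]
        raw["K"][j] = temporal_kurtosis(tc, fs, plan)
        raw["MEV"][j] = max_epoch_variance(tc, fs, plan)
        raw["SAD"][j] = spatial_average_difference(w, montage, reg)
        raw["SED"][j] = spatial_eye_difference(w, montage, reg)
        for name, val in band_power_fractions(tc, fs, cfg).items():
            rows[j, col[name]] = val
        rows[j, col["CIF"]] = cardiac_identification(tc, fs, cfg)
        rows[j, col["MIF"]] = myogenic_identification(tc, fs, cfg)
        rows[j, col["EM_CORR"]] = template_correlation(tc, fs, templates["eye-movement"], cfg)
        rows[j, col["EB_CORR"]] = template_correlation(tc, fs, templates["eyeblink"], cfg)
    for name in ("K", "MEV", "SAD", "SED"):
        rows[:, col[name]] = normalize_within_dataset(raw[name])
    try:
        rows[:, col["EF"]] = entropy_feature(decomp.timecourses, fs, cfg)
    except ValueError as err:
        warnings.warn(f"entropy feature unavailable: {err}; set to 0", stacklevel=2)
    if not np.all(np.isfinite(rows)):
        raise FloatingPointError("non-finite fingerprint values")
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df.insert(0, "dataset_id", decomp.dataset_id)
    df.insert(1, "ic_id", np.arange(n))
    return df
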