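"""Band-limited EEG features per channel and 1-s segment.

Three feature domains are computed on each 1-s segment of each channel:

* time — kurtosis, SD, max |amplitude| and Shannon entropy of the amplitude
  histogram, on the broadband segment and on each of the five band-filtered
  versions (4 statistics x 6 signals = 24 features per channel);
* frequency — per band: total power, SD of the in-band PSD values and
  Shannon entropy of the in-band PSD normalized to a probability vector,
  from a multitaper spectrum on a 1-50 Hz grid (3 x 5 = 15);
* wavelet — the same three statistics on Morlet scalogram power (15).

Feature tables carry one row per (subject, piece, segment) and a sidecar
metadata table naming each column's (domain, channel, band, statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats

from .preprocess import EpochSet


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float


#: The five analysis bands of the study.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 15.0, 25.0),
    BandDefinition("gamma", 30.0, 50.0),
)

TIME_STATS = ("kurtosis", "sd", "max", "entropy")
SPECTRAL_STATS = ("power", "sd", "entropy")

_ENTROPY_BINS = 32


def bandpass(x: np.ndarray, fs: float, band: BandDefinition,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    sos = signal.butter(order, [band.low, band.high], btype="bandpass",
                        fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def amplitude_entropy(x: np.ndarray, bins: int = _ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of the amplitude histogram of a segment."""
    if np.ptp(x) == 0:
        return 0.0
    hist, _ = np.histogram(x, bins=bins)
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _time_stats(x: np.ndarray) -> list[float]:
    sd = float(np.std(x))
    kurt = float(stats.kurtosis(x, fisher=False)) if sd > 0 else 0.0
    return [kurt, sd, float(np.max(np.abs(x))), amplitude_entropy(x)]


def time_domain_features(segment: np.ndarray, fs: float,
                         bands=BANDS) -> np.ndarray:
    """24 values: 4 statistics on broadband + each band-filtered version."""
    vals = _time_stats(np.asarray(segment, dtype=float))
    for band in bands:
        vals.extend(_time_stats(bandpass(segment, fs, band)))
    return np.asarray(vals)


def multitaper_psd(segment: np.ndarray, fs: float, nw: float = 2.0,
                   n_tapers: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper power spectral density (DPSS tapers, eigenvalue-unweighted).

    Returns (freqs, psd) on the rfft grid; for a 1-s segment the grid step
    is 1 Hz.
    """
    x = np.asarray(segment, dtype=float)
    n = x.size
    tapers = signal.windows.dpss(n, nw, Kmax=n_tapers)
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    psd[1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def _spectral_stats(power_vals: np.ndarray, df: float) -> list[float]:
    total = float(power_vals.sum() * df)
    sd = float(power_vals.std())
    s = power_vals.sum()
    if s <= 0:
        return [total, sd, 0.0]
    p = power_vals / s
    p = p[p > 0]
    return [total, sd, float(-np.sum(p * np.log2(p)))]


def frequency_domain_features(segment: np.ndarray, fs: float,
                              bands=BANDS) -> np.ndarray:
    """15 values: (power, SD, entropy) of the multitaper PSD per band."""
    freqs, psd = multitaper_psd(segment, fs)
    df = freqs[1] - freqs[0]
    vals: list[float] = []
    for band in bands:
        if band.high > freqs[-1]:
            raise ValueError(f"band {band.name} outside the spectral grid")
        sel = (freqs >= band.low) & (freqs <= band.high)
        vals.extend(_spectral_stats(psd[sel], df))
    return np.asarray(vals)


def morlet_scalogram(segment: np.ndarray, fs: float,
                     freqs: np.ndarray | None = None,
                     wavelet: str = "cmor1.5-1.0") -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet scalogram on a 1-50 Hz grid; returns (freqs, power)."""
    if freqs is None:
        freqs = np.arange(1.0, 51.0)
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(np.asarray(segment, dtype=float), scales, wavelet,
                        sampling_period=1.0 / fs)
    return freqs, np.abs(coefs) ** 2


def wavelet_domain_features(segment: np.ndarray, fs: float,
                            bands=BANDS) -> np.ndarray:
    """15 values: (power, SD, entropy) of in-band scalogram power per band."""
    freqs, power = morlet_scalogram(segment, fs)
    vals: list[float] = []
    for band in bands:
        sel = (freqs >= band.low) & (freqs <= band.high)
        if not np.any(sel):
            raise ValueError(f"band {band.name} outside the scalogram grid")
        pv = power[sel].ravel()
        mean_power = float(pv.mean())
        sd = float(pv.std())
        p = pv / pv.sum() if pv.sum() > 0 else None
        ent = float(-np.sum(p[p > 0] * np.log2(p[p > 0]))) if p is not None else 0.0
        vals.extend([mean_power, sd, ent])
    return np.asarray(vals)


_DOMAIN_FUNCS = {
    "time": time_domain_features,
    "frequency": frequency_domain_features,
    "wavelet": wavelet_domain_features,
}


# Vectorized epoch-level equivalents of the per-segment functions above.
# They produce identical numbers (same filters, same estimators) but run one
# filter / FFT call per epoch array instead of one per segment and channel.

def _entropy_rows(arr: np.ndarray) -> np.ndarray:
    flat = arr.reshape(-1, arr.shape[-1])
    out = np.array([amplitude_entropy(row) for row in flat])
    return out.reshape(arr.shape[:-1])


def _time_rows(segments: np.ndarray, fs: float, bands) -> np.ndarray:
    """(n_seg, n_ch * 24) time-domain features for one epoch's segments."""
    versions = [segments] + [bandpass(segments, fs, b) for b in bands]
    per_version = []
    for v in versions:
        sd = v.std(axis=-1)
        kurt = np.where(sd > 0, stats.kurtosis(v, axis=-1, fisher=False), 0.0)
        mx = np.abs(v).max(axis=-1)
        ent = _entropy_rows(v)
        per_version.append(np.stack([kurt, sd, mx, ent], axis=-1))
    feats = np.stack(per_version, axis=2)        # (n_seg, n_ch, n_ver, 4)
    return feats.reshape(segments.shape[0], -1)


def _frequency_rows(segments: np.ndarray, fs: float, bands) -> np.ndarray:
    n_seg, n_ch, n = segments.shape
    tapers = signal.windows.dpss(n, 2.0, Kmax=3)
    spec = np.fft.rfft(segments[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=2) / fs
    psd[..., 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    df = freqs[1] - freqs[0]
    feats = []
    for band in bands:
        if band.high > freqs[-1]:
            raise ValueError(f"band {band.name} outside the spectral grid")
        sub = psd[..., (freqs >= band.low) & (freqs <= band.high)]
        total = sub.sum(axis=-1) * df
        sd = sub.std(axis=-1)
        ssum = sub.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ssum > 0, sub / ssum, 0.0)
            logp = np.where(p > 0, np.log2(p), 0.0)
        ent = -(p * logp).sum(axis=-1)
        feats.append(np.stack([total, sd, ent], axis=-1))
    return np.stack(feats, axis=2).reshape(n_seg, -1)


def _wavelet_rows(segments: np.ndarray, fs: float, bands) -> np.ndarray:
    n_seg, n_ch, n = segments.shape
    freqs = np.arange(1.0, 51.0)
    fc = pywt.central_frequency("cmor1.5-1.0")
    scales = fc * fs / freqs
    coefs, _ = pywt.cwt(segments, scales, "cmor1.5-1.0",
                        sampling_period=1.0 / fs, axis=-1)
    power = np.abs(coefs) ** 2                   # (n_scales, n_seg, n_ch, n)
    feats = []
    for band in bands:
        sel = (freqs >= band.low) & (freqs <= band.high)
        sub = power[sel]                         # (n_band, n_seg, n_ch, n)
        pv = np.moveaxis(sub, 0, 2).reshape(n_seg, n_ch, -1)
        mean_power = pv.mean(axis=-1)
        sd = pv.std(axis=-1)
        ssum = pv.sum(axis=-1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(ssum > 0, pv / ssum, 0.0)
            logp = np.where(p > 0, np.log2(p), 0.0)
        ent = -(p * logp).sum(axis=-1)
        feats.append(np.stack([mean_power, sd, ent], axis=-1))
    return np.stack(feats, axis=2).reshape(n_seg, -1)


_EPOCH_FUNCS = {"time": _time_rows, "frequency": _frequency_rows,
                "wavelet": _wavelet_rows}


def feature_names(domain: str, bands=BANDS) -> list[tuple[str, str]]:
    """(band, statistic) pairs in column order for one channel."""
    if domain == "time":
        return [("broadband", s) for s in TIME_STATS] + \
               [(b.name, s) for b in bands for s in TIME_STATS]
    if domain in ("frequency", "wavelet"):
        return [(b.name, s) for b in bands for s in SPECTRAL_STATS]
    raise ValueError(f"unknown feature domain {domain!r}")


def features_per_channel(domain: str, bands=BANDS) -> int:
    return len(feature_names(domain, bands))


def build_feature_table(
    epoch_sets: list[EpochSet] | EpochSet,
    classes: dict[str, str],
    domain: str = "time",
    bands=BANDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per 1-s segment across subjects; returns (table, metadata).

    ``classes`` maps epoch labels (``piece_<id>``/``baseline``) to class
    labels; epochs without a class entry are skipped. The table index is
    (subject, piece, segment) and a ``class_label`` column is attached; the
    metadata frame names (domain, channel, band, statistic) per feature
    column.
    """
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    epoch_func = _EPOCH_FUNCS[domain]
    names = feature_names(domain, bands)

    columns, meta_rows = [], []
    chs = epoch_sets[0].ch_names
    for es in epoch_sets:
        if es.ch_names != chs:
            raise ValueError("montage mismatch across epoch sets")
    for ch in chs:
        for band, stat in names:
            columns.append(f"{domain}|{ch}|{band}|{stat}")
            meta_rows.append({"column": columns[-1], "domain": domain,
                              "channel": ch, "band": band, "statistic": stat})

    rows, index, labels = [], [], []
    for es in epoch_sets:
        for ep in es.all_epochs():
            if ep.label not in classes:
                continue
            ep_rows = epoch_func(np.asarray(ep.segments, dtype=float), es.fs, bands)
            for si in range(ep_rows.shape[0]):
                rows.append(ep_rows[si])
                index.append((es.subject_id, ep.label, si))
                labels.append(classes[ep.label])
    table = pd.DataFrame(
        rows, columns=columns,
        index=pd.MultiIndex.from_tuples(index, names=["subject", "piece", "segment"]),
    )
    if table.isna().any().any():
        raise ValueError("feature table contains missing values")
    table["class_label"] = labels
    meta = pd.DataFrame(meta_rows).set_index("column")
    return table, meta
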