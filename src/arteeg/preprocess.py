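"""Cleaning and segmentation of raw recordings.

The stage order is: zero-phase high-pass filter -> correlation-based bad
channel rejection -> peripheral channel removal -> artifact subspace
reconstruction -> common average reference -> epoch segmentation. Cleaning
never changes the sample count; only bad-channel and peripheral rejection
change the montage.

The artifact subspace reconstruction here is a deliberately simplified
sliding-window PCA method (calibration statistics, component-wise variance
thresholding, reconstruction from retained components). It follows the same
idea as the EEGLAB plug-in but makes no claim of bit-compatibility with it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import montage
from .recording import Recording

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# filtering

def highpass_filter(recording: Recording, cutoff: float = 0.1,
                    order: int = 8) -> Recording:
    """Zero-phase high-pass Butterworth filter (forward-backward).

    An ``order``-th order design applied forward and backward, i.e. an
    effective magnitude response of twice the order, which is the common EEG
    convention for "zero-phase N-th order".
    """
    if not cutoff < recording.fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    bad = [ch for ch, row in zip(recording.ch_names, recording.data)
           if not np.all(np.isfinite(row))]
    if bad:
        raise ValueError(f"non-finite samples in channel(s): {', '.join(bad)}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=recording.fs,
                        output="sos")
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def highpass_response_db(fs: float, freq: float, cutoff: float = 0.1,
                         order: int = 8) -> float:
    """Magnitude (dB) of the forward-backward design at ``freq`` Hz."""
    sos = signal.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    # filtfilt squares the magnitude response
    return float(20 * np.log10(np.abs(h[0]) ** 2 + 1e-300))


# ---------------------------------------------------------------------------
# bad channels

@dataclass
class BadChannelReport:
    bad_fraction: dict[str, float]
    rejected: list[str]
    corr_threshold: float
    window_s: float
    bad_window_channel_frac: float
    bad_channel_window_frac: float


def detect_bad_channels(
    recording: Recording,
    corr_threshold: float = 0.4,
    window: float = 2.0,
    bad_window_channel_frac: float = 0.8,
    bad_channel_window_frac: float = 0.5,
) -> BadChannelReport:
    """Correlation-based bad-channel detection on non-overlapping windows.

    Within each ``window``-second window a channel is flagged bad when at
    least ``bad_window_channel_frac`` (default 80%) of its absolute pairwise
    correlations fall below ``corr_threshold``; a channel is rejected when at
    least ``bad_channel_window_frac`` (default 50%) of its windows are
    flagged. A zero-variance window yields undefined correlations, which are
    treated as 0 (flagging the channel for that window).
    """
    wlen = int(round(window * recording.fs))
    n_win = recording.n_samples // wlen
    if n_win < 1:
        raise ValueError("recording shorter than one analysis window")
    n = recording.n_channels
    if n < 2:
        raise ValueError("need at least two channels")
    flags = np.zeros((n, n_win), dtype=bool)
    for w in range(n_win):
        seg = recording.data[:, w * wlen:(w + 1) * wlen]
        sd = seg.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(seg)
        corr[~np.isfinite(corr)] = 0.0
        for i in range(n):
            if sd[i] == 0:
                flags[i, w] = True
                continue
            others = np.abs(np.delete(corr[i], i))
            flags[i, w] = np.mean(others < corr_threshold) >= bad_window_channel_frac
    frac = flags.mean(axis=1)
    rejected = [recording.ch_names[i] for i in range(n)
                if frac[i] >= bad_channel_window_frac]
    return BadChannelReport(
        bad_fraction=dict(zip(recording.ch_names, frac.tolist())),
        rejected=rejected, corr_threshold=corr_threshold, window_s=window,
        bad_window_channel_frac=bad_window_channel_frac,
        bad_channel_window_frac=bad_channel_window_frac,
    )


def remove_peripheral_channels(
    recording: Recording,
    labels=montage.PERIPHERAL_DEFAULT,
    strict: bool = False,
) -> Recording:
    """Drop the peripheral montage rows (case-insensitive label matching)."""
    lower = {ch.lower(): ch for ch in recording.ch_names}
    to_drop = []
    for lbl in labels:
        hit = lower.get(lbl.lower())
        if hit is None:
            if strict:
                raise ValueError(f"unknown channel label {lbl!r}")
            continue
        to_drop.append(hit)
    keep = [ch for ch in recording.ch_names if ch not in set(to_drop)]
    if not keep:
        raise ValueError("peripheral removal would leave no channels")
    return recording.pick(keep)


# ---------------------------------------------------------------------------
# artifact subspace reconstruction (simplified)

def select_calibration(recording: Recording, duration: float = 10.0,
                       step: float = 1.0) -> Recording:
    """Lowest-variance contiguous run, used as artifact-light calibration."""
    wlen = int(round(duration * recording.fs))
    if wlen > recording.n_samples:
        raise ValueError("recording shorter than requested calibration length")
    hop = max(1, int(round(step * recording.fs)))
    best_s0, best_v = 0, np.inf
    for s0 in range(0, recording.n_samples - wlen + 1, hop):
        v = float(recording.data[:, s0:s0 + wlen].var(axis=1).mean())
        if v < best_v:
            best_s0, best_v = s0, v
    return recording.crop(best_s0, best_s0 + wlen)


def asr_clean(recording: Recording, calibration: Recording,
              window: float = 0.5, k_sd: float = 3.0) -> Recording:
    """Sliding-window PCA artifact removal against calibration statistics.

    Principal components are computed from the calibration covariance; per
    calibration window the RMS of each component score is collected, giving a
    mean and SD per component. In each analysis window, components whose RMS
    exceeds mean + ``k_sd`` * SD are scaled down to that threshold and the
    window is reconstructed — clipping rather than deleting the offending
    subspace, so genuine high-power activity keeps its waveform shape while
    transient artifacts lose their excess amplitude. ``k_sd = inf`` is the
    identity.
    """
    if calibration.duration < 5.0:
        raise ValueError("calibration segment must be at least 5 s")
    if calibration.n_channels != recording.n_channels:
        raise ValueError("calibration montage mismatch")
    wlen = int(round(window * recording.fs))
    calib = calibration.data - calibration.data.mean(axis=1, keepdims=True)
    cov = calib @ calib.T / calib.shape[1]
    evals, evecs = np.linalg.eigh(cov)          # ascending
    comps = evecs.T                              # rows are components

    n_cal_win = calibration.n_samples // wlen
    scores = comps @ calib
    rms = np.empty((recording.n_channels, n_cal_win))
    for w in range(n_cal_win):
        rms[:, w] = np.sqrt(np.mean(scores[:, w * wlen:(w + 1) * wlen] ** 2, axis=1))
    mu, sd = rms.mean(axis=1), rms.std(axis=1)
    thresh = mu + k_sd * sd

    out = recording.copy()
    n_win = int(np.ceil(recording.n_samples / wlen))
    for w in range(n_win):
        s0, s1 = w * wlen, min((w + 1) * wlen, recording.n_samples)
        seg = out.data[:, s0:s1]
        sc = comps @ seg
        seg_rms = np.sqrt(np.mean(sc ** 2, axis=1))
        kill = seg_rms > thresh
        if np.any(kill):
            sc[kill] *= (thresh[kill] / seg_rms[kill])[:, None]
            out.data[:, s0:s1] = comps.T @ sc
    return out


# ---------------------------------------------------------------------------
# referencing and segmentation

def rereference_car(recording: Recording) -> Recording:
    """Common average reference: subtract the per-sample mean over channels."""
    if recording.n_channels < 2:
        raise ValueError("CAR requires at least two channels")
    out = recording.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    return out


@dataclass
class Epoch:
    """One 5-s viewing (or baseline) epoch split into 1-s segments."""

    label: str
    start_sample: int
    segments: np.ndarray  # (n_segments, n_channels, segment_len)

    @property
    def data(self) -> np.ndarray:
        """Contiguous (n_channels, n_samples) view of the whole epoch."""
        return np.concatenate(list(self.segments), axis=1)


@dataclass
class EpochSet:
    subject_id: str
    ch_names: list[str]
    fs: float
    epochs: list[Epoch] = field(default_factory=list)
    baseline: Epoch | None = None

    def all_epochs(self) -> list[Epoch]:
        out = list(self.epochs)
        if self.baseline is not None:
            out = [self.baseline] + out
        return out


def segment_epochs(
    recording: Recording,
    epoch_len: float = 5.0,
    sub_len: float = 1.0,
    baseline_label: str = "baseline",
    subject_id: str = "",
) -> EpochSet:
    """First ``epoch_len`` seconds after each annotation, split into segments.

    Piece epochs start at their annotation. The baseline epoch is the
    lowest-variance ``epoch_len``-second window inside the baseline block
    (from the baseline annotation to the next annotation), standing in for an
    artifact-free stretch. Truncated epochs are dropped with a logged warning.
    """
    fs = recording.fs
    elen = int(round(epoch_len * fs))
    slen = int(round(sub_len * fs))
    n_seg = elen // slen
    out = EpochSet(subject_id=subject_id, ch_names=list(recording.ch_names), fs=fs)

    anns = recording.annotations
    for k, (lbl, s0) in enumerate(anns):
        if lbl == baseline_label:
            s_end = anns[k + 1][1] if k + 1 < len(anns) else recording.n_samples
            s_start = _lowest_variance_window(recording.data[:, s0:s_end], elen)
            if s_start is None:
                logger.warning("baseline block shorter than %g s; skipped", epoch_len)
                continue
            seg = recording.data[:, s0 + s_start:s0 + s_start + elen]
            out.baseline = Epoch(baseline_label, s0 + s_start,
                                 _split(seg, n_seg, slen))
        else:
            if s0 + elen > recording.n_samples:
                logger.warning("epoch %r truncated; dropped", lbl)
                continue
            seg = recording.data[:, s0:s0 + elen]
            out.epochs.append(Epoch(lbl, s0, _split(seg, n_seg, slen)))
    return out


def _split(seg: np.ndarray, n_seg: int, slen: int) -> np.ndarray:
    return np.stack([seg[:, i * slen:(i + 1) * slen] for i in range(n_seg)])


def _lowest_variance_window(block: np.ndarray, wlen: int,
                            hop: int | None = None) -> int | None:
    if block.shape[1] < wlen:
        return None
    hop = hop or max(1, wlen // 5)
    best, best_v = 0, np.inf
    for s0 in range(0, block.shape[1] - wlen + 1, hop):
        v = float(block[:, s0:s0 + wlen].var(axis=1).mean())
        if v < best_v:
            best, best_v = s0, v
    return best


# ---------------------------------------------------------------------------
# full stage chain

def preprocess_recording(
    recording: Recording,
    corr_threshold: float = 0.4,
    peripheral=montage.PERIPHERAL_DEFAULT,
    asr_window: float = 0.5,
    asr_k_sd: float = 3.0,
    epoch_len: float = 5.0,
    sub_len: float = 1.0,
    subject_id: str = "",
) -> tuple[EpochSet, dict]:
    """Run the full cleaning chain in the canonical order; returns a log dict."""
    log: dict = {}
    rec = highpass_filter(recording)
    report = detect_bad_channels(rec, corr_threshold=corr_threshold)
    log["bad_channels"] = report.rejected
    if report.rejected:
        if len(report.rejected) >= rec.n_channels - 1:
            warnings.warn("bad-channel rule rejected nearly all channels; "
                          "keeping montage", stacklevel=2)
        else:
            rec = rec.drop(report.rejected)
    rec = remove_peripheral_channels(rec, peripheral)
    calib = select_calibration(rec, duration=min(10.0, max(5.0, rec.duration / 4)))
    rec = asr_clean(rec, calib, window=asr_window, k_sd=asr_k_sd)
    rec = rereference_car(rec)
    epochs = segment_epochs(rec, epoch_len=epoch_len, sub_len=sub_len,
                            subject_id=subject_id)
    log["n_channels"] = rec.n_channels
    log["n_epochs"] = len(epochs.epochs)
    log["has_baseline"] = epochs.baseline is not None
    return epochs, log
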