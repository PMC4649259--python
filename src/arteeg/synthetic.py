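"""Synthetic EEG sessions and stimulus images with known ground truth.

The museum study's raw EEG is not publicly deposited, so every downstream
stage of this package is exercised against a generator whose directed
structure is known exactly. Channels are damped second-order oscillators
(a VAR(2) diagonal) and directed coupling is injected as off-diagonal lag-1
coefficients, optionally switched on and off on a schedule — the same model
family the connectivity stage fits, which closes the generator/detector loop.

Amplitudes are calibrated so clean traces span roughly ±50 µV, keeping the
artifact-related thresholds of the preprocessing stage meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import montage
from .recording import Recording


class StabilityError(ValueError):
    """Raised when a requested VAR process is not stable."""


# ---------------------------------------------------------------------------
# specs

@dataclass
class Coupling:
    """Directed lag-1 influence ``source -> target``.

    ``freq`` records the band the coupling is meant to act in (the source
    oscillator's frequency); the dynamic effect itself is the lag-1 gain.
    ``onset``/``offset`` (seconds) make the coupling time-varying; both
    ``None`` means always active.
    """

    source: int
    target: int
    gain: float
    freq: float = 10.0
    onset: float | None = None
    offset: float | None = None

    def active_at(self, t_s: float) -> bool:
        if self.onset is not None and t_s < self.onset:
            return False
        if self.offset is not None and t_s >= self.offset:
            return False
        return True


@dataclass
class ConnectivitySpec:
    """Ground-truth generating process for one recording.

    Each channel is a damped oscillator with pole radius ``damping`` at
    ``osc_freqs`` Hz, driven by white noise of SD ``noise_scale`` µV.
    """

    n_channels: int
    couplings: list[Coupling] = field(default_factory=list)
    osc_freqs: float | list[float] = 10.0
    damping: float | list[float] = 0.95
    noise_scale: float = 4.0

    def __post_init__(self) -> None:
        if np.isscalar(self.osc_freqs):
            self.osc_freqs = [float(self.osc_freqs)] * self.n_channels
        if np.isscalar(self.damping):
            self.damping = [float(self.damping)] * self.n_channels
        if len(self.osc_freqs) != self.n_channels or len(self.damping) != self.n_channels:
            raise ValueError("per-channel parameter length mismatch")
        for c in self.couplings:
            if not (0 <= c.source < self.n_channels and 0 <= c.target < self.n_channels):
                raise ValueError(f"coupling index out of range: {c}")
            if not np.isfinite(c.gain):
                raise ValueError(f"non-finite coupling gain: {c}")

    def lag_matrices(self, fs: float, active: list[Coupling]) -> tuple[np.ndarray, np.ndarray]:
        """(A1, A2) for the given set of active couplings at sampling rate fs."""
        n = self.n_channels
        a1 = np.zeros((n, n))
        a2 = np.zeros((n, n))
        for i in range(n):
            r = self.damping[i]
            a1[i, i] = 2.0 * r * np.cos(2 * np.pi * self.osc_freqs[i] / fs)
            a2[i, i] = -r * r
        for c in active:
            a1[c.target, c.source] += c.gain
        return a1, a2

    def change_points(self, duration: float) -> list[float]:
        pts = {0.0, float(duration)}
        for c in self.couplings:
            for edge in (c.onset, c.offset):
                if edge is not None and 0.0 < edge < duration:
                    pts.add(float(edge))
        return sorted(pts)

    def stability_report(self, fs: float, duration: float) -> list[dict]:
        """Spectral radius of the companion matrix for every coupling regime."""
        out = []
        pts = self.change_points(duration)
        n = self.n_channels
        for t0, t1 in zip(pts[:-1], pts[1:]):
            mid = 0.5 * (t0 + t1)
            active = [c for c in self.couplings if c.active_at(mid)]
            a1, a2 = self.lag_matrices(fs, active)
            companion = np.block([[a1, a2], [np.eye(n), np.zeros((n, n))]])
            rho = float(np.max(np.abs(np.linalg.eigvals(companion))))
            out.append({"start_s": t0, "end_s": t1, "spectral_radius": rho,
                        "stable": rho < 1.0})
        return out


@dataclass
class ArtifactPlan:
    """What to inject: blink bumps, slow drift, high-amplitude pops, a dead channel.

    ``blinks``: (time s, amplitude µV); applied to frontal channels.
    ``pops``: (channel index, time s, amplitude µV, width s).
    ``dead_channel``: index replaced by independent noise (decorrelated).
    """

    blinks: list[tuple[float, float]] = field(default_factory=list)
    blink_width_s: float = 0.3
    drift_amplitude: float = 0.0
    drift_period_s: float = 20.0
    pops: list[tuple[int, float, float, float]] = field(default_factory=list)
    dead_channel: int | None = None

    def is_empty(self) -> bool:
        return (not self.blinks and not self.pops and self.drift_amplitude == 0
                and self.dead_channel is None)


@dataclass
class PieceEpoch:
    piece_id: str
    class_label: str  # "complex" | "moderate"
    duration_s: float = 6.0


@dataclass
class SessionSpec:
    """One synthetic museum visit: baseline block then annotated piece epochs."""

    subject_id: str
    seed: int
    age: float = 27.0
    gender: str = "M"
    baseline_s: float = 60.0
    pieces: list[PieceEpoch] = field(default_factory=list)
    fs: float = 1000.0
    channels: tuple[str, ...] = montage.ACTICAP_32
    artifact_plan: ArtifactPlan | None = None
    gain_scale: float = 1.0       # group-level modulation hook (off by default)
    boost_scale: float = 1.0
    #: SD (µV) of a shared alpha-range background added identically to every
    #: channel. It emulates the strong common signal volume conduction puts on
    #: real scalp recordings — the correlation-based bad-channel rule depends
    #: on it — and the common average reference removes it exactly.
    background_scale: float = 20.0
    #: Per-channel SD (µV) the raw oscillator output is calibrated to before
    #: boosts and background are added; keeps clean traces within ±50 µV or so
    #: regardless of how sharply the oscillator chain resonates.
    amplitude_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.baseline_s <= 0:
            raise ValueError("baseline duration must be positive")
        for p in self.pieces:
            if p.duration_s <= 0:
                raise ValueError(f"epoch duration must be positive: {p}")


@dataclass
class GroundTruth:
    """Generator-side truth aligned with the emitted samples."""

    blocks: list[dict] = field(default_factory=list)          # start_s, end_s, gain_matrix
    epochs: list[dict] = field(default_factory=list)          # piece_id, class_label, start_s, end_s
    artifact_intervals: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# simulation

def simulate_mvar_eeg(
    spec: ConnectivitySpec,
    duration: float,
    fs: float,
    seed: int,
    ch_names: list[str] | None = None,
    burn_in: float = 1.0,
) -> tuple[Recording, GroundTruth]:
    """Realize the (possibly time-varying) VAR process of ``spec``.

    Deterministic given ``seed``. Raises :class:`StabilityError` with the full
    per-regime report when any coupling regime has companion spectral
    radius >= 1.
    """
    if fs <= 2 * max(list(spec.osc_freqs) + [c.freq for c in spec.couplings] + [0.0]):
        raise ValueError("fs must exceed twice the highest center frequency")
    report = spec.stability_report(fs, duration)
    if not all(r["stable"] for r in report):
        raise StabilityError(f"unstable VAR spec: {report}")

    n = spec.n_channels
    n_samples = int(round(duration * fs))
    n_burn = int(round(burn_in * fs))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n, n_burn + n_samples)) * spec.noise_scale

    pts = spec.change_points(duration)
    # per-sample regime index (burn-in runs under the first regime)
    regimes = []
    for t0, t1 in zip(pts[:-1], pts[1:]):
        mid = 0.5 * (t0 + t1)
        active = [c for c in spec.couplings if c.active_at(mid)]
        a1, a2 = spec.lag_matrices(fs, active)
        gain = np.zeros((n, n))
        for c in active:
            gain[c.target, c.source] += c.gain
        regimes.append({"start": int(round(t0 * fs)), "end": int(round(t1 * fs)),
                        "a1": a1, "a2": a2, "gain": gain,
                        "start_s": t0, "end_s": t1})

    x = np.zeros((n, n_burn + n_samples))
    a1, a2 = regimes[0]["a1"], regimes[0]["a2"]
    boundaries = {n_burn + r["start"]: r for r in regimes}
    for t in range(2, n_burn + n_samples):
        r = boundaries.get(t)
        if r is not None:
            a1, a2 = r["a1"], r["a2"]
        x[:, t] = a1 @ x[:, t - 1] + a2 @ x[:, t - 2] + noise[:, t]

    data = x[:, n_burn:]
    if ch_names is None:
        ch_names = [f"ch{i}" for i in range(n)]
    truth = GroundTruth(blocks=[
        {"start_s": r["start_s"], "end_s": r["end_s"], "gain_matrix": r["gain"]}
        for r in regimes
    ])
    return Recording(data, ch_names, fs), truth


def inject_artifacts(
    recording: Recording, plan: ArtifactPlan, seed: int
) -> tuple[Recording, list[dict]]:
    """Add blink-like frontal transients, drift, pops and/or a dead channel.

    Returns the contaminated copy plus the list of truth intervals. Intervals
    that overlap are merged with a warning.
    """
    rec = recording.copy()
    fs = rec.fs
    intervals: list[dict] = []
    rng = np.random.default_rng(seed)

    def _bump(width_samp: int) -> np.ndarray:
        # raised-cosine transient
        return 0.5 * (1 - np.cos(2 * np.pi * np.arange(width_samp) / width_samp))

    frontal = [i for i, ch in enumerate(rec.ch_names)
               if _is_frontal(ch)] or list(range(min(4, rec.n_channels)))

    for t_s, amp in plan.blinks:
        w = int(round(plan.blink_width_s * fs))
        s0 = int(round(t_s * fs))
        s1 = min(s0 + w, rec.n_samples)
        if s0 >= rec.n_samples:
            raise ValueError(f"blink at {t_s} s outside recording")
        shape = _bump(s1 - s0) * amp
        for rank, ci in enumerate(frontal):
            rec.data[ci, s0:s1] += shape * (1.0 - 0.15 * rank)
        intervals.append({"start_s": s0 / fs, "end_s": s1 / fs, "kind": "blink",
                          "channels": [rec.ch_names[i] for i in frontal]})

    if plan.drift_amplitude != 0.0:
        t = np.arange(rec.n_samples) / fs
        drift = plan.drift_amplitude * np.sin(2 * np.pi * t / plan.drift_period_s)
        rec.data += drift[None, :]
        intervals.append({"start_s": 0.0, "end_s": rec.duration, "kind": "drift",
                          "channels": list(rec.ch_names)})

    for ci, t_s, amp, width_s in plan.pops:
        w = max(2, int(round(width_s * fs)))
        s0 = int(round(t_s * fs))
        s1 = min(s0 + w, rec.n_samples)
        if s0 >= rec.n_samples:
            raise ValueError(f"pop at {t_s} s outside recording")
        rec.data[ci, s0:s1] += _bump(s1 - s0) * amp
        intervals.append({"start_s": s0 / fs, "end_s": s1 / fs, "kind": "pop",
                          "channels": [rec.ch_names[ci]]})

    if plan.dead_channel is not None:
        ci = plan.dead_channel
        sd = float(np.std(rec.data[ci])) or 1.0
        rec.data[ci] = rng.standard_normal(rec.n_samples) * sd
        intervals.append({"start_s": 0.0, "end_s": rec.duration, "kind": "dead",
                          "channels": [rec.ch_names[ci]]})

    merged = _merge_overlaps(intervals)
    if len(merged) < len(intervals):
        warnings.warn("overlapping artifact intervals merged", stacklevel=2)
    return rec, merged


def _is_frontal(ch: str) -> bool:
    try:
        return montage.split_label(ch)[0] in {"Fp", "AF", "F"}
    except ValueError:
        return False


def _merge_overlaps(intervals: list[dict]) -> list[dict]:
    out: list[dict] = []
    for iv in sorted(intervals, key=lambda d: (d["kind"], d["start_s"])):
        if out and out[-1]["kind"] == iv["kind"] and iv["start_s"] < out[-1]["end_s"] \
                and set(iv["channels"]) & set(out[-1]["channels"]):
            out[-1]["end_s"] = max(out[-1]["end_s"], iv["end_s"])
            out[-1]["channels"] = sorted(set(out[-1]["channels"]) | set(iv["channels"]))
        else:
            out.append(dict(iv))
    return out


# ---------------------------------------------------------------------------
# sessions

#: Directed coupling templates per stimulus class, as (source, target) labels.
#: Right->left cross-hemisphere pairs plus posterior->anterior pairs — the
#: effect structure the connectivity stage is designed to detect. The
#: template is chain-free (no channel is both a coupling target and a
#: source), so resonance-matched oscillators cannot cascade and blow up one
#: channel's variance relative to the rest of the montage.
CLASS_COUPLING_PAIRS: tuple[tuple[str, str], ...] = (
    ("F4", "F3"), ("CP6", "CP5"), ("P4", "P3"), ("O2", "O1"),   # R -> L
    ("Pz", "Fz"), ("Oz", "FC1"), ("Oz", "FC2"),                 # P -> A
)

#: Lag-1 gains per class on the template pairs. Baseline carries no coupling.
CLASS_GAINS: dict[str, float] = {"complex": 0.18, "moderate": 0.09, "baseline": 0.0}

#: Narrowband amplitude boosts per class: (band center Hz, channel labels, SD µV).
#: Occipital gamma and frontal delta are boosted, mirroring the bands and sites
#: that carry class information in this analysis.
CLASS_BOOSTS: dict[str, list[tuple[float, tuple[str, ...], float]]] = {
    "complex": [(40.0, ("O1", "Oz", "O2"), 6.0), (2.0, ("F3", "Fz", "F4"), 8.0)],
    "moderate": [(40.0, ("O1", "Oz", "O2"), 3.0), (2.0, ("F3", "Fz", "F4"), 4.0)],
    "baseline": [],
}


def _ar2_series(freq: float, fs: float, n: int, rng, r: float = 0.97) -> np.ndarray:
    """Unit-SD narrowband noise centered at ``freq`` Hz (damped AR(2))."""
    a1 = 2 * r * np.cos(2 * np.pi * freq / fs)
    a2 = -r * r
    e = rng.standard_normal(n + 500)
    x = np.zeros(n + 500)
    for t in range(2, n + 500):
        x[t] = a1 * x[t - 1] + a2 * x[t - 2] + e[t]
    x = x[500:]
    return x / (np.std(x) or 1.0)


def session_connectivity_spec(spec: SessionSpec) -> ConnectivitySpec:
    """Build the time-varying generating process for one session."""
    rng = np.random.default_rng(spec.seed)
    chs = list(spec.channels)
    n = len(chs)
    # per-channel alpha-range oscillators with deterministic jitter
    freqs = 10.0 + rng.uniform(-1.0, 1.0, size=n)
    couplings: list[Coupling] = []
    t0 = spec.baseline_s
    for p in spec.pieces:
        gain = CLASS_GAINS[p.class_label] * spec.gain_scale
        if gain != 0.0:
            for src, tgt in CLASS_COUPLING_PAIRS:
                if src in chs and tgt in chs:
                    couplings.append(Coupling(
                        chs.index(src), chs.index(tgt), gain,
                        freq=float(freqs[chs.index(src)]),
                        onset=t0, offset=t0 + p.duration_s))
        t0 += p.duration_s
    # damping 0.90: broad enough resonances that a coupled target's variance
    # stays within a factor of a few of its neighbors (amplitude calibration
    # then barely distorts the coupling coefficients)
    return ConnectivitySpec(n, couplings, osc_freqs=list(freqs),
                            damping=0.90, noise_scale=4.0)


def generate_session(spec: SessionSpec) -> tuple[Recording, GroundTruth]:
    """Baseline block followed by annotated piece-viewing epochs.

    Viewing epochs carry class-dependent elevated directed couplings and
    class-dependent narrowband amplitude boosts; the baseline block carries
    neither. Deterministic given ``spec.seed``.
    """
    conn = session_connectivity_spec(spec)
    duration = spec.baseline_s + sum(p.duration_s for p in spec.pieces)
    rec, truth = simulate_mvar_eeg(conn, duration, spec.fs, spec.seed,
                                   ch_names=list(spec.channels))

    # amplitude calibration: nominal coupling gains stay in the ground truth,
    # the realized traces are scaled channel-wise to a physiological SD
    sd = rec.data.std(axis=1, keepdims=True)
    rec.data *= spec.amplitude_sd / np.maximum(sd, 1e-12)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    if spec.background_scale > 0:
        bg = _ar2_series(10.0, spec.fs, rec.n_samples, rng) * spec.background_scale
        rec.data += bg[None, :]
    ann = [("baseline", 0)]
    t0 = spec.baseline_s
    for p in spec.pieces:
        s0 = int(round(t0 * spec.fs))
        s1 = int(round((t0 + p.duration_s) * spec.fs))
        ann.append((f"piece_{p.piece_id}", s0))
        for freq, sites, amp in CLASS_BOOSTS[p.class_label]:
            series_len = s1 - s0
            for site in sites:
                if site in rec.ch_names:
                    ci = rec.index_of(site)
                    rec.data[ci, s0:s1] += amp * spec.boost_scale * _ar2_series(
                        freq, spec.fs, series_len, rng)
        truth.epochs.append({"piece_id": p.piece_id, "class_label": p.class_label,
                             "start_s": t0, "end_s": t0 + p.duration_s})
        t0 += p.duration_s
    rec.annotations = sorted(ann, key=lambda a: a[1])
    rec = Recording(rec.data, rec.ch_names, rec.fs, rec.annotations)

    if spec.artifact_plan is not None and not spec.artifact_plan.is_empty():
        rec, intervals = inject_artifacts(rec, spec.artifact_plan,
                                          seed=spec.seed + 7)
        truth.artifact_intervals = intervals
    return rec, truth


# ---------------------------------------------------------------------------
# stimulus images

def generate_synthetic_images(class_label: str, size: int = 128, seed: int = 0) -> np.ndarray:
    """One 8-bit RGB stimulus image of controlled visual complexity.

    ``complex``  — dense multi-orientation gratings, broad luminance spread;
    ``moderate`` — sparse low-contrast smooth structure;
    ``baseline`` — near-uniform bright field (a white wall) with sensor noise.
    """
    if size < 64:
        raise ValueError("size must be at least 64 pixels")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    if class_label == "baseline":
        gray = 235.0 + rng.normal(0.0, 2.0, (size, size))
    elif class_label == "moderate":
        # sparse low-contrast structure in a consistent layout: a central
        # shaded region and one lighter accent, amplitudes jittered per seed
        gray = np.full((size, size), 130.0)
        dip = -(35.0 + rng.uniform(0.0, 12.0))
        bump = 18.0 + rng.uniform(0.0, 8.0)
        c = size / 2
        gray += dip * np.exp(-((xx - c) ** 2 + (yy - c) ** 2)
                             / (2 * (0.22 * size) ** 2))
        gray += bump * np.exp(-((xx - 0.75 * size) ** 2 + (yy - 0.3 * size) ** 2)
                              / (2 * (0.12 * size) ** 2))
        gray += rng.normal(0.0, 2.0, (size, size))
    elif class_label == "complex":
        gray = np.full((size, size), 120.0)
        for _ in range(6):
            theta = rng.uniform(0, np.pi)
            f = rng.uniform(0.04, 0.25)
            phase = rng.uniform(0, 2 * np.pi)
            gray += 25.0 * np.sin(
                2 * np.pi * f * (xx * np.cos(theta) + yy * np.sin(theta)) + phase)
        gray += rng.normal(0.0, 5.0, (size, size))
    else:
        raise ValueError(f"unknown class label {class_label!r}")

    gray = np.clip(gray, 0, 255)
    # slight channel tints keep the image genuinely RGB without moving luminance
    tints = 1.0 + rng.uniform(-0.03, 0.03, 3)
    img = np.clip(gray[:, :, None] * tints[None, None, :], 0, 255)
    return img.astype(np.uint8)
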