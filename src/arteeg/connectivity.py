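"""Time-varying directed connectivity: Kalman-filtered MVAAR and the ADTF.

The signal model is a multivariate adaptive autoregressive (MVAAR) process

    X(t) = sum_{i=1..p} Lambda(i,t) X(t-i) + E(t)

whose time-varying coefficient matrices are tracked with a Kalman filter
(random-walk state over the coefficients). Fourier-transforming the
coefficients at each time point gives Lambda(f,t); its inverse is the
transfer matrix H(f,t), and the adaptive directed transfer function

    gamma^2(i,j,f,t) = |H_ij(f,t)|^2 / sum_m |H_im(f,t)|^2

quantifies the normalized directed influence of source channel j on target
channel i per frequency and time. Rows of gamma^2 sum to one by
construction.

Pattern-level statistics collect supra-threshold coefficients over the six
directed region patterns (anterior<->posterior, left<->right and the two
within-hemisphere patterns) and compare viewing vs. baseline or subject
groups with rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import montage
from .features import BandDefinition

logger = logging.getLogger(__name__)

#: Default analysis grid, Hz.
DEFAULT_FREQS = np.arange(1.0, 51.0)

#: Default supra-threshold cut on gamma^2.
DEFAULT_THRESHOLD = 0.3


# ---------------------------------------------------------------------------
# model fitting

@dataclass
class MVAARModel:
    """Time-varying VAR coefficients. ``coeffs[t]`` is (n, n*p): [A1 ... Ap]."""

    coeffs: np.ndarray
    order: int
    fs: float
    ch_names: list[str]
    update_coeff: float
    innovation_var: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]

    def mean_coeffs(self, discard_frac: float = 0.5) -> np.ndarray:
        """Time-averaged (n, n*p) coefficients over the converged tail."""
        t0 = int(self.n_samples * discard_frac)
        return self.coeffs[t0:].mean(axis=0)


class KalmanDivergenceError(RuntimeError):
    pass


def decimate_signal(data: np.ndarray, fs: float, target_fs: float = 250.0
                    ) -> tuple[np.ndarray, float]:
    """Anti-aliased integer-factor decimation before model fitting."""
    q = int(round(fs / target_fs))
    if q <= 1:
        return np.asarray(data, dtype=float), fs
    out = signal.decimate(np.asarray(data, dtype=float), q, axis=-1,
                          zero_phase=True)
    return out, fs / q


def fit_mvaar_kalman(
    data: np.ndarray,
    fs: float,
    p: int = 5,
    update_coeff: float = 1e-3,
    ch_names: list[str] | None = None,
    seed: int | None = None,
) -> MVAARModel:
    """Track time-varying VAR(p) coefficients with a Kalman filter.

    The state is the stacked coefficient matrix C = [A1 ... Ap] under a
    random-walk model realized as covariance forgetting: after every
    measurement update the (measurement-noise-normalized) state covariance is
    inflated by 1/(1 - ``update_coeff``), which sets how fast the
    coefficients may drift — the effective memory is about
    1/``update_coeff`` samples. The innovation variance is tracked with an
    exponentially weighted estimate for diagnostics.

    ``seed`` is accepted for interface symmetry; the filter itself is
    deterministic.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be (n_channels >= 2, n_samples)")
    n, t_len = x.shape
    if t_len <= 10 * p:
        raise ValueError("epoch too short for the requested model order")
    if not 0 < update_coeff < 1:
        raise ValueError("update_coeff must lie in (0, 1)")
    m = n * p
    c = np.zeros((n, m))
    pmat = np.eye(m)
    coeffs = np.zeros((t_len, n, m))
    innov = np.zeros(n)
    forget = 1.0 - update_coeff

    for t in range(p, t_len):
        z = x[:, t - p:t][:, ::-1].reshape(-1, order="F")  # [x(t-1); ...; x(t-p)]
        pz = pmat @ z
        denom = float(z @ pz) + 1.0
        k = pz / denom
        err = x[:, t] - c @ z
        c = c + np.outer(err, k)
        pmat = (pmat - np.outer(k, pz)) / forget
        tr = float(np.trace(pmat))
        if not np.isfinite(tr) or tr > 1e14:
            raise KalmanDivergenceError(
                f"state covariance diverged at sample {t} (trace {tr:.3g}); "
                f"update_coeff={update_coeff}, p={p}")
        innov = (1 - update_coeff) * innov + update_coeff * err ** 2
        coeffs[t] = c
    coeffs[:p] = coeffs[p]
    return MVAARModel(coeffs=coeffs, order=p, fs=fs,
                      ch_names=list(ch_names or (f"ch{i}" for i in range(n))),
                      update_coeff=update_coeff, innovation_var=innov)


def _z_lag_stack(x: np.ndarray, t: int, p: int) -> np.ndarray:  # test hook
    return x[:, t - p:t][:, ::-1].reshape(-1, order="F")


def least_squares_var(data: np.ndarray, p: int) -> np.ndarray:
    """Stationary least-squares VAR(p) fit, (n, n*p); the classic estimate."""
    x = np.asarray(data, dtype=float)
    n, t_len = x.shape
    zs = np.stack([_z_lag_stack(x, t, p) for t in range(p, t_len)])
    y = x[:, p:].T
    coef, *_ = np.linalg.lstsq(zs, y, rcond=None)
    return coef.T


# ---------------------------------------------------------------------------
# ADTF

@dataclass
class ADTFTensor:
    """gamma^2(target i, source j, frequency, time), rows normalized to 1."""

    gamma2: np.ndarray          # (n, n, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray           # seconds, relative to epoch start
    ch_names: list[str]
    regularized: bool = False

    def band_sel(self, band: BandDefinition) -> np.ndarray:
        sel = (self.freqs >= band.low) & (self.freqs <= band.high)
        if not np.any(sel):
            raise ValueError(f"band {band.name} outside the frequency grid")
        return sel


def adtf(model: MVAARModel, freqs: np.ndarray = DEFAULT_FREQS,
         time_step: float = 0.01) -> ADTFTensor:
    """Adaptive directed transfer function of a fitted MVAAR model.

    Coefficients are evaluated on a decimated time grid (default every
    10 ms). A numerically singular Lambda(f,t) is inverted with a
    pseudo-inverse and the tensor flagged ``regularized``.
    """
    freqs = np.asarray(freqs, dtype=float)
    n, p = model.n_channels, model.order
    dt = 1.0 / model.fs
    step = max(1, int(round(time_step * model.fs)))
    t_idx = np.arange(p, model.n_samples, step)

    # e^{-i 2 pi f dt k} for k = 1..p  -> (n_freqs, p)
    phases = np.exp(-2j * np.pi * np.outer(freqs, dt * np.arange(1, p + 1)))
    # stacked coefficients: C[:, k*n + c] -> a_lags[t, i, k, c]
    a_lags = model.coeffs[t_idx].reshape(len(t_idx), n, p, n)
    # Lambda(f,t) = I - sum_k A_k(t) e^{-i 2 pi f dt k}
    lam = np.einsum("fk,tikc->tfic", phases, a_lags)
    np.negative(lam, out=lam)
    lam[:, :, np.arange(n), np.arange(n)] += 1.0
    regularized = False
    try:
        h = np.linalg.inv(lam)
    except np.linalg.LinAlgError:
        h = np.empty_like(lam)
        for ti in range(lam.shape[0]):
            for fi in range(lam.shape[1]):
                try:
                    h[ti, fi] = np.linalg.inv(lam[ti, fi])
                except np.linalg.LinAlgError:
                    h[ti, fi] = np.linalg.pinv(lam[ti, fi])
                    regularized = True
    del lam
    power = np.abs(h)                                 # (t, f, i, j)
    del h
    np.multiply(power, power, out=power)
    power /= power.sum(axis=3, keepdims=True)
    gamma2 = np.moveaxis(power, (2, 3, 1, 0), (0, 1, 2, 3))
    times = t_idx / model.fs
    return ADTFTensor(gamma2=gamma2, freqs=freqs, times=times,
                      ch_names=list(model.ch_names), regularized=regularized)


def epoch_adtf(data: np.ndarray, fs: float, ch_names: list[str],
               p: int = 5, update_coeff: float = 1e-3,
               target_fs: float = 250.0,
               freqs: np.ndarray = DEFAULT_FREQS,
               time_step: float = 0.01) -> ADTFTensor:
    """Decimate -> Kalman MVAAR -> ADTF, the standard per-epoch chain."""
    dec, fs_dec = decimate_signal(data, fs, target_fs)
    model = fit_mvaar_kalman(dec, fs_dec, p=p, update_coeff=update_coeff,
                             ch_names=ch_names)
    return adtf(model, freqs=freqs, time_step=time_step)


# ---------------------------------------------------------------------------
# patterns

@dataclass(frozen=True)
class PatternDefinition:
    name: str
    pairs: tuple[tuple[str, str], ...]   # (source, target) labels


PATTERN_NAMES = ("A->P", "P->A", "L->R", "R->L", "L->L", "R->R")


def define_patterns(labels) -> dict[str, PatternDefinition]:
    """The six directed region patterns over the retained montage.

    Anterior = frontal/fronto-central rows; posterior = centro-parietal,
    parietal and occipital rows; the central row belongs to neither. Left =
    odd-numbered sites, right = even-numbered; midline (z) channels are
    excluded from the lateral patterns. Every ordered cross product is
    emitted, without self-pairs.
    """
    labels = list(labels)
    for ch in labels:
        montage.split_label(ch)  # raises on unknown label shapes
    anterior = [ch for ch in labels if montage.is_anterior(ch)]
    posterior = [ch for ch in labels if montage.is_posterior(ch)]
    left = [ch for ch in labels if montage.is_left(ch)]
    right = [ch for ch in labels if montage.is_right(ch)]

    def cross(src, tgt):
        return tuple((s, t) for s in src for t in tgt if s != t)

    return {
        "A->P": PatternDefinition("A->P", cross(anterior, posterior)),
        "P->A": PatternDefinition("P->A", cross(posterior, anterior)),
        "L->R": PatternDefinition("L->R", cross(left, right)),
        "R->L": PatternDefinition("R->L", cross(right, left)),
        "L->L": PatternDefinition("L->L", cross(left, left)),
        "R->R": PatternDefinition("R->R", cross(right, right)),
    }


@dataclass
class PatternSample:
    """Concatenated supra-threshold gamma^2 values for one (pattern, band)."""

    values: np.ndarray
    pattern: str
    band: str
    threshold: float
    n_pairs: int = 0
    meta: dict = field(default_factory=dict)


def pattern_samples(tensor: ADTFTensor, band: BandDefinition,
                    pattern: PatternDefinition,
                    threshold: float = DEFAULT_THRESHOLD) -> PatternSample:
    """Collect in-band gamma^2 over all pattern pairs and time points, keep
    values above ``threshold``. An empty result is a valid (empty) sample."""
    sel = tensor.band_sel(band)
    idx = {ch: i for i, ch in enumerate(tensor.ch_names)}
    chunks = []
    n_pairs = 0
    for src, tgt in pattern.pairs:
        if src not in idx or tgt not in idx:
            logger.info("pattern %s: pair %s->%s missing from montage",
                        pattern.name, src, tgt)
            continue
        n_pairs += 1
        chunks.append(tensor.gamma2[idx[tgt], idx[src], sel, :].ravel())
    vals = np.concatenate(chunks) if chunks else np.empty(0)
    return PatternSample(values=vals[vals > threshold], pattern=pattern.name,
                         band=band.name, threshold=threshold, n_pairs=n_pairs)


def pattern_mean_strength(tensor: ADTFTensor, band: BandDefinition,
                          pattern: PatternDefinition) -> float:
    """Mean in-band gamma^2 over a pattern's pairs (no thresholding).

    One number per epoch; used as the per-epoch observation in the
    rank-sum condition and group contrasts, where the raw concatenated
    values would be heavily autocorrelated.
    """
    sel = tensor.band_sel(band)
    idx = {ch: i for i, ch in enumerate(tensor.ch_names)}
    vals = [tensor.gamma2[idx[tgt], idx[src], sel, :].mean()
            for src, tgt in pattern.pairs if src in idx and tgt in idx]
    return float(np.mean(vals)) if vals else np.nan


# ---------------------------------------------------------------------------
# statistics

def compare_conditions(viewing: PatternSample | np.ndarray,
                       baseline: PatternSample | np.ndarray,
                       bins: int = 20) -> dict:
    """Rank-sum comparison of viewing vs. baseline coefficient samples.

    One-sided (viewing greater, the directional claim) and two-sided
    p values, medians, rank-biserial effect size, and normalized histograms
    on [0, 1]. Empty samples are flagged incomparable rather than raised.
    """
    v = viewing.values if isinstance(viewing, PatternSample) else np.asarray(viewing)
    b = baseline.values if isinstance(baseline, PatternSample) else np.asarray(baseline)
    report: dict = {"n_viewing": int(v.size), "n_baseline": int(b.size)}
    if v.size == 0 or b.size == 0:
        report["comparable"] = False
        return report
    u, p_greater = stats.mannwhitneyu(v, b, alternative="greater")
    _, p_two = stats.mannwhitneyu(v, b, alternative="two-sided")
    edges = np.linspace(0.0, 1.0, bins + 1)
    report.update({
        "comparable": True,
        "median_viewing": float(np.median(v)),
        "median_baseline": float(np.median(b)),
        "u_statistic": float(u),
        "p_one_sided": float(p_greater),
        "p_two_sided": float(p_two),
        "rank_biserial": float(2.0 * u / (v.size * b.size) - 1.0),
        "hist_viewing": np.histogram(v, bins=edges)[0] / v.size,
        "hist_baseline": np.histogram(b, bins=edges)[0] / b.size,
        "hist_edges": edges,
    })
    return report


def count_strong_connections(tensor: ADTFTensor, band: BandDefinition,
                             patterns: dict[str, PatternDefinition],
                             threshold: float = DEFAULT_THRESHOLD) -> dict:
    """Supra-threshold (bin, time) counts per ordered electrode pair.

    Returns per-pattern count tables and, per pattern, the source channel
    contributing the most connections.
    """
    sel = tensor.band_sel(band)
    idx = {ch: i for i, ch in enumerate(tensor.ch_names)}
    out: dict = {}
    for name, pat in patterns.items():
        rows = []
        for src, tgt in pat.pairs:
            if src not in idx or tgt not in idx:
                continue
            vals = tensor.gamma2[idx[tgt], idx[src], sel, :]
            rows.append({"source": src, "target": tgt,
                         "count": int(np.sum(vals > threshold))})
        counts = pd.DataFrame(rows, columns=["source", "target", "count"])
        by_src = counts.groupby("source")["count"].sum() if len(counts) else pd.Series(dtype=int)
        top = by_src.idxmax() if len(by_src) and by_src.max() > 0 else None
        out[name] = {"counts": counts, "top_source": top}
    return out


def pattern_timecourse(tensor: ADTFTensor, band: BandDefinition,
                       patterns: dict[str, PatternDefinition],
                       window: float = 1.0) -> pd.DataFrame:
    """Mean in-band gamma^2 per pattern per non-overlapping time window.

    A 5-s epoch yields exactly five 1-s windows; a partial trailing window
    is dropped with a log message.
    """
    sel = tensor.band_sel(band)
    idx = {ch: i for i, ch in enumerate(tensor.ch_names)}
    t_end = tensor.times[-1] + (tensor.times[1] - tensor.times[0]
                                if len(tensor.times) > 1 else 0)
    n_win = int(np.floor(round(t_end / window, 6)))
    if t_end / window - n_win > 1e-6:
        logger.info("partial trailing window (%.3f s) dropped",
                    t_end - n_win * window)
    if n_win < 1:
        raise ValueError("epoch shorter than one window")
    rows = {}
    for name, pat in patterns.items():
        means = []
        for w in range(n_win):
            tsel = (tensor.times >= w * window) & (tensor.times < (w + 1) * window)
            vals = [tensor.gamma2[idx[tgt], idx[src]][np.ix_(sel, tsel)].mean()
                    for src, tgt in pat.pairs if src in idx and tgt in idx]
            means.append(float(np.mean(vals)) if vals else np.nan)
        rows[name] = means
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"window_{w}" for w in range(n_win)])


def group_contrast(samples: dict[str, dict], alpha: float = 0.05) -> pd.DataFrame:
    """Rank-sum contrasts between two groups, per (pattern, band) key.

    ``samples`` maps group name -> {key -> PatternSample or value array}.
    Groups with fewer than two values for a key are reported descriptively
    (flagged, no test).
    """
    groups = list(samples)
    if len(groups) != 2:
        raise ValueError("group_contrast expects exactly two groups")
    ga, gb = groups
    keys = sorted(set(samples[ga]) & set(samples[gb]), key=str)
    rows = []
    for key in keys:
        va = _values(samples[ga][key])
        vb = _values(samples[gb][key])
        row = {"key": str(key), "group_a": ga, "group_b": gb,
               "n_a": va.size, "n_b": vb.size,
               "mean_a": float(va.mean()) if va.size else np.nan,
               "mean_b": float(vb.mean()) if vb.size else np.nan}
        if va.size < 2 or vb.size < 2:
            row.update({"p_two_sided": np.nan, "significant": False,
                        "descriptive_only": True})
        else:
            _, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            row.update({"p_two_sided": float(p), "significant": bool(p < alpha),
                        "descriptive_only": False})
        rows.append(row)
    return pd.DataFrame(rows)


def _values(sample) -> np.ndarray:
    if isinstance(sample, PatternSample):
        return np.asarray(sample.values, dtype=float)
    return np.asarray(sample, dtype=float)
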