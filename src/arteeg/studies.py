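"""Desk-scale study designs built on the generator/detector closed loop.

These helpers wire the synthetic generator to the analysis stages at sizes a
single CPU handles in minutes: coefficient-recovery and directionality
checks for the Kalman-ADTF chain, Monte-Carlo calibration of the
viewing-vs-baseline rank-sum contrast, and the end-to-end three-class
clustering study (features -> mRMR -> US-ELM -> GMM).

For the rank-sum calibration each condition contributes independent epochs
and each epoch is reduced to one observation (its mean in-band pattern
coefficient). Concatenated per-bin samples from a single epoch are heavily
autocorrelated — the Kalman coefficients drift slowly — and carry no nominal
test level; independent epochs restore it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cluster as cl
from . import connectivity as conn
from . import features as ft
from . import montage, preprocess, synthetic

#: Small lateralized montage for fast connectivity Monte Carlos.
SMALL_MONTAGE: tuple[str, ...] = ("F3", "F4", "O1", "O2")

ALPHA_BAND = ft.BANDS[2]


# ---------------------------------------------------------------------------
# Kalman / ADTF checks

def stationary_var2_recovery(seed: int = 0, duration: float = 5.0,
                             fs: float = 250.0) -> dict:
    """Fit a stationary 3-channel VAR(2); compare Kalman vs truth and vs a
    least-squares oracle. Returns the coefficient RMSEs."""
    spec = synthetic.ConnectivitySpec(
        3,
        couplings=[synthetic.Coupling(0, 1, 0.3, freq=10.0),
                   synthetic.Coupling(1, 2, 0.25, freq=10.0)],
        osc_freqs=[9.0, 10.0, 11.0], damping=0.90, noise_scale=1.0)
    rec, _ = synthetic.simulate_mvar_eeg(spec, duration, fs, seed)
    a1, a2 = spec.lag_matrices(fs, spec.couplings)
    truth = np.concatenate([a1, a2], axis=1)

    model = conn.fit_mvaar_kalman(rec.data, fs, p=2, update_coeff=1e-3)
    est = model.mean_coeffs(discard_frac=0.5)
    ls = conn.least_squares_var(rec.data, p=2)
    return {
        "rmse_kalman_truth": float(np.sqrt(np.mean((est - truth) ** 2))),
        "rmse_ls_truth": float(np.sqrt(np.mean((ls - truth) ** 2))),
        "rmse_kalman_ls": float(np.sqrt(np.mean((est - ls) ** 2))),
        "truth": truth, "kalman": est, "least_squares": ls,
    }


def directionality_ratio(seed: int = 0, gain: float = 0.4,
                         duration: float = 5.0, fs: float = 250.0) -> dict:
    """Unidirectional 10 Hz coupling 1->2: alpha-band gamma^2 asymmetry."""
    spec = synthetic.ConnectivitySpec(
        2, couplings=[synthetic.Coupling(0, 1, gain, freq=10.0)],
        osc_freqs=10.0, damping=0.92, noise_scale=1.0)
    rec, _ = synthetic.simulate_mvar_eeg(spec, duration, fs, seed)
    tensor = conn.epoch_adtf(rec.data, fs, rec.ch_names, p=2,
                             target_fs=fs)
    sel = tensor.band_sel(ALPHA_BAND)
    forward = float(np.median(tensor.gamma2[1, 0, sel, :]))
    reverse = float(np.median(tensor.gamma2[0, 1, sel, :]))
    return {"forward": forward, "reverse": reverse,
            "ratio": forward / max(reverse, 1e-12), "tensor": tensor}


# ---------------------------------------------------------------------------
# condition-contrast Monte Carlo

def _condition_epoch(gain: float, seed: int, duration: float, fs: float,
                     channels=SMALL_MONTAGE) -> np.ndarray:
    """One epoch on the small montage with right->left coupling ``gain``."""
    chs = list(channels)
    couplings = []
    if gain != 0.0:
        for src, tgt in (("F4", "F3"), ("O2", "O1")):
            couplings.append(synthetic.Coupling(chs.index(src), chs.index(tgt),
                                                gain, freq=10.0))
    spec = synthetic.ConnectivitySpec(len(chs), couplings, osc_freqs=10.0,
                                      damping=0.92, noise_scale=1.0)
    rec, _ = synthetic.simulate_mvar_eeg(spec, duration, fs, seed,
                                         ch_names=chs)
    return rec.data


def condition_contrast_replicate(
    viewing_gain: float, baseline_gain: float, seed: int,
    n_epochs: int = 10, duration: float = 3.0, fs: float = 250.0,
    pattern: str = "R->L", band: ft.BandDefinition = ALPHA_BAND,
    p: int = 2,
) -> dict:
    """One replicate: independent epochs per condition, one mean in-band
    pattern coefficient per epoch, one-sided rank-sum viewing > baseline."""
    chs = list(SMALL_MONTAGE)
    patterns = conn.define_patterns(chs)
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * n_epochs)
    # gamma^2 is computed per frequency bin, so evaluating only the in-band
    # grid is exact and keeps the Monte Carlo fast
    freqs = np.arange(np.ceil(band.low), np.floor(band.high) + 1)

    def _strengths(gain: float, offset: int) -> np.ndarray:
        out = np.empty(n_epochs)
        for e in range(n_epochs):
            data = _condition_epoch(gain, int(seeds[offset + e] % (2 ** 31)),
                                    duration, fs)
            tensor = conn.epoch_adtf(data, fs, chs, p=p, target_fs=fs,
                                     freqs=freqs, time_step=0.02)
            out[e] = conn.pattern_mean_strength(tensor, band, patterns[pattern])
        return out

    v = _strengths(viewing_gain, 0)
    b = _strengths(baseline_gain, n_epochs)
    from scipy.stats import mannwhitneyu
    _, p_one = mannwhitneyu(v, b, alternative="greater")
    return {"p_one_sided": float(p_one), "viewing": v, "baseline": b}


def null_rejection_rate(n_reps: int = 200, seed: int = 0, alpha: float = 0.05,
                        **kwargs) -> dict:
    """Type-I error of the condition contrast under a null generator."""
    ss = np.random.SeedSequence([seed, 42])
    seeds = ss.generate_state(n_reps)
    pvals = np.array([
        condition_contrast_replicate(0.0, 0.0, int(s % (2 ** 31)), **kwargs)["p_one_sided"]
        for s in seeds])
    return {"rejection_rate": float(np.mean(pvals < alpha)), "p_values": pvals}


def boosted_detection(n_reps: int = 20, seed: int = 0, gain: float = 0.35,
                      **kwargs) -> dict:
    """Power of the contrast with an elevated right->left viewing gain."""
    ss = np.random.SeedSequence([seed, 43])
    seeds = ss.generate_state(n_reps)
    pvals = np.array([
        condition_contrast_replicate(gain, 0.0, int(s % (2 ** 31)), **kwargs)["p_one_sided"]
        for s in seeds])
    return {"p_values": pvals, "all_significant": bool(np.all(pvals < 0.05)),
            "max_p": float(pvals.max())}


# ---------------------------------------------------------------------------
# end-to-end clustering study

#: Piece-to-class layout mirroring the analyzed exhibit structure: two
#: visually complex pieces, four moderate ones, plus the blank-wall baseline.
DEFAULT_PIECES: tuple[tuple[str, str], ...] = (
    ("1", "complex"), ("2", "moderate"), ("4", "complex"),
    ("5", "moderate"), ("6", "moderate"), ("8", "moderate"),
)


def clustering_sessions(n_subjects: int = 20, seed: int = 0,
                        baseline_s: float = 12.0,
                        piece_duration_s: float = 6.0,
                        pieces=DEFAULT_PIECES) -> list[preprocess.EpochSet]:
    """Simulate the cohort on the retained montage and segment it.

    Sessions run on the 20-channel retained montage directly (no artifacts
    injected), re-referenced and segmented exactly as the cleaning chain
    would emit them.
    """
    ss = np.random.SeedSequence([seed, 7])
    seeds = ss.generate_state(n_subjects)
    epoch_sets = []
    for si in range(n_subjects):
        spec = synthetic.SessionSpec(
            subject_id=f"S{si:02d}", seed=int(seeds[si] % (2 ** 31)),
            baseline_s=baseline_s,
            pieces=[synthetic.PieceEpoch(pid, lbl, piece_duration_s)
                    for pid, lbl in pieces],
            channels=montage.RETAINED_20)
        rec, _ = synthetic.generate_session(spec)
        rec = preprocess.rereference_car(rec)
        epoch_sets.append(preprocess.segment_epochs(rec, subject_id=spec.subject_id))
    return epoch_sets


def clustering_feature_table(n_subjects: int = 20, seed: int = 0,
                             domain: str = "time",
                             pieces=DEFAULT_PIECES,
                             **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    classes = {f"piece_{pid}": lbl for pid, lbl in pieces}
    classes["baseline"] = "baseline"
    epoch_sets = clustering_sessions(n_subjects=n_subjects, seed=seed, **kwargs)
    return ft.build_feature_table(epoch_sets, classes, domain=domain)


def end_to_end_clustering(seed: int = 0, n_subjects: int = 20,
                          n_iter: int = 100, k: int = 50,
                          method: str = "GMM",
                          table: pd.DataFrame | None = None,
                          meta: pd.DataFrame | None = None) -> dict:
    """features -> mRMR(k) -> US-ELM -> GMM, repeated over random hidden
    layers; reports the Rand-index and agreement-accuracy distributions."""
    if table is None:
        table, meta = clustering_feature_table(n_subjects=n_subjects, seed=seed)
    labels = table["class_label"].to_numpy()
    ranking = cl.mrmr_select(table, k=k)
    x = table[ranking.top].to_numpy(dtype=float)

    params = cl.ELMParams(n_hidden=200, n_components=3, n_neighbors=9, reg=1.0)
    ss = np.random.SeedSequence([seed, 11])
    seeds = ss.generate_state(2 * n_iter)
    rand = np.empty(n_iter)
    agree = np.empty(n_iter)
    for it in range(n_iter):
        emb = cl.uselm_embed(x, params, seed=int(seeds[2 * it] % (2 ** 31)))
        res = cl.cluster_embedding(emb, labels, method=method,
                                   seed=int(seeds[2 * it + 1] % (2 ** 31)))
        rand[it] = res.rand_index
        agree[it] = res.agreement_accuracy
    return {"mean_rand": float(rand.mean()), "mean_agreement": float(agree.mean()),
            "rand": rand, "agreement": agree, "ranking": ranking,
            "table": table, "meta": meta, "params": params}
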