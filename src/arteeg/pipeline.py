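"""Study orchestration: configuration, fixtures and the full analysis flow.

``run_study`` executes the complete analogue of the museum analysis over a
set of synthetic sessions: simulate -> preprocess -> image classes ->
features -> selection/clustering -> connectivity -> contrasts, with
per-stage logging and a machine-readable report. ``make_fixture`` persists a
synthetic study to disk (BrainVision triplets, stimulus images, ground-truth
sidecars) for the file-based entry points.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import connectivity as conn
from . import features as ft
from . import images as im
from . import io, montage, preprocess, studies, synthetic

logger = logging.getLogger(__name__)

_KNOWN_BANDS = {b.name for b in ft.BANDS}


@dataclass
class StudyConfig:
    """All tunable parameters of the study flow; round-trips through YAML."""

    # cohort / generator
    n_subjects: int = 20
    baseline_s: float = 60.0
    piece_duration_s: float = 6.0
    pieces: list = field(default_factory=lambda: [list(p) for p in studies.DEFAULT_PIECES])
    image_size: int = 128
    # preprocessing
    highpass_cutoff: float = 0.1
    filter_order: int = 8
    corr_threshold: float = 0.4
    bad_window_s: float = 2.0
    peripheral: list = field(default_factory=lambda: list(montage.PERIPHERAL_DEFAULT))
    asr_window_s: float = 0.5
    asr_k_sd: float = 3.0
    epoch_len_s: float = 5.0
    sub_len_s: float = 1.0
    # features / clustering
    feature_domain: str = "time"
    mrmr_k: int = 50
    n_classes: int = 3
    n_iterations: int = 100
    n_hidden: int = 200
    elm_grid: dict = field(default_factory=lambda: {
        "n_components": [2, 3], "n_neighbors": [5, 9], "reg": [0.1, 1.0]})
    # connectivity
    var_order: int = 5
    update_coeff: float = 1e-3
    adtf_threshold: float = 0.3
    target_fs: float = 250.0
    connectivity_bands: list = field(default_factory=lambda: ["delta", "alpha", "gamma"])
    # bookkeeping
    seed: int = 0

    def validate(self) -> None:
        for b in self.connectivity_bands:
            if b not in _KNOWN_BANDS:
                raise ValueError(f"unknown band name {b!r}; known: {sorted(_KNOWN_BANDS)}")
        if self.feature_domain not in ("time", "frequency", "wavelet"):
            raise ValueError(f"unknown feature domain {self.feature_domain!r}")
        if self.mrmr_k < 1 or self.n_classes < 1:
            raise ValueError("mrmr_k and n_classes must be positive")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False),
                        encoding="utf-8")
        return path

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update(overrides)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def tiny(cls, seed: int = 0) -> "StudyConfig":
        """Minutes-of-data profile used by the test suite."""
        return cls(n_subjects=4, baseline_s=12.0,
                   pieces=[["1", "complex"], ["2", "moderate"], ["4", "complex"]],
                   n_iterations=6, seed=seed)


def _subject_specs(config: StudyConfig) -> list[synthetic.SessionSpec]:
    ss = np.random.SeedSequence([config.seed, 2027])
    seeds = ss.generate_state(config.n_subjects)
    rng = np.random.default_rng(seeds[0])
    specs = []
    for si in range(config.n_subjects):
        # 16 male / 4 female and a 20-50 y age range echo the analyzed cohort
        gender = "F" if si % 5 == 4 else "M"
        age = float(rng.uniform(20, 50))
        specs.append(synthetic.SessionSpec(
            subject_id=f"S{si:02d}", seed=int(seeds[si] % (2 ** 31)),
            age=age, gender=gender, baseline_s=config.baseline_s,
            pieces=[synthetic.PieceEpoch(pid, lbl, config.piece_duration_s)
                    for pid, lbl in config.pieces],
            channels=montage.ACTICAP_32))
    return specs


def make_fixture(outdir: str | Path, profile: str = "tiny", seed: int = 0,
                 overwrite: bool = False) -> dict:
    """Persist a synthetic study to disk: recordings, images, ground truth."""
    config = StudyConfig.tiny(seed) if profile == "tiny" else StudyConfig(seed=seed)
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists; pass overwrite=True")
    (outdir / "eeg").mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(parents=True, exist_ok=True)

    manifest = {"profile": profile, "seed": seed, "subjects": [], "images": []}
    for spec in _subject_specs(config):
        rec, truth = synthetic.generate_session(spec)
        base = outdir / "eeg" / spec.subject_id
        io.write_brainvision(rec, base)
        io.write_ground_truth(dataclasses.asdict(truth), base.with_suffix(".truth.json"))
        manifest["subjects"].append({
            "subject_id": spec.subject_id, "age": spec.age,
            "gender": spec.gender,
            "vhdr": str(base.with_suffix(".vhdr").relative_to(outdir))})

    import imageio.v3 as iio
    img_seed = np.random.SeedSequence([seed, 3001])
    img_seeds = img_seed.generate_state(len(config.pieces) + 1)
    for k, (pid, lbl) in enumerate(config.pieces):
        img = synthetic.generate_synthetic_images(lbl, config.image_size,
                                                  int(img_seeds[k] % (2 ** 31)))
        path = outdir / "images" / f"piece_{pid}.png"
        iio.imwrite(path, img)
        manifest["images"].append({"piece_id": pid, "class": lbl,
                                   "path": str(path.relative_to(outdir))})
    wall = synthetic.generate_synthetic_images("baseline", config.image_size,
                                               int(img_seeds[-1] % (2 ** 31)))
    wall_path = outdir / "images" / "baseline.png"
    iio.imwrite(wall_path, wall)
    manifest["images"].append({"piece_id": "baseline", "class": "baseline",
                               "path": str(wall_path.relative_to(outdir))})
    config.to_yaml(outdir / "config.yaml")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                          encoding="utf-8")
    return manifest


@dataclass
class RunReport:
    config: StudyConfig
    stages: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {"config": dataclasses.asdict(self.config),
                   "stages": self.stages, "summary": self.summary}
        path.write_text(json.dumps(payload, indent=1, default=_jsonable),
                        encoding="utf-8")
        return path


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="list")
    if isinstance(o, pd.Series):
        return o.to_dict()
    return str(o)


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full flow on in-memory synthetic sessions.

    Stages fail fast: an exception carries the stage name; partial stage
    outputs written so far (when ``outdir`` is given) are left in place.
    """
    config.validate()
    report = RunReport(config=config)
    outdir = Path(outdir) if outdir is not None else None
    stage_t0 = time.perf_counter()

    def _done(stage: str, **info):
        nonlocal stage_t0
        dt = time.perf_counter() - stage_t0
        stage_t0 = time.perf_counter()
        report.stages[stage] = {"elapsed_s": round(dt, 3), **info}
        logger.info("stage %s done in %.1f s", stage, dt)

    # 1. simulate
    specs = _subject_specs(config)
    sessions = [synthetic.generate_session(s) for s in specs]
    _done("simulate", n_subjects=len(sessions), seed=config.seed)

    # 2. preprocess
    epoch_sets, prep_logs = [], {}
    for spec, (rec, _truth) in zip(specs, sessions):
        es, log = preprocess.preprocess_recording(
            rec, corr_threshold=config.corr_threshold,
            peripheral=config.peripheral, asr_window=config.asr_window_s,
            asr_k_sd=config.asr_k_sd, epoch_len=config.epoch_len_s,
            sub_len=config.sub_len_s, subject_id=spec.subject_id)
        epoch_sets.append(es)
        prep_logs[spec.subject_id] = log
    _done("preprocess", logs=prep_logs)

    # 3. image classes
    img_seed = np.random.SeedSequence([config.seed, 3001])
    img_seeds = img_seed.generate_state(len(config.pieces) + 1)
    imgs = {f"piece_{pid}": synthetic.generate_synthetic_images(
                lbl, config.image_size, int(img_seeds[k] % (2 ** 31)))
            for k, (pid, lbl) in enumerate(config.pieces)}
    imgs["baseline"] = synthetic.generate_synthetic_images(
        "baseline", config.image_size, int(img_seeds[-1] % (2 ** 31)))
    img_features = im.image_feature_table(imgs)
    classes_result = im.cluster_images(img_features, baseline_id="baseline")
    classes = dict(classes_result.labels)
    _done("images", classes=classes)

    # 4. features
    table, meta = ft.build_feature_table(epoch_sets, classes,
                                         domain=config.feature_domain)
    _done("features", n_rows=len(table), n_columns=table.shape[1] - 1)

    # 5. selection + clustering
    ranking = cl.mrmr_select(table, k=min(config.mrmr_k, table.shape[1] - 1))
    x = table[ranking.top].to_numpy(dtype=float)
    search = cl.parameter_search(x, table["class_label"].to_numpy(),
                                 grid=config.elm_grid,
                                 n_iter=config.n_iterations,
                                 n_classes=config.n_classes,
                                 seed=config.seed, n_hidden=config.n_hidden)
    importance = cl.importance_summary(ranking, meta)
    _done("cluster", mean_rand=float(search.runs["rand"].mean()),
          mean_agreement=float(search.runs["agreement"].mean()),
          chance_rand=search.chance_rand,
          chance_agreement=search.chance_agreement,
          best_params=dataclasses.asdict(search.best_params),
          p_vs_chance=search.p_value)

    # 6. connectivity: first complex piece vs baseline, pooled over subjects
    complex_pieces = [pid for pid, lbl in
                      ((p, classes.get(f"piece_{p}")) for p, _ in config.pieces)
                      if lbl == "complex"]
    target_piece = f"piece_{complex_pieces[0]}" if complex_pieces else None
    # gamma^2 is per-frequency; evaluating only the configured bands' integer
    # grid is exact and keeps the stage tractable
    conn_bands = [b for b in ft.BANDS if b.name in config.connectivity_bands]
    freqs = np.unique(np.concatenate([
        np.arange(np.ceil(b.low), np.floor(b.high) + 1) for b in conn_bands]))
    patterns = None
    contrasts: dict = {}
    strengths_rows = []
    for es in epoch_sets:
        if patterns is None:
            patterns = conn.define_patterns(es.ch_names)
        view_ep = next((e for e in es.epochs if e.label == target_piece), None)
        if view_ep is None or es.baseline is None:
            continue
        for cond, ep in (("viewing", view_ep), ("baseline", es.baseline)):
            tensor = conn.epoch_adtf(ep.data, es.fs, es.ch_names,
                                     p=config.var_order,
                                     update_coeff=config.update_coeff,
                                     target_fs=config.target_fs, freqs=freqs)
            for band in conn_bands:
                for pname, pat in patterns.items():
                    samp = conn.pattern_samples(tensor, band, pat,
                                                threshold=config.adtf_threshold)
                    strengths_rows.append({
                        "subject": es.subject_id, "condition": cond,
                        "band": band.name, "pattern": pname,
                        "mean_strength": conn.pattern_mean_strength(tensor, band, pat),
                        "n_supra": int(samp.values.size),
                        "supra_sum": float(samp.values.sum()),
                        "gender": next(s.gender for s in specs
                                       if s.subject_id == es.subject_id),
                        "age": next(s.age for s in specs
                                    if s.subject_id == es.subject_id),
                    })
    strengths = pd.DataFrame(strengths_rows)
    if len(strengths):
        from scipy.stats import mannwhitneyu
        for (band, pname), sub in strengths.groupby(["band", "pattern"]):
            v = sub.loc[sub["condition"] == "viewing", "mean_strength"].to_numpy()
            b = sub.loc[sub["condition"] == "baseline", "mean_strength"].to_numpy()
            if len(v) >= 2 and len(b) >= 2:
                _, p = mannwhitneyu(v, b, alternative="greater")
                contrasts[f"{band}:{pname}"] = {
                    "p_one_sided": float(p), "mean_viewing": float(v.mean()),
                    "mean_baseline": float(b.mean()), "n": int(len(v))}
    _done("connectivity", n_rows=len(strengths), contrasts=contrasts)

    # 7. group contrasts on viewing strengths
    group_reports = {}
    if len(strengths):
        view = strengths[strengths["condition"] == "viewing"]
        for grouping, col, split in (("gender", "gender", None),
                                     ("age_extremes", "age", "extremes")):
            if split == "extremes":
                ages = view.drop_duplicates("subject")[["subject", "age"]]
                young = set(ages.nsmallest(2, "age")["subject"])
                old = set(ages.nlargest(2, "age")["subject"])
                samples = {
                    "young": {k: g.loc[g["subject"].isin(young), "mean_strength"].to_numpy()
                              for k, g in view.groupby(["band", "pattern"])},
                    "old": {k: g.loc[g["subject"].isin(old), "mean_strength"].to_numpy()
                            for k, g in view.groupby(["band", "pattern"])},
                }
            else:
                samples = {
                    lvl: {k: g.loc[g[col] == lvl, "mean_strength"].to_numpy()
                          for k, g in view.groupby(["band", "pattern"])}
                    for lvl in view[col].unique()
                }
            if len(samples) == 2:
                group_reports[grouping] = conn.group_contrast(samples)
    _done("contrasts", groupings=list(group_reports))

    report.summary = {
        "n_subjects": len(epoch_sets),
        "classes": classes,
        "mean_rand": float(search.runs["rand"].mean()),
        "chance_agreement": search.chance_agreement,
        "top_channels": importance["channel_pct"].head(5).to_dict(),
        "top_bands": importance["band_pct"].to_dict(),
        "condition_contrasts": contrasts,
    }
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "feature_table.csv")
        meta.to_csv(outdir / "feature_metadata.csv")
        search.runs.to_csv(outdir / "clustering_runs.csv", index=False)
        strengths.to_csv(outdir / "pattern_strengths.csv", index=False)
        for name, rep in group_reports.items():
            rep.to_csv(outdir / f"group_contrast_{name}.csv", index=False)
        report.to_json(outdir / "run_report.json")
    return report
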