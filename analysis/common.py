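"""Shared plumbing for the numbered analysis drivers.

The fixture (raw recordings, images, ground truth) lives under ``scratch/``,
which holds binary intermediates; the tables each step reports live under
``results/``. Every driver can rebuild what it needs, so they also run in
isolation.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def parser(description: str) -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--profile", choices=["tiny", "default"], default="tiny",
                    help="cohort size: tiny = 4 subjects for a quick pass, "
                         "default = the full 20-subject cohort")
    return ap


def fixture_dir(profile: str, seed: int) -> Path:
    return SCRATCH / f"{profile}_seed{seed}"


def ensure_fixture(profile: str, seed: int) -> Path:
    from arteeg import pipeline

    out = fixture_dir(profile, seed)
    if not (out / "manifest.json").exists():
        pipeline.make_fixture(out, profile=profile, seed=seed, overwrite=True)
    return out


def load_epoch_sets(fixture: Path):
    """Read every session from disk and run the full cleaning chain."""
    import json

    from arteeg import io, preprocess

    manifest = json.loads((fixture / "manifest.json").read_text())
    epoch_sets, logs = [], {}
    for sub in manifest["subjects"]:
        rec = io.read_brainvision(fixture / sub["vhdr"])
        es, log = preprocess.preprocess_recording(
            rec, subject_id=sub["subject_id"])
        epoch_sets.append(es)
        logs[sub["subject_id"]] = log
    return manifest, epoch_sets, logs
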