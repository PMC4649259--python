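#!/usr/bin/env python
"""Generate the synthetic study: EEG sessions plus stimulus images.

Writes BrainVision triplets, ground-truth sidecars and piece images under
scratch/, and a session manifest table under results/.
"""

import json

import pandas as pd

from common import RESULTS, ensure_fixture, parser


def main() -> None:
    args = parser(__doc__).parse_args()
    fixture = ensure_fixture(args.profile, args.seed)
    manifest = json.loads((fixture / "manifest.json").read_text())

    subjects = pd.DataFrame(manifest["subjects"])
    images = pd.DataFrame(manifest["images"])
    RESULTS.mkdir(exist_ok=True)
    subjects.to_csv(RESULTS / "01_sessions.csv", index=False)
    images.to_csv(RESULTS / "01_images.csv", index=False)

    print(f"fixture: {fixture}")
    print(f"{len(subjects)} sessions "
          f"({(subjects['gender'] == 'M').sum()} M / "
          f"{(subjects['gender'] == 'F').sum()} F), "
          f"{len(images)} stimulus images "
          f"({dict(images['class'].value_counts())})")
    print(f"wrote {RESULTS / '01_sessions.csv'} and 01_images.csv")


if __name__ == "__main__":
    main()
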