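#!/usr/bin/env python
"""Clean every session: high-pass, bad channels, peripherals, ASR, CAR,
segmentation. Reports how many channels and epochs survive per subject."""

import pandas as pd

from common import RESULTS, ensure_fixture, load_epoch_sets, parser


def main() -> None:
    args = parser(__doc__).parse_args()
    fixture = ensure_fixture(args.profile, args.seed)
    _, epoch_sets, logs = load_epoch_sets(fixture)

    rows = []
    for es in epoch_sets:
        log = logs[es.subject_id]
        rows.append({"subject": es.subject_id,
                     "channels_retained": log["n_channels"],
                     "bad_channels": ";".join(log["bad_channels"]) or "-",
                     "piece_epochs": log["n_epochs"],
                     "baseline_found": log["has_baseline"]})
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "02_preprocessing.csv", index=False)

    print(table.to_string(index=False))
    print(f"\nall sessions reduce to "
          f"{table['channels_retained'].unique().tolist()} channels; "
          f"wrote {RESULTS / '02_preprocessing.csv'}")


if __name__ == "__main__":
    main()
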