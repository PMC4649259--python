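#!/usr/bin/env python
"""Extract per-segment EEG features in the three domains.

The full tables go to scratch/ (they are wide); results/ receives a summary
of table shapes and per-class feature means for a few indicative columns.
"""

import pandas as pd

from common import RESULTS, ensure_fixture, fixture_dir, load_epoch_sets, parser

from arteeg import features as ft


def main() -> None:
    args = parser(__doc__).parse_args()
    fixture = ensure_fixture(args.profile, args.seed)
    manifest, epoch_sets, _ = load_epoch_sets(fixture)

    classes = {f"piece_{e['piece_id']}": e["class"] for e in manifest["images"]
               if e["piece_id"] != "baseline"}
    classes["baseline"] = "baseline"

    summary_rows = []
    for domain in ("time", "frequency", "wavelet"):
        table, meta = ft.build_feature_table(epoch_sets, classes, domain=domain)
        table.to_csv(fixture_dir(args.profile, args.seed) /
                     f"features_{domain}.csv")
        meta.to_csv(fixture_dir(args.profile, args.seed) /
                    f"features_{domain}_meta.csv")
        summary_rows.append({"domain": domain, "rows": len(table),
                             "feature_columns": table.shape[1] - 1,
                             "per_channel": ft.features_per_channel(domain)})
        if domain == "time":
            probe = [c for c in table.columns
                     if c.endswith("|gamma|sd") and "|O" in c][:1]
            probe += [c for c in table.columns
                      if c.endswith("|delta|sd") and "|F" in c][:1]
            means = table.groupby("class_label")[probe].mean()
            means.to_csv(RESULTS / "04_probe_feature_means.csv")
            print("class means of indicative features "
                  "(occipital gamma SD, frontal delta SD):")
            print(means.to_string())

    summary = pd.DataFrame(summary_rows)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "04_feature_tables.csv", index=False)
    print()
    print(summary.to_string(index=False))
    print(f"\nfull tables in {fixture_dir(args.profile, args.seed)}; "
          f"wrote {RESULTS / '04_feature_tables.csv'}")


if __name__ == "__main__":
    main()
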