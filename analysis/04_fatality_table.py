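"""Cross-tabulate the fatality records.

Reads the fatality table from the input bundle and writes the state × year
count table (with totals) and the by-month counts to results/.
"""

import argparse
from pathlib import Path

from isomove import aggregate_fatalities
from isomove.ranges import read_fatalities_csv

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    records = read_fatalities_csv(args.data / "fatalities.csv")
    table, by_month = aggregate_fatalities(records)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "fatality_counts.csv")
    by_month.to_csv(args.out / "fatality_by_month.csv", index_label="month")

    print(table)
    print()
    print("by month:")
    print(by_month.to_string())
    print(f"\ngrand total: {table.loc['Total', 'Total']} carcasses")
    print(f"wrote {args.out / 'fatality_counts.csv'} and fatality_by_month.csv")


if __name__ == "__main__":
    main()
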