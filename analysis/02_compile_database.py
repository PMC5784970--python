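"""Compile the raw multi-source records into one row per species.

Applies the database rules — median AFR rounded up to the day, maximum
longevity with ranges resolved to their upper bound, wild records only
when flagged wild, unknown provenance pooled with captive — and writes
results/compiled.csv.
"""

import pathlib

import pandas as pd

from genlen.records import compile_database, read_records

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_records(ROOT / "world" / "records.csv")
    taxonomy = pd.read_csv(ROOT / "world" / "taxa.csv")
    compiled = compile_database(records, taxonomy)
    compiled.to_csv(ROOT / "compiled.csv", index=False)
    n = len(compiled)
    print(f"compiled {n} species -> {ROOT / 'compiled.csv'}")
    print(f"  AFR present for {int(compiled['afr_days'].notna().sum())}/{n}")
    print(f"  wild ALR present for {int(compiled['alr_wild_days'].notna().sum())}/{n}, "
          f"captive ALR for {int(compiled['alr_captive_days'].notna().sum())}/{n}")


if __name__ == "__main__":
    main()
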