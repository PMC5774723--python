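#!/usr/bin/env python
"""Build the sequence registry and the oligomer/target mismatch table.

Writes results/mismatch_counts.csv, results/registry.json and
results/strands.fasta.  The mismatch table is the selectivity argument in
sequence form: every 2'-O-methyl decamer is fully complementary to the
prokaryotic strand B, while carrying 3 (1489), 2 (1490) or 1 (1491)
mismatches against the eukaryotic strand B.
"""

from pathlib import Path

import pandas as pd

from asitekit.constructs import (
    build_registry,
    count_mismatches,
    registry_to_json,
    write_fasta,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    registry = build_registry()
    (OUT / "registry.json").write_text(registry_to_json(registry))
    write_fasta(registry, OUT / "strands.fasta")

    rows = []
    for oligo in ("oligo_1489", "oligo_1490", "oligo_1491"):
        for target in ("prok_B", "euk_B"):
            report = count_mismatches(registry[oligo], registry[target])
            rows.append(
                {
                    "oligomer": oligo,
                    "target": target,
                    "window_start": report.window_start,
                    "mismatches": report.mismatch_count,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "mismatch_counts.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nAll three oligomers are perfect antiparallel complements of the "
        "prokaryotic strand B; against the eukaryotic strand B they carry "
        f"{table[table.target == 'euk_B'].mismatches.tolist()} mismatches "
        "(1489/1490/1491)."
    )


if __name__ == "__main__":
    main()
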