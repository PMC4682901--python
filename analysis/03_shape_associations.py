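"""Association of SED tertiles with tumor size and nodal status.

Builds the per-subtype association blocks (counts with column percentages,
chi-square p for node status; mean +/- SD with ANOVA p for tumor size) and
writes them as results/table1.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from tumorshape.io import read_clinical, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_clinical(OUT / "clinical.csv").records
    report = run_pipeline(records, stages=("table1",))
    blocks = report.table1

    rows = []
    for subtype, block in blocks.items():
        counts = block["ln_counts"]
        pct = block["ln_percent"]
        for label, i in (("node_negative", 0), ("node_positive", 1)):
            rows.append(
                {
                    "subtype": subtype,
                    "variable": label,
                    "low": f"{counts[i][0]:.0f} ({pct[i][0]}%)",
                    "middle": f"{counts[i][1]:.0f} ({pct[i][1]}%)",
                    "high": f"{counts[i][2]:.0f} ({pct[i][2]}%)",
                    "p": block.get("ln_chi2_p"),
                }
            )
        if "size_mean" in block:
            rows.append(
                {
                    "subtype": subtype,
                    "variable": "tumor_size_cm",
                    "low": f"{block['size_mean']['Low']:.2f} (+-{block['size_sd']['Low']:.2f})",
                    "middle": f"{block['size_mean']['Middle']:.2f} (+-{block['size_sd']['Middle']:.2f})",
                    "high": f"{block['size_mean']['High']:.2f} (+-{block['size_sd']['High']:.2f})",
                    "p": block["size_anova_p"],
                }
            )
        else:  # a tertile too sparse within this subtype for a summary
            rows.append(
                {"subtype": subtype, "variable": "tumor_size_cm",
                 "low": "-", "middle": "-", "high": "-", "p": None}
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "table1.tsv", sep="\t", index=False)
    (OUT / "table1_full.json").write_text(json.dumps(blocks, indent=2))
    print(table.to_string(index=False))
    print(f"\nwrote {OUT / 'table1.tsv'}")


if __name__ == "__main__":
    main()
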