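"""Generate the reference synthetic cohort used by every downstream script.

Writes the 2,250-patient clinical table and the 41-sample FPKM expression
matrix (with the planted-gene key) under results/.
"""

import sys
from pathlib import Path

import numpy as np

from tumorshape.io import cohort_table, write_clinical
from tumorshape.simulate import SimulationConfig, generate_clinical, generate_expression

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    rng = np.random.default_rng(cfg.seed)
    records = generate_clinical(cfg, rng)
    write_clinical(records, OUT / "clinical.csv")

    df = cohort_table(records)
    sub = df.sample(n=cfg.n_expression_samples, random_state=np.random.RandomState(SEED))
    matrix, planted = generate_expression(
        sub["sed"].to_numpy(), cfg, rng, sample_ids=sub["patient_id"].tolist()
    )
    matrix.to_tsv(OUT / "expression.tsv")
    (OUT / "planted_genes.txt").write_text("\n".join(planted) + "\n")

    print(f"cohort: {len(records)} patients -> {OUT / 'clinical.csv'}")
    print(
        f"expression: {matrix.n_genes} genes x {matrix.n_samples} samples "
        f"({len(planted)} planted) -> {OUT / 'expression.tsv'}"
    )


if __name__ == "__main__":
    main()
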