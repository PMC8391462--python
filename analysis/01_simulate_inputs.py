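#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes a genome whose designated promoters carry the planted
Alu-Alu-Low_complexity-L1 configuration with an embedded PPRE heptamer,
the matching repeat/TSS annotations and planted-truth table, a
tumor/control expression pair, observed/null mutation-score sets, and a
survival cohort — all under results/inputs/.
"""

import sys
from pathlib import Path

from pprealu.synthetic_data import (
    SimulationConfig,
    builtin_alu_library,
    generate_expression_pair,
    generate_genome_with_annotations,
    generate_mutation_sets,
    generate_survival_cohort,
    random_score_table,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
CDS = "ATG" + "GCTTGGAAGCTGCGTCCA" * 20 + "TAA"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    lib = builtin_alu_library()

    syn = generate_genome_with_annotations(cfg, lib)
    paths = syn.write_outputs(OUT)
    print(f"genome: {len(syn.genome)} bp, {len(syn.tss)} genes, "
          f"{len(syn.truth.configs)} planted configurations, "
          f"{len(syn.repeats)} repeat annotations")

    expr = generate_expression_pair(cfg)
    expr.to_csv(OUT / "expression.tsv", sep="\t", index=False)
    print(f"expression: {len(expr)} samples "
          f"({(expr.cohort == 'tumor').sum()} tumor / {(expr.cohort == 'control').sum()} control)")

    table = random_score_table(CDS, seed=seed + 7)
    observed, null = generate_mutation_sets(cfg, CDS, table)
    observed.to_csv(OUT / "mutations_observed.tsv", sep="\t", index=False)
    null.to_csv(OUT / "mutations_null.tsv", sep="\t", index=False)
    print(f"mutations: {len(observed)} observed vs {len(null)} possible missense changes")

    cohort = generate_survival_cohort(cfg)
    cohort.to_csv(OUT / "survival_cohort.csv", index=False)
    print(f"survival: {len(cohort)} cases, "
          f"{(cohort.chr3_class == 'monosomy3').sum()} monosomy 3, "
          f"{cohort.event.sum()} events")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
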