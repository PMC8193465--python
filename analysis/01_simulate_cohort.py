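#!/usr/bin/env python
"""Simulate the study cohort: four phenotypes, three with planted structure.

Generates the default synthetic cohort (6000 genes x 1000 miRs, 100 samples
per phenotype). Phenotypes 1-3 each carry one planted driver miR (120
disjoint targets, latent-factor strength 0.9) and one redundant trio
sharing 120 targets; phenotype 4 is pure background noise, mirroring a
disease subtype without commodore regulation. Also generates a 150-term toy
ontology whose "true" terms annotate the planted neighborhoods.

Writes the expression tables to scratch/ (large intermediates) and a small
ground-truth summary to results/.
"""

from pathlib import Path

import pandas as pd

from cdremir.enrichment import write_annotations
from cdremir.io import write_expression_table, write_subtype_table
from cdremir.pipeline import SyntheticConfig, build_synthetic_cohort
from cdremir.semantic import write_ontology
from cdremir.synthetic import true_term_ids

SEED = 7
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = SyntheticConfig()
    gene, mir, assign, structures, dag, db = build_synthetic_cohort(cfg, SEED)

    data = SCRATCH / "data"
    write_expression_table(gene, data / "gene_expression.tsv")
    write_expression_table(mir, data / "mir_expression.tsv")
    write_subtype_table(assign, data / "subtypes.tsv")
    write_ontology(dag, data / "ontology.tsv")
    write_annotations(db, data / "annotations.tsv", data / "term_names.tsv")

    truth = true_term_ids(db, structures)
    rows = []
    for label, st in structures.items():
        for m in st.commodore_mirs:
            rows.append(
                {
                    "subtype": label, "planted_role": "driver", "mir_id": m,
                    "n_targets": len(st.commodore_targets[m]),
                    "strength": st.driver_strength,
                    "true_term": truth.get((label, m), ""),
                }
            )
        for members, shared in st.redundant_hub_groups:
            for m in members:
                rows.append(
                    {
                        "subtype": label, "planted_role": "redundant_hub",
                        "mir_id": m, "n_targets": len(shared),
                        "strength": st.driver_strength, "true_term": "",
                    }
                )
    RESULTS.mkdir(parents=True, exist_ok=True)
    truth_table = pd.DataFrame(rows)
    truth_table.to_csv(RESULTS / "planted_ground_truth.tsv", sep="\t", index=False)

    print(f"cohort: {gene.n_transcripts} genes x {mir.n_transcripts} miRs, "
          f"{gene.n_samples} samples over {len(structures)} phenotypes")
    print(f"planted miRs:\n{truth_table.to_string(index=False)}")
    print(f"inputs written to {data}")


if __name__ == "__main__":
    main()
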