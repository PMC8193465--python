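#!/usr/bin/env python
"""Functional over-representation of each commodore neighborhood.

Each commodore neighborhood is tested against every ontology term with the
hypergeometric tail; Benjamini-Hochberg adjusted p-values at <= 1e-3 flag
significant terms. The universe is the set of annotated genes expressed in
the phenotype. Writes per-commodore enriched-term counts and the
significant term rows to results/, full result tables to scratch/.
"""

from pathlib import Path

import pandas as pd

from cdremir.enrichment import enrich_neighborhood, read_annotations
from cdremir.io import read_expression_table

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"
ALPHA = 1e-3


def main() -> None:
    data = SCRATCH / "data"
    db = read_annotations(data / "annotations.tsv", data / "term_names.tsv")
    gene = read_expression_table(data / "gene_expression.tsv", layer="gene")
    universe = sorted(set(gene.transcript_ids) & db.annotated_genes)
    print(f"universe: {len(universe)} annotated expressed genes, "
          f"{len(db.terms)} terms")

    counts, sig_rows = [], []
    for nb_file in sorted((SCRATCH / "neighborhoods").glob("*.txt")):
        subtype, mir = nb_file.stem.split("_", 1)
        query = set(nb_file.read_text().split()) & set(universe)
        result = enrich_neighborhood(query, universe, db, alpha=ALPHA)
        (SCRATCH / "enrichment").mkdir(parents=True, exist_ok=True)
        result.to_csv(
            SCRATCH / "enrichment" / f"{subtype}_{mir}.tsv", sep="\t", index=False,
        )
        sig = result[result["significant"]]
        counts.append({"subtype": subtype, "mir_id": mir, "enriched_terms": len(sig)})
        for _, row in sig.iterrows():
            sig_rows.append(
                {
                    "subtype": subtype, "mir_id": mir, "term_id": row["term_id"],
                    "name": row["name"], "overlap": int(row["overlap"]),
                    "term_size": int(row["term_size"]),
                    "p_adjusted": f"{row['p_adjusted']:.3e}",
                }
            )
        print(f"{subtype}/{mir}: {len(sig)} significant term(s) "
              f"of {len(result)} tested")

    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(counts).to_csv(
        RESULTS / "enrichment_counts.tsv", sep="\t", index=False
    )
    pd.DataFrame(sig_rows).to_csv(
        RESULTS / "enriched_terms.tsv", sep="\t", index=False
    )
    print(f"enrichment tables written to {RESULTS}")


if __name__ == "__main__":
    main()
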