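#!/usr/bin/env python
"""Group enriched terms by Wang semantic similarity; pick representatives.

For each commodore, the significant terms are clustered (average linkage on
1 - Wang similarity) into up to ten function groups; each group is
represented by its lowest-adjusted-p member. Also prints the literature
query strings ("mir + representative function") that a validation step
would submit — no external service is contacted.
"""

from pathlib import Path

import pandas as pd

from cdremir.semantic import aggregate_function_groups, groups_table, read_ontology

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis"
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dag = read_ontology(SCRATCH / "data" / "ontology.tsv")
    names = pd.read_csv(SCRATCH / "data" / "term_names.tsv", sep="\t")
    name_of = dict(zip(names.iloc[:, 0], names.iloc[:, 1]))

    all_rows, queries = [], []
    for enr_file in sorted((SCRATCH / "enrichment").glob("*.tsv")):
        subtype, mir = enr_file.stem.split("_", 1)
        result = pd.read_csv(enr_file, sep="\t")
        groups = aggregate_function_groups(result, dag, n_groups=10)
        gtab = groups_table(groups, name_of)
        for _, row in gtab.iterrows():
            all_rows.append({"subtype": subtype, "mir_id": mir, **row.to_dict()})
            queries.append(f"{mir} + {row['representative_name']}")
        print(f"{subtype}/{mir}: {len(groups)} function group(s); "
              f"top representative: "
              f"{gtab.iloc[0]['representative_name'] if len(gtab) else 'n/a'}")

    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(all_rows).to_csv(
        RESULTS / "function_groups.tsv", sep="\t", index=False
    )
    print("\nliterature query strings (validation stub):")
    for q in queries:
        print(f"  {q}")
    print(f"\nfunction groups written to {RESULTS / 'function_groups.tsv'}")


if __name__ == "__main__":
    main()
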