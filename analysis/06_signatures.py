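"""Summarize common blood-microbiome signatures.

Computes overall and per-study prevalence, selects the common genus set
(prevalence > 20%), partitions each sample's abundance mass by origin
category, and compares Ct vs NCt prevalence for the significant genera
with study prevalence above 50%.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import DIFFABUND, ORIGINS, QC, SIGNATURES, SYNTH

from bloodsig.io import read_metadata
from bloodsig.origins import OriginAssignment
from bloodsig.signatures import (
    cohort_origin_stats,
    compute_prevalence,
    origin_proportions,
    prevalence_compare,
    select_common,
    top_taxa_by_abundance,
)


def main():
    SIGNATURES.mkdir(parents=True, exist_ok=True)
    rel = pd.read_csv(QC / "relative_abundance.tsv", sep="\t", index_col=0)
    metadata = read_metadata(SYNTH / "metadata.tsv")
    assignments_df = pd.read_csv(ORIGINS / "assignments.tsv", sep="\t")
    diffabund = pd.read_csv(DIFFABUND / "differential_abundance.tsv", sep="\t", index_col=0)

    prevalence = compute_prevalence(rel, metadata)
    prevalence.to_csv(SIGNATURES / "prevalence.tsv", sep="\t")
    common = select_common(prevalence, overall_threshold=0.20)
    print(f"{common.shape[0]} genera with overall prevalence > 20%")
    print("top 5 by mean abundance:", ", ".join(top_taxa_by_abundance(rel, 5)))

    assignments = {
        r.taxon: OriginAssignment(
            r.taxon,
            frozenset() if r.category == "unidentified"
            else frozenset(r.label[6:-1].split("+")) if r.category == "multi"
            else frozenset({r.category}),
        )
        for r in assignments_df.itertuples(index=False)
    }
    props = origin_proportions(rel, assignments)
    props.to_csv(SIGNATURES / "origin_proportions.tsv", sep="\t")
    stats = cohort_origin_stats(props)
    stats.to_csv(SIGNATURES / "origin_summary.tsv", sep="\t")
    print("mean origin proportions per sample:")
    for category, row in stats.iterrows():
        print(f"  {category}: {row['mean']:.1%} "
              f"(>50% in {row['frac_gt_half']:.0%} of samples, "
              f"absent in {row['frac_zero']:.0%})")

    significant = list(diffabund.index[diffabund["significant"]])
    pooled, per_study = prevalence_compare(
        rel, metadata, significant, study_threshold=0.50, prevalence=prevalence
    )
    pooled.to_csv(SIGNATURES / "prevalence_ct_vs_nct.tsv", sep="\t")
    per_study.to_csv(SIGNATURES / "prevalence_by_study.tsv", sep="\t", index=False)
    higher = (pooled["nct_prevalence"] >= pooled["ct_prevalence"]).sum()
    print(f"{pooled.shape[0]} significant genera pass the >50% study-prevalence cut; "
          f"{higher} are at least as prevalent in NCt as in Ct")
    print(f"outputs -> {SIGNATURES}")


if __name__ == "__main__":
    main()
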