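"""Compare microbial diversity between control and case groups.

Rarefies the filtered table to 2000 reads, computes observed richness and
Faith's phylogenetic diversity per sample, runs the pooled and per-study
Kruskal-Wallis comparisons with control-mean normalization, and ordinates
the unweighted UniFrac distances by PCoA (samples colour by study in the
figure, illustrating study-wise clustering).
"""

import json
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _paths import DIVERSITY, QC, SEED, SYNTH

from bloodsig.diversity import alpha_diversity, compare_alpha, pcoa, rarefy, unweighted_unifrac
from bloodsig.io import read_feature_table, read_metadata, read_newick


def main():
    DIVERSITY.mkdir(parents=True, exist_ok=True)
    table = read_feature_table(QC / "filtered_table.tsv")
    metadata = read_metadata(SYNTH / "metadata.tsv")
    tree = read_newick(SYNTH / "tree.nwk")

    rarefied, excluded = rarefy(table, 2000, seed=SEED)
    print(f"rarefied to 2000 reads; {len(excluded)} samples excluded")

    alpha = alpha_diversity(rarefied, tree)
    alpha.to_csv(DIVERSITY / "alpha_diversity.tsv", sep="\t")
    tests = {}
    for metric in ("observed_richness", "faith_pd"):
        cmp = compare_alpha(alpha, metadata, metric)
        tests[metric] = {"H": cmp["H"], "p": cmp["p"], "per_study": cmp["per_study"]}
        cmp["normalized"].to_csv(DIVERSITY / f"relative_{metric}.tsv", sep="\t")
        print(f"{metric}: Kruskal-Wallis H={cmp['H']:.2f}, p={cmp['p']:.3g}")
    (DIVERSITY / "alpha_tests.json").write_text(json.dumps(tests, indent=2))

    dm = unweighted_unifrac(rarefied, tree)
    ordination = pcoa(dm)
    coords = ordination.samples.iloc[:, :2]
    coords.index = rarefied.sample_ids
    coords.to_csv(DIVERSITY / "pcoa_coordinates.tsv", sep="\t")

    md = metadata.set_index("sample_id").loc[coords.index]
    fig, ax = plt.subplots(figsize=(6, 5))
    for study, idx in md.groupby("study_id").groups.items():
        ax.scatter(coords.loc[idx].iloc[:, 0], coords.loc[idx].iloc[:, 1], s=12, label=study)
    explained = ordination.proportion_explained
    ax.set_xlabel(f"PCo1 ({explained.iloc[0]:.1%})")
    ax.set_ylabel(f"PCo2 ({explained.iloc[1]:.1%})")
    ax.legend(fontsize=7, markerscale=1.5)
    ax.set_title("Unweighted UniFrac PCoA")
    fig.tight_layout()
    fig.savefig(DIVERSITY / "pcoa.png", dpi=120)
    print(f"PCo1 explains {explained.iloc[0]:.1%} of UniFrac variation")
    print(f"outputs -> {DIVERSITY}")


if __name__ == "__main__":
    main()
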