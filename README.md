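# bloodsig

A tested, reusable pipeline for meta-analysis of blood 16S amplicon
microbiome data. Human blood is a low-biomass, contamination-prone
environment; microbial DNA detected there is largely translocated from
microbiota-rich body sites (gut, oral cavity, skin). `bloodsig`
harmonizes per-study genus-level count tables, attributes each genus to a
body-site origin from database evidence, quantifies the common
blood-microbiome signature (prevalence, origin proportions, phylogenetic
diversity), and detects amplification of microbial signatures in case
(NCt) versus control (Ct) cohorts.

It is aimed at microbiome researchers who already have per-study
genus-level feature tables (e.g. from a QIIME 2 / DADA2 workflow with
taxonomy collapsed to genus) and want the downstream meta-analysis to be
reproducible and testable. A synthetic-data generator emulates the whole
multi-study structure — batch effects, depth variation, study-specific
reagent contaminants, disease amplification — so every stage is validated
against known ground truth without any sequence downloads.

## Methods at a glance

- **Harmonization & QC** — per-study tables are merged over the union of
  genera (absent genera are explicit zeros); samples with fewer than 100
  reads are dropped; study-specific contaminant genera are zeroed within
  their study; every stage appends to an exactly-balancing read ledger.
- **Origin attribution** — from an evidence table of experiment counts
  per (genus, sample type), raw sample types are grouped into body sites
  (feces/anal/rectal swab → gut; saliva, plaque, etc. → oral; skin/foot
  swab → skin). A site is valid evidence only with **more than five
  experiments**; one valid site → single origin, two or more →
  multi-origin, none → unidentified.
- **Diversity** — counts rarefied once to 2000 reads; observed richness
  and Faith's PD (total branch length of the minimal rooted subtree over
  observed taxa); unweighted UniFrac with PCoA; Ct vs NCt compared by
  Kruskal–Wallis, with per-study control-mean normalization.
- **Differential abundance** — an ALDEx2-style procedure: for each of 128
  Monte-Carlo instances, per-sample proportions are drawn from
  Dirichlet(counts + 0.5) and CLR-transformed
  (log p_i − mean_j log p_j); a two-sided Wilcoxon rank-sum test per genus
  is BH-corrected within each instance; expected p and q are means over
  instances and genera with q < 0.05 are called. Effect size is the
  median-over-instances of (median CLR difference)/(max within-group IQR).
- **Signatures** — overall prevalence (fraction of samples detecting a
  genus) and study prevalence (fraction of studies with ≥ 1 detecting
  sample), strict-threshold common-signature selection, per-sample origin
  proportions, and Ct vs NCt prevalence for significant genera with study
  prevalence above 50%.

## Worked example

The numbered drivers in `analysis/` run the whole pipeline on the default
synthetic design (8 studies × 20 Ct + 20 NCt samples, 300 genera, 12
gut/oral-origin genera amplified 8-fold in cases):

```bash
python analysis/01_simulate.py
python analysis/02_qc.py
python analysis/03_origins.py
python analysis/04_diversity.py
python analysis/05_diffabund.py
python analysis/06_signatures.py
```

Output of the central steps (seed 1):

```
=== 02_qc ===
8 studies, 160 Ct / 160 NCt samples (per-study controls 20..20)
           stage  reads_in  reads_removed  reads_retained  fraction_retained
low-depth-filter   5556407              0         5556407           1.000000
   decontaminate   5556407         214046         5342361           0.961478
retained 5342361/5556407 reads (96.1%)

=== 03_origins ===
classified 316 genera: 124 with an identified origin
  gut: 63 ... multi-origin combinations: {'gut+oral': 31, 'gut+vaginal': 2}

=== 04_diversity ===
observed_richness: Kruskal-Wallis H=8.17, p=0.00427

=== 05_diffabund ===
12 significant genera at q<0.05: 12 NCt-enriched, 0 Ct-enriched
truth check: 12/12 amplified taxa recovered, 0 false positives
```

Read: decontamination removed 3.9% of reads and the ledger balances
exactly; the evidence classifier labels most genera by body site (the
remainder unidentified, as in real blood data); rarefied richness is
significantly higher in the case group; and the differential-abundance
stage recovers all 12 truly amplified genera with no false positives —
the case-enrichment asymmetry (12 vs 0) mirrors the amplification of
gut/oral signatures expected in clinical cohorts.

Each library function is importable directly, e.g.:

```python
from bloodsig import simulate_dataset, differential_abundance, PipelineConfig
ds = simulate_dataset(seed=1)
results, summary = differential_abundance(ds["table"], ds["metadata"],
                                          PipelineConfig(rng_seed=1))
```

## Layout

```
src/bloodsig/     library: io, origins, qc, diversity, diffabund,
                  signatures, synth
analysis/         numbered narrative drivers (see worked example)
tests/            pytest suite, property tests, end-to-end checks
scripts/          acceptance.py
docs/methods.md   model, assumptions, parameter choices, limitations
```
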