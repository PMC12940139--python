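"""Synthetic multi-study blood-microbiome data with known ground truth.

Emulates the structure of a multi-cohort 16S blood meta-analysis: several
studies, each with control (Ct) and case (NCt) samples; genus counts drawn
multinomially at a log-normally distributed sequencing depth from
per-study expected proportions. Study batch effects are per-(study, taxon)
log-normal offsets on a global log-abundance profile (so samples cluster
by study, as real cohorts do); disease amplification multiplies the
expected proportions of a designated set of rare gut/oral-origin taxa in
NCt samples by a fold-change before renormalization, which raises both
their abundance and their detectability (hence case-group richness). A
core taxon set receives a high baseline so it is prevalent in every study.
Study-specific reagent contaminants are spiked into every sample of their
study, and an origin-evidence table is generated whose zero-noise limit is
exactly recoverable by the evidence classifier.

Everything is reproducible: ``(config, seed) -> byte-identical outputs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from bloodsig.io import GROUP_CASE, GROUP_CONTROL, FeatureTable, validate_metadata
from bloodsig.origins import DEFAULT_SITE_GROUPING, OriginConfig

#: raw sample-type names emitted per site, to exercise sample-type grouping
_RAW_TYPES_PER_SITE = {
    "gut": ["feces", "rectal swab", "anal swab"],
    "oral": ["saliva", "buccal", "dental plaque", "oral swab"],
    "skin": ["skin swab", "foot swab"],
    "vaginal": ["vaginal swab"],
}
#: sample types with no body-site mapping, emitted as part of evidence noise
_UNMAPPED_TYPES = ["sputum", "bronchial lavage", "urine catheter"]


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic meta-analysis.

    Defaults emulate a mid-sized multi-cohort design: 8 studies of
    20 Ct + 20 NCt samples, 300 genera, per-sample depths log-normal and
    clipped to [5000, 50000] reads, study batch effects of one log-unit
    SD, 12 rare gut/oral-origin taxa amplified 8-fold in cases, 2 reagent
    contaminants per study, and a 10% evidence noise rate.
    """

    n_studies: int = 8
    n_control: int = 20
    n_case: int = 20
    n_taxa: int = 300
    origin_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "gut": 0.20,
            "oral": 0.06,
            "skin": 0.04,
            "multi": 0.10,
            "unidentified": 0.60,
        }
    )
    n_core: int = 30
    core_boost: float = 3.0
    n_amplified: int = 12
    fold_change: float = 8.0
    batch_scale: float = 1.0
    depth_log_mean: float = np.log(15000.0)
    depth_log_sd: float = 0.5
    depth_min: int = 5000
    depth_max: int = 50000
    contaminants_per_study: int = 2
    contaminant_frac: float = 0.02
    evidence_noise: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_studies", "n_control", "n_case", "n_taxa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")
        if not (0 <= self.evidence_noise < 1):
            raise ValueError("evidence_noise must lie in [0, 1)")
        if abs(sum(self.origin_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("origin_fractions must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth realized by one generator run."""

    origins: dict[str, frozenset[str]]  # taxon -> true site set (empty = unidentified)
    core_taxa: list[str]
    amplified_taxa: list[str]
    contaminants: pd.DataFrame  # columns study_id, taxon
    batch_offsets: pd.DataFrame  # studies x taxa
    depths: pd.Series  # per-sample realized depth
    fold_change: float

    def origin_category(self, taxon: str) -> str:
        sites = self.origins.get(taxon, frozenset())
        if not sites:
            return "unidentified"
        if len(sites) == 1:
            return next(iter(sites))
        return "multi"


def generate_tree(taxa: list[str], seed: int | np.random.Generator = 0) -> TreeNode:
    """Random rooted binary tree over ``taxa`` by sequential random join.

    Branch lengths are exponential(0.1). The result has exactly
    ``len(taxa)`` tips and ``len(taxa) - 1`` internal nodes.
    """
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa to build a tree")
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxon names must be unique")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = [TreeNode(name=t, length=float(rng.exponential(0.1))) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[left, right])
        nodes.append(parent)
    root = nodes[0]
    root.length = None  # the root has no branch above it
    return root


def _assign_origins(config: GeneratorConfig, rng: np.random.Generator, taxa):
    cats = list(config.origin_fractions)
    probs = np.array([config.origin_fractions[c] for c in cats])
    draws = rng.choice(len(cats), size=len(taxa), p=probs)
    single_sites = [s for s in ("gut", "oral", "skin") if s in cats]
    origins: dict[str, frozenset[str]] = {}
    for taxon, k in zip(taxa, draws):
        cat = cats[k]
        if cat == "unidentified":
            origins[taxon] = frozenset()
        elif cat == "multi":
            # mostly gut+oral, occasionally gut+vaginal, mirroring blood data
            combo = ("gut", "oral") if rng.random() < 0.8 else ("gut", "vaginal")
            origins[taxon] = frozenset(combo)
        else:
            origins[taxon] = frozenset({cat})
    return origins


def generate_counts(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame, SyntheticTruth]:
    """Generate the multi-study count table, metadata and ground truth.

    Per study, expected proportions are softmax(global log-abundance +
    batch offsets); NCt samples get amplified taxa's proportions
    multiplied by the fold-change and renormalized; counts are multinomial
    at a clipped log-normal depth. Contaminant taxa exist in the namespace
    with zero baseline counts (spiking is a separate step so the
    decontamination inverse-pair is exact).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    taxa = [f"Genus_{i + 1:04d}" for i in range(config.n_taxa)]
    origins = _assign_origins(config, rng, taxa)

    # contaminant taxa are a dedicated namespace block, absent from blood
    contam_records = []
    contam_taxa = []
    studies = [f"Study_{chr(ord('A') + s)}" for s in range(config.n_studies)]
    for study in studies:
        for c in range(config.contaminants_per_study):
            name = f"Contam_{study.split('_')[1]}{c + 1}"
            contam_taxa.append(name)
            contam_records.append({"study_id": study, "taxon": name})
            origins[name] = frozenset()
    all_taxa = taxa + contam_taxa

    # global log-abundance: core taxa high, amplified taxa rare
    base = rng.normal(0.0, 1.0, size=config.n_taxa)
    core = sorted(rng.choice(config.n_taxa, size=config.n_core, replace=False))
    core_taxa = [taxa[i] for i in core]
    base[core] += config.core_boost
    gut_oral = [
        i
        for i, t in enumerate(taxa)
        if origins[t] and origins[t] <= {"gut", "oral", "vaginal"} and origins[t] & {"gut", "oral"}
        and i not in core
    ]
    if len(gut_oral) < config.n_amplified:
        raise ValueError("not enough non-core gut/oral-origin taxa to amplify")
    amplified = sorted(rng.choice(gut_oral, size=config.n_amplified, replace=False))
    amplified_taxa = [taxa[i] for i in amplified]
    base[amplified] = rng.normal(-2.5, 0.25, size=config.n_amplified)

    offsets = rng.normal(0.0, config.batch_scale, size=(config.n_studies, config.n_taxa))
    batch_offsets = pd.DataFrame(offsets, index=studies, columns=taxa)

    rows, meta_rows, depth_rows = [], [], []
    amp_mask = np.zeros(config.n_taxa, dtype=bool)
    amp_mask[amplified] = True
    for s_idx, study in enumerate(studies):
        logits = base + offsets[s_idx]
        p_ct = np.exp(logits - logits.max())
        p_ct /= p_ct.sum()
        p_nct = p_ct.copy()
        p_nct[amp_mask] *= config.fold_change
        p_nct /= p_nct.sum()
        for group, n, p in (
            (GROUP_CONTROL, config.n_control, p_ct),
            (GROUP_CASE, config.n_case, p_nct),
        ):
            for i in range(n):
                depth = int(
                    np.clip(
                        rng.lognormal(config.depth_log_mean, config.depth_log_sd),
                        config.depth_min,
                        config.depth_max,
                    )
                )
                counts = rng.multinomial(depth, p)
                rows.append(np.concatenate([counts, np.zeros(len(contam_taxa), dtype=np.int64)]))
                sid = f"{study}_{group}_{i + 1:03d}"
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "study_id": study,
                        "group": group,
                        "cohort_label": "synthetic",
                    }
                )
                depth_rows.append((sid, depth))
    counts_df = pd.DataFrame(
        np.vstack(rows),
        index=[m["sample_id"] for m in meta_rows],
        columns=all_taxa,
    )
    counts_df.index.name = "sample_id"
    metadata = validate_metadata(pd.DataFrame(meta_rows))
    truth = SyntheticTruth(
        origins=origins,
        core_taxa=core_taxa,
        amplified_taxa=amplified_taxa,
        contaminants=pd.DataFrame(contam_records, columns=["study_id", "taxon"]),
        batch_offsets=batch_offsets,
        depths=pd.Series(dict(depth_rows), name="depth"),
        fold_change=config.fold_change,
    )
    return FeatureTable(counts_df), metadata, truth


def spike_contaminants(
    table: FeatureTable,
    truth: SyntheticTruth,
    metadata: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    contaminant_frac: float = 0.02,
) -> FeatureTable:
    """Spike study-specific contaminant counts into every sample of the
    contaminant's study (both groups); zero elsewhere.

    The spike is roughly ``contaminant_frac`` of each sample's depth (at
    least one read), so removing the truth list restores the pre-spike
    table exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts.copy()
    study_of = metadata.set_index("sample_id")["study_id"]
    totals = table.sample_totals()
    for rec in truth.contaminants.itertuples(index=False):
        in_study = study_of.reindex(counts.index) == rec.study_id
        lam = np.maximum(1.0, contaminant_frac * totals[in_study].to_numpy())
        counts.loc[in_study, rec.taxon] = 1 + rng.poisson(lam)
    return FeatureTable(counts)


def generate_evidence(
    truth: SyntheticTruth,
    noise_rate: float = 0.1,
    seed: int | np.random.Generator = 0,
    origin_config: OriginConfig | None = None,
) -> pd.DataFrame:
    """Raw origin-evidence records (taxon, sample_type, experiment_count).

    Each taxon with a true origin gets, at each true site, experiment
    counts at or above the validity threshold, split across that site's
    raw sample-type names. Noise adds sub-threshold records at wrong sites
    and occasionally unmapped sample types. Unidentified-truth taxa get at
    most 4 experiments at any site, so the classifier's zero-noise output
    equals the truth.
    """
    if not (0 <= noise_rate < 1):
        raise ValueError("noise_rate must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = origin_config or OriginConfig()
    records = []
    sites = list(_RAW_TYPES_PER_SITE)
    for taxon in sorted(truth.origins):
        true_sites = truth.origins[taxon]
        for site in sorted(true_sites):
            total = int(rng.integers(cfg.min_experiments, cfg.min_experiments + 60))
            raw_types = _RAW_TYPES_PER_SITE[site]
            split = rng.multinomial(total, np.ones(len(raw_types)) / len(raw_types))
            # guarantee the site total stays >= threshold after splitting
            for raw, n in zip(raw_types, split):
                if n > 0:
                    records.append(
                        {"taxon": taxon, "sample_type": raw, "experiment_count": int(n)}
                    )
        weak_sites: set[str] = set()
        if not true_sites and rng.random() < 0.5:
            # unidentified taxa may still have scattered weak records
            site = sites[rng.integers(len(sites))]
            weak_sites.add(site)
            records.append(
                {
                    "taxon": taxon,
                    "sample_type": _RAW_TYPES_PER_SITE[site][0],
                    "experiment_count": int(rng.integers(1, 5)),
                }
            )
        if noise_rate > 0 and rng.random() < noise_rate:
            # spurious sub-threshold evidence at a site with no record yet,
            # so no site can accumulate past the validity threshold
            wrong = [s for s in sites if s not in true_sites and s not in weak_sites]
            if wrong:
                site = wrong[rng.integers(len(wrong))]
                records.append(
                    {
                        "taxon": taxon,
                        "sample_type": _RAW_TYPES_PER_SITE[site][0],
                        "experiment_count": int(rng.integers(1, 5)),
                    }
                )
        if noise_rate > 0 and rng.random() < noise_rate / 2:
            raw = _UNMAPPED_TYPES[rng.integers(len(_UNMAPPED_TYPES))]
            records.append(
                {
                    "taxon": taxon,
                    "sample_type": raw,
                    "experiment_count": int(rng.integers(1, 20)),
                }
            )
    return pd.DataFrame(records, columns=["taxon", "sample_type", "experiment_count"])


def simulate_dataset(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    with_contaminants: bool = True,
) -> dict:
    """One full synthetic dataset: spiked table, metadata, tree, evidence,
    contaminant list, pre-spike table and truth.

    All randomness derives from a single seeded generator, so the bundle
    is byte-identical for a given (config, seed).
    """
    config = config or GeneratorConfig()
    root_seed = config.rng_seed if seed is None else seed
    seeds = np.random.SeedSequence(root_seed).spawn(4)
    table, metadata, truth = generate_counts(config, seed=seeds[0])
    tree = generate_tree(table.taxon_ids, np.random.default_rng(seeds[1]))
    evidence = generate_evidence(
        truth, config.evidence_noise, np.random.default_rng(seeds[2])
    )
    spiked = (
        spike_contaminants(
            table,
            truth,
            metadata,
            np.random.default_rng(seeds[3]),
            config.contaminant_frac,
        )
        if with_contaminants
        else table
    )
    return {
        "table": spiked,
        "pre_spike_table": table,
        "metadata": metadata,
        "tree": tree,
        "evidence": evidence,
        "contaminants": truth.contaminants,
        "truth": truth,
        "seed": root_seed,
    }
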