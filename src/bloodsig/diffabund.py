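"""CLR Dirichlet Monte-Carlo differential abundance (ALDEx2-style).

Count uncertainty is propagated by drawing, for each Monte-Carlo instance,
per-sample proportions from Dirichlet(counts + 0.5) and mapping them to
centered log-ratios (CLR): log p_i - mean_j log p_j, so every sample row
sums to zero. Within each instance a two-sided Wilcoxon rank-sum test is
run per taxon between the Ct and NCt groups and Benjamini-Hochberg
adjusted across taxa; the reported expected p and q are means over
instances, and significance is q < threshold. The effect size is the
ALDEx2-style standardized median difference: per instance,
(median CLR in NCt - median CLR in Ct) / max(within-group IQR, eps),
reported as the median across instances; positive values mean higher in
the case (NCt) group.

The per-taxon rank-sum test is exact (full enumeration via the
Mann-Whitney U null distribution) when both groups have at most 8 samples
and the values are tie-free; otherwise a vectorized normal approximation
with midranks, tie correction and continuity correction is used.
"""

from __future__ import annotations

from collections.abc import Iterator

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bloodsig.io import GROUP_CASE, GROUP_CONTROL, FeatureTable, PipelineConfig

DIRICHLET_PRIOR = 0.5
EFFECT_EPS = 1e-12
EXACT_MAX_N = 8


def dirichlet_clr_instances(
    counts: FeatureTable | pd.DataFrame | np.ndarray,
    mc_instances: int,
    seed: int | np.random.Generator = 0,
    prior: float = DIRICHLET_PRIOR,
) -> Iterator[np.ndarray]:
    """Yield ``mc_instances`` CLR matrices (samples x taxa), one per draw.

    Each draw samples per-sample proportions from Dirichlet(counts + prior)
    via normalized gamma variates and centers the log-proportions per
    sample. Reproducible under the seed; a sample with all-zero counts is
    rejected (its posterior is pure prior and carries no signal).
    """
    if isinstance(counts, FeatureTable):
        arr = counts.counts.to_numpy()
    elif isinstance(counts, pd.DataFrame):
        arr = counts.to_numpy()
    else:
        arr = np.asarray(counts)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need a 2-D counts matrix with at least 2 samples")
    if np.any(arr.sum(axis=1) == 0):
        bad = np.nonzero(arr.sum(axis=1) == 0)[0].tolist()
        raise ValueError(f"samples with all-zero counts (rows {bad}) must be filtered")
    if mc_instances < 1:
        raise ValueError("mc_instances must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = arr.astype(float) + prior
    for _ in range(mc_instances):
        gamma = rng.standard_gamma(alpha)
        logp = np.log(gamma) - np.log(gamma.sum(axis=1, keepdims=True))
        yield logp - logp.mean(axis=1, keepdims=True)


def wilcoxon_per_taxon(instance: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per taxon for one CLR instance.

    ``group_mask`` is a boolean vector over samples (True = NCt). Exact
    enumeration when both groups have <= 8 samples and no ties in any
    taxon; vectorized normal approximation with tie and continuity
    correction otherwise. A taxon constant across both groups gets p = 1.
    """
    x = np.asarray(instance, float)
    mask = np.asarray(group_mask, bool)
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n_taxa = x.shape[1]
    has_ties = any(
        np.any(np.diff(np.sort(x[:, j])) == 0) for j in range(n_taxa)
    )
    if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N and not has_ties:
        p = np.empty(n_taxa)
        for j in range(n_taxa):
            p[j] = stats.mannwhitneyu(
                x[mask, j], x[~mask, j], alternative="two-sided", method="exact"
            ).pvalue
        return p
    return _ranksum_normal_approx(x, mask)


def _ranksum_normal_approx(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p with midranks, tie correction and
    continuity correction, matching the large-sample Mann-Whitney test."""
    n, n_taxa = x.shape
    n1 = int(mask.sum())
    n2 = n - n1
    ranks = stats.rankdata(x, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie term per taxon: sum over tie groups of t^3 - t
    tie_term = np.zeros(n_taxa)
    xs = np.sort(x, axis=0)
    for j in range(n_taxa):
        col = xs[:, j]
        if np.any(np.diff(col) == 0):
            _, counts = np.unique(col, return_counts=True)
            tie_term[j] = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(n_taxa)
    ok = sigma2 > 0
    diff = u1[ok] - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2[ok])
    p[ok] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return p


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def effect_sizes(instance: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Per-taxon standardized median CLR difference for one instance.

    (median NCt - median Ct) / max(IQR_Ct, IQR_NCt, eps). Antisymmetric in
    the group labels and zero for identical group values.
    """
    x = np.asarray(instance, float)
    mask = np.asarray(group_mask, bool)
    med_diff = np.median(x[mask], axis=0) - np.median(x[~mask], axis=0)
    iqr_nct = np.subtract(*np.percentile(x[mask], [75, 25], axis=0))
    iqr_ct = np.subtract(*np.percentile(x[~mask], [75, 25], axis=0))
    denom = np.maximum(np.maximum(iqr_ct, iqr_nct), EFFECT_EPS)
    return med_diff / denom


def aggregate_mc(
    p_instances: np.ndarray,
    q_threshold: float = 0.05,
    taxa: list[str] | None = None,
    effect_instances: np.ndarray | None = None,
) -> pd.DataFrame:
    """Aggregate per-instance p (and effect) matrices into final results.

    ``p_instances`` is (instances x taxa). expected_p is the mean raw p
    per taxon; q is the mean of within-instance BH-adjusted p (the
    expected-q convention); significance is q < threshold.
    """
    p_mat = np.atleast_2d(np.asarray(p_instances, float))
    if p_mat.shape[0] < 1:
        raise ValueError("need at least one Monte-Carlo instance")
    q_mat = np.vstack([bh_adjust(row) for row in p_mat])
    expected_p = p_mat.mean(axis=0)
    q = q_mat.mean(axis=0)
    n_taxa = p_mat.shape[1]
    if taxa is None:
        taxa = [f"taxon_{i}" for i in range(n_taxa)]
    effect = (
        np.median(np.atleast_2d(effect_instances), axis=0)
        if effect_instances is not None
        else np.full(n_taxa, np.nan)
    )
    res = pd.DataFrame(
        {
            "effect_size": effect,
            "expected_p": expected_p,
            "q_value": q,
            "significant": q < q_threshold,
        },
        index=pd.Index(taxa, name="taxon"),
    )
    res["direction"] = np.where(
        res["effect_size"] > 0, GROUP_CASE, np.where(res["effect_size"] < 0, GROUP_CONTROL, "none")
    )
    return res


def differential_abundance(
    table: FeatureTable,
    metadata: pd.DataFrame,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full Ct vs NCt differential-abundance run on a count table.

    Pools all studies into one two-group comparison (the per-study
    stratified variant is a caller-side loop over study subsets). Returns
    the per-taxon result frame and a volcano-style summary with counts of
    significant taxa per direction. Bit-for-bit reproducible given
    (table, config, seed).
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.rng_seed
    md = metadata.set_index("sample_id").loc[table.counts.index]
    mask = (md["group"] == GROUP_CASE).to_numpy()
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both Ct and NCt groups must be present in the table")
    rng = np.random.default_rng(seed)
    p_rows, eff_rows = [], []
    for clr in dirichlet_clr_instances(table, config.mc_instances, rng):
        p_rows.append(wilcoxon_per_taxon(clr, mask))
        eff_rows.append(effect_sizes(clr, mask))
    result = aggregate_mc(
        np.vstack(p_rows),
        q_threshold=config.q_threshold,
        taxa=table.taxon_ids,
        effect_instances=np.vstack(eff_rows),
    )
    sig = result[result["significant"]]
    summary = {
        "n_taxa": int(result.shape[0]),
        "n_significant": int(sig.shape[0]),
        "n_case_enriched": int((sig["direction"] == GROUP_CASE).sum()),
        "n_control_enriched": int((sig["direction"] == GROUP_CONTROL).sum()),
        "mc_instances": config.mc_instances,
        "q_threshold": config.q_threshold,
        "seed": seed,
    }
    return result, summary
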