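"""Rarefaction, alpha/beta phylogenetic diversity, PCoA, group comparison.

Alpha diversity is observed genus richness and Faith's phylogenetic
diversity (total branch length of the minimal rooted subtree spanning the
observed taxa); beta diversity is the unweighted UniFrac distance (branch
length unique to one of two communities over branch length covered by
either, on presence/absence). Both are computed on counts rarefied once to
a fixed depth so sampling effort is standardized; samples below the depth
are excluded from diversity analyses.

Faith's PD, UniFrac and PCoA are delegated to scikit-bio; this module owns
rarefaction, validation, the rooted-PD convention, and the Ct/NCt
comparison (pooled and per-study Kruskal-Wallis with per-study
control-mean normalization).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from bloodsig.io import GROUP_CASE, GROUP_CONTROL, FeatureTable


def rarefy(
    table: FeatureTable,
    depth: int,
    seed: int | np.random.Generator = 0,
) -> tuple[FeatureTable, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples whose total is below the depth are excluded and returned in
    the second element. A sample at exactly the depth is passed through
    unchanged. Subsampling is multivariate hypergeometric and reproducible
    under the seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.sample_totals()
    excluded = list(totals.index[totals < depth])
    kept = table.counts.loc[totals >= depth]
    rows = []
    for _, row in kept.iterrows():
        vec = row.to_numpy()
        if vec.sum() == depth:
            rows.append(vec)
        else:
            rows.append(rng.multivariate_hypergeometric(vec, depth))
    rarefied = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, table.shape[1]), dtype=np.int64),
        index=kept.index,
        columns=kept.columns,
    )
    out = FeatureTable.__new__(FeatureTable)
    out.counts = rarefied.astype(np.int64)
    return out, excluded


def observed_richness(counts) -> int | pd.Series:
    """Number of taxa with count > 0 (per sample for 2-D input)."""
    if isinstance(counts, FeatureTable):
        counts = counts.counts
    if isinstance(counts, pd.DataFrame):
        return (counts > 0).sum(axis=1)
    arr = np.asarray(counts)
    return int((arr > 0).sum())


def _check_taxa_on_tree(taxa: list[str], tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")


def faith_pd(present_taxa, tree: TreeNode) -> float:
    """Faith's PD of a presence set: branch length of the minimal rooted
    subtree connecting the present tips (root connection included)."""
    present = sorted(set(present_taxa))
    if not present:
        return 0.0
    _check_taxa_on_tree(present, tree)
    return float(
        _skbio_faith_pd([1] * len(present), taxa=present, tree=tree, validate=True)
    )


def alpha_diversity(table: FeatureTable, tree: TreeNode) -> pd.DataFrame:
    """Per-sample observed richness and Faith's PD.

    The table is expected to be rarefied already; the ``rarefied`` flag is
    not tracked here but in the caller's manifest.
    """
    _check_taxa_on_tree(table.taxon_ids, tree)
    richness = observed_richness(table)
    pd_values = [
        faith_pd(row.index[row > 0], tree) for _, row in table.counts.iterrows()
    ]
    return pd.DataFrame(
        {"observed_richness": richness, "faith_pd": pd_values}, index=table.counts.index
    )


def unweighted_unifrac(table: FeatureTable, tree: TreeNode) -> DistanceMatrix:
    """All-pairs unweighted UniFrac on presence/absence of the table."""
    _check_taxa_on_tree(table.taxon_ids, tree)
    totals = table.sample_totals()
    empty = list(totals.index[totals == 0])
    if empty:
        raise ValueError(f"samples with no present taxa: {empty}")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.taxon_ids,
        tree=tree,
        validate=True,
    )


def unweighted_unifrac_pair(presence_i, presence_j, tree: TreeNode) -> float:
    """Unweighted UniFrac between two presence sets."""
    set_i, set_j = sorted(set(presence_i)), sorted(set(presence_j))
    if not set_i or not set_j:
        raise ValueError("UniFrac requires at least one present taxon per sample")
    taxa = sorted(set(set_i) | set(set_j))
    _check_taxa_on_tree(taxa, tree)
    counts = np.array(
        [[1 if t in set(s) else 0 for t in taxa] for s in (set_i, set_j)]
    )
    dm = beta_diversity(
        "unweighted_unifrac", counts, ids=["i", "j"], taxa=taxa, tree=tree
    )
    return float(dm["i", "j"])


def pcoa(dm: DistanceMatrix | pd.DataFrame | np.ndarray) -> OrdinationResults:
    """Principal coordinate analysis of a distance matrix.

    Gower double-centering followed by eigendecomposition; coordinates are
    eigenvector * sqrt(eigenvalue) on positive axes. Negative eigenvalues
    are reported as-is (no correction). Raises on a non-symmetric matrix.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = dm.to_numpy() if isinstance(dm, pd.DataFrame) else np.asarray(dm, float)
        ids = list(dm.index) if isinstance(dm, pd.DataFrame) else None
        dm = DistanceMatrix(arr, ids=ids)  # validates symmetry/zero diagonal
    return _skbio_pcoa(dm, method="eigh")


def compare_alpha(
    alpha: pd.DataFrame,
    metadata: pd.DataFrame,
    metric: str = "observed_richness",
    per_study: bool = True,
) -> dict:
    """Ct vs NCt comparison of an alpha-diversity metric.

    Pooled two-group Kruskal-Wallis (midranks, tie-corrected H), optional
    per-study tests, and per-study control-normalized values (each sample's
    value divided by the mean of its study's Ct samples; studies without a
    Ct sample are skipped with a warning entry).
    """
    md = metadata.set_index("sample_id").loc[alpha.index]
    values = alpha[metric]
    groups = md["group"]
    ct = values[groups == GROUP_CONTROL]
    nct = values[groups == GROUP_CASE]
    if len(ct) == 0 or len(nct) == 0:
        raise ValueError("both Ct and NCt groups must be non-empty")
    pooled_h, pooled_p = _kruskal_safe(ct, nct)

    per_study_tests = {}
    normalized = pd.Series(np.nan, index=alpha.index, name=f"relative_{metric}")
    skipped: list[str] = []
    for study, idx in md.groupby("study_id").groups.items():
        v = values.loc[idx]
        g = groups.loc[idx]
        v_ct = v[g == GROUP_CONTROL]
        if len(v_ct) == 0:
            skipped.append(str(study))
            continue
        ct_mean = v_ct.mean()
        if ct_mean > 0:
            normalized.loc[idx] = v / ct_mean
        v_nct = v[g == GROUP_CASE]
        if per_study and len(v_nct) > 0:
            h, p = _kruskal_safe(v_ct, v_nct)
            per_study_tests[str(study)] = {"H": h, "p": p}
    return {
        "metric": metric,
        "H": pooled_h,
        "p": pooled_p,
        "per_study": per_study_tests,
        "normalized": normalized,
        "studies_without_controls": skipped,
    }


def _kruskal_safe(a, b) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 0.0, 1.0
    h, p = stats.kruskal(a, b)
    return float(h), float(p)
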