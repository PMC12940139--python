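"""Core data containers and readers/writers.

The pipeline's central object is the :class:`FeatureTable`: a samples x taxa
matrix of non-negative integer genus counts. Sample metadata (study
membership and Ct/NCt group label) travels alongside it as a plain
:class:`pandas.DataFrame`. Trees are :class:`skbio.TreeNode` objects read
from Newick with mandatory branch lengths.

Feature tables are tab-separated text: samples as rows, first column the
sample ID, header row the genus names. Metadata is TSV with columns
``sample_id``, ``study_id``, ``group`` (``Ct``/``NCt``) and
``cohort_label``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

GROUP_CONTROL = "Ct"
GROUP_CASE = "NCt"
VALID_GROUPS = frozenset({GROUP_CONTROL, GROUP_CASE})

METADATA_COLUMNS = ["sample_id", "study_id", "group", "cohort_label"]


class FeatureTable:
    """Samples x taxa table of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with sample IDs as the index and taxon (genus) names as
        columns. Values must be non-negative integers; duplicate sample or
        taxon IDs are rejected.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon IDs: {dups}")
        if counts.shape[1] == 0:
            raise ValueError("feature table has no taxa")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.rename("sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"FeatureTable({n} samples x {m} taxa, {self.total_reads()} reads)"


@dataclass
class PipelineConfig:
    """Pipeline-wide constants.

    Each threshold of the analysis appears here exactly once:

    - ``min_reads_per_sample``: samples with fewer reads are dropped
      (strict ``<``; a sample at exactly the minimum is retained).
    - ``rarefaction_depth``: subsampling depth for diversity analyses.
    - ``prevalence_threshold``: overall-prevalence cut (strict ``>``) for
      the common-signature genus set.
    - ``study_prevalence_threshold``: study-prevalence cut (strict ``>``)
      for the case/control prevalence comparison.
    - ``q_threshold``: BH-corrected significance level.
    - ``mc_instances``: Dirichlet Monte-Carlo instances for the
      differential-abundance procedure.
    """

    min_reads_per_sample: int = 100
    rarefaction_depth: int = 2000
    prevalence_threshold: float = 0.20
    study_prevalence_threshold: float = 0.50
    q_threshold: float = 0.05
    mc_instances: int = 128
    rng_seed: int = 0

    def __post_init__(self):
        if self.min_reads_per_sample < 0:
            raise ValueError("min_reads_per_sample must be >= 0")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be a positive integer")
        if self.mc_instances <= 0:
            raise ValueError("mc_instances must be a positive integer")
        for name in ("prevalence_threshold", "study_prevalence_threshold", "q_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a TSV feature table (samples as rows, header = taxon names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate metadata records for samples: {dups}")
    bad = set(df["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}; expected Ct/NCt")
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path_or_str: str | Path) -> TreeNode:
    """Read a rooted Newick tree, requiring branch lengths on every edge.

    Accepts a path or a literal Newick string. A tip without a label or an
    edge without a length raises instead of defaulting silently.
    """
    src = str(path_or_str)
    if src.strip().endswith(";"):
        handle = _io.StringIO(src)
    else:
        handle = open(src)
    try:
        tree = TreeNode.read(handle, format="newick")
    finally:
        handle.close()
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if any(n is None or n == "" for n in names):
        raise ValueError("tree contains an unlabeled tip")
    if len(set(names)) != len(names):
        raise ValueError("tree tip labels are not unique")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"branch above {node.name or 'internal node'} has no length")
        if node.length < 0:
            raise ValueError("negative branch length")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=False))


# ---------------------------------------------------------------------------
# Cohort summarization


def summarize_cohorts(metadata: pd.DataFrame) -> dict:
    """Per-study control/case accounting for a sample metadata table.

    Returns a dict with a ``per_study`` DataFrame (columns ``Ct``, ``NCt``,
    ``total``), the number of distinct studies, and min/max per-study
    control-cohort sizes.
    """
    md = validate_metadata(metadata)
    if md.empty:
        raise ValueError("metadata is empty")
    per_study = (
        md.groupby(["study_id", "group"], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[GROUP_CONTROL, GROUP_CASE], fill_value=0)
    )
    per_study["total"] = per_study[GROUP_CONTROL] + per_study[GROUP_CASE]
    controls = per_study[GROUP_CONTROL]
    return {
        "per_study": per_study,
        "n_studies": int(per_study.shape[0]),
        "n_samples": int(per_study["total"].sum()),
        "min_control": int(controls.min()),
        "max_control": int(controls.max()),
        "n_control": int(controls.sum()),
        "n_case": int(per_study[GROUP_CASE].sum()),
    }


def load_reference_cohorts() -> pd.DataFrame:
    """Sample metadata expanded from the published per-study cohort sizes.

    The packaged ``cohort_sizes.tsv`` transcribes, for each of the 15
    public blood-microbiome studies in the meta-analysis, the number of
    control (Ct) and case (NCt) subjects. One synthetic metadata record per
    subject is generated (``S03_Ct_001`` etc.) so cohort accounting can be
    exercised without the sequence data.
    """
    ref = resources.files("bloodsig").joinpath("data/cohort_sizes.tsv")
    sizes = pd.read_csv(_io.StringIO(ref.read_text()), sep="\t")
    rows = []
    for _, rec in sizes.iterrows():
        for group, n in ((GROUP_CONTROL, rec["control_n"]), (GROUP_CASE, rec["case_n"])):
            for i in range(int(n)):
                rows.append(
                    {
                        "sample_id": f"{rec['study_id']}_{group}_{i + 1:03d}",
                        "study_id": rec["study_id"],
                        "group": group,
                        "cohort_label": rec["cohort_label"],
                    }
                )
    return validate_metadata(pd.DataFrame(rows, columns=METADATA_COLUMNS))
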