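"""Prevalence analytics and per-sample origin proportions.

Detection of a genus in a sample is strictly positive abundance after QC.
Overall prevalence is the fraction of samples detecting the genus; study
prevalence the fraction of studies with at least one detecting sample.
Common-signature selection applies strict ``>`` thresholds to these
fractions. Per-sample origin proportions partition each sample's relative
abundance mass across origin categories (gut, oral, skin, other single
sites, multi, unidentified); multi-origin mass is its own category and is
not redistributed to constituent sites.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from bloodsig.io import GROUP_CASE, GROUP_CONTROL
from bloodsig.origins import MULTI, UNIDENTIFIED, OriginAssignment


def compute_prevalence(rel: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon overall, study, and per-study prevalence.

    ``rel`` is any abundance table (detection uses only the zero pattern,
    so counts and relative abundance give identical prevalence). Returns a
    frame indexed by taxon with ``overall_prevalence``,
    ``study_prevalence`` and one ``prev_<study>`` column per study.
    """
    md = metadata.set_index("sample_id").loc[rel.index]
    detected = rel > 0
    overall = detected.mean(axis=0)
    per_study = detected.groupby(md["study_id"]).mean().T  # taxa x studies
    study_prev = (per_study > 0).mean(axis=1)
    out = pd.DataFrame(
        {"overall_prevalence": overall, "study_prevalence": study_prev}
    )
    for study in per_study.columns:
        out[f"prev_{study}"] = per_study[study]
    # rename, not in-place: the index object is shared with the input table
    out.index = out.index.rename("taxon")
    return out


def select_common(
    records: pd.DataFrame,
    overall_threshold: float | None = None,
    study_threshold: float | None = None,
) -> pd.DataFrame:
    """Filter prevalence records by strict ``>`` thresholds."""
    for name, value in (
        ("overall_threshold", overall_threshold),
        ("study_threshold", study_threshold),
    ):
        if value is not None and not (0 <= value <= 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    keep = pd.Series(True, index=records.index)
    if overall_threshold is not None:
        keep &= records["overall_prevalence"] > overall_threshold
    if study_threshold is not None:
        keep &= records["study_prevalence"] > study_threshold
    return records.loc[keep]


def origin_proportions(
    rel: pd.DataFrame,
    assignments: Mapping[str, OriginAssignment],
) -> pd.DataFrame:
    """Per-sample abundance proportion per origin category.

    Every taxon contributes its relative abundance to exactly one category
    (its assignment's category; taxa without an assignment count as
    unidentified), so rows sum to 1 for samples with nonzero totals.
    """
    categories = {}
    for taxon in rel.columns:
        a = assignments.get(taxon)
        categories[taxon] = a.category if a is not None else UNIDENTIFIED
    cat_series = pd.Series(categories)
    order = sorted(set(cat_series), key=lambda c: (c in (MULTI, UNIDENTIFIED), c))
    props = rel.T.groupby(cat_series).sum().T.reindex(columns=order, fill_value=0.0)
    totals = props.sum(axis=1)
    nonzero = totals > 0
    assert np.allclose(totals[nonzero], 1.0, atol=1e-9)
    props.index = props.index.rename("sample_id")
    return props


def cohort_origin_stats(proportions: pd.DataFrame) -> pd.DataFrame:
    """Per-category mean proportion, fraction of samples above one half,
    and fraction of samples with zero mass in the category."""
    if proportions.shape[0] < 1:
        raise ValueError("need at least one sample")
    return pd.DataFrame(
        {
            "mean": proportions.mean(axis=0),
            "frac_gt_half": (proportions > 0.5).mean(axis=0),
            "frac_zero": (proportions == 0).mean(axis=0),
        }
    )


def prevalence_compare(
    rel: pd.DataFrame,
    metadata: pd.DataFrame,
    significant_taxa: list[str],
    study_threshold: float = 0.50,
    prevalence: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct vs NCt prevalence for significant taxa above a study-prevalence cut.

    Returns ``(pooled, per_study)``: pooled has one row per retained taxon
    with ``ct_prevalence`` and ``nct_prevalence`` over all samples;
    per_study is long-form (taxon, study, group, prevalence) with paired
    Ct/NCt records per study for plotting.
    """
    md = metadata.set_index("sample_id").loc[rel.index]
    if prevalence is None:
        prevalence = compute_prevalence(rel, metadata)
    passing = [
        t
        for t in significant_taxa
        if t in prevalence.index
        and prevalence.loc[t, "study_prevalence"] > study_threshold
    ]
    detected = rel[passing] > 0 if passing else pd.DataFrame(index=rel.index)
    groups = md["group"]
    pooled_rows, long_rows = [], []
    for taxon in passing:
        d = detected[taxon]
        pooled_rows.append(
            {
                "taxon": taxon,
                "ct_prevalence": float(d[groups == GROUP_CONTROL].mean()),
                "nct_prevalence": float(d[groups == GROUP_CASE].mean()),
            }
        )
        for study, idx in md.groupby("study_id").groups.items():
            for group in (GROUP_CONTROL, GROUP_CASE):
                sel = idx[groups.loc[idx] == group]
                if len(sel) == 0:
                    continue
                long_rows.append(
                    {
                        "taxon": taxon,
                        "study_id": study,
                        "group": group,
                        "prevalence": float(d.loc[sel].mean()),
                    }
                )
    pooled = pd.DataFrame(
        pooled_rows, columns=["taxon", "ct_prevalence", "nct_prevalence"]
    ).set_index("taxon")
    per_study = pd.DataFrame(
        long_rows, columns=["taxon", "study_id", "group", "prevalence"]
    )
    return pooled, per_study


def top_taxa_by_abundance(rel: pd.DataFrame, n: int = 30) -> list[str]:
    """The ``n`` taxa with the highest mean relative abundance."""
    return list(rel.mean(axis=0).sort_values(ascending=False).head(n).index)
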