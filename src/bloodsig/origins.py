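"""Body-site origin attribution for blood-detected genera.

A genus found in blood is attributed to the body site(s) it most plausibly
translocated from, using an evidence table of how many microbiome
experiments reported that genus per sample type (a Disbiome-style export).
Raw sample types are first grouped into site categories (feces, anal swab
and rectal swab -> gut; saliva, buccal, dental plaque, ... -> oral; skin
and foot swabs -> skin); sample types that cannot be matched to a body
site are dropped and logged. A site is *valid* evidence for a genus only
when strictly more than five experiments report it there. A genus with one
valid site is single-origin, with two or more valid sites multi-origin,
and with none (including no records at all) unidentified.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

#: Raw sample-type -> site category grouping used for the evidence table.
DEFAULT_SITE_GROUPING: dict[str, str] = {
    # gut
    "feces": "gut",
    "anal swab": "gut",
    "rectal swab": "gut",
    # oral
    "buccal": "oral",
    "dental plaque": "oral",
    "mouthwash": "oral",
    "oral plaque": "oral",
    "oral swab": "oral",
    "oral wash": "oral",
    "oropharynx swab": "oral",
    "saliva": "oral",
    "subgingival plaque": "oral",
    "supragingival plaque": "oral",
    "tongue scrape": "oral",
    # skin
    "skin swab": "skin",
    "foot swab": "skin",
    # additional sites seen in evidence exports; the vocabulary is open
    "vaginal swab": "vaginal",
    "vaginal": "vaginal",
}

UNIDENTIFIED = "unidentified"
MULTI = "multi"


@dataclass
class OriginConfig:
    """Thresholds for the evidence classifier.

    ``min_experiments`` is the smallest experiment count that makes a site
    valid evidence; the default 6 encodes a strict "more than five"
    reading, so a site with exactly 5 experiments supports nothing.
    ``multi_min_sites`` is the number of valid sites at which a genus
    becomes multi-origin. ``site_fraction_equivalents`` documents the
    approximate fraction of each site's total experiments that the
    absolute threshold corresponded to in the source database; the
    classifier itself uses absolute counts only.
    """

    min_experiments: int = 6
    multi_min_sites: int = 2
    site_fraction_equivalents: dict[str, float] = field(
        default_factory=lambda: {"gut": 0.001, "oral": 0.005, "skin": 0.01}
    )

    def __post_init__(self):
        if self.min_experiments < 1:
            raise ValueError("min_experiments must be >= 1")
        if self.multi_min_sites < 2:
            raise ValueError("multi_min_sites must be >= 2")


@dataclass(frozen=True)
class OriginAssignment:
    """Origin label for one taxon.

    ``sites`` is the frozenset of valid sites: empty for unidentified,
    a singleton for single-origin, two or more for multi-origin.
    """

    taxon_id: str
    sites: frozenset[str]

    @property
    def category(self) -> str:
        """``unidentified``, the site name (single-origin), or ``multi``."""
        if not self.sites:
            return UNIDENTIFIED
        if len(self.sites) == 1:
            return next(iter(self.sites))
        return MULTI

    @property
    def label(self) -> str:
        if len(self.sites) < 2:
            return self.category
        return "multi(" + "+".join(sorted(self.sites)) + ")"


def group_sample_types(
    raw: pd.DataFrame,
    grouping: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate raw evidence records into per-(taxon, site) counts.

    Parameters
    ----------
    raw
        DataFrame with columns ``taxon``, ``sample_type``,
        ``experiment_count``.
    grouping
        Raw sample-type -> site mapping; defaults to
        :data:`DEFAULT_SITE_GROUPING`.

    Returns
    -------
    (evidence, discarded)
        ``evidence`` has columns ``taxon``, ``site``, ``experiment_count``
        with counts summed within each (taxon, site); ``discarded`` holds
        the records whose sample type had no site mapping.
    """
    if grouping is None:
        grouping = DEFAULT_SITE_GROUPING
    cols = ["taxon", "sample_type", "experiment_count"]
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise ValueError(f"evidence table missing columns: {missing}")
    if raw.empty:
        empty = pd.DataFrame(columns=["taxon", "site", "experiment_count"])
        return empty, raw.copy()
    if (raw["experiment_count"] < 0).any():
        raise ValueError("negative experiment counts in evidence table")
    mapped_site = raw["sample_type"].str.lower().map(grouping)
    discarded = raw.loc[mapped_site.isna(), cols].copy()
    kept = raw.loc[mapped_site.notna(), cols].assign(site=mapped_site.dropna())
    evidence = (
        kept.groupby(["taxon", "site"], as_index=False, sort=True)["experiment_count"]
        .sum()
    )
    return evidence, discarded


def classify_origin(
    site_counts: Mapping[str, int],
    config: OriginConfig | None = None,
    taxon_id: str = "",
) -> OriginAssignment:
    """Classify one taxon from its aggregated per-site experiment counts.

    Sites reaching ``min_experiments`` are valid; exactly one valid site
    gives a single-origin label, ``multi_min_sites`` or more give
    multi-origin, and none (including an empty evidence record) gives
    unidentified.
    """
    config = config or OriginConfig()
    if any(c < 0 for c in site_counts.values()):
        raise ValueError(f"negative evidence count for taxon {taxon_id!r}")
    valid = frozenset(
        site for site, c in site_counts.items() if c >= config.min_experiments
    )
    if len(valid) >= 2 and len(valid) < config.multi_min_sites:
        # e.g. multi_min_sites=3: two valid sites stay single-labelled by
        # their dominant site; resolved by the largest count, ties by name
        top = max(sorted(valid), key=lambda s: site_counts[s])
        valid = frozenset({top})
    return OriginAssignment(taxon_id=taxon_id, sites=valid)


def classify_taxa(
    evidence: pd.DataFrame,
    taxa: list[str],
    config: OriginConfig | None = None,
) -> dict[str, OriginAssignment]:
    """Classify every taxon in ``taxa``; taxa without records are unidentified."""
    config = config or OriginConfig()
    by_taxon: dict[str, dict[str, int]] = {}
    for rec in evidence.itertuples(index=False):
        per_site = by_taxon.setdefault(rec.taxon, {})
        per_site[rec.site] = per_site.get(rec.site, 0) + int(rec.experiment_count)
    return {
        t: classify_origin(by_taxon.get(t, {}), config, taxon_id=t) for t in taxa
    }


def summarize_origins(assignments: Mapping[str, OriginAssignment]) -> dict:
    """Category counts for a full assignment set.

    Returns per-category counts (each single site, ``multi``,
    ``unidentified``), the count of taxa with an identified origin, and
    counts per multi-origin site combination (keyed by the sorted
    ``site+site`` label). Counts partition the input taxa.
    """
    categories: dict[str, int] = {}
    combos: dict[str, int] = {}
    for a in assignments.values():
        categories[a.category] = categories.get(a.category, 0) + 1
        if a.category == MULTI:
            key = "+".join(sorted(a.sites))
            combos[key] = combos.get(key, 0) + 1
    n_total = len(assignments)
    n_unident = categories.get(UNIDENTIFIED, 0)
    return {
        "n_taxa": n_total,
        "n_identified": n_total - n_unident,
        "categories": categories,
        "multi_combinations": combos,
    }
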