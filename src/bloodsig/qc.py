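"""Study merging, depth/contaminant filters, and QC read accounting.

The harmonization chain merges per-study genus tables into one table
(union of taxa, explicit zeros for genera a study never observed), drops
samples below a minimum read depth (strict ``<``, so a sample at exactly
the threshold survives), removes contaminant genera, and converts counts
to relative abundance. Every filtering stage appends a ledger entry to a
:class:`QCAccounting` so that read mass is conserved end to end, mirroring
the stage-wise retention accounting of low-biomass QC (human-read removal
and denoising happen upstream and can be recorded as user-supplied
entries).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bloodsig.io import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class QCStage:
    name: str
    reads_in: int
    reads_removed: int

    @property
    def reads_retained(self) -> int:
        return self.reads_in - self.reads_removed

    @property
    def fraction_retained(self) -> float:
        return 1.0 if self.reads_in == 0 else self.reads_retained / self.reads_in


@dataclass
class QCAccounting:
    """Ordered read ledger across QC stages.

    Invariants: within a stage, reads_in = reads_removed + reads_retained;
    between stages, each stage's reads_in equals the previous stage's
    reads_retained.
    """

    stages: list[QCStage] = field(default_factory=list)

    def add_stage(self, name: str, reads_in: int, reads_removed: int) -> QCStage:
        if reads_removed < 0 or reads_removed > reads_in:
            raise ValueError("reads_removed must lie in [0, reads_in]")
        if self.stages and reads_in != self.stages[-1].reads_retained:
            raise ValueError(
                f"stage {name!r} reads_in={reads_in} does not chain from previous "
                f"stage's retained={self.stages[-1].reads_retained}"
            )
        stage = QCStage(name, int(reads_in), int(reads_removed))
        self.stages.append(stage)
        return stage

    def validate(self) -> None:
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.reads_in != prev.reads_retained:
                raise ValueError(f"accounting broken between {prev.name} and {cur.name}")

    @property
    def initial_reads(self) -> int:
        return self.stages[0].reads_in if self.stages else 0

    @property
    def final_reads(self) -> int:
        return self.stages[-1].reads_retained if self.stages else 0

    @property
    def total_removed(self) -> int:
        return sum(s.reads_removed for s in self.stages)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "reads_in": s.reads_in,
                    "reads_removed": s.reads_removed,
                    "reads_retained": s.reads_retained,
                    "fraction_retained": s.fraction_retained,
                }
                for s in self.stages
            ]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict("records"), indent=2))


def merge_studies(
    tables: dict[str, FeatureTable],
) -> tuple[FeatureTable, pd.Series]:
    """Merge per-study tables into one (union of taxa, zero fill).

    Returns the merged table and a sample -> study_id mapping. Sample IDs
    must be unique across studies.
    """
    if not tables:
        raise ValueError("no tables to merge")
    seen: dict[str, str] = {}
    for study, ft in tables.items():
        for s in ft.sample_ids:
            if s in seen:
                raise ValueError(
                    f"sample ID {s!r} appears in both study {seen[s]!r} and {study!r}"
                )
            seen[s] = study
    merged = pd.concat([ft.counts for ft in tables.values()], axis=0).fillna(0)
    sample_study = pd.Series(seen, name="study_id")
    return FeatureTable(merged), sample_study.loc[merged.index]


def filter_low_depth(
    table: FeatureTable,
    min_reads: int,
    accounting: QCAccounting | None = None,
    stage_name: str = "low-depth-filter",
) -> tuple[FeatureTable, QCStage]:
    """Drop samples with total reads strictly below ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    totals = table.sample_totals()
    keep = totals >= min_reads
    removed_reads = int(totals[~keep].sum())
    if not keep.any():
        logger.warning("low-depth filter removed every sample")
        kept = table.counts.iloc[0:0]
    else:
        kept = table.counts.loc[keep]
    acct = accounting if accounting is not None else QCAccounting()
    stage = acct.add_stage(stage_name, table.total_reads(), removed_reads)
    out = FeatureTable(kept) if kept.shape[0] else _empty_like(table)
    return out, stage


def _empty_like(table: FeatureTable) -> FeatureTable:
    ft = FeatureTable.__new__(FeatureTable)
    ft.counts = table.counts.iloc[0:0].copy()
    return ft


def remove_contaminants(
    table: FeatureTable,
    contaminants: pd.DataFrame,
    sample_study: pd.Series | None = None,
    mode: str = "per-study",
    accounting: QCAccounting | None = None,
    stage_name: str = "decontaminate",
) -> tuple[FeatureTable, QCStage]:
    """Remove contaminant genera from the table.

    ``contaminants`` has columns ``study_id`` and ``taxon``; a study_id of
    ``"*"`` marks a global contaminant. In ``per-study`` mode (default) a
    study-specific contaminant is zeroed only in that study's samples and
    the column is kept (possibly all-zero); in ``global`` mode any listed
    taxon column is dropped table-wide. Unknown taxon names are logged and
    ignored.
    """
    if mode not in {"per-study", "global"}:
        raise ValueError("mode must be 'per-study' or 'global'")
    for col in ("study_id", "taxon"):
        if col not in contaminants.columns:
            raise ValueError(f"contaminant list missing column {col!r}")
    counts = table.counts.copy()
    reads_in = table.total_reads()
    unknown = sorted(set(contaminants["taxon"]) - set(counts.columns))
    if unknown:
        logger.info("contaminant names absent from table: %s", unknown)
    known = contaminants[contaminants["taxon"].isin(counts.columns)]
    if mode == "global" or sample_study is None:
        drop = sorted(set(known["taxon"]))
        counts = counts.drop(columns=drop)
    else:
        for rec in known.itertuples(index=False):
            if rec.study_id == "*":
                counts[rec.taxon] = 0
            else:
                in_study = sample_study.reindex(counts.index) == rec.study_id
                counts.loc[in_study, rec.taxon] = 0
    removed = reads_in - int(counts.to_numpy().sum())
    acct = accounting if accounting is not None else QCAccounting()
    stage = acct.add_stage(stage_name, reads_in, removed)
    return FeatureTable(counts), stage


def to_relative_abundance(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample relative abundance (rows sum to 1)."""
    counts = table.counts if isinstance(table, FeatureTable) else table
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"samples with zero total reads must be filtered first: {list(zero.index)}"
        )
    rel = counts.div(totals, axis=0).astype(float)
    assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-9)
    return rel
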