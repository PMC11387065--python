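"""Sample x plant-taxon count tables from dietary DNA metabarcoding.

The analysis unit is a herd-level faecal sample: pooled dung from one herd,
sequenced at the trnL-P6 marker and tallied into read counts per plant
taxon.  This module ingests such tables together with per-sample metadata
(consumer species, season, herd, collection date), removes shallow samples,
rarefies to a common read depth so that richness and dissimilarity are
comparable across samples, and optionally collapses taxa into plant
functional groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "autumn")

#: Plant functional groups used when collapsing taxa. ``other`` holds taxa
#: outside the six growth forms (e.g. horsetails, mosses); ``undetermined``
#: holds taxa whose growth form cannot be resolved from reference data.
FUNCTIONAL_GROUPS = (
    "coniferous tree",
    "non-coniferous tree",
    "forb",
    "grass",
    "non-grass graminoid",
    "shrub",
    "other",
    "undetermined",
)

META_COLUMNS = ("species", "season", "herd", "date")


class DietTableError(ValueError):
    """Raised when a diet table or an operation on it is invalid."""


@dataclass
class DietTable:
    """Read counts per sample (rows) and plant taxon (columns) plus metadata.

    Parameters
    ----------
    counts:
        Non-negative integer DataFrame, one row per herd-level sample, one
        column per plant taxon. The index holds sample ids.
    sample_meta:
        DataFrame indexed identically to ``counts`` with at least the
        columns ``species``, ``season``, ``herd``, ``date``. Seasons must be
        drawn from ``{winter, spring, summer, autumn}``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.sample_meta = self.sample_meta.copy()
        if len(self.counts) == 0:
            raise DietTableError("diet table has no samples")
        if (self.counts.values < 0).any():
            raise DietTableError("negative read counts")
        if not self.counts.index.equals(self.sample_meta.index):
            raise DietTableError("counts and sample_meta indices differ")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise DietTableError(f"sample_meta missing columns: {missing}")
        bad = set(self.sample_meta["season"]) - set(SEASONS)
        if bad:
            raise DietTableError(f"unknown seasons: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def totals(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=1)

    def subset(self, sample_ids) -> "DietTable":
        """Restrict to the given sample ids, preserving their order."""
        return DietTable(self.counts.loc[sample_ids], self.sample_meta.loc[sample_ids])

    def season_filter(self, seasons=("summer", "winter")) -> "DietTable":
        """Keep samples from the given seasons (the summer-vs-winter tests)."""
        keep = self.sample_meta["season"].isin(seasons)
        if not keep.any():
            raise DietTableError(f"no samples in seasons {seasons}")
        return DietTable(self.counts.loc[keep], self.sample_meta.loc[keep])

    # -- I/O ------------------------------------------------------------
    def to_tsv(self, counts_path, meta_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        self.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "DietTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
        return cls(counts, meta)


@dataclass
class FunctionalAnnotation:
    """Mapping from plant taxon to functional group.

    Taxa absent from the mapping default to ``undetermined``.
    """

    mapping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.mapping.values()) - set(FUNCTIONAL_GROUPS)
        if bad:
            raise DietTableError(f"unknown functional groups: {sorted(bad)}")

    def group_of(self, taxon: str) -> str:
        return self.mapping.get(taxon, "undetermined")

    def groups_for(self, taxa) -> pd.Series:
        return pd.Series([self.group_of(t) for t in taxa], index=pd.Index(taxa))

    def to_tsv(self, path) -> None:
        pd.Series(self.mapping, name="group").rename_axis("taxon_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "FunctionalAnnotation":
        s = pd.read_csv(path, sep="\t", index_col="taxon_id")["group"]
        return cls(dict(s))


def filter_low_depth(table: DietTable, min_reads: int = 1000) -> DietTable:
    """Drop samples whose total read count is below ``min_reads``.

    The threshold is strict: a sample with exactly ``min_reads`` reads is
    retained. Removals are logged by sample id.
    """
    totals = table.totals
    keep = totals >= min_reads
    dropped = list(totals.index[~keep])
    if dropped:
        logger.info("filter_low_depth removed %d sample(s): %s", len(dropped), dropped)
    if not keep.any():
        raise DietTableError(f"all samples fall below {min_reads} reads")
    return DietTable(table.counts.loc[keep], table.sample_meta.loc[keep])


def rarefy(table: DietTable, depth: int = 1453, seed: int | None = None) -> DietTable:
    """Rarefy every sample to exactly ``depth`` reads without replacement.

    Each sample's reads are subsampled as a multivariate hypergeometric
    draw, so a taxon can never gain reads and never appears where it was
    absent. Reproducible given ``seed``.
    """
    totals = table.totals
    short = totals[totals < depth]
    if len(short):
        raise DietTableError(
            f"samples below rarefaction depth {depth}: {dict(short)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.values)
    for i, row in enumerate(table.counts.values):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row.astype(np.int64), depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return DietTable(counts, table.sample_meta)


def aggregate_functional(
    table: DietTable,
    annot: FunctionalAnnotation,
    include_undetermined: bool = True,
    re_rarefy_depth: int | None = None,
    seed: int | None = None,
) -> DietTable:
    """Collapse taxa into functional groups by summing member-taxon counts.

    With ``include_undetermined=False`` the undetermined group is removed
    and, if ``re_rarefy_depth`` is given, samples are re-rarefied to that
    depth so the table stays comparable after the removal.
    """
    groups = annot.groups_for(table.taxon_ids)
    agg = table.counts.T.groupby(groups.values).sum().T
    if not include_undetermined:
        agg = agg.drop(columns=["undetermined"], errors="ignore")
        totals = agg.sum(axis=1)
        empty = list(totals.index[totals == 0])
        if empty:
            raise DietTableError(f"samples empty after dropping undetermined: {empty}")
        if re_rarefy_depth is not None:
            short = list(totals.index[totals < re_rarefy_depth])
            if short:
                raise DietTableError(
                    f"samples below re-rarefaction depth {re_rarefy_depth}: {short}"
                )
    out = DietTable(agg, table.sample_meta)
    if not include_undetermined and re_rarefy_depth is not None:
        out = rarefy(out, depth=re_rarefy_depth, seed=seed)
    return out


def relative_abundance_by_group(table: DietTable) -> pd.DataFrame:
    """Mean relative abundance per (species, season); rows sum to 1."""
    rel = table.counts.div(table.totals, axis=0)
    rel = rel.join(table.sample_meta[["species", "season"]])
    out = rel.groupby(["species", "season"]).mean()
    return out.div(out.sum(axis=1), axis=0)
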