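"""Sorted-fraction microbiome enrichment analysis.

After staining a complex gut community with a fucose-binding lectin (AAL)
or with serum IgG and sorting the positive fraction, 16S OTU count tables
of sorted and matched unsorted samples quantify which taxa the stain
captured.  This module implements:

* per-sample relative abundances (percent of total bacteria);
* aggregation of OTU counts to a taxonomic rank, with OTUs unassigned at
  that rank grouped under their lowest assigned ancestor
  (``f:Lachnospiraceae;g:unclassified``);
* fold enrichment of a taxon in a sorted fraction versus its matched
  unsorted sample, with an additive pseudo-proportion for zero
  denominators;
* the >= 1.5-fold enrichment flag with a majority rule across replicate
  sorted samples;
* the candidate intersection: taxa enriched in the lectin-positive
  fraction AND in the IgG-positive fraction, and preferentially captured
  by IgG from CD sera relative to healthy-control sera;
* alpha richness (number of distinct OTUs per sample).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: "at least 1.5-fold" enrichment threshold.
DEFAULT_FOLD_THRESHOLD = 1.5

RANK_PREFIXES = ("d", "p", "c", "o", "f", "g", "s")
FRACTIONS = ("unsorted", "AAL_pos", "IgG_pos")

__all__ = [
    "OTUTable",
    "CandidateTaxon",
    "CandidateSet",
    "read_otu_table",
    "relative_abundance",
    "aggregate_taxa",
    "fold_enrichment",
    "default_pseudocount",
    "sample_fold_enrichments",
    "alpha_richness",
    "flag_enriched",
    "candidate_intersection",
]


@dataclass
class OTUTable:
    """OTU x sample counts with taxonomy lineages and sample annotations.

    ``taxonomy`` maps otu_id to a semicolon-delimited, rank-prefixed
    lineage (``d:Bacteria;p:Bacteroidetes;...;g:Bacteroides;s:stercoris``),
    possibly truncated.  ``samples`` is indexed by sample_id with columns
    ``fraction`` (unsorted | AAL_pos | IgG_pos), ``serum_group`` (ctrl |
    UC | CD | none) and ``matched_unsorted_id``.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str]
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        missing_tax = [o for o in self.counts.index if o not in self.taxonomy]
        if missing_tax:
            raise ValueError(f"OTUs without taxonomy: {missing_tax[:5]}")

    def sorted_samples(self, fraction: str) -> list[str]:
        return list(self.samples.index[self.samples["fraction"] == fraction])


def read_otu_table(counts_path, taxonomy_path, samples_path) -> OTUTable:
    """Load the three-file interchange format (counts, taxonomy, sample sheet)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tax_frame = pd.read_csv(taxonomy_path, sep="\t", dtype=str)
    if not {"otu_id", "lineage"} <= set(tax_frame.columns):
        raise ValueError("taxonomy table needs otu_id and lineage columns")
    taxonomy = dict(zip(tax_frame["otu_id"], tax_frame["lineage"]))
    samples = pd.read_csv(samples_path, sep="\t", dtype=str).set_index("sample_id")
    return OTUTable(counts=counts, taxonomy=taxonomy, samples=samples)


def relative_abundance(counts: pd.DataFrame | OTUTable) -> pd.DataFrame:
    """Per-sample percentages: 100 * count / column total; columns sum to 100."""
    frame = counts.counts if isinstance(counts, OTUTable) else counts
    totals = frame.sum(axis=0)
    zero = [str(s) for s in totals.index[totals == 0]]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    return 100.0 * frame / totals


def parse_lineage(lineage: str) -> dict[str, str]:
    """Split a rank-prefixed lineage string into a rank -> name mapping."""
    out: dict[str, str] = {}
    for part in str(lineage).split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            rank, name = part.split(":", 1)
            rank = rank.strip().lower()
            if rank in RANK_PREFIXES and name.strip():
                out[rank] = name.strip()
    return out


def taxon_key(lineage: str, rank: str) -> str:
    """Taxon key at ``rank``; truncated lineages fall back to the lowest
    assigned ancestor plus an ``unclassified`` marker.

    ``g:Bacteroides`` when the genus is assigned, otherwise e.g.
    ``f:Lachnospiraceae;g:unclassified``.
    """
    if rank not in RANK_PREFIXES:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANK_PREFIXES}")
    parsed = parse_lineage(lineage)
    if rank in parsed:
        return f"{rank}:{parsed[rank]}"
    target_idx = RANK_PREFIXES.index(rank)
    for r in reversed(RANK_PREFIXES[:target_idx]):
        if r in parsed:
            return f"{r}:{parsed[r]};{rank}:unclassified"
    return f"{rank}:unclassified"


def aggregate_taxa(table: OTUTable, rank: str = "g") -> pd.DataFrame:
    """Sum OTU counts over taxa sharing a rank label; conserves column totals."""
    keys = pd.Series(
        {otu: taxon_key(table.taxonomy[otu], rank) for otu in table.counts.index},
        name="taxon",
    )
    aggregated = table.counts.groupby(keys, sort=True).sum()
    assert (aggregated.sum(axis=0) == table.counts.sum(axis=0)).all()
    return aggregated


def fold_enrichment(
    sorted_pct: float | pd.Series,
    unsorted_pct: float | pd.Series,
    pseudo: float = 0.0,
) -> float | pd.Series:
    """Fold enrichment of a taxon: sorted % over matched unsorted %.

    An additive pseudo-proportion keeps the ratio finite at zero
    denominators; a taxon absent from both fractions sits exactly at 1.
    """
    if pseudo < 0:
        raise ValueError("pseudocount must be >= 0")
    num = np.asarray(sorted_pct, dtype=float) + pseudo
    den = np.asarray(unsorted_pct, dtype=float) + pseudo
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    if isinstance(sorted_pct, pd.Series):
        return pd.Series(ratio, index=sorted_pct.index)
    return float(ratio)


def default_pseudocount(total_sorted: int, total_unsorted: int) -> float:
    """Pseudo-proportion of one read in the smaller of the two libraries (%)"""
    smaller = min(int(total_sorted), int(total_unsorted))
    if smaller <= 0:
        raise ValueError("library sizes must be positive")
    return 100.0 / smaller


def sample_fold_enrichments(
    table: OTUTable,
    rank: str = "g",
    fraction: str = "AAL_pos",
    serum_group: str | None = None,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Taxa x sorted-sample fold enrichments against matched unsorted samples.

    ``pseudo=None`` selects, per sorted/unsorted pair, the default
    pseudo-proportion of one read in the smaller library.
    """
    aggregated = aggregate_taxa(table, rank)
    pct = relative_abundance(aggregated)
    chosen = table.samples[table.samples["fraction"] == fraction]
    if serum_group is not None:
        chosen = chosen[chosen["serum_group"] == serum_group]
    if chosen.empty:
        raise ValueError(
            f"no sorted samples for fraction={fraction!r} group={serum_group!r}"
        )
    cols = {}
    for sample_id, row in chosen.iterrows():
        unsorted_id = row["matched_unsorted_id"]
        if unsorted_id not in pct.columns:
            raise ValueError(
                f"matched unsorted sample {unsorted_id!r} for {sample_id!r} missing"
            )
        pair_pseudo = pseudo
        if pair_pseudo is None:
            pair_pseudo = default_pseudocount(
                aggregated[sample_id].sum(), aggregated[unsorted_id].sum()
            )
        cols[sample_id] = fold_enrichment(
            pct[sample_id], pct[unsorted_id], pair_pseudo
        )
    return pd.DataFrame(cols)


def alpha_richness(table: OTUTable | pd.DataFrame, sample: str | None = None):
    """Number of OTUs observed (count >= 1); per sample or for one sample."""
    counts = table.counts if isinstance(table, OTUTable) else table
    richness = (counts >= 1).sum(axis=0)
    if sample is not None:
        if sample not in richness.index:
            raise KeyError(f"sample {sample!r} not in table")
        return int(richness[sample])
    return richness.astype(int)


def flag_enriched(
    enrichments: pd.DataFrame | pd.Series,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    inclusive: bool = True,
) -> set[str]:
    """Taxa enriched beyond the threshold, majority-voted across replicates.

    ``inclusive=True`` implements "at least 1.5-fold" (>=); exclusive uses
    strict >.  For a DataFrame (taxa x replicate sorted samples) a taxon
    passes when it is flagged in more than half of the replicates.
    """
    if isinstance(enrichments, pd.Series):
        flags = enrichments >= threshold if inclusive else enrichments > threshold
        return set(flags.index[flags])
    flags = enrichments >= threshold if inclusive else enrichments > threshold
    votes = flags.sum(axis=1)
    return set(votes.index[votes > enrichments.shape[1] / 2.0])


@dataclass(frozen=True)
class CandidateTaxon:
    """One candidate with the per-criterion evidence that admitted it."""

    taxon: str
    aal_enriched: bool
    igg_fold_by_group: dict[str, float]
    igg_enriched: bool
    cd_preferential: bool


@dataclass
class CandidateSet:
    """Taxa passing lectin enrichment, IgG enrichment and CD preference."""

    candidates: list[CandidateTaxon]
    threshold: float

    @property
    def taxa(self) -> set[str]:
        return {c.taxon for c in self.candidates}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {
                "taxon": c.taxon,
                "aal_enriched": c.aal_enriched,
                "igg_enriched": c.igg_enriched,
                "cd_preferential": c.cd_preferential,
            }
            row.update({f"igg_fold_{g}": v for g, v in c.igg_fold_by_group.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def candidate_intersection(
    aal_set: set[str],
    igg_enrichments_by_group: Mapping[str, pd.DataFrame],
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> CandidateSet:
    """Intersect lectin- and IgG-captured taxa and keep CD-preferential ones.

    A taxon is a candidate when (a) it is in the lectin-enriched set,
    (b) its IgG-capture fold enrichment exceeds the threshold (strict >,
    "more than 1.5-fold") for at least one serum group, taking the median
    fold across that group's sorted samples, and (c) its median fold under
    CD-serum capture exceeds that under healthy-control capture.  The
    returned set is by construction a subset of both the lectin set and
    the IgG-enriched set; per-criterion evidence is attached.
    """
    for needed in ("ctrl", "CD"):
        if needed not in igg_enrichments_by_group:
            raise ValueError(f"missing IgG enrichment for group {needed!r}")
    group_medians = {
        g: frame.median(axis=1) for g, frame in igg_enrichments_by_group.items()
    }
    candidates = []
    for taxon in sorted(aal_set):
        folds = {
            g: float(med.get(taxon, np.nan)) for g, med in group_medians.items()
        }
        igg_enriched = any(
            np.isfinite(v) and v > threshold for v in folds.values()
        )
        cd_pref = (
            np.isfinite(folds.get("CD", np.nan))
            and np.isfinite(folds.get("ctrl", np.nan))
            and folds["CD"] > folds["ctrl"]
        )
        if igg_enriched and cd_pref:
            candidates.append(
                CandidateTaxon(
                    taxon=taxon,
                    aal_enriched=True,
                    igg_fold_by_group=folds,
                    igg_enriched=True,
                    cd_preferential=True,
                )
            )
    result = CandidateSet(candidates=candidates, threshold=threshold)
    assert result.taxa <= set(aal_set)
    return result
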