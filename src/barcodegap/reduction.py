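"""Reduced-database construction and barcode-coverage statistics.

The "reduced database" is the subset of a species checklist having at least
one barcode record in the requested reference libraries (BOLD and/or GenBank).
Filtering a community through it emulates what a DNA-based survey could have
detected; coverage statistics quantify the library gap per phylum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import ConfigError, ValidationError
from .tables_io import CommunityTable, SpeciesCatalog

logger = logging.getLogger(__name__)

SOURCES = ("bold", "genbank")
_FLAG = {"bold": "barcoded_bold", "genbank": "barcoded_genbank"}


def round_half_up(x: float) -> int:
    """Round to the nearest integer with halves going up (display convention;
    unrounded values are always carried alongside)."""
    return int(math.floor(x + 0.5))


@dataclass
class PhylumCoverage:
    n_total: int
    n_barcoded: int

    @property
    def percent_barcoded(self) -> float:
        return 100.0 * self.n_barcoded / self.n_total if self.n_total else 0.0


@dataclass
class CoverageSummary:
    """Barcode coverage of a checklist, overall and per phylum.

    ``missing_share_per_phylum`` apportions the non-barcoded species among
    phyla (shares of the missing pool, summing to 100); ``per_phylum``
    percentages are within-phylum coverage.  Both statistics are reported
    because published gap figures are quoted under either denominator.
    """

    n_total: int
    n_barcoded: int
    per_phylum: dict[str, PhylumCoverage] = field(default_factory=dict)

    @property
    def n_missing(self) -> int:
        return self.n_total - self.n_barcoded

    @property
    def percent_barcoded(self) -> float:
        return 100.0 * self.n_barcoded / self.n_total

    @property
    def percent_barcoded_rounded(self) -> int:
        return round_half_up(self.percent_barcoded)

    @property
    def missing_share_per_phylum(self) -> dict[str, float]:
        if self.n_missing == 0:
            return {}
        return {
            ph: 100.0 * (c.n_total - c.n_barcoded) / self.n_missing
            for ph, c in self.per_phylum.items()
            if c.n_total > c.n_barcoded
        }


def _check_sources(sources) -> tuple[str, ...]:
    sources = tuple(sources)
    if not sources:
        raise ConfigError("sources set must not be empty")
    unknown = set(sources) - set(SOURCES)
    if unknown:
        raise ConfigError(f"unknown barcode sources: {sorted(unknown)}")
    return sources


def _barcoded_mask(catalog: SpeciesCatalog, sources):
    mask = False
    for src in sources:
        mask = mask | catalog.df[_FLAG[src]]
    return mask


def reduce_catalog(catalog: SpeciesCatalog, sources=SOURCES) -> SpeciesCatalog:
    """Sub-catalog of species with a barcode in at least one requested source
    (union semantics); input ordering preserved."""
    sources = _check_sources(sources)
    mask = _barcoded_mask(catalog, sources)
    reduced = SpeciesCatalog(catalog.df[mask].reset_index(drop=True))
    if len(reduced) == 0:
        logger.warning("reduced catalog is empty: no species barcoded in %s",
                       sources)
    return reduced


def reduce_community(community: CommunityTable,
                     reduced: SpeciesCatalog) -> CommunityTable:
    """Drop community entries whose taxon lacks a barcode.

    (site, season) sample keys are preserved even when every species of a
    sample is dropped; such samples become azoic under the reduced database
    and are flagged by a log notice.
    """
    out = community.subset_taxa(reduced.taxa)
    have = {(s, t) for s, t in
            zip(out.df.loc[out.df["abundance"] > 0, "site_id"],
                out.df.loc[out.df["abundance"] > 0, "season"])}
    azoic = [k for k in out.sample_keys if k not in have]
    if azoic:
        logger.warning("samples azoic under reduction: %s", azoic)
    return out


def coverage_stats(catalog: SpeciesCatalog, sources=SOURCES) -> CoverageSummary:
    """Overall and per-phylum barcode coverage of a catalog.

    Percentages are 100 * n_barcoded / n_total, carried unrounded with a
    half-up integer rounding for display.
    """
    sources = _check_sources(sources)
    if len(catalog) == 0:
        raise ValidationError("cannot compute coverage of an empty catalog")
    mask = _barcoded_mask(catalog, sources)
    per_phylum: dict[str, PhylumCoverage] = {}
    for ph, sub in catalog.df.groupby("phylum", sort=True):
        per_phylum[ph] = PhylumCoverage(len(sub), int(mask[sub.index].sum()))
    return CoverageSummary(
        n_total=len(catalog),
        n_barcoded=int(mask.sum()),
        per_phylum=per_phylum,
    )
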