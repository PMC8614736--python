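"""Biodiversity descriptors and the AMBI biotic coefficient.

Per (site, season, database) sample this module computes species richness S,
Shannon diversity H (default log base 2, base recorded) and the AMBI
coefficient: the abundance-weighted mean of the ecological-group weights

    AMBI = 0*fI + 1.5*fII + 3*fIII + 4.5*fIV + 6*fV,

with f_i the fraction of *assigned* individuals in group i (individuals of
not-assigned species are excluded by renormalization).  A sample whose
not-assigned fraction exceeds the validity threshold (default 20%) still gets
a value but is flagged invalid; an azoic sample (zero total abundance) gets
the sentinel AMBI value (default 7) and zero richness and diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .errors import AzoicError, TaxonLookupError
from .tables_io import CommunityTable, SpeciesCatalog

#: Weights of the five ecological groups, I (sensitive) .. V (first-order
#: opportunists).  Config-exposed via the ``weights`` argument of :func:`ambi`.
AMBI_WEIGHTS = {"I": 0.0, "II": 1.5, "III": 3.0, "IV": 4.5, "V": 6.0}

#: Sentinel coefficient reported for azoic samples (worst status downstream).
AZOIC_AMBI = 7.0


@dataclass
class MetricsRecord:
    """Descriptor triple of one sample under one database."""

    site_id: str
    season: str
    database: str
    s: int
    h: float
    ambi: float
    na_fraction: float
    ambi_valid: bool
    azoic: bool
    log_base: float = 2.0


def richness(abundances: Mapping[str, float]) -> int:
    """Number of taxa with strictly positive abundance."""
    return sum(1 for a in abundances.values() if a > 0)


def shannon(abundances: Mapping[str, float], log_base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i) in the requested base.

    Zero-abundance taxa are ignored; a single-taxon sample gives 0; an
    all-zero sample raises :class:`AzoicError` (azoic samples are the
    caller's responsibility).
    """
    values = [a for a in abundances.values() if a > 0]
    total = sum(values)
    if total <= 0:
        raise AzoicError("Shannon diversity undefined for an azoic sample")
    h = 0.0
    for a in values:
        p = a / total
        h -= p * math.log(p)
    return h / math.log(log_base)


def ambi(abundances: Mapping[str, float], catalog: SpeciesCatalog,
         na_threshold: float = 0.20,
         weights: Mapping[str, float] = AMBI_WEIGHTS,
         azoic_value: float = AZOIC_AMBI) -> tuple[float, float, bool]:
    """AMBI coefficient of one sample.

    Returns ``(ambi_value, na_fraction, ambi_valid)``.  ``na_fraction`` is the
    share of individuals belonging to not-assigned (group ``NA``) species;
    the coefficient is the weighted mean over assigned individuals only, and
    ``ambi_valid`` is False when the not-assigned share exceeds the threshold.
    An azoic sample returns the sentinel value with ``ambi_valid`` False.
    """
    groups = catalog.group_of()
    missing = [t for t, a in abundances.items() if a > 0 and t not in groups]
    if missing:
        raise TaxonLookupError(
            "taxa missing from catalog: " + ", ".join(sorted(missing)))
    total = sum(a for a in abundances.values() if a > 0)
    if total <= 0:
        return azoic_value, 0.0, False
    na_abundance = sum(a for t, a in abundances.items()
                       if a > 0 and groups[t] == "NA")
    assigned = total - na_abundance
    na_fraction = na_abundance / total
    if assigned <= 0:
        # every individual unassigned: no coefficient can be formed
        return float("nan"), na_fraction, False
    value = sum(weights[groups[t]] * a for t, a in abundances.items()
                if a > 0 and groups[t] != "NA") / assigned
    return value, na_fraction, na_fraction <= na_threshold


def community_metrics(community: CommunityTable, catalog: SpeciesCatalog,
                      database: str, log_base: float = 2.0,
                      na_threshold: float = 0.20,
                      azoic_value: float = AZOIC_AMBI) -> list[MetricsRecord]:
    """Compute (S, H, AMBI) for every sampled (site, season) of a community.

    Azoic samples (including samples emptied by database reduction) are
    retained with S = 0, H = 0 and the sentinel AMBI value.
    """
    community.validate_against(catalog)
    records = []
    for site_id, season in community.sample_keys:
        ab = community.abundances(site_id, season)
        s = richness(ab)
        if s == 0:
            records.append(MetricsRecord(site_id, season, database,
                                         0, 0.0, azoic_value, 0.0,
                                         False, True, log_base))
            continue
        h = 0.0 if s == 1 else shannon(ab, log_base)
        value, na_frac, valid = ambi(ab, catalog, na_threshold,
                                     azoic_value=azoic_value)
        records.append(MetricsRecord(site_id, season, database,
                                     s, h, value, na_frac, valid,
                                     False, log_base))
    return records
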