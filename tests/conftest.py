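"""Shared fixtures: small hand-built catalogs and communities."""

import pandas as pd
import pytest
from hypothesis import settings

from barcodegap.tables_io import CommunityTable, SpeciesCatalog

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


def make_catalog(rows):
    """rows: list of (name, phylum, group, bold, genbank)."""
    return SpeciesCatalog(pd.DataFrame(
        [{"taxon_name": n, "phylum": p, "ecological_group": g,
          "barcoded_bold": b, "barcoded_genbank": gb,
          "primer_reported": None}
         for n, p, g, b, gb in rows]))


def make_community(entries, seasons=("fall", "spring")):
    """entries: list of (site, season, taxon, abundance)."""
    return CommunityTable(pd.DataFrame(
        [{"site_id": s, "season": se, "taxon_name": t, "abundance": a}
         for s, se, t, a in entries]), seasons=seasons)


@pytest.fixture
def small_catalog():
    return make_catalog([
        ("Aphelochaeta marioni", "Annelida", "IV", True, False),
        ("Cerastoderma glaucum", "Mollusca", "III", True, True),
        ("Gammarus aequicauda", "Arthropoda", "I", False, True),
        ("Hediste diversicolor", "Annelida", "III", False, False),
        ("Abra segmentum", "Mollusca", "III", True, False),
        ("Mysidopsis gibbosa", "Arthropoda", "NA", False, False),
    ])


@pytest.fixture
def small_community():
    return make_community([
        ("s1", "fall", "Aphelochaeta marioni", 10),
        ("s1", "fall", "Cerastoderma glaucum", 5),
        ("s1", "fall", "Hediste diversicolor", 3),
        ("s1", "spring", "Gammarus aequicauda", 7),
        ("s1", "spring", "Abra segmentum", 2),
        ("s2", "fall", "Hediste diversicolor", 20),
        ("s2", "fall", "Mysidopsis gibbosa", 1),
        ("s2", "spring", "Cerastoderma glaucum", 4),
        ("s2", "spring", "Gammarus aequicauda", 6),
        ("s2", "spring", "Abra segmentum", 9),
    ])
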