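"""Readers, writers and validation for catalogs, community tables, quality-class
grids, FASTA alignments and newick trees.

The tabular formats are plain delimited text (comma or tab, auto-detected).
Taxon names are normalized before joining: whitespace collapsed, case folded to
the conventional binomial form (leading capital, rest lower).  Joining across
tables is exact string matching on the normalized name; synonym resolution
against external taxonomic registries is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateError,
    SchemaError,
    TaxonLookupError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Admissible AMBI ecological-group labels (I sensitive ... V first-order
#: opportunists; NA = not assigned).
ECOLOGICAL_GROUPS = ("I", "II", "III", "IV", "V", "NA")

#: Closed season vocabulary of the survey design (fall 2010 / spring 2011 style
#: two-season sampling).  Extend via the ``seasons`` argument of the readers.
SEASONS = ("fall", "spring")

#: Database labels of a paired morphological-vs-reduced comparison.
DATABASES = ("morphological", "reduced")

#: Five WFD quality classes with their fixed ordinal encoding.
EQS_CLASSES = ("Bad", "Poor", "Moderate", "Good", "High")
EQS_ORDINAL = {label: i for i, label in enumerate(EQS_CLASSES)}

#: IUPAC nucleotide one-letter codes (15 codes) plus the gap character.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")
GAP = "-"

# base sets of the IUPAC codes, used for primer matching and consensus calls
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
# reverse lookup: frozenset of bases -> minimal covering code
CODE_FOR_BASES = {bases: code for code, bases in IUPAC_BASES.items()}


def normalize_taxon(name: str) -> str:
    """Normalize a taxon name for exact-match joining.

    Trims, collapses internal whitespace and folds case to the binomial
    convention (``"nereis  FALSA"`` -> ``"Nereis falsa"``).  Idempotent.
    """
    s = " ".join(str(name).split()).lower()
    return s[:1].upper() + s[1:]


def _read_delimited(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # sep=None lets pandas sniff comma vs tab; keep_default_na=False so the
    # ecological-group label "NA" survives as a string
    return pd.read_csv(path, sep=sep, engine="python", dtype=str,
                       skip_blank_lines=True, keep_default_na=False)


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} file is missing required column(s): {', '.join(missing)}"
        )


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", "", "nan"}


def _parse_bool(value: object, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(
        f"row {row}: cannot interpret {value!r} as boolean in column {column}"
    )


# ---------------------------------------------------------------------------
# Species catalog
# ---------------------------------------------------------------------------

@dataclass
class SpeciesCatalog:
    """Checklist of benthic macroinvertebrate species.

    One record per species with its phylum, AMBI ecological group (I-V or
    ``"NA"`` when not assigned) and barcode-availability flags per reference
    library (BOLD / GenBank).  Taxon names are stored normalized and are
    unique.
    """

    df: pd.DataFrame = field(repr=False)

    _COLUMNS = ("taxon_name", "phylum", "ecological_group",
                "barcoded_bold", "barcoded_genbank", "primer_reported")

    def __post_init__(self) -> None:
        df = self.df
        for col in self._COLUMNS[:5]:
            if col not in df.columns:
                raise SchemaError(f"catalog is missing column {col}")
        if "primer_reported" not in df.columns:
            df = df.assign(primer_reported=None)
        bad = ~df["ecological_group"].isin(ECOLOGICAL_GROUPS)
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"row {row}: illegal ecological group "
                f"{df['ecological_group'].iloc[row]!r} "
                f"(admissible: {', '.join(ECOLOGICAL_GROUPS)})"
            )
        dup = df["taxon_name"].duplicated(keep=False)
        if dup.any():
            names = sorted(df.loc[dup, "taxon_name"].unique())
            raise DuplicateError(
                f"duplicate taxa after normalization: {', '.join(names)}"
            )
        self.df = df.reset_index(drop=True)[list(self._COLUMNS)]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list[str]:
        return self.df["taxon_name"].tolist()

    @property
    def phyla(self) -> list[str]:
        return sorted(self.df["phylum"].unique())

    def group_of(self) -> dict[str, str]:
        """Map normalized taxon name -> ecological group label."""
        return dict(zip(self.df["taxon_name"], self.df["ecological_group"]))

    def subset(self, taxa: Iterable[str]) -> "SpeciesCatalog":
        keep = set(taxa)
        return SpeciesCatalog(
            self.df[self.df["taxon_name"].isin(keep)].reset_index(drop=True)
        )


def read_catalog(path: str | Path, sep: str | None = None) -> SpeciesCatalog:
    """Read and validate a species catalog from delimited text.

    Required columns: ``taxon_name, phylum, ecological_group, barcoded_bold,
    barcoded_genbank`` (``primer_reported`` optional).  Raises
    :class:`SchemaError` on a missing column, :class:`DuplicateError` when two
    raw names collide after normalization (both raw spellings are reported) and
    :class:`ValidationError` on an illegal ecological-group label.
    """
    raw = _read_delimited(path, sep)
    _require_columns(raw, SpeciesCatalog._COLUMNS[:5], "catalog")
    norm = raw["taxon_name"].map(normalize_taxon)
    dup = norm.duplicated(keep=False)
    if dup.any():
        raw_names = sorted(raw.loc[dup, "taxon_name"].unique())
        raise DuplicateError(
            "duplicate taxa after normalization; raw names: "
            + ", ".join(repr(n) for n in raw_names)
        )
    df = pd.DataFrame({
        "taxon_name": norm,
        "phylum": raw["phylum"].str.strip(),
        "ecological_group": raw["ecological_group"].str.strip(),
        "barcoded_bold": [
            _parse_bool(v, "barcoded_bold", i)
            for i, v in enumerate(raw["barcoded_bold"])
        ],
        "barcoded_genbank": [
            _parse_bool(v, "barcoded_genbank", i)
            for i, v in enumerate(raw["barcoded_genbank"])
        ],
        "primer_reported": (raw["primer_reported"].replace("", None)
                            if "primer_reported" in raw.columns else None),
    })
    return SpeciesCatalog(df)


def write_catalog(catalog: SpeciesCatalog, path: str | Path,
                  sep: str = "\t") -> None:
    catalog.df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Community table
# ---------------------------------------------------------------------------

@dataclass
class CommunityTable:
    """Long-format (site, season, taxon) -> abundance table.

    The (site, season) grid may be ragged, but each triple is unique.  The
    full set of sampled (site, season) keys is remembered so that a sample
    whose every species is later dropped (azoic under reduction) keeps its
    row in downstream outputs.
    """

    df: pd.DataFrame = field(repr=False)
    sample_keys: tuple[tuple[str, str], ...] = ()
    seasons: tuple[str, ...] = SEASONS

    def __post_init__(self) -> None:
        df = self.df
        for col in ("site_id", "season", "taxon_name", "abundance"):
            if col not in df.columns:
                raise SchemaError(f"community table is missing column {col}")
        df = df.assign(abundance=pd.to_numeric(df["abundance"]))
        neg = df["abundance"] < 0
        if neg.any():
            row = int(neg.idxmax())
            raise ValidationError(
                f"row {row}: negative abundance "
                f"{df['abundance'].iloc[row]} for {df['taxon_name'].iloc[row]}"
            )
        bad_season = ~df["season"].isin(self.seasons)
        if bad_season.any():
            row = int(bad_season.idxmax())
            raise ValidationError(
                f"row {row}: season {df['season'].iloc[row]!r} not in "
                f"{self.seasons}"
            )
        key = df[["site_id", "season", "taxon_name"]]
        dup = key.duplicated(keep=False)
        if dup.any():
            cells = key[dup].drop_duplicates().itertuples(index=False)
            raise DuplicateError(
                "duplicate (site, season, taxon) triples: "
                + "; ".join(f"({c.site_id}, {c.season}, {c.taxon_name})"
                            for c in cells)
            )
        self.df = df.reset_index(drop=True)
        if not self.sample_keys:
            self.sample_keys = tuple(
                sorted({(s, t) for s, t in
                        zip(df["site_id"], df["season"])})
            )
        pos = self.df.loc[self.df["abundance"] > 0, "abundance"]
        if len(pos) and (pos == 1).all():
            logger.warning(
                "community looks like presence/absence data (all positive "
                "abundances equal 1); Shannon and AMBI degrade to "
                "richness-driven values"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.df["taxon_name"].unique())

    def abundances(self, site_id: str, season: str) -> dict[str, float]:
        sub = self.df[(self.df["site_id"] == site_id)
                      & (self.df["season"] == season)]
        return dict(zip(sub["taxon_name"], sub["abundance"]))

    def validate_against(self, catalog: SpeciesCatalog) -> None:
        unknown = set(self.df["taxon_name"]) - set(catalog.taxa)
        if unknown:
            raise TaxonLookupError(
                "community taxa absent from catalog: "
                + ", ".join(sorted(unknown))
            )

    def subset_taxa(self, taxa: Iterable[str]) -> "CommunityTable":
        """Keep only the given taxa; sampled (site, season) keys preserved."""
        keep = set(taxa)
        return CommunityTable(
            self.df[self.df["taxon_name"].isin(keep)].reset_index(drop=True),
            sample_keys=self.sample_keys, seasons=self.seasons,
        )


def read_community(path: str | Path, sep: str | None = None,
                   seasons: tuple[str, ...] = SEASONS,
                   catalog: SpeciesCatalog | None = None) -> CommunityTable:
    """Read a long-format community table (site, season, taxon, abundance).

    Zero-abundance rows are retained (they mark recorded absences).  If a
    catalog is supplied, every taxon must appear in it.
    """
    raw = _read_delimited(path, sep)
    _require_columns(raw, ("site_id", "season", "taxon_name", "abundance"),
                     "community")
    df = pd.DataFrame({
        "site_id": raw["site_id"].str.strip(),
        "season": raw["season"].str.strip().str.lower(),
        "taxon_name": raw["taxon_name"].map(normalize_taxon),
        "abundance": raw["abundance"],
    })
    table = CommunityTable(df, seasons=seasons)
    if catalog is not None:
        table.validate_against(catalog)
    return table


def write_community(community: CommunityTable, path: str | Path,
                    sep: str = "\t") -> None:
    community.df.to_csv(path, sep=sep, index=False)


def wide_to_long(wide: pd.DataFrame, season: str) -> pd.DataFrame:
    """Convert a wide site x species abundance matrix to the long schema.

    The wide frame has sites as its index and species as columns; one call
    per season.
    """
    long = wide.rename_axis("site_id").reset_index().melt(
        id_vars="site_id", var_name="taxon_name", value_name="abundance")
    long.insert(1, "season", season)
    long["taxon_name"] = long["taxon_name"].map(normalize_taxon)
    return long


# ---------------------------------------------------------------------------
# EQS class table
# ---------------------------------------------------------------------------

@dataclass
class EqsClassTable:
    """(site, season, database) -> WFD quality class, ordinal Bad=0..High=4."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("site_id", "season", "database", "eqs_class"):
            if col not in df.columns:
                raise SchemaError(f"class table is missing column {col}")
        bad = ~df["eqs_class"].isin(EQS_CLASSES)
        if bad.any():
            row = int(bad.idxmax())
            raise ValidationError(
                f"row {row}: unknown quality class "
                f"{df['eqs_class'].iloc[row]!r}"
            )
        bad_db = ~df["database"].isin(DATABASES)
        if bad_db.any():
            row = int(bad_db.idxmax())
            raise ValidationError(
                f"row {row}: unknown database label "
                f"{df['database'].iloc[row]!r}"
            )
        dup = df[["site_id", "season", "database"]].duplicated(keep=False)
        if dup.any():
            raise DuplicateError("duplicate (site, season, database) keys")
        df = df.assign(ordinal=df["eqs_class"].map(EQS_ORDINAL))
        self.df = df.reset_index(drop=True)


def read_classes(path: str | Path, sep: str | None = None) -> EqsClassTable:
    raw = _read_delimited(path, sep)
    _require_columns(raw, ("site_id", "season", "database", "eqs_class"),
                     "class table")
    return EqsClassTable(raw[["site_id", "season", "database",
                              "eqs_class"]].copy())


def load_published_eqs_grid() -> EqsClassTable:
    """Packaged worked example: the published EQS class grid for the 15
    Apulian transitional-water sampling sites (fall 2010 / spring 2011) under
    the morphological and the barcode-reduced database."""
    ref = resources.files("barcodegap.data") / "apulia_eqs_grid.tsv"
    with resources.as_file(ref) as path:
        return read_classes(path, sep="\t")


def load_folmer_primers() -> pd.DataFrame:
    """Packaged universal COI primer pairs (LCO1490/HCO2198 and a degenerate
    variant with inosine positions encoded as N)."""
    ref = resources.files("barcodegap.data") / "primers_folmer.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sequences and trees
# ---------------------------------------------------------------------------

@dataclass
class AlignedSequences:
    """A multiple alignment keyed by (accession, species label).

    FASTA headers are parsed as ``>accession species name...``; the species
    label may be empty.  All sequences share one alignment length and use the
    IUPAC nucleotide alphabet plus ``-`` for gaps.
    """

    accessions: list[str]
    species: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences} | set()) > 1:
            lengths = sorted({len(s) for s in self.sequences})
            raise ValidationError(
                f"ragged alignment: sequence lengths {lengths}"
            )
        allowed = IUPAC_CODES | {GAP}
        for acc, seq in zip(self.accessions, self.sequences):
            bad = set(seq.upper()) - allowed
            if bad:
                raise ValidationError(
                    f"sequence {acc}: illegal characters {sorted(bad)}"
                )
        self.sequences = [s.upper() for s in self.sequences]
        if len(set(self.accessions)) != len(self.accessions):
            raise DuplicateError("duplicate accessions in alignment")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def by_species(self) -> dict[str, "AlignedSequences"]:
        """Split the alignment into one sub-alignment per species label."""
        out: dict[str, AlignedSequences] = {}
        for label in sorted(set(self.species)):
            idx = [i for i, s in enumerate(self.species) if s == label]
            out[label] = AlignedSequences(
                [self.accessions[i] for i in idx],
                [label] * len(idx),
                [self.sequences[i] for i in idx],
            )
        return out


def read_fasta(path: str | Path) -> AlignedSequences:
    """Read an aligned FASTA file; raises on ragged alignments."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"no sequences in {path}")
    accessions, species, seqs = [], [], []
    for rec in records:
        accessions.append(rec.id)
        parts = rec.description.split(None, 1)
        species.append(parts[1].strip() if len(parts) > 1 else "")
        seqs.append(str(rec.seq))
    return AlignedSequences(accessions, species, seqs)


def write_fasta(aln: AlignedSequences, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description=sp)
        for acc, sp, seq in zip(aln.accessions, aln.species, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; malformed input raises :class:`ValidationError`
    carrying the tokenizer's position information."""
    try:
        return dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several tokenizer errors
        raise ValidationError(f"malformed newick in {path}: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
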