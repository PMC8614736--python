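"""Morphological-vs-reduced comparison: EQS class divergence accounting,
paired correlations, and the end-to-end pipeline driver.

Class divergence uses the fixed ordinal encoding Bad=0 .. High=4; any nonzero
signed distance ordinal(reduced) - ordinal(morphological) counts as a
divergence, and the maximum absolute distance is reported so multi-class
jumps are surfaced rather than hidden.  Correlations are computed per season
(pooling available behind a flag), Pearson r with the two-sided t-transform
p-value, unadjusted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .errors import (
    ConfigError,
    PairingError,
    UndefinedCorrelationError,
)
from .indices import MetricsRecord, community_metrics
from .mambi import (
    EqsThresholds,
    MambiResult,
    ReferenceConditions,
    classify_all,
    default_references,
    mambi_scores,
)
from .reduction import coverage_stats, reduce_catalog, reduce_community, round_half_up
from .tables_io import (
    CommunityTable,
    EqsClassTable,
    SpeciesCatalog,
    write_catalog,
    write_community,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("S", "H", "AMBI", "MAMBI")


@dataclass
class DivergenceSummary:
    """Accounting of EQS class differences between the two databases."""

    n_comparisons: int
    n_divergent: int
    n_reduced_better: int
    n_reduced_worse: int
    max_class_distance: int
    per_cell: pd.DataFrame = field(repr=False)

    @property
    def percent_divergent(self) -> float:
        return 100.0 * self.n_divergent / self.n_comparisons

    @property
    def percent_divergent_rounded(self) -> int:
        return round_half_up(self.percent_divergent)


@dataclass
class CorrelationResult:
    metric: str
    season: str
    r: float
    p_value: float
    n: int


def class_divergence(classes: EqsClassTable) -> DivergenceSummary:
    """Pair the two databases cell-by-cell and count class divergences.

    Every (site, season) must be classified under both databases; a missing
    partner raises :class:`PairingError` naming the cell.
    """
    df = classes.df
    wide = df.pivot_table(index=["site_id", "season"], columns="database",
                          values="ordinal", aggfunc="first")
    for db in ("morphological", "reduced"):
        if db not in wide.columns:
            raise PairingError(f"no cells for database {db!r}")
        missing = wide.index[wide[db].isna()]
        if len(missing):
            site, season = missing[0]
            raise PairingError(
                f"cell (site {site}, {season}) missing under {db!r}")
    per_cell = wide.reset_index()
    per_cell["signed_distance"] = (per_cell["reduced"]
                                   - per_cell["morphological"]).astype(int)
    rev = {v: k for k, v in
           {"Bad": 0, "Poor": 1, "Moderate": 2, "Good": 3, "High": 4}.items()}
    per_cell["class_morph"] = per_cell["morphological"].astype(int).map(rev)
    per_cell["class_reduced"] = per_cell["reduced"].astype(int).map(rev)
    per_cell = per_cell[["site_id", "season", "class_morph", "class_reduced",
                         "signed_distance"]].sort_values(
        ["site_id", "season"]).reset_index(drop=True)
    d = per_cell["signed_distance"]
    return DivergenceSummary(
        n_comparisons=len(per_cell),
        n_divergent=int((d != 0).sum()),
        n_reduced_better=int((d > 0).sum()),
        n_reduced_worse=int((d < 0).sum()),
        max_class_distance=int(d.abs().max()) if len(d) else 0,
        per_cell=per_cell,
    )


def pearson(x: Sequence[float], y: Sequence[float],
            metric: str = "", season: str = "") -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p (t transform,
    n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("x and y must be 1-d vectors of equal length")
    if len(x) < 3:
        raise ConfigError("need at least 3 pairs for a correlation test")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: zero variance in input")
    res = scipy.stats.pearsonr(x, y)
    return CorrelationResult(metric, season, float(res.statistic),
                             float(res.pvalue), len(x))


def paired_metrics(morph: list[MetricsRecord], reduced: list[MetricsRecord],
                   metric: str, season: str | None = None,
                   mambi_morph: list[MambiResult] | None = None,
                   mambi_reduced: list[MambiResult] | None = None,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Aligned morphological/reduced value vectors for one metric.

    Records are matched on (site, season) and returned in deterministic
    sorted key order; an unmatched key raises :class:`PairingError`.
    ``metric`` is one of S, H, AMBI, MAMBI (the last requires the
    corresponding score lists).
    """
    if metric not in METRIC_NAMES:
        raise ConfigError(f"unknown metric {metric!r}; use one of "
                          f"{METRIC_NAMES}")

    def extract(records, scores):
        if metric == "MAMBI":
            if scores is None:
                raise ConfigError("MAMBI pairing requires score lists")
            return {(r.site_id, r.season): r.score for r in scores
                    if season is None or r.season == season}
        attr = {"S": "s", "H": "h", "AMBI": "ambi"}[metric]
        return {(r.site_id, r.season): getattr(r, attr) for r in records
                if season is None or r.season == season}

    a = extract(morph, mambi_morph)
    b = extract(reduced, mambi_reduced)
    if set(a) != set(b):
        odd = sorted(set(a) ^ set(b))
        raise PairingError(f"unmatched (site, season) keys: {odd}")
    if not a:
        raise PairingError("no overlapping (site, season) keys")
    keys = sorted(a)
    return (np.array([a[k] for k in keys]), np.array([b[k] for k in keys]))


@dataclass
class PipelineConfig:
    """End-to-end run configuration (all defaults config-exposed)."""

    sources: tuple[str, ...] = ("bold", "genbank")
    log_base: float = 2.0
    na_threshold: float = 0.20
    azoic_ambi: float = 7.0
    inflation: float = 1.15
    n_factors: int = 3
    boundaries: tuple[float, float, float, float] = (0.77, 0.53, 0.39, 0.20)
    shared_references: bool = True
    pool_seasons: bool = False
    references: ReferenceConditions | None = None
    seed: int | None = None


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    mambi: pd.DataFrame
    classes: EqsClassTable
    divergence: DivergenceSummary
    correlations: pd.DataFrame
    coverage: "CoverageSummary"  # noqa: F821 - from reduction
    references: ReferenceConditions


def _metrics_frame(records, scores) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    sc = pd.DataFrame([asdict(s) for s in scores])
    df = df.merge(sc[["site_id", "season", "database", "score", "raw_score",
                      "eqs_class"]], on=["site_id", "season", "database"])
    return df.sort_values(["database", "site_id",
                           "season"]).reset_index(drop=True)


def run_pipeline(catalog: SpeciesCatalog, community: CommunityTable,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Full analysis: reduce, compute indices, score M-AMBI, classify,
    and quantify morphological-vs-reduced divergence and correlation.

    With ``outdir`` given, writes every table as delimited text plus a run
    log (seed, config hash, package and library versions).  Re-running with
    identical inputs reproduces byte-identical outputs.
    """
    config = config or PipelineConfig()
    community.validate_against(catalog)

    reduced_catalog = reduce_catalog(catalog, config.sources)
    reduced_community = reduce_community(community, reduced_catalog)
    coverage = coverage_stats(catalog, config.sources)

    kw = dict(log_base=config.log_base, na_threshold=config.na_threshold,
              azoic_value=config.azoic_ambi)
    morph = community_metrics(community, catalog, "morphological", **kw)
    redu = community_metrics(reduced_community, catalog, "reduced", **kw)

    if config.references is not None:
        refs = config.references
    elif config.shared_references:
        refs = default_references(morph + redu, config.inflation)
    else:
        refs = None  # per-database references

    thresholds = EqsThresholds(config.boundaries)
    scores = {}
    for db, records in (("morphological", morph), ("reduced", redu)):
        db_refs = refs if refs is not None else default_references(
            records, config.inflation)
        scores[db] = classify_all(
            mambi_scores(records, db_refs, config.n_factors), thresholds)
    used_refs = refs if refs is not None else default_references(
        morph, config.inflation)

    class_rows = [
        {"site_id": r.site_id, "season": r.season, "database": r.database,
         "eqs_class": r.eqs_class}
        for db in ("morphological", "reduced") for r in scores[db]
    ]
    classes = EqsClassTable(pd.DataFrame(class_rows))
    divergence = class_divergence(classes)

    seasons = ([None] if config.pool_seasons
               else sorted({r.season for r in morph}))
    corr_rows = []
    for metric in METRIC_NAMES:
        for season in seasons:
            x, y = paired_metrics(morph, redu, metric, season,
                                  scores["morphological"], scores["reduced"])
            try:
                c = pearson(x, y, metric, season or "pooled")
            except UndefinedCorrelationError:
                logger.warning("correlation undefined for %s/%s", metric,
                               season)
                continue
            corr_rows.append(asdict(c))
    correlations = pd.DataFrame(corr_rows)

    metrics_df = pd.concat([
        _metrics_frame(morph, scores["morphological"]),
        _metrics_frame(redu, scores["reduced"]),
    ], ignore_index=True)

    result = PipelineResult(metrics_df, metrics_df[
        ["site_id", "season", "database", "score", "raw_score", "eqs_class"]
    ].copy(), classes, divergence, correlations, coverage, used_refs)

    if outdir is not None:
        _write_bundle(result, catalog, reduced_catalog, reduced_community,
                      config, Path(outdir))
    return result


def _config_hash(config: PipelineConfig) -> str:
    payload = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(config).items()}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_bundle(result: PipelineResult, catalog, reduced_catalog,
                  reduced_community, config: PipelineConfig,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_catalog(reduced_catalog, outdir / "reduced_catalog.tsv")
    write_community(reduced_community, outdir / "reduced_community.tsv")
    result.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    result.classes.df.to_csv(outdir / "eqs_classes.tsv", sep="\t",
                             index=False)
    result.divergence.per_cell.to_csv(outdir / "divergence_cells.tsv",
                                      sep="\t", index=False)
    result.correlations.to_csv(outdir / "correlations.tsv", sep="\t",
                               index=False)
    cov = result.coverage
    cov_rows = [{"phylum": "ALL", "n_total": cov.n_total,
                 "n_barcoded": cov.n_barcoded,
                 "percent_barcoded": cov.percent_barcoded}]
    for ph, c in cov.per_phylum.items():
        cov_rows.append({"phylum": ph, "n_total": c.n_total,
                         "n_barcoded": c.n_barcoded,
                         "percent_barcoded": c.percent_barcoded})
    pd.DataFrame(cov_rows).to_csv(outdir / "coverage.tsv", sep="\t",
                                  index=False)
    log = {
        "package": f"barcodegap {__version__}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "divergence": {
            "n_comparisons": result.divergence.n_comparisons,
            "n_divergent": result.divergence.n_divergent,
            "percent_divergent": result.divergence.percent_divergent,
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                    sort_keys=True))
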