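"""M-AMBI: factor-analysis combination of (AMBI, H, S) scaled between
reference conditions, and the five-class WFD quality classification.

The construction is deterministic: the sample rows plus the two reference
rows ("high" = pristine, "bad" = worst) are standardized column-wise, the
correlation matrix is eigen-decomposed, every row is projected onto the
leading factors, and each sample is scored by the scalar projection of its
displacement from "bad" onto the bad->high axis in factor space.  The high
reference scores exactly 1 and the bad reference exactly 0; sample scores are
clamped to [0, 1] (the raw score is kept for diagnostics).  With all three
factors retained the projection is an isometry of the standardized space, so
the score equals the direct standardized-space computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateInputError, ReferenceError_
from .indices import MetricsRecord
from .tables_io import EQS_CLASSES

#: Default class boundaries high/good, good/moderate, moderate/poor, poor/bad
#: (WFD intercalibration values in common use for transitional waters; the
#: boundaries are fully config-exposed).
DEFAULT_BOUNDARIES = (0.77, 0.53, 0.39, 0.20)


@dataclass
class ReferenceConditions:
    """Anchor metric triplets for the M-AMBI scale."""

    high: tuple[float, float, float]  # (ambi, h, s)
    bad: tuple[float, float, float] = (6.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        ha, hh, hs = self.high
        ba, bh, bs = self.bad
        if not (ha < ba and hh > bh and hs > bs):
            raise ConfigError(
                "invalid reference conditions: require high.ambi < bad.ambi, "
                "high.h > bad.h, high.s > bad.s; got "
                f"high={self.high}, bad={self.bad}"
            )


@dataclass
class EqsThresholds:
    """Four strictly descending boundaries in (0, 1)."""

    boundaries: tuple[float, float, float, float] = DEFAULT_BOUNDARIES

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.boundaries)
        if len(b) != 4 or any(not (0 < x < 1) for x in b) or \
                any(b[i] <= b[i + 1] for i in range(3)):
            raise ConfigError(
                f"boundaries must be four strictly descending values in "
                f"(0, 1); got {self.boundaries}"
            )
        self.boundaries = b


@dataclass
class MambiResult:
    site_id: str
    season: str
    database: str
    score: float
    raw_score: float
    eqs_class: str = ""
    azoic: bool = False


def default_references(metrics: list[MetricsRecord],
                       inflation: float = 1.15) -> ReferenceConditions:
    """Derive reference conditions from observed data.

    "bad" is the azoic anchor (AMBI 6, H 0, S 0); "high" takes AMBI 0 with
    diversity and richness at the observed maxima inflated by a safety factor
    (default 15%) so that real samples rarely sit beyond the pristine anchor.
    User-supplied references override this entirely.
    """
    usable = [m for m in metrics if not m.azoic]
    if not usable:
        raise ReferenceError_(
            "cannot derive reference conditions: all samples azoic")
    max_h = max(m.h for m in usable)
    max_s = max(m.s for m in usable)
    if max_h <= 0 or max_s <= 0:
        raise ReferenceError_(
            "cannot derive reference conditions: no sample with positive "
            "diversity and richness")
    return ReferenceConditions(high=(0.0, inflation * max_h,
                                     inflation * max_s))


def mambi_scores(metrics: list[MetricsRecord], refs: ReferenceConditions,
                 n_factors: int = 3) -> list[MambiResult]:
    """Score every sample on the 0-1 M-AMBI scale.

    Azoic samples are scored 0 directly.  Raises
    :class:`DegenerateInputError` when a column has zero variance across the
    assembled (samples + references) matrix, because standardization is then
    undefined.
    """
    if not metrics:
        raise ConfigError("no metrics records to score")
    if n_factors < 1:
        raise ConfigError("n_factors must be >= 1")
    scored = [m for m in metrics if not m.azoic]
    rows = np.array([[m.ambi, m.h, m.s] for m in scored], dtype=float)
    X = np.vstack([rows.reshape(-1, 3),
                   np.asarray(refs.high, dtype=float),
                   np.asarray(refs.bad, dtype=float)])
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    if np.any(std <= 0):
        cols = np.array(["AMBI", "H", "S"])[std <= 0]
        raise DegenerateInputError(
            f"zero-variance column(s) {', '.join(cols)}: all samples equal "
            "the references; M-AMBI is undefined"
        )
    Z = (X - mean) / std
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    rank = int(np.sum(eigval[order] > 1e-12 * eigval[order[0]]))
    k = min(n_factors, rank, 3)
    V = eigvec[:, order[:k]]
    Y = Z @ V
    y_high, y_bad = Y[-2], Y[-1]
    axis = y_high - y_bad
    denom = float(axis @ axis)
    if denom <= 0:
        raise DegenerateInputError("reference rows coincide in factor space")
    raw = (Y[:-2] - y_bad) @ axis / denom

    results = []
    it = iter(raw)
    for m in metrics:
        if m.azoic:
            results.append(MambiResult(m.site_id, m.season, m.database,
                                       0.0, 0.0, azoic=True))
        else:
            r = float(next(it))
            results.append(MambiResult(m.site_id, m.season, m.database,
                                       min(1.0, max(0.0, r)), r))
    return results


def classify_eqs(score: float,
                 thresholds: EqsThresholds | None = None) -> str:
    """Map a clamped 0-1 score to its WFD class label.

    Boundary values belong to the upper class (a score exactly on the
    good/moderate boundary is Good).
    """
    if not 0.0 <= score <= 1.0:
        raise ConfigError(f"score {score} outside [0, 1]; clamp first")
    b = (thresholds or EqsThresholds()).boundaries
    labels = ("High", "Good", "Moderate", "Poor")
    for boundary, label in zip(b, labels):
        if score >= boundary:
            return label
    return "Bad"


def classify_all(results: list[MambiResult],
                 thresholds: EqsThresholds | None = None) -> list[MambiResult]:
    """Attach a class label to every result (azoic samples are Bad)."""
    for r in results:
        r.eqs_class = "Bad" if r.azoic else classify_eqs(r.score, thresholds)
    return results
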