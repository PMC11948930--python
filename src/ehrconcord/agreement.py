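"""Agreement statistics for paired binary classifications.

Implements the proportion-of-specific-agreement statistics (positive and
negative agreement in the Cicchetti–Feinstein sense), Youden's J, and a
marginal-consistency solver that recovers integer 2x2 cell counts from a
published table's margins and rounded positive agreement.

Orientation convention used throughout the package: rows of the 2x2
table are the survey self-report, columns the medical record, and the
medical record is the reference standard when computing sensitivity,
specificity, and J.  Neither source is a true gold standard here; the
concordant cells ``a`` and ``d`` are exactly that — concordant — and are
not presumed to be "true" positives or negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Tuple

POSITIVE = "positive"
NEGATIVE = "negative"
MISSING = "missing"


class DegenerateTableError(ValueError):
    """Every pair was missing, or a statistic's denominator is empty."""


class InconsistentTableError(ValueError):
    """No integer cell count reproduces the printed statistics."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties going up, at the precision used in printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwoTable:
    """Cross-classification counts: a=(+,+), b=(+,-), c=(-,+), d=(-,-).

    The first sign refers to the survey, the second to the medical
    record.  Pairs with a missing status in either source must be
    excluded before construction (see :func:`build_table`).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name!r} must be a nonnegative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_table(pairs: Iterable[Tuple[str, str]]) -> TwoByTwoTable:
    """Count (survey status, record status) pairs into a 2x2 table.

    Pairs in which either status is missing are dropped; if nothing
    remains a :class:`DegenerateTableError` is raised rather than
    returning an all-zero table.
    """
    a = b = c = d = 0
    for survey, record in pairs:
        if survey in (MISSING, None) or record in (MISSING, None):
            continue
        if survey == POSITIVE:
            if record == POSITIVE:
                a += 1
            else:
                b += 1
        else:
            if record == POSITIVE:
                c += 1
            else:
                d += 1
    if a + b + c + d == 0:
        raise DegenerateTableError("no pair has both statuses observed")
    return TwoByTwoTable(a, b, c, d)


def positive_agreement(t: TwoByTwoTable) -> Optional[float]:
    """2a / [N + (a - d)], identically 2a / (2a + b + c).

    Undefined (returns ``None``) when the denominator is zero, i.e. when
    neither source classifies anyone positive.
    """
    den = t.n + (t.a - t.d)
    if den <= 0:
        return None
    return 2 * t.a / den


def negative_agreement(t: TwoByTwoTable) -> Optional[float]:
    """2d / [N - (a - d)], identically 2d / (2d + b + c)."""
    den = t.n - (t.a - t.d)
    if den <= 0:
        return None
    return 2 * t.d / den


def sensitivity(t: TwoByTwoTable) -> Optional[float]:
    """Sensitivity of self-report in detecting record diagnoses: a/(a+c)."""
    margin = t.a + t.c
    if margin == 0:
        return None
    return t.a / margin


def specificity(t: TwoByTwoTable) -> Optional[float]:
    """Specificity of self-report against the record: d/(b+d)."""
    margin = t.b + t.d
    if margin == 0:
        return None
    return t.d / margin


def youden_j(t: TwoByTwoTable) -> Optional[float]:
    """Youden's J = sensitivity + specificity - 1, in [-1, 1].

    Prevalence-independent overall concordance; undefined when either
    record margin is empty.
    """
    se = sensitivity(t)
    sp = specificity(t)
    if se is None or sp is None:
        return None
    return se + sp - 1


@dataclass(frozen=True)
class AgreementResult:
    """Prevalences and agreement statistics for one comparison.

    ``n`` is the number of retained (dually observed) pairs, or 1.0 when
    the result was derived from cell probabilities rather than counts.
    Undefined statistics are ``None``, never coerced to zero.
    """

    condition: Optional[str]
    n: float
    survey_prevalence: Optional[float]
    ehr_prevalence: Optional[float]
    positive_agreement: Optional[float]
    negative_agreement: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    youden_j: Optional[float]

    @classmethod
    def from_cells(cls, a: float, b: float, c: float, d: float,
                   condition: Optional[str] = None) -> "AgreementResult":
        n = a + b + c + d
        if n <= 0:
            raise DegenerateTableError("empty table")
        pa = 2 * a / (2 * a + b + c) if (2 * a + b + c) > 0 else None
        na = 2 * d / (2 * d + b + c) if (2 * d + b + c) > 0 else None
        se = a / (a + c) if (a + c) > 0 else None
        sp = d / (b + d) if (b + d) > 0 else None
        j = se + sp - 1 if se is not None and sp is not None else None
        return cls(condition, n, (a + b) / n, (a + c) / n, pa, na, se, sp, j)

    @classmethod
    def from_table(cls, t: TwoByTwoTable,
                   condition: Optional[str] = None) -> "AgreementResult":
        return cls.from_cells(t.a, t.b, t.c, t.d, condition=condition)


def reconstruct_cells(n_total: int, n_survey: int, n_ehr: int,
                      pa_percent: float, decimals: int = 1) -> list[TwoByTwoTable]:
    """Invert a printed table row back to candidate integer cell counts.

    Given the overall N, the survey-positive and record-positive margins,
    and the positive agreement as printed (a percentage rounded half-up
    to ``decimals``), return every integer dual-positive count ``a``
    whose exact positive agreement rounds to the printed value, with the
    remaining cells filled from the margins.  Raises
    :class:`InconsistentTableError` when no integer ``a`` is consistent,
    which flags a contradiction in the printed table.
    """
    if n_survey > n_total or n_ehr > n_total:
        raise ValueError("margins cannot exceed the total")
    s = n_survey + n_ehr
    if s == 0:
        raise DegenerateTableError("both margins empty; positive agreement undefined")
    scale = 100 * 10 ** decimals
    target = int(round(pa_percent * 10 ** decimals))
    a_lo = max(0, s - n_total)          # keeps d nonnegative
    a_hi = min(n_survey, n_ehr)
    out = []
    for a in range(a_lo, a_hi + 1):
        # floor(2a*scale/s + 1/2), exact integer arithmetic, ties up
        if (4 * a * scale + s) // (2 * s) == target:
            out.append(TwoByTwoTable(a, n_survey - a, n_ehr - a, n_total - s + a))
    if not out:
        raise InconsistentTableError(
            f"no integer dual-positive count reproduces PA={pa_percent}% "
            f"with margins ({n_survey}, {n_ehr}) and N={n_total}")
    return out


def reconstructed_statistics(n_total: int, n_survey: int, n_ehr: int,
                             pa_percent: float, *, pa_decimals: int = 1,
                             na_decimals: int = 1,
                             j_decimals: int = 2) -> dict:
    """Reconstruct a row's cells and recompute its rounded NA and J.

    Returns the candidate tables plus the sets of rounded negative
    agreement (percent) and Youden's J values they imply.  When the sets
    are singletons the printed row is internally determined by its
    margins and positive agreement alone.
    """
    tables = reconstruct_cells(n_total, n_survey, n_ehr, pa_percent,
                               decimals=pa_decimals)
    na_each = [round_half_up(100 * negative_agreement(t), na_decimals)
               for t in tables]
    j_each = [round_half_up(youden_j(t), j_decimals) for t in tables]
    return {"tables": tables,
            "na_percent": sorted(set(na_each)), "j": sorted(set(j_each)),
            "na_percent_by_candidate": na_each, "j_by_candidate": j_each}


def modal_candidate_value(values: list) -> float:
    """Most frequent value across reconstruction candidates.

    A frequency tie resolves to the value taken by the median candidate,
    i.e. the centre of the consistent dual-positive range.
    """
    if not values:
        raise ValueError("no candidate values")
    from collections import Counter
    counts = Counter(values)
    best = max(counts.values())
    modal = {v for v, n in counts.items() if n == best}
    if len(modal) == 1:
        return modal.pop()
    return values[len(values) // 2]
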