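"""Differential isoform usage from exon-exon junction-spanning read counts.

An alternative-isoform event is quantified in each condition by its isoform
fraction (psi): the proportion of junction reads supporting the inclusion
isoform.  Differential usage between a control (A) and a mutant (B) library
is tested with an exact binomial test against the pooled fraction:

    p_hat = (a_inc + b_inc) / (a_inc + a_exc + b_inc + b_exc)

and the two-sided p-value is the doubled smaller exact tail of
Binomial(n_B, p_hat) at the observed b_inc, capped at 1.  The p-value is
reported alongside a base-10 log-odds value, log10((1 - p) / p), so that a
log-odds of 1 corresponds to 10-to-1 odds — the same quorum as a minimum
Bayes factor of 10.

Calls are filtered on an isoform-fraction difference threshold (default
|delta psi| >= 0.2) and a minimum log-odds (default 1.0).  Fold-changes are
reported unsigned (always >= 1); when exactly one condition has a zero
fraction the fold-change is the sentinel ``LARGE``, serialized as the
literal string ``Large``.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence, Union

import pandas as pd
from scipy.stats import binom

#: Sentinel fold-change for events where one condition's fraction is zero.
LARGE = math.inf

EVENT_CLASSES = frozenset({"skipped_exon", "alt_5ss", "alt_3ss", "alt_TSS", "alt_3end"})

_EPS = sys.float_info.epsilon
_LOG_ODDS_CAP = math.log10((1.0 - _EPS) / _EPS)


class UntestableEventError(ValueError):
    """Raised when an event has zero junction reads in a condition."""


@dataclass
class JunctionEvent:
    """Junction read counts for one alternative-isoform event in two conditions.

    ``a_*`` counts belong to condition A (control), ``b_*`` to condition B
    (mutant); ``*_inc`` are reads supporting the inclusion isoform, ``*_exc``
    the exclusion isoform.
    """

    event_id: str
    gene_id: str
    event_class: str
    a_inc: int
    a_exc: int
    b_inc: int
    b_exc: int

    def __post_init__(self) -> None:
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(
                f"event {self.event_id}: unknown event_class {self.event_class!r}"
            )
        for name in ("a_inc", "a_exc", "b_inc", "b_exc"):
            value = getattr(self, name)
            if int(value) != value or value < 0:
                raise ValueError(f"event {self.event_id}: {name} must be a non-negative integer")
            setattr(self, name, int(value))

    @property
    def testable(self) -> bool:
        """True when both conditions have at least one junction read."""
        return (self.a_inc + self.a_exc) >= 1 and (self.b_inc + self.b_exc) >= 1

    def swapped(self) -> "JunctionEvent":
        """The same event with conditions A and B exchanged."""
        return JunctionEvent(
            event_id=self.event_id,
            gene_id=self.gene_id,
            event_class=self.event_class,
            a_inc=self.b_inc,
            a_exc=self.b_exc,
            b_inc=self.a_inc,
            b_exc=self.a_exc,
        )


@dataclass
class IsoformCall:
    """Test result for one event: fractions, p-value, log-odds, fold-change."""

    event_id: str
    gene_id: str
    event_class: str
    psi_a: float
    psi_b: float
    delta_psi: float
    p_value: float
    log_odds: float
    fold_change: float
    significant: bool
    status: str = "ok"
    p_adjusted: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == "ok":
            for name in ("psi_a", "psi_b"):
                v = getattr(self, name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{name} outside [0, 1]: {v}")
            if not 0.0 <= self.p_value <= 1.0:
                raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
            if self.fold_change < 1.0:
                raise ValueError(f"fold_change below 1: {self.fold_change}")


def isoform_fraction(inc: int, exc: int) -> float:
    """Fraction of junction reads supporting the inclusion isoform."""
    if inc < 0 or exc < 0:
        raise ValueError("read counts must be non-negative")
    total = inc + exc
    if total == 0:
        raise UntestableEventError("no junction reads: isoform fraction undefined")
    return inc / total


def log_odds_from_p(p_value: float, base: float = 10.0) -> float:
    """Convert a p-value to log-odds, log_base((1 - p) / p).

    The p-value is floored at machine epsilon so the result is finite, and
    the log-odds is capped symmetrically at the value that floor implies.
    A p-value of 1 (or beyond, after capping) maps to 0.
    """
    if p_value >= 1.0:
        return 0.0
    p = max(p_value, _EPS)
    cap = _LOG_ODDS_CAP / math.log10(base)
    lo = math.log10((1.0 - p) / p) / math.log10(base)
    return max(-cap, min(cap, lo))


def binomial_isoform_test(
    event: JunctionEvent,
    alternative: str = "two-sided",
    log_base: float = 10.0,
) -> tuple[float, float]:
    """Exact binomial test of condition B's inclusion fraction against the pooled null.

    Returns ``(p_value, log_odds)``.  The null inclusion probability is the
    fraction pooled over both conditions; the two-sided p-value doubles the
    smaller exact tail of Binomial(n_B, p_hat) at b_inc and caps at 1.
    One-sided alternatives ("less", "greater") are available.
    """
    if not event.testable:
        raise UntestableEventError(
            f"event {event.event_id}: zero junction reads in one condition"
        )
    n_a = event.a_inc + event.a_exc
    n_b = event.b_inc + event.b_exc
    p_hat = (event.a_inc + event.b_inc) / (n_a + n_b)
    lower = float(binom.cdf(event.b_inc, n_b, p_hat))
    upper = float(binom.sf(event.b_inc - 1, n_b, p_hat))
    if alternative == "two-sided":
        p_value = min(1.0, 2.0 * min(lower, upper))
    elif alternative == "less":
        p_value = min(1.0, lower)
    elif alternative == "greater":
        p_value = min(1.0, upper)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return p_value, log_odds_from_p(p_value, base=log_base)


def isoform_fold_change(psi_a: float, psi_b: float) -> float:
    """Unsigned fold-change between two isoform fractions (always >= 1).

    When exactly one fraction is zero the change is unbounded and the
    sentinel :data:`LARGE` is returned; when both are zero there is no
    change and the result is 1.  Direction is recoverable from delta psi.
    """
    for name, v in (("psi_a", psi_a), ("psi_b", psi_b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    hi, lo = max(psi_a, psi_b), min(psi_a, psi_b)
    if hi == 0.0:
        return 1.0
    if lo == 0.0:
        return LARGE
    return hi / lo


def bayes_factor_to_null_probability(bf: float) -> float:
    """Probability that a call is due to chance, from bf-to-1 odds: 1/(1+bf)."""
    if bf <= 0:
        raise ValueError(f"Bayes factor must be positive, got {bf}")
    return 1.0 / (1.0 + bf)


def call_differential_isoforms(
    events: Iterable[JunctionEvent],
    delta_psi_min: float = 0.2,
    log_odds_min: float = 1.0,
    alternative: str = "two-sided",
    log_base: float = 10.0,
    fdr: bool = False,
) -> list[IsoformCall]:
    """Test every event and apply the delta-psi and log-odds filters.

    An event is significant when |delta psi| >= ``delta_psi_min`` and
    log-odds >= ``log_odds_min`` (defaults mirror an isoform-fraction
    difference of 0.2 and 10-to-1 odds).  Untestable events (zero reads in
    a condition) are reported with status ``"untestable"``, never dropped.
    Output is sorted by descending log-odds, ties broken by event_id; with
    ``fdr=True`` Benjamini-Hochberg adjusted p-values are attached (the
    filters themselves are unchanged).
    """
    calls: list[IsoformCall] = []
    for event in events:
        if not event.testable:
            calls.append(
                IsoformCall(
                    event_id=event.event_id,
                    gene_id=event.gene_id,
                    event_class=event.event_class,
                    psi_a=math.nan,
                    psi_b=math.nan,
                    delta_psi=math.nan,
                    p_value=math.nan,
                    log_odds=math.nan,
                    fold_change=math.nan,
                    significant=False,
                    status="untestable",
                )
            )
            continue
        psi_a = isoform_fraction(event.a_inc, event.a_exc)
        psi_b = isoform_fraction(event.b_inc, event.b_exc)
        p_value, log_odds = binomial_isoform_test(
            event, alternative=alternative, log_base=log_base
        )
        delta = psi_b - psi_a
        calls.append(
            IsoformCall(
                event_id=event.event_id,
                gene_id=event.gene_id,
                event_class=event.event_class,
                psi_a=psi_a,
                psi_b=psi_b,
                delta_psi=delta,
                p_value=p_value,
                log_odds=log_odds,
                fold_change=isoform_fold_change(psi_a, psi_b),
                significant=(abs(delta) >= delta_psi_min) and (log_odds >= log_odds_min),
            )
        )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = [c for c in calls if c.status == "ok"]
        if ok:
            _, adjusted, _, _ = multipletests([c.p_value for c in ok], method="fdr_bh")
            for call, q in zip(ok, adjusted):
                call.p_adjusted = float(q)
    calls.sort(
        key=lambda c: (c.status != "ok", -(c.log_odds if c.status == "ok" else 0.0), c.event_id)
    )
    return calls


# ---------------------------------------------------------------------------
# TSV interface
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["event_id", "gene_id", "event_class", "a_inc", "a_exc", "b_inc", "b_exc"]
_CALL_COLUMNS = [
    "event_id",
    "gene_id",
    "event_class",
    "psi_a",
    "psi_b",
    "delta_psi",
    "p_value",
    "log_odds",
    "fold_change",
    "significant",
    "status",
]


def read_junction_counts(path: Union[str, IO[str]]) -> list[JunctionEvent]:
    """Read junction-count events from a headered TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"junction-count TSV missing columns: {missing}")
    return [
        JunctionEvent(
            event_id=str(row.event_id),
            gene_id=str(row.gene_id),
            event_class=str(row.event_class),
            a_inc=int(row.a_inc),
            a_exc=int(row.a_exc),
            b_inc=int(row.b_inc),
            b_exc=int(row.b_exc),
        )
        for row in df.itertuples()
    ]


def write_junction_counts(events: Sequence[JunctionEvent], path: Union[str, IO[str]]) -> None:
    pd.DataFrame(
        [[e.event_id, e.gene_id, e.event_class, e.a_inc, e.a_exc, e.b_inc, e.b_exc] for e in events],
        columns=_COUNT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def write_isoform_calls(calls: Sequence[IsoformCall], path: Union[str, IO[str]]) -> None:
    """Write calls as TSV; an unbounded fold-change appears as ``Large``."""
    rows = []
    for c in calls:
        fold = "Large" if c.fold_change == LARGE else c.fold_change
        rows.append(
            [c.event_id, c.gene_id, c.event_class, c.psi_a, c.psi_b, c.delta_psi,
             c.p_value, c.log_odds, fold, c.significant, c.status]
        )
    df = pd.DataFrame(rows, columns=_CALL_COLUMNS)
    if any(c.p_adjusted is not None for c in calls):
        df["p_adjusted"] = [c.p_adjusted for c in calls]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
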