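"""Gene-set overlap against an expected-by-chance baseline.

For two gene sets A and B drawn from a universe of N genes, the number of
genes shared by chance follows a hypergeometric distribution with mean
|A|·|B|/N.  The observed intersection is reported together with that
expectation, their ratio, and a one-sided (enrichment) hypergeometric
p-value, P(X >= observed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Union

from scipy.stats import hypergeom


@dataclass
class OverlapResult:
    n_a: int
    n_b: int
    n_universe: int
    observed: int
    expected: float
    enrichment_ratio: float
    p_value: float

    def __post_init__(self) -> None:
        if self.observed > min(self.n_a, self.n_b):
            raise ValueError("observed intersection exceeds the smaller set")
        if self.expected < 0:
            raise ValueError("expected overlap must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def expected_overlap(n_a: int, n_b: int, n_universe: int) -> float:
    """Mean chance intersection of two random sets: n_a * n_b / n_universe."""
    if n_universe < 1:
        raise ValueError("universe must contain at least one gene")
    for name, n in (("n_a", n_a), ("n_b", n_b)):
        if not 0 <= n <= n_universe:
            raise ValueError(f"{name}={n} outside [0, universe size {n_universe}]")
    return n_a * n_b / n_universe


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Observed vs. expected intersection of two gene sets, with p-value.

    Both sets must be subsets of the universe; ids outside it are reported
    in the error.  The p-value is the hypergeometric upper tail
    P(X >= observed) for X ~ Hypergeom(N, |A|, |B|).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    outside = sorted((a | b) - u)
    if outside:
        shown = ", ".join(outside[:10]) + ("..." if len(outside) > 10 else "")
        raise ValueError(f"{len(outside)} gene id(s) outside the universe: {shown}")
    observed = len(a & b)
    expected = expected_overlap(len(a), len(b), len(u))
    if expected > 0:
        enrichment = observed / expected
    else:
        enrichment = math.nan if observed == 0 else math.inf
    p_value = float(hypergeom.sf(observed - 1, len(u), len(a), len(b)))
    return OverlapResult(
        n_a=len(a),
        n_b=len(b),
        n_universe=len(u),
        observed=observed,
        expected=expected,
        enrichment_ratio=enrichment,
        p_value=min(1.0, p_value),
    )


def read_gene_list(path: Union[str, IO[str]]) -> list[str]:
    """Read a plain-text gene list, one id per line; blanks and # comments skipped."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()  # type: ignore[union-attr]
    else:
        with open(path) as handle:
            lines = handle.read().splitlines()
    ids = [ln.strip() for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    seen: set[str] = set()
    out = []
    for gid in ids:
        if gid in seen:
            raise ValueError(f"duplicate gene id in list: {gid}")
        seen.add(gid)
        out.append(gid)
    return out
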