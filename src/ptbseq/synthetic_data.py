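"""Synthetic inputs with the statistical structure the analyses assume.

Three generators emulate the data the pipeline consumes:

* junction counts — per event, per-condition read totals are Poisson around
  a mean depth (optionally negative-binomial for overdispersion) and
  inclusion counts are Binomial(total, psi), independently per condition;
* coverage pairs — a control pileup Poisson around ``coverage_depth`` along
  the whole region, and a mutant pileup whose downstream mean is scaled by
  ``full_length_fraction``, emulating transcript truncation at a transposon
  insertion breakpoint;
* multi-species alignments — a purine-biased reference sequence, per-species
  rows derived by uniform substitution plus geometric-length indels, and
  C/U-rich tracts planted into a chosen number of species with bounded
  per-species substitutions and positional offsets.

Every generator is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical configs produce byte-identical output.  Truth
records always accompany generated data so parameter-recovery tests can
close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import AlignmentBlock, AlignmentRow, CoverageProfile
from .isoform_analysis import JunctionEvent

#: An extended C/U-rich tract of the kind PTB binds with high affinity
#: (SELEX-like, DNA alphabet).  21 nt and G-free, so any single substitution
#: still leaves a qualifying 9-nt sub-tract.
DEFAULT_TRACT = "TCTTCTCTCTCTTTCTTCTCT"

_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))
_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSite:
    """A conserved tract to embed in a simulated alignment."""

    position: int
    sequence: str = DEFAULT_TRACT
    n_conserved_species: int = 12
    max_subs_per_species: int = 1
    max_offset_nt: int = 10


@dataclass
class SimConfig:
    """All knobs for the generators; defaults are the study conditions.

    Junction events default to depth 50 (mean junction reads per condition);
    coverage pairs to 200x depth with a 4% full-length fraction at a mid-gene
    breakpoint; alignments to 15 species over a purine-biased background
    (pyrimidine fraction 0.3) with 10% per-species substitution and sparse
    geometric indels (mean length 2).
    """

    seed: int = 0
    # junction counts
    n_events: int = 100
    depth: float = 50.0
    psi_pairs: list[tuple[float, float]] = field(default_factory=lambda: [(0.5, 0.5)])
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    # coverage
    coverage_depth: float = 200.0
    coverage_length: int = 2000
    breakpoint: int = 1000
    full_length_fraction: float = 0.04
    # alignment
    n_species: int = 15
    alignment_length: int = 5000
    background_pyrimidine: float = 0.3
    substitution_rate: float = 0.1
    indel_rate: float = 0.01
    indel_mean_length: float = 2.0
    planted_sites: list[PlantedSite] = field(default_factory=list)
    # gene sets
    n_universe: int = 1000
    set_a_size: int = 200
    set_b_size: int = 300
    overlap_enrichment: float = 2.0

    def __post_init__(self) -> None:
        for psi_a, psi_b in self.psi_pairs:
            if not (0.0 <= psi_a <= 1.0 and 0.0 <= psi_b <= 1.0):
                raise ValueError(f"psi pair ({psi_a}, {psi_b}) outside [0, 1]")
        if not 0.0 <= self.full_length_fraction <= 1.0:
            raise ValueError("full_length_fraction outside [0, 1]")
        if not 0.0 <= self.background_pyrimidine <= 1.0:
            raise ValueError("background_pyrimidine outside [0, 1]")
        for site in self.planted_sites:
            if site.n_conserved_species > self.n_species:
                raise ValueError("n_conserved_species exceeds n_species")
            if site.position < 0 or site.position + len(site.sequence) > self.alignment_length:
                raise ValueError(f"planted site at {site.position} outside alignment bounds")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------


def _draw_totals(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    if config.overdispersion is None:
        return rng.poisson(config.depth, size=n)
    # negative binomial with mean `depth` and size (dispersion) parameter k
    k = config.overdispersion
    p = k / (k + config.depth)
    return rng.negative_binomial(k, p, size=n)


def simulate_junction_counts(config: SimConfig) -> tuple[list[JunctionEvent], pd.DataFrame]:
    """Simulate junction-read counts for alternative-isoform events.

    Events cycle through ``config.psi_pairs``.  Returns the events plus a
    truth table (event_id, true psi_A, true psi_B) for parameter-recovery
    tests.
    """
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = config.rng()
    n = config.n_events
    totals_a = _draw_totals(rng, n, config)
    totals_b = _draw_totals(rng, n, config)
    classes = sorted(["skipped_exon", "alt_5ss", "alt_3ss", "alt_TSS", "alt_3end"])
    events: list[JunctionEvent] = []
    truth_rows = []
    for i in range(n):
        psi_a, psi_b = config.psi_pairs[i % len(config.psi_pairs)]
        a_inc = int(rng.binomial(totals_a[i], psi_a)) if totals_a[i] > 0 else 0
        b_inc = int(rng.binomial(totals_b[i], psi_b)) if totals_b[i] > 0 else 0
        event_id = f"ev{i:05d}"
        events.append(
            JunctionEvent(
                event_id=event_id,
                gene_id=f"gene{i:05d}",
                event_class=classes[i % len(classes)],
                a_inc=a_inc,
                a_exc=int(totals_a[i]) - a_inc,
                b_inc=b_inc,
                b_exc=int(totals_b[i]) - b_inc,
            )
        )
        truth_rows.append([event_id, psi_a, psi_b])
    truth = pd.DataFrame(truth_rows, columns=["event_id", "psi_a_true", "psi_b_true"])
    return events, truth


# ---------------------------------------------------------------------------
# Coverage pairs
# ---------------------------------------------------------------------------


def simulate_coverage_pair(config: SimConfig) -> tuple[CoverageProfile, CoverageProfile]:
    """Simulate (mutant, control) pileups with a truncation breakpoint.

    The control is Poisson around ``coverage_depth`` everywhere; the mutant
    keeps that mean upstream of ``config.breakpoint`` and drops to
    ``coverage_depth * full_length_fraction`` downstream (plus-strand
    orientation: upstream = left).
    """
    if not 0 < config.breakpoint < config.coverage_length:
        raise ValueError("breakpoint must fall strictly inside the simulated region")
    rng = config.rng()
    length, bp = config.coverage_length, config.breakpoint
    control = rng.poisson(config.coverage_depth, size=length).astype(float)
    mut_up = rng.poisson(config.coverage_depth, size=bp)
    mut_down = rng.poisson(config.coverage_depth * config.full_length_fraction, size=length - bp)
    mutant = np.concatenate([mut_up, mut_down]).astype(float)
    return (
        CoverageProfile(chrom="chrSim", start=0, values=mutant),
        CoverageProfile(chrom="chrSim", start=0, values=control),
    )


# ---------------------------------------------------------------------------
# Multi-species alignments
# ---------------------------------------------------------------------------


def _background_sequence(rng: np.random.Generator, length: int, pyrimidine_fraction: float) -> np.ndarray:
    is_pyr = rng.random(length) < pyrimidine_fraction
    pyr = _PYRIMIDINES[rng.integers(0, 2, size=length)]
    pur = _PURINES[rng.integers(0, 2, size=length)]
    return np.where(is_pyr, pyr, pur)


def _substitute(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(0, 3)]
    return out


def simulate_alignment(config: SimConfig) -> tuple[list[AlignmentBlock], pd.DataFrame]:
    """Simulate one multiz-style alignment block with planted conserved tracts.

    Species are named ``sp00`` (the reference) through ``sp{n-1}``.  Each
    non-reference row is a substituted copy of the reference with sparse
    indels (geometric lengths, mean ``indel_mean_length``); deletions appear
    as gaps in that species, insertions as gap columns in all others.  For
    every planted site, the tract is written into the reference and into
    ``n_conserved_species - 1`` randomly chosen other species (with at most
    ``max_subs_per_species`` substitutions and a positional offset up to
    ``max_offset_nt``); the remaining species have the site region ablated
    with purines.  Indels never touch a planted-site neighbourhood, so the
    plants are exact ground truth.  Returns the block plus a truth table of
    reference-coordinate site intervals.
    """
    rng = config.rng()
    L = config.alignment_length
    S = config.n_species
    sites = sorted(config.planted_sites, key=lambda s: s.position)
    for prev, cur in zip(sites, sites[1:]):
        if prev.position + len(prev.sequence) > cur.position:
            raise ValueError(
                f"planted sites at {prev.position} and {cur.position} overlap"
            )

    ref = _background_sequence(rng, L, config.background_pyrimidine)

    # per-site conserved species (reference always conserved)
    conserved_by_site: list[set[int]] = []
    for site in sites:
        others = rng.choice(np.arange(1, S), size=site.n_conserved_species - 1, replace=False)
        conserved_by_site.append({0} | set(int(x) for x in others))

    rows = [ref]
    for _ in range(1, S):
        rows.append(_substitute(rng, ref, config.substitution_rate))

    protected = np.zeros(L, dtype=bool)
    for site in sites:
        tract = np.array(list(site.sequence.upper().replace("U", "T")))
        lo = max(0, site.position - site.max_offset_nt - 1)
        hi = min(L, site.position + len(tract) + site.max_offset_nt + 1)
        protected[lo:hi] = True
    for site, conserved in zip(sites, conserved_by_site):
        tract = np.array(list(site.sequence.upper().replace("U", "T")))
        for sp in range(S):
            if sp in conserved:
                planted = tract.copy()
                if sp != 0 and site.max_subs_per_species > 0:
                    n_subs = int(rng.integers(0, site.max_subs_per_species + 1))
                    for pos in rng.choice(len(planted), size=n_subs, replace=False):
                        choices = [b for b in "ACGT" if b != planted[pos]]
                        planted[pos] = choices[rng.integers(0, 3)]
                offset = 0
                if sp != 0 and site.max_offset_nt > 0:
                    offset = int(rng.integers(-site.max_offset_nt, site.max_offset_nt + 1))
                start = min(max(0, site.position + offset), L - len(planted))
                rows[sp][start : start + len(planted)] = planted
            else:
                # ablate: purine fill so the species cannot support the site
                region = slice(site.position, site.position + len(tract))
                rows[sp][region] = _PURINES[rng.integers(0, 2, size=len(tract))]

    # indels (never inside protected neighbourhoods, never in the reference)
    deletions = np.zeros((S, L), dtype=bool)
    insertions: dict[int, list[tuple[int, str]]] = {}
    for sp in range(1, S):
        n_del = rng.poisson(L * config.indel_rate / 2)
        for _ in range(n_del):
            start = int(rng.integers(0, L))
            length = int(rng.geometric(1.0 / config.indel_mean_length))
            end = min(L, start + length)
            if protected[start:end].any():
                continue
            deletions[sp, start:end] = True
        n_ins = rng.poisson(L * config.indel_rate / 2)
        for _ in range(n_ins):
            pos = int(rng.integers(0, L + 1))
            if protected[max(0, pos - 1) : min(L, pos + 1)].any():
                continue
            length = int(rng.geometric(1.0 / config.indel_mean_length))
            seq = "".join(_background_sequence(rng, length, config.background_pyrimidine))
            insertions.setdefault(pos, []).append((sp, seq))

    # assemble gapped rows column by column
    gapped: list[list[str]] = [[] for _ in range(S)]
    for p in range(L + 1):
        for sp_ins, seq in sorted(insertions.get(p, [])):
            for ch in seq:
                for sp in range(S):
                    gapped[sp].append(ch if sp == sp_ins else "-")
        if p < L:
            for sp in range(S):
                gapped[sp].append("-" if deletions[sp, p] else str(rows[sp][p]))

    block_rows: dict[str, AlignmentRow] = {}
    for sp in range(S):
        text = "".join(gapped[sp])
        size = len(text) - text.count("-")
        block_rows[f"sp{sp:02d}"] = AlignmentRow(
            species=f"sp{sp:02d}",
            chrom="chrSim",
            start=0,
            size=size,
            strand="+",
            src_size=size,
            text=text,
        )
    block = AlignmentBlock(rows=block_rows, ref_species="sp00")
    truth = pd.DataFrame(
        [
            ["chrSim", s.position, s.position + len(s.sequence), s.n_conserved_species]
            for s in sites
        ],
        columns=["chrom", "start", "end", "n_conserved_species"],
    )
    return [block], truth


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------


def simulate_gene_sets(config: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """Simulate (set_a, set_b, universe) with a controllable overlap enrichment.

    The target intersection is ``overlap_enrichment`` times the chance
    expectation |A||B|/N, clipped to feasibility; enrichment 1 corresponds
    to random sets.
    """
    rng = config.rng()
    n, n_a, n_b = config.n_universe, config.set_a_size, config.set_b_size
    if n_a > n or n_b > n:
        raise ValueError("set sizes cannot exceed the universe size")
    universe = [f"g{i:05d}" for i in range(n)]
    set_a = sorted(rng.choice(universe, size=n_a, replace=False).tolist())
    target = int(round(config.overlap_enrichment * n_a * n_b / n))
    target = min(target, n_a, n_b)
    target = max(target, n_a + n_b - n, 0)
    inside = rng.choice(sorted(set_a), size=target, replace=False).tolist()
    outside_pool = sorted(set(universe) - set(set_a))
    outside = rng.choice(outside_pool, size=n_b - target, replace=False).tolist()
    set_b = sorted(inside + outside)
    return set_a, set_b, universe


def write_gene_list(ids: Iterable[str], path) -> None:
    with open(path, "w") as handle:
        for gid in ids:
            handle.write(f"{gid}\n")
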