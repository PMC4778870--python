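"""Conserved polypyrimidine-tract (PTB binding site) scanning over alignments.

A candidate PTB binding site is a stretch of at least ``min_length`` C or U
residues tolerating at most ``max_g`` G residues (default: nine C/U with at
most one G).  T and U are equivalent; A and N terminate a tract and never
count.  A site found in the reference species is called *conserved* when at
least ``min_species`` of the aligned species (the reference included) carry
a qualifying tract within ``window_nt`` ungapped reference nucleotides of
the site — indels do not consume window budget.

The scan walks multiz MAF blocks independently; a site spanning a block
boundary is not detected (documented limitation).  Minus-strand rows are
reverse-complemented before tract search, so all reported coordinates are
forward-strand reference genome coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

from .io_formats import AlignmentBlock, reverse_complement

_PYRIMIDINE = frozenset("CTU")
_VALID = frozenset("ACGTUN")


@dataclass
class TractParams:
    """Tract definition and conservation quorum.

    Defaults encode: >= 9 C/U residues allowing at most one G, conserved
    within 25 ungapped nucleotides in at least 9 of the 15 aligned species.
    """

    min_length: int = 9
    max_g: int = 1
    window_nt: int = 25
    min_species: int = 9
    total_species: int = 15

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.max_g < self.min_length:
            raise ValueError("max_g must satisfy 0 <= max_g < min_length")
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")
        if not 1 <= self.min_species <= self.total_species:
            raise ValueError("min_species must satisfy 1 <= min_species <= total_species")


@dataclass
class PTBSiteHit:
    """A conserved pyrimidine tract in reference genome coordinates (0-based half-open)."""

    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    ref_sequence: str
    supporting_species: list[str] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.supporting_species)


def _maximal_windows(seq: str, lo: int, hi: int, max_g: int) -> list[tuple[int, int]]:
    """Maximal sub-windows of the C/U/G run seq[lo:hi] containing <= max_g Gs."""
    g_positions = [k for k in range(lo, hi) if seq[k] == "G"]
    n_g = len(g_positions)
    if n_g <= max_g:
        return [(lo, hi)]
    windows = []
    for i in range(n_g - max_g + 1):
        start = g_positions[i - 1] + 1 if i > 0 else lo
        end = g_positions[i + max_g] if i + max_g < n_g else hi
        windows.append((start, end))
    return windows


def find_pyrimidine_tracts(sequence: str, params: TractParams | None = None) -> list[tuple[int, int]]:
    """All maximal pyrimidine tracts in ``sequence`` as (start, end) half-open pairs.

    A tract is a substring of length >= ``min_length`` composed of C/U (or T)
    residues plus at most ``max_g`` G residues, extendable in neither
    direction without breaking that composition.  The tolerated G may sit
    anywhere, boundaries included.
    """
    params = params or TractParams()
    seq = sequence.upper()
    invalid = set(seq) - _VALID
    if invalid:
        raise ValueError(f"invalid nucleotide characters: {sorted(invalid)}")
    tracts: list[tuple[int, int]] = []
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] in _PYRIMIDINE or seq[i] == "G":
            j = i
            while j < n and (seq[j] in _PYRIMIDINE or seq[j] == "G"):
                j += 1
            tracts.extend(_maximal_windows(seq, i, j, params.max_g))
            i = j
        else:
            i += 1
    return [(a, b) for a, b in tracts if b - a >= params.min_length]


def _normalize(block: AlignmentBlock) -> AlignmentBlock:
    """Reverse-complement the whole block if the reference row is minus-strand."""
    if block.rows[block.ref_species].strand == "-":
        return block.reverse_complement()
    return block


def column_window(
    block: AlignmentBlock,
    species: str,
    ref_interval: tuple[int, int],
    window_nt: int,
) -> Optional[str]:
    """The ungapped species subsequence aligned to a reference window.

    ``ref_interval`` is (start, end) in forward reference genome coordinates
    (0-based half-open) and must lie within the block's reference row.  The
    window extends ``window_nt`` ungapped reference positions on each side,
    truncated at the block edges; gap columns in the reference row do not
    consume window budget.  Returns ``None`` when the species is absent from
    the block (it simply cannot support a site there).
    """
    block = _normalize(block)
    ref = block.rows[block.ref_species]
    cols = [c for c, ch in enumerate(ref.text) if ch != "-"]
    g0, g1 = ref_interval
    u0, u1 = g0 - ref.start, g1 - ref.start
    if not (0 <= u0 < u1 <= len(cols)):
        raise ValueError(
            f"reference interval {ref_interval} outside block reference row "
            f"[{ref.start}, {ref.start + len(cols)})"
        )
    lo = max(0, u0 - window_nt)
    hi = min(len(cols), u1 + window_nt)
    if species not in block.rows:
        return None
    span = block.rows[species].text[cols[lo] : cols[hi - 1] + 1]
    return span.replace("-", "")


def scan_alignment(
    blocks: Iterable[AlignmentBlock],
    params: TractParams | None = None,
    ref_species: str | None = None,
) -> list[PTBSiteHit]:
    """Scan alignment blocks for conserved pyrimidine tracts.

    For every tract in the reference row, each aligned species supports the
    site if its window subsequence itself contains a qualifying tract (same
    ``min_length``/``max_g``); minus-strand species rows are searched on
    their forward strand.  A hit is emitted when at least ``min_species``
    species support (the reference counts toward the quorum).  Blocks
    missing the reference species are skipped with a warning.
    """
    params = params or TractParams()
    hits: list[PTBSiteHit] = []
    for index, block in enumerate(blocks):
        ref_sp = ref_species or block.ref_species
        if ref_sp not in block.rows:
            warnings.warn(f"block {index}: reference species {ref_sp!r} absent; skipped")
            continue
        if block.ref_species != ref_sp:
            block = AlignmentBlock(rows=block.rows, ref_species=ref_sp)
        block = _normalize(block)
        ref = block.rows[ref_sp]
        ref_seq = block.ungapped(ref_sp)
        for u0, u1 in find_pyrimidine_tracts(ref_seq, params):
            g0, g1 = ref.start + u0, ref.start + u1
            supporting = [ref_sp]
            for sp, row in block.rows.items():
                if sp == ref_sp:
                    continue
                sub = column_window(block, sp, (g0, g1), params.window_nt)
                if not sub:
                    continue
                if row.strand == "-":
                    sub = reverse_complement(sub)
                if find_pyrimidine_tracts(sub, params):
                    supporting.append(sp)
            if len(supporting) >= params.min_species:
                hits.append(
                    PTBSiteHit(
                        chrom=ref.chrom,
                        ref_start=g0,
                        ref_end=g1,
                        strand="+",
                        ref_sequence=ref_seq[u0:u1],
                        supporting_species=supporting,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.ref_start, h.ref_end))
    return hits


def write_hit_table(hits: Iterable[PTBSiteHit], path: Union[str, IO[str]]) -> None:
    """TSV companion to the BED output, with per-hit supporting-species lists."""
    import pandas as pd

    rows = [
        [h.chrom, h.ref_start, h.ref_end, h.strand, h.ref_sequence, h.n_support,
         ",".join(h.supporting_species)]
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "ref_sequence", "n_support", "supporting_species"],
    ).to_csv(path, sep="\t", index=False)
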