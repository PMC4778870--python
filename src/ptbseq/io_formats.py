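"""Readers and writers for the genomic file formats the pipeline touches.

Coordinate conventions, stated once and used everywhere:

* GTF: 1-based, inclusive on both ends.
* BED / bedGraph: 0-based, half-open.
* MAF (multiz): 0-based starts; a minus-strand start is counted from the
  beginning of the reverse-complemented source sequence, per the standard.

``T`` and ``U`` are treated as equivalent everywhere: binding motifs are
written in the RNA alphabet while the alignments are DNA.  ``N`` is an
unknown residue and never matches anything.

All readers accept plain or gzip-compressed paths (suffix ``.gz``), or an
already-open text handle.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

import numpy as np
from Bio import AlignIO

PathOrHandle = Union[str, Path, IO[str]]

COMPLEMENT = str.maketrans("ACGTUNacgtun-", "TGCAANtgcaan-")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string; gaps and N are preserved."""
    return seq.translate(COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated its format contract (syntax or invariants)."""


def _open_text(path: PathOrHandle, mode: str = "rt") -> IO[str]:
    if hasattr(path, "read") or hasattr(path, "write"):
        return path  # type: ignore[return-value]
    p = Path(path)
    if p.suffix == ".gz":
        return gzip.open(p, mode)
    return open(p, mode)


def _maybe_close(handle: IO[str], original: PathOrHandle) -> None:
    if handle is not original or not (hasattr(original, "read") or hasattr(original, "write")):
        handle.close()


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """A gene with its transcript structures, in GTF coordinates.

    ``exons`` is the ordered union of exon intervals across transcripts;
    ``transcripts`` maps transcript_id to that transcript's own ordered exon
    list.  All intervals are 1-based inclusive.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    transcripts: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        for tx_id, exons in self.transcripts.items():
            prev_end = None
            for start, end in exons:
                if end < start:
                    raise FormatError(f"gene {self.gene_id} transcript {tx_id}: exon end {end} < start {start}")
                if prev_end is not None and start <= prev_end:
                    raise FormatError(
                        f"gene {self.gene_id} transcript {tx_id}: overlapping exons at {start}-{end}"
                    )
                prev_end = end


def _prescan_gtf(content: str) -> None:
    # gffutils error messages do not carry line numbers, so structural
    # validity is checked here first.
    for lineno, line in enumerate(content.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer coordinates {fields[3]!r}/{fields[4]!r}") from None
        if end < start:
            raise FormatError(f"line {lineno}: end {end} < start {start}")
        if fields[2] == "exon":
            if "gene_id" not in fields[8]:
                raise FormatError(f"line {lineno}: missing gene_id attribute")
            if "transcript_id" not in fields[8]:
                raise FormatError(f"line {lineno}: missing transcript_id attribute")


def read_gene_models(path: PathOrHandle) -> list[GeneModel]:
    """Parse a GTF file into :class:`GeneModel` objects, one per gene_id.

    Coordinates are preserved as 1-based inclusive.  Gene and transcript
    structures are assembled from exon features via gffutils, as in the
    Flybase GTF dialect (``gene_id`` / ``transcript_id`` attributes).
    """
    import gffutils

    handle = _open_text(path)
    try:
        content = handle.read()
    finally:
        _maybe_close(handle, path)
    _prescan_gtf(content)
    if not content.strip():
        return []
    try:
        db = gffutils.create_db(
            content,
            dbfn=":memory:",
            from_string=True,
            keep_order=True,
            merge_strategy="create_unique",
            verbose=False,
        )
    except Exception as exc:  # gffutils raises assorted exception types
        raise FormatError(f"malformed GTF: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene"):
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for tx in db.children(gene, featuretype="transcript"):
            exons = sorted(
                (exon.start, exon.end) for exon in db.children(tx, featuretype="exon")
            )
            transcripts[tx.id] = exons
        union = sorted({iv for exons in transcripts.values() for iv in exons})
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=union,
                transcripts=transcripts,
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: PathOrHandle) -> None:
    """Serialize gene models back to exon-level GTF."""
    handle = _open_text(path, "wt")
    try:
        for gm in models:
            for tx_id, exons in gm.transcripts.items():
                for start, end in exons:
                    attrs = f'gene_id "{gm.gene_id}"; transcript_id "{tx_id}";'
                    handle.write(
                        f"{gm.chrom}\tptbseq\texon\t{start}\t{end}\t.\t{gm.strand}\t.\t{attrs}\n"
                    )
    finally:
        _maybe_close(handle, path)


# ---------------------------------------------------------------------------
# Multi-species alignments (MAF)
# ---------------------------------------------------------------------------

_MAF_ALPHABET = frozenset("ACGTUN-")


@dataclass
class AlignmentRow:
    """One species row of a MAF block (gapped text plus source coordinates)."""

    species: str
    chrom: str
    start: int  # 0-based; minus-strand starts count from the RC'd source
    size: int  # ungapped length
    strand: str
    src_size: int
    text: str

    def reverse_complement(self) -> "AlignmentRow":
        return AlignmentRow(
            species=self.species,
            chrom=self.chrom,
            start=self.src_size - self.start - self.size,
            size=self.size,
            strand="-" if self.strand == "+" else "+",
            src_size=self.src_size,
            text=reverse_complement(self.text),
        )


@dataclass
class AlignmentBlock:
    """One multiz alignment block: equal-length gapped rows keyed by species."""

    rows: dict[str, AlignmentRow]
    ref_species: str

    def __post_init__(self) -> None:
        if self.ref_species not in self.rows:
            raise FormatError(f"reference species {self.ref_species!r} absent from block")
        lengths = {len(r.text) for r in self.rows.values()}
        if len(lengths) > 1:
            raise FormatError(f"rows have unequal gapped lengths: {sorted(lengths)}")
        for r in self.rows.values():
            bad = set(r.text.upper()) - _MAF_ALPHABET
            if bad:
                raise FormatError(f"row {r.species}: invalid characters {sorted(bad)}")
            ungapped = len(r.text) - r.text.count("-")
            if ungapped != r.size:
                raise FormatError(
                    f"row {r.species}: declared size {r.size} != ungapped length {ungapped}"
                )

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())).text)

    def ungapped(self, species: str) -> str:
        return self.rows[species].text.replace("-", "")

    def reverse_complement(self) -> "AlignmentBlock":
        return AlignmentBlock(
            rows={sp: row.reverse_complement() for sp, row in self.rows.items()},
            ref_species=self.ref_species,
        )


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        species, chrom = src.split(".", 1)
    else:
        species, chrom = src, src
    return species, chrom


def read_alignment_blocks(path: PathOrHandle, ref_species: str | None = None) -> Iterator[AlignmentBlock]:
    """Stream MAF blocks in file order.

    The reference species defaults to the first row of each block (the multiz
    convention).  Row lengths and declared ungapped sizes are validated; a
    violation raises :class:`FormatError` naming the block index.
    """
    handle = _open_text(path)
    try:
        content = handle.read()
    finally:
        _maybe_close(handle, path)
    if not content.strip():
        return
    try:
        alignments = list(AlignIO.parse(io.StringIO(content), "maf"))
    except ValueError as exc:
        raise FormatError(f"malformed MAF: {exc}") from exc
    for idx, aln in enumerate(alignments):
        rows: dict[str, AlignmentRow] = {}
        for rec in aln:
            species, chrom = _split_src(rec.id)
            ann = rec.annotations
            rows[species] = AlignmentRow(
                species=species,
                chrom=chrom,
                start=int(ann["start"]),
                size=int(ann["size"]),
                strand="+" if int(ann["strand"]) == 1 else "-",
                src_size=int(ann["srcSize"]),
                text=str(rec.seq),
            )
        try:
            yield AlignmentBlock(rows=rows, ref_species=ref_species or next(iter(rows)))
        except FormatError as exc:
            raise FormatError(f"block {idx}: {exc}") from exc


def write_alignment_blocks(blocks: Iterable[AlignmentBlock], path: PathOrHandle) -> None:
    """Serialize blocks as multiz MAF (``##maf`` header, a/s lines)."""
    handle = _open_text(path, "wt")
    try:
        handle.write("##maf version=1 scoring=none\n")
        for block in blocks:
            handle.write("a score=0.0\n")
            for row in block.rows.values():
                src = f"{row.species}.{row.chrom}" if row.chrom != row.species else row.species
                handle.write(
                    f"s {src} {row.start} {row.size} {row.strand} {row.src_size} {row.text}\n"
                )
            handle.write("\n")
    finally:
        _maybe_close(handle, path)


# ---------------------------------------------------------------------------
# Per-base coverage (bedGraph)
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Per-base coverage over a contiguous genomic interval.

    ``start`` is 0-based; the profile covers ``[start, start + len(values))``
    half-open, one depth value per base.
    """

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise FormatError("coverage values must be one-dimensional")
        if np.any(self.values < 0):
            raise FormatError("coverage values must be non-negative")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageProfile):
            return NotImplemented
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and np.array_equal(self.values, other.values)
        )


def read_coverage(path: PathOrHandle) -> list[CoverageProfile]:
    """Parse a 4-column bedGraph into contiguous per-base profiles.

    Abutting intervals on the same chromosome are merged; a gap starts a new
    profile.  Overlapping intervals or negative values raise
    :class:`FormatError`.
    """
    handle = _open_text(path)
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    try:
        for lineno, line in enumerate(handle, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split()
            if len(fields) != 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric fields") from None
            if end <= start:
                raise FormatError(f"line {lineno}: empty or inverted interval {start}-{end}")
            if value < 0:
                raise FormatError(f"line {lineno}: negative coverage {value}")
            by_chrom.setdefault(chrom, []).append((start, end, value))
    finally:
        _maybe_close(handle, path)

    profiles: list[CoverageProfile] = []
    for chrom in by_chrom:
        intervals = sorted(by_chrom[chrom])
        run_start = None
        starts: list[int] = []
        lengths: list[int] = []
        vals: list[float] = []

        def flush() -> None:
            if run_start is not None:
                profiles.append(
                    CoverageProfile(
                        chrom=chrom,
                        start=run_start,
                        values=np.repeat(np.array(vals), np.array(lengths)),
                    )
                )

        prev_end = None
        for start, end, value in intervals:
            if prev_end is not None and start < prev_end:
                raise FormatError(f"{chrom}: overlapping intervals at {start}-{end}")
            if prev_end is None or start > prev_end:
                flush()
                run_start, lengths, vals = start, [], []
            lengths.append(end - start)
            vals.append(value)
            prev_end = end
        flush()
    return profiles


def write_coverage(profiles: Iterable[CoverageProfile], path: PathOrHandle) -> None:
    """Serialize profiles to bedGraph, run-length-encoding equal values."""
    handle = _open_text(path, "wt")
    try:
        for prof in profiles:
            vals = prof.values
            if len(vals) == 0:
                continue
            boundaries = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                v_repr = int(v) if float(v).is_integer() else v
                handle.write(f"{prof.chrom}\t{prof.start + s}\t{prof.start + e}\t{v_repr}\n")
    finally:
        _maybe_close(handle, path)


# ---------------------------------------------------------------------------
# Site hits (BED6)
# ---------------------------------------------------------------------------


def write_site_hits(hits: Iterable, path: PathOrHandle) -> None:
    """Write conserved-site hits as BED6.

    Columns: chrom, start, end (0-based half-open), name, score (supporting
    species count), strand.
    """
    handle = _open_text(path, "wt")
    try:
        for hit in hits:
            name = f"{hit.chrom}:{hit.ref_start}-{hit.ref_end}"
            handle.write(
                f"{hit.chrom}\t{hit.ref_start}\t{hit.ref_end}\t{name}\t{hit.n_support}\t{hit.strand}\n"
            )
    finally:
        _maybe_close(handle, path)
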