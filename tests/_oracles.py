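"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (exhaustive enumeration, direct
probability-mass summation) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N", "-": "-"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


# --- exact binomial test ----------------------------------------------------


def binomial_pvalue_oracle(a_inc: int, a_exc: int, b_inc: int, b_exc: int) -> float:
    """Two-sided doubled-tail p-value by direct PMF summation."""
    n_b = b_inc + b_exc
    total = a_inc + a_exc + n_b
    p = (a_inc + b_inc) / total
    pmf = [math.comb(n_b, k) * p**k * (1.0 - p) ** (n_b - k) for k in range(n_b + 1)]
    lower = sum(pmf[: b_inc + 1])
    upper = sum(pmf[b_inc:])
    return min(1.0, 2.0 * min(lower, upper))


# --- pyrimidine tracts ------------------------------------------------------


def _composition_ok(sub: str, max_g: int) -> bool:
    sub = sub.upper().replace("U", "T")
    return all(c in "CTG" for c in sub) and sub.count("G") <= max_g


def naive_tracts(seq: str, min_length: int, max_g: int) -> list[tuple[int, int]]:
    """All maximal qualifying tracts by quadratic window enumeration."""
    seq = seq.upper()
    n = len(seq)
    out = set()
    for i in range(n):
        for j in range(i + min_length, n + 1):
            if not _composition_ok(seq[i:j], max_g):
                continue
            extend_left = i > 0 and _composition_ok(seq[i - 1 : j], max_g)
            extend_right = j < n and _composition_ok(seq[i : j + 1], max_g)
            if not extend_left and not extend_right:
                out.add((i, j))
    return sorted(out)


def tracts_by_extension(seq: str, min_length: int, max_g: int) -> list[tuple[int, int]]:
    """Maximal tracts by greedy per-start extension (for long sequences).

    Independent of the package's run-splitting algorithm: every start
    position is extended right as far as the composition rule allows, then
    windows that could still be extended left are discarded.
    """
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    g_prefix = [0]
    for c in seq:
        g_prefix.append(g_prefix[-1] + (c == "G"))

    def g_count(i, j):
        return g_prefix[j] - g_prefix[i]

    out = set()
    for i in range(n):
        if seq[i] not in "CTG":
            continue
        g = 0
        j = i
        while j < n and seq[j] in "CTG" and g + (seq[j] == "G") <= max_g:
            g += seq[j] == "G"
            j += 1
        if j - i < min_length:
            continue
        left_extendable = i > 0 and seq[i - 1] in "CTG" and g_count(i - 1, j) <= max_g
        if not left_extendable:
            out.add((i, j))
    return sorted(out)


def contains_tract(seq: str, min_length: int, max_g: int) -> bool:
    seq = seq.upper()
    return any(
        _composition_ok(seq[i : i + min_length], max_g)
        for i in range(len(seq) - min_length + 1)
    )


def naive_scan(block, params, tract_fn=None) -> list[tuple]:
    """Exhaustive re-scan of one alignment block.

    Returns sorted tuples (chrom, start, end, frozenset(supporting species))
    in forward reference coordinates.  ``tract_fn`` defaults to the
    quadratic enumeration; pass :func:`tracts_by_extension` for long rows.
    """
    tract_fn = tract_fn or naive_tracts
    rows = dict(block.rows)
    ref_sp = block.ref_species
    if rows[ref_sp].strand == "-":
        flipped = {}
        for sp, row in rows.items():
            flipped[sp] = type(row)(
                species=row.species,
                chrom=row.chrom,
                start=row.src_size - row.start - row.size,
                size=row.size,
                strand="-" if row.strand == "+" else "+",
                src_size=row.src_size,
                text=rc(row.text),
            )
        rows = flipped
    ref = rows[ref_sp]
    cols = [c for c, ch in enumerate(ref.text) if ch != "-"]
    ref_seq = ref.text.replace("-", "")
    hits = []
    for u0, u1 in tract_fn(ref_seq, params.min_length, params.max_g):
        lo = max(0, u0 - params.window_nt)
        hi = min(len(ref_seq), u1 + params.window_nt)
        c0, c1 = cols[lo], cols[hi - 1]
        supporting = {ref_sp}
        for sp, row in rows.items():
            if sp == ref_sp:
                continue
            sub = "".join(ch for ch in row.text[c0 : c1 + 1] if ch != "-")
            if row.strand == "-":
                sub = rc(sub)
            if contains_tract(sub, params.min_length, params.max_g):
                supporting.add(sp)
        if len(supporting) >= params.min_species:
            hits.append((ref.chrom, ref.start + u0, ref.start + u1, frozenset(supporting)))
    return sorted(hits, key=lambda h: (h[0], h[1], h[2]))


# --- hypergeometric overlap -------------------------------------------------


def hypergeom_upper_tail_oracle(observed: int, n_universe: int, n_a: int, n_b: int) -> float:
    """P(X >= observed) by direct summation of the hypergeometric PMF."""
    denom = math.comb(n_universe, n_b)
    total = 0.0
    for k in range(observed, min(n_a, n_b) + 1):
        if n_b - k > n_universe - n_a:
            continue
        total += math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k) / denom
    return min(1.0, total)


# --- random alignment blocks for randomized oracle comparison ---------------


def random_block(rng: np.random.Generator):
    """A random small, valid alignment block (<= 5 species, rows <= 60 nt)."""
    from ptbseq.io_formats import AlignmentBlock, AlignmentRow

    n_species = int(rng.integers(2, 6))
    width = int(rng.integers(12, 61))
    alphabet = np.array(list("ACGTUN-"))
    probs = np.array([0.12, 0.27, 0.10, 0.27, 0.03, 0.03, 0.18])
    rows = {}
    for s in range(n_species):
        chars = rng.choice(alphabet, size=width, p=probs)
        if all(c == "-" for c in chars):
            chars[int(rng.integers(0, width))] = "C"
        text = "".join(chars)
        size = width - text.count("-")
        start = int(rng.integers(0, 200))
        strand = "+" if rng.random() < 0.7 else "-"
        src_size = start + size + int(rng.integers(0, 100))
        rows[f"sp{s}"] = AlignmentRow(
            species=f"sp{s}", chrom="chrR", start=start, size=size,
            strand=strand, src_size=src_size, text=text,
        )
    return AlignmentBlock(rows=rows, ref_species="sp0")
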