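"""Transcript truncation at an insertion breakpoint from coverage drop-off.

A transposon inserted into an intron truncates transcription, which appears
in an RNA-seq pileup as an abrupt loss of coverage downstream of the
insertion.  The fraction of transcripts still read through the breakpoint is
estimated with a ratio-of-ratios:

    full_length_fraction = (mutant_down / mutant_up) / (control_down / control_up)

where each term is the mean per-base coverage on one side of the breakpoint.
Normalizing by the control ratio cancels 3'/5' coverage bias shared by both
genotypes; the estimate is clamped to [0, 1] and ``truncated_fraction`` is
its complement.  Upstream/downstream follow the transcript strand, not the
genome axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CoverageProfile


@dataclass
class TruncationEstimate:
    """Per-side coverage means and the resulting full-length/truncated split."""

    gene_id: str
    breakpoint: int
    upstream_mean: float
    downstream_mean: float
    control_upstream_mean: float
    control_downstream_mean: float
    full_length_fraction: float
    truncated_fraction: float

    def __post_init__(self) -> None:
        for name in (
            "upstream_mean",
            "downstream_mean",
            "control_upstream_mean",
            "control_downstream_mean",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.full_length_fraction <= 1.0:
            raise ValueError("full_length_fraction outside [0, 1]")
        if abs(self.full_length_fraction + self.truncated_fraction - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def mean_coverage(profile: CoverageProfile, interval: tuple[int, int]) -> float:
    """Mean per-base coverage over a half-open genomic interval."""
    start, end = interval
    if end <= start:
        raise ValueError(f"empty interval ({start}, {end})")
    if start < profile.start or end > profile.end:
        raise ValueError(
            f"interval ({start}, {end}) outside profile [{profile.start}, {profile.end})"
        )
    return float(np.mean(profile.values[start - profile.start : end - profile.start]))


def estimate_truncation(
    mutant: CoverageProfile,
    control: CoverageProfile,
    breakpoint: int,
    exclusion_nt: int = 0,
    strand: str = "+",
    gene_id: str = "",
) -> TruncationEstimate:
    """Estimate the full-length transcript fraction surviving past a breakpoint.

    ``exclusion_nt`` bases on each side of the breakpoint are omitted from
    both profiles (reads spanning the insertion junction are unmappable in a
    window of unknown width).  For a minus-strand transcript the genomic
    left side is downstream.  Raises when the mutant upstream or either
    control side has zero coverage, which leaves the ratio undefined.
    """
    if strand not in {"+", "-"}:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if exclusion_nt < 0:
        raise ValueError("exclusion_nt must be >= 0")

    sides = {}
    for label, profile in (("mutant", mutant), ("control", control)):
        left = (profile.start, breakpoint - exclusion_nt)
        right = (breakpoint + exclusion_nt, profile.end)
        if left[1] <= left[0] or right[1] <= right[0]:
            raise ValueError(
                f"{label} profile has no usable bases on one side of the "
                f"breakpoint after excluding {exclusion_nt} nt"
            )
        left_mean = mean_coverage(profile, left)
        right_mean = mean_coverage(profile, right)
        up, down = (left_mean, right_mean) if strand == "+" else (right_mean, left_mean)
        sides[label] = (up, down)

    mut_up, mut_down = sides["mutant"]
    ctl_up, ctl_down = sides["control"]
    if mut_up == 0:
        raise ValueError("mutant upstream coverage is zero; estimate undefined")
    if ctl_up == 0 or ctl_down == 0:
        raise ValueError("control ratio is zero or undefined; estimate undefined")

    raw = (mut_down / mut_up) / (ctl_down / ctl_up)
    full_length = min(1.0, max(0.0, raw))
    return TruncationEstimate(
        gene_id=gene_id,
        breakpoint=breakpoint,
        upstream_mean=mut_up,
        downstream_mean=mut_down,
        control_upstream_mean=ctl_up,
        control_downstream_mean=ctl_down,
        full_length_fraction=full_length,
        truncated_fraction=1.0 - full_length,
    )
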