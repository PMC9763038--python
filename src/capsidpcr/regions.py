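"""Per-column polymorphism profiling of amplicon translations and
segmentation into conserved (<= 1 residue) / variable (>= 2 residues)
regions.

A column is polymorphic when it holds two or more distinct non-gap residues;
maximal runs of polymorphic columns, merged across short monomorphic gaps,
become variable regions and the remainder is conserved. Gaps are excluded
from the distinct-residue count by default (a deletion is not a residue
polymorphism); ``count_gaps=True`` counts the gap state as a variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .seqcore import SequenceError, SequenceRecord


@dataclass(frozen=True)
class PolymorphismProfile:
    counts: tuple[int, ...]  # distinct non-gap residues per column

    @property
    def n_cols(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class RegionAnnotation:
    """(interval, label) tiles of [0, n_cols); adjacent labels differ."""

    regions: tuple[tuple[tuple[int, int], str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        prev_label = None
        for (s, e), label in self.regions:
            if s != prev_end or e <= s:
                raise SequenceError("regions do not tile the alignment")
            if label == prev_label:
                raise SequenceError("adjacent regions share a label")
            if label not in ("conserved", "variable"):
                raise SequenceError(f"bad region label {label!r}")
            prev_end, prev_label = e, label

    def variable_intervals(self) -> list[tuple[int, int]]:
        return [iv for iv, lb in self.regions if lb == "variable"]


def column_polymorphism(
    aln: Sequence[SequenceRecord], count_gaps: bool = False
) -> PolymorphismProfile:
    """Distinct residues per alignment column (gaps excluded by default)."""
    if len(aln) < 2:
        raise SequenceError("need >= 2 rows")
    L = len(aln[0])
    if any(len(r) != L for r in aln):
        raise SequenceError("rows have unequal lengths")
    counts = []
    for i in range(L):
        col = {r.residues[i] for r in aln}
        if not count_gaps:
            col -= {"-"}
        counts.append(max(len(col), 1))
    return PolymorphismProfile(tuple(counts))


def segment_regions(
    p: PolymorphismProfile, merge_gap: int = 2, min_polymorphisms: int = 2
) -> RegionAnnotation:
    """Call variable regions as maximal runs of polymorphic columns
    (count >= 2), merging runs separated by <= ``merge_gap`` monomorphic
    columns; everything else is conserved.

    A merged run must contain at least ``min_polymorphisms`` polymorphic
    columns to be called variable: a conserved region may contain a single
    isolated polymorphism, a variable region needs two or more. Set
    ``min_polymorphisms=1`` for the strict column-run reading.
    """
    if p.n_cols == 0:
        raise SequenceError("empty profile")
    poly = [c >= 2 for c in p.counts]
    # raw runs of polymorphic columns
    runs: list[list[int]] = []
    i = 0
    while i < p.n_cols:
        if poly[i]:
            j = i
            while j < p.n_cols and poly[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    # merge runs across short monomorphic separations
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    merged = [
        [s, e] for s, e in merged if sum(poly[s:e]) >= min_polymorphisms
    ]
    # tile
    regions: list[tuple[tuple[int, int], str]] = []
    pos = 0
    for s, e in merged:
        if pos < s:
            regions.append(((pos, s), "conserved"))
        regions.append(((s, e), "variable"))
        pos = e
    if pos < p.n_cols:
        regions.append(((pos, p.n_cols), "conserved"))
    return RegionAnnotation(tuple(regions))


def map_regions_to_reference(
    r: RegionAnnotation, ref: SequenceRecord, aln: Sequence[SequenceRecord]
) -> list[tuple[tuple[int, int], str]]:
    """Convert alignment-column intervals to ungapped 0-based half-open
    coordinates on ``ref`` (which must be a row of the alignment)."""
    row = next((a for a in aln if a.id == ref.id), None)
    if row is None or row.residues != ref.residues:
        raise SequenceError(f"reference {ref.id!r} is not a row of the alignment")
    # cumulative ungapped offset per alignment column
    offsets = []
    k = 0
    for ch in row.residues:
        offsets.append(k)
        if ch != "-":
            k += 1
    offsets.append(k)
    out = []
    for (s, e), label in r.regions:
        out.append(((offsets[s], offsets[e]), label))
    return out


def profile_to_frame(p: PolymorphismProfile) -> pd.DataFrame:
    return pd.DataFrame(
        dict(column=range(p.n_cols), distinct_residues=p.counts)
    )


def regions_to_frame(r: RegionAnnotation) -> pd.DataFrame:
    """BED-like frame (0-based half-open) suitable for external annotation
    tools (secondary-structure or 3D-structure overlays are not computed
    here; the intervals are the hook)."""
    return pd.DataFrame(
        dict(start=s, end=e, label=lb) for (s, e), lb in r.regions
    )
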