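"""Degenerate primer design from conserved protein motifs.

Scans a protein alignment of reference major-capsid-protein sequences for
windows that are conserved across all rows, back-translates each window into
the IUPAC-coded union of every codon combination encoding it, and pairs
forward/reverse motifs that flank a designated hypervariable interval.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data import CodonTable

from .seqcore import (
    SequenceError,
    SequenceRecord,
    expand_iupac,
    iupac_for_bases,
    reverse_complement,
)

# Standard genetic code, residue -> set of codons (stops excluded: '*' has no
# codon for design purposes by default).
_STD = CodonTable.unambiguous_dna_by_id[1]
CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STD.forward_table.items():
    CODONS_FOR_AA.setdefault(_aa, ())
    CODONS_FOR_AA[_aa] += (_codon,)


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinAlignment:
    """Equal-length amino-acid rows (gaps allowed), >= 2 rows."""

    rows: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise DesignError("alignment needs >= 2 rows")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise DesignError(f"rows have unequal lengths {sorted(lengths)}")
        for r in self.rows:
            if r.alphabet != "aa":
                raise DesignError(f"row {r.id!r} is not amino-acid")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, i: int) -> list[str]:
        return [r.residues[i] for r in self.rows]


@dataclass(frozen=True)
class ConservedMotif:
    """A gap-free alignment window whose columns each hold few residues."""

    start_col: int
    aa_window: tuple[frozenset[str], ...]  # per-column residue sets

    @property
    def length_aa(self) -> int:
        return len(self.aa_window)

    @property
    def end_col(self) -> int:
        return self.start_col + self.length_aa


@dataclass(frozen=True)
class DegeneratePrimer:
    iupac_seq: str
    degeneracy: int
    orientation: str  # 'forward' | 'reverse'
    motif_start_col: int
    motif_len_aa: int = 0

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise DesignError(f"bad orientation {self.orientation!r}")
        if self.degeneracy != degeneracy_of(self.iupac_seq):
            raise DesignError("degeneracy inconsistent with sequence")


@dataclass(frozen=True)
class PrimerPair:
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    insert_cols: tuple[int, int]  # alignment columns between the motifs
    expected_insert_len_nt: tuple[int, int]  # (min, max) over rows

    @property
    def pair_degeneracy(self) -> int:
        return self.forward.degeneracy * self.reverse.degeneracy


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def find_conserved_motifs(
    aln: ProteinAlignment, window_len_aa: int, max_variants: int = 1
) -> list[ConservedMotif]:
    """Exhaustively return every gap-free window with <= ``max_variants``
    distinct residues per column, sorted by start column."""
    if window_len_aa < 5:
        raise DesignError("window_len_aa must be >= 5")
    if max_variants < 1:
        raise DesignError("max_variants must be >= 1")
    if window_len_aa > aln.n_cols:
        raise DesignError(
            f"window {window_len_aa} longer than alignment ({aln.n_cols} cols)"
        )
    col_sets = [frozenset(aln.column(i)) for i in range(aln.n_cols)]
    ok = [("-" not in s) and len(s) <= max_variants for s in col_sets]
    out: list[ConservedMotif] = []
    for start in range(aln.n_cols - window_len_aa + 1):
        if all(ok[start : start + window_len_aa]):
            out.append(
                ConservedMotif(start, tuple(col_sets[start : start + window_len_aa]))
            )
    return out


def back_translate(motif: ConservedMotif) -> str:
    """IUPAC nucleotide string covering every codon of every residue per
    column; each codon position gets the minimal code over the base union.

    Over-coverage is expected and one-sided: the IUPAC string may expand to
    codons no residue in the column uses (e.g. Leu alone gives ``YTN``,
    8 expansions for 6 codons).
    """
    parts: list[str] = []
    for col in motif.aa_window:
        codons: list[str] = []
        for aa in sorted(col):
            if aa not in CODONS_FOR_AA:
                raise DesignError(f"residue {aa!r} has no codon")
            codons.extend(CODONS_FOR_AA[aa])
        for pos in range(3):
            parts.append(iupac_for_bases({c[pos] for c in codons}))
    return "".join(parts)


def degeneracy_of(iupac_seq: str) -> int:
    """Number of distinct expansions: product of per-position base-set sizes."""
    deg = 1
    for c in iupac_seq:
        deg *= len(expand_iupac(c))
    return deg


def wallace_tm(iupac_seq: str) -> float:
    """Wallace-rule melting temperature 2(A+T)+4(G+C), averaged over the
    primer's expansions (reported informationally, never a constraint)."""
    tm = 0.0
    for c in iupac_seq:
        bases = expand_iupac(c)
        tm += sum(2.0 if b in "AT" else 4.0 for b in bases) / len(bases)
    return tm


def design_primer_pairs(
    aln: ProteinAlignment,
    hypervariable: tuple[int, int],
    window_len_aa: int = 7,
    max_variants: int = 1,
    max_degeneracy: int = 512,
    insert_len_range_nt: tuple[int, int] = (30, 1000),
) -> tuple[list[PrimerPair], Counter]:
    """Pair conserved motifs flanking the hypervariable interval.

    The forward primer back-translates a motif ending at or before the
    interval start; the reverse primer is the reverse complement of the
    back-translation of a motif starting at or after the interval end. Both
    degeneracies must be <= ``max_degeneracy`` and the expected insert
    length (3x the per-row gap-free residue count between the motifs, as a
    min–max range) must lie within ``insert_len_range_nt``.

    Returns the qualifying pairs ranked by ascending pair degeneracy, ties
    broken by smaller maximal insert length, then leftmost forward start,
    together with a diagnostic counter of why candidates were rejected
    (useful when the list is empty).
    """
    hv_start, hv_end = hypervariable
    if not (0 <= hv_start < hv_end <= aln.n_cols):
        raise DesignError(f"hypervariable interval {hypervariable} outside alignment")
    motifs = find_conserved_motifs(aln, window_len_aa, max_variants)
    fwd_motifs = [m for m in motifs if m.end_col <= hv_start]
    rev_motifs = [m for m in motifs if m.start_col >= hv_end]
    diag: Counter = Counter()
    if not fwd_motifs:
        diag["no_conserved_motif_upstream"] += 1
    if not rev_motifs:
        diag["no_conserved_motif_downstream"] += 1

    pairs: list[PrimerPair] = []
    for fm in fwd_motifs:
        fseq = back_translate(fm)
        fdeg = degeneracy_of(fseq)
        if fdeg > max_degeneracy:
            diag["forward_degeneracy_exceeded"] += len(rev_motifs)
            continue
        fwd = DegeneratePrimer(fseq, fdeg, "forward", fm.start_col, fm.length_aa)
        for rm in rev_motifs:
            rseq_plus = back_translate(rm)
            rdeg = degeneracy_of(rseq_plus)
            if rdeg > max_degeneracy:
                diag["reverse_degeneracy_exceeded"] += 1
                continue
            spans = [
                3 * len(r.residues[fm.end_col : rm.start_col].replace("-", ""))
                for r in aln.rows
            ]
            lo, hi = min(spans), max(spans)
            if lo < insert_len_range_nt[0] or hi > insert_len_range_nt[1]:
                diag["insert_length_out_of_range"] += 1
                continue
            rev = DegeneratePrimer(
                reverse_complement(rseq_plus), rdeg, "reverse", rm.start_col,
                rm.length_aa,
            )
            pairs.append(
                PrimerPair(fwd, rev, (fm.end_col, rm.start_col), (lo, hi))
            )
    pairs.sort(
        key=lambda p: (
            p.pair_degeneracy,
            p.expected_insert_len_nt[1],
            p.forward.motif_start_col,
        )
    )
    return pairs, diag


def primers_to_tsv(pairs: Sequence[PrimerPair], path: str) -> None:
    import pandas as pd

    rows = []
    for i, p in enumerate(pairs):
        for primer in (p.forward, p.reverse):
            rows.append(
                dict(
                    pair_id=f"pair_{i:03d}",
                    orientation=primer.orientation,
                    iupac_seq=primer.iupac_seq,
                    degeneracy=primer.degeneracy,
                    motif_start_col=primer.motif_start_col,
                    motif_len_aa=primer.motif_len_aa,
                    tm_wallace=round(wallace_tm(primer.iupac_seq), 2),
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
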