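"""IUPAC-aware primer binding and in-silico amplicon extraction.

Used both to validate designed primers against their reference panel and to
generate synthetic amplicons. No thermodynamics: a primer binds wherever the
template window falls inside the primer's IUPAC base sets at every position,
up to a mismatch tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .primer_design import DegeneratePrimer, PrimerPair
from .seqcore import SequenceError, SequenceRecord, expand_iupac, reverse_complement


@dataclass(frozen=True)
class BindingSite:
    template_id: str
    start: int
    strand: str  # '+' : primer matches the template as written; '-' : its rc does
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    insert_seq: str  # primers trimmed, reported on the forward-primer strand
    insert_interval: tuple[int, int]  # template coordinates of the insert
    strand: str  # strand carrying the forward primer
    fwd_site: BindingSite
    rev_site: BindingSite


def iupac_mismatches(primer: str, window: str) -> int:
    """Positions where the window base is outside the primer code's base set."""
    if len(primer) != len(window):
        raise SequenceError(
            f"length mismatch: primer {len(primer)} vs window {len(window)}"
        )
    return sum(1 for p, w in zip(primer, window) if w not in expand_iupac(p))


def _scan(template: str, primer: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) where primer matches the template plus strand.

    Vectorised: per primer position a 256-entry lookup of disallowed bytes,
    summed over a strided view of the template.
    """
    m = len(primer)
    n = len(template)
    if m > n:
        return []
    tpl = np.frombuffer(template.encode(), dtype=np.uint8)
    bad = np.ones((m, 256), dtype=np.uint8)
    for i, code in enumerate(primer):
        for b in expand_iupac(code):
            bad[i, ord(b)] = 0
    windows = np.lib.stride_tricks.sliding_window_view(tpl, m)
    mism = bad[np.arange(m), windows].sum(axis=1)
    starts = np.nonzero(mism <= max_mismatch)[0]
    return [(int(s), int(mism[s])) for s in starts]


def find_binding_sites(
    template: SequenceRecord,
    primer: DegeneratePrimer | str,
    max_mismatch: int = 0,
) -> list[BindingSite]:
    """All windows on both strands with <= ``max_mismatch`` mismatches.

    A ``'-'`` strand site means the primer matches the reverse complement of
    the template window (i.e. the primer's reverse complement appears on the
    plus strand at that interval). Sorted by start, then strand.
    """
    seq = primer.iupac_seq if isinstance(primer, DegeneratePrimer) else primer
    tpl = template.residues
    bad = set(tpl) - set("ACGT")
    if bad:
        raise SequenceError(f"template {template.id!r} has ambiguous bases {sorted(bad)}")
    if len(seq) > len(tpl):
        return []
    sites = [
        BindingSite(template.id, s, "+", mm, len(seq))
        for s, mm in _scan(tpl, seq, max_mismatch)
    ]
    sites += [
        BindingSite(template.id, s, "-", mm, len(seq))
        for s, mm in _scan(tpl, reverse_complement(seq), max_mismatch)
    ]
    sites.sort(key=lambda b: (b.start, b.strand))
    return sites


def amplify(
    template: SequenceRecord,
    pair: PrimerPair,
    max_mismatch: int = 0,
    insert_len_range: tuple[int, int] = (1, 10_000),
) -> list[Amplicon]:
    """Enumerate every PCR product of the pair on the template.

    A product needs a forward-primer site and, downstream of it, a site where
    the reverse primer (as written, i.e. already reverse-complemented relative
    to the coding strand) appears on the plus strand. The symmetric situation
    with the roles swapped on the minus strand is also enumerated, so
    amplification is strand-symmetric. Inserts are reported with the
    primer-binding regions trimmed, on the forward-primer strand.
    """
    fwd, rev = pair.forward.iupac_seq, pair.reverse.iupac_seq
    tpl = template.residues
    out: list[Amplicon] = []

    # forward primer on '+': fwd matches plus strand, rc(rev primer) is what
    # the plus strand shows at the reverse-binding site... the reverse primer
    # binds the minus strand, so the plus strand carries rc(rev) — but `rev`
    # is already written 5'->3' on the minus strand, so the plus strand shows
    # reverse_complement(rev).
    f_hits = _scan(tpl, fwd, max_mismatch)
    r_hits = _scan(tpl, reverse_complement(rev), max_mismatch)
    for fs, fmm in f_hits:
        f_end = fs + len(fwd)
        for rs, rmm in r_hits:
            if rs < f_end:
                continue
            insert = tpl[f_end:rs]
            if not insert_len_range[0] <= len(insert) <= insert_len_range[1]:
                continue
            out.append(
                Amplicon(
                    template.id,
                    insert,
                    (f_end, rs),
                    "+",
                    BindingSite(template.id, fs, "+", fmm, len(fwd)),
                    BindingSite(template.id, rs, "-", rmm, len(rev)),
                )
            )

    # forward primer on '-': same geometry on the reverse complement strand.
    f_hits_m = _scan(tpl, reverse_complement(fwd), max_mismatch)
    r_hits_m = _scan(tpl, rev, max_mismatch)
    for fs, fmm in f_hits_m:
        # on the minus strand the forward primer runs rightward from the
        # right edge of this plus-strand window
        for rs, rmm in r_hits_m:
            if rs + len(rev) > fs:
                continue
            insert_plus = tpl[rs + len(rev) : fs]
            if not insert_len_range[0] <= len(insert_plus) <= insert_len_range[1]:
                continue
            out.append(
                Amplicon(
                    template.id,
                    reverse_complement(insert_plus),
                    (rs + len(rev), fs),
                    "-",
                    BindingSite(template.id, fs, "-", fmm, len(fwd)),
                    BindingSite(template.id, rs, "+", rmm, len(rev)),
                )
            )

    out.sort(key=lambda a: (a.insert_interval, a.strand))
    return out
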