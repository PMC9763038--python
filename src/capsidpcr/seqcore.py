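"""Sequence data model, IUPAC algebra, translation and FASTA/FASTQ/TSV I/O.

Conventions used throughout the package:

* all coordinates are 0-based, half-open intervals; strand is ``'+'``/``'-'``;
* nucleotide sequences are uppercased on input and ``U`` is mapped to ``T``
  (RNA virus genomes are deposited both ways);
* the gap character ``'-'`` is legal only in alignment contexts and is
  rejected in reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# IUPAC algebra
# ---------------------------------------------------------------------------

#: The 15 IUPAC nucleotide ambiguity codes mapped to their base sets.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse map: base set -> the minimal IUPAC code covering exactly that set.
BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

NT_ALPHABET = frozenset(IUPAC_CODES)
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_ALPHABET = AA_LETTERS | frozenset("*-X")


class SequenceError(ValueError):
    """Raised for malformed sequences or sequence files."""


def expand_iupac(code: str) -> frozenset[str]:
    """Return the base set of one IUPAC nucleotide code (``N`` -> ACGT)."""
    try:
        return IUPAC_CODES[code]
    except KeyError:
        raise SequenceError(f"unknown IUPAC code: {code!r}") from None


def iupac_for_bases(bases: Iterable[str]) -> str:
    """Minimal IUPAC code covering exactly the given base set."""
    key = frozenset(bases)
    try:
        return BASES_TO_CODE[key]
    except KeyError:
        raise SequenceError(f"no IUPAC code for base set {sorted(key)}") from None


def reverse_complement(nt: str) -> str:
    """IUPAC-aware reverse complement; involution on every legal string."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(nt))
    except KeyError as exc:
        raise SequenceError(f"illegal nucleotide {exc.args[0]!r} in {nt!r}") from None


def translate(nt: str, frame: int = 0) -> str:
    """Translate an unambiguous nucleotide string in the given frame.

    Standard genetic code; the trailing partial codon is dropped and stop
    codons are emitted as ``'*'``. Ambiguous bases are an error — degenerate
    sequences are never translated.
    """
    if frame not in (0, 1, 2):
        raise SequenceError(f"frame must be 0, 1 or 2, got {frame}")
    bad = set(nt) - set("ACGT")
    if bad:
        raise SequenceError(f"cannot translate ambiguous/illegal bases {sorted(bad)}")
    sub = nt[frame:]
    if len(sub) < 3:
        raise SequenceError("fewer than one full codon after applying frame")
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate(table=1))


# ---------------------------------------------------------------------------
# SequenceRecord
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence.

    ``alphabet`` is ``'nt'`` or ``'aa'``. Residues are uppercased; ``U`` in
    nucleotide input is normalised to ``T``. Amino-acid sequences may contain
    ``'*'`` (stop) and ``'-'`` (gap, alignment contexts only).
    """

    id: str
    residues: str
    alphabet: str = "nt"

    def __post_init__(self) -> None:
        res = self.residues.upper()
        if self.alphabet == "nt":
            res = res.replace("U", "T")
            legal = NT_ALPHABET
        elif self.alphabet == "aa":
            legal = AA_ALPHABET
        else:
            raise SequenceError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")
        if not res:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(res) - legal
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal {self.alphabet} characters {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise SequenceError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a multi-record FASTA file; order preserved, sequences uppercased.

    Errors on an empty file and on duplicate ids (naming the id).
    """
    records = [
        SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet=alphabet)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    _check_unique_ids(records)
    return records


def write_fasta(path: str | os.PathLike, records: Sequence[SequenceRecord]) -> None:
    _check_unique_ids(records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.residues}\n")


def read_fastq(
    path: str | os.PathLike, min_mean_q: float | None = None
) -> list[SequenceRecord]:
    """Read FASTQ reads (nt). Quality is parsed; reads below ``min_mean_q``
    mean Phred quality are dropped when the cutoff is given."""
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        if min_mean_q is not None:
            quals = rec.letter_annotations["phred_quality"]
            if sum(quals) / len(quals) < min_mean_q:
                continue
        out.append(SequenceRecord(id=rec.id, residues=str(rec.seq), alphabet="nt"))
    if not out:
        raise SequenceError(f"no FASTQ reads retained from {path}")
    _check_unique_ids(out)
    return out


def write_fastq(path: str | os.PathLike, records: Sequence[SequenceRecord]) -> None:
    """Write reads as FASTQ with uniform placeholder quality (Phred 40)."""
    _check_unique_ids(records)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"@{r.id}\n{r.residues}\n+\n{'I' * len(r.residues)}\n")


def read_layer_tsv(path: str | os.PathLike) -> dict[str, str]:
    """Read read/sample -> layer metadata TSV (columns: read_id, layer)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("read_id") or cols.get("sample")
    layer_col = cols.get("layer")
    if id_col is None or layer_col is None:
        raise SequenceError(
            f"metadata TSV {path} must have columns read_id/sample and layer"
        )
    return dict(zip(df[id_col], df[layer_col]))


def write_layer_tsv(path: str | os.PathLike, mapping: dict[str, str]) -> None:
    pd.DataFrame(
        {"read_id": list(mapping), "layer": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)
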