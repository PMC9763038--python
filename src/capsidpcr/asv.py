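"""Amplicon sequence variant (ASV) tables: dereplication, singleton removal,
synonymous collapse to amino-acid ASVs, and the relative-abundance floor.

Exact dereplication stands in for error-model denoising: with error-free or
low-error reads every distinct sequence is its own variant, which is the
faithful desk-scale surrogate (see the methods note).
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .seqcore import SequenceError, SequenceRecord, translate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ASVRow:
    asv_id: str
    sequence: str
    per_layer_counts: tuple[tuple[str, int], ...]  # (layer, count), layer order
    members: tuple[str, ...] = ()  # nt member ids for aa rows

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.per_layer_counts)

    def layer_count(self, layer: str) -> int:
        return dict(self.per_layer_counts).get(layer, 0)


@dataclass(frozen=True)
class ASVTable:
    """Rows sorted by descending total count, ties by sequence lexicographic."""

    level: str  # 'nt' | 'aa'
    rows: tuple[ASVRow, ...]
    layers: tuple[str, ...]

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.rows]
        if len(set(seqs)) != len(seqs):
            raise SequenceError("duplicate sequences in ASV table")

    @property
    def grand_total(self) -> int:
        return sum(r.total_count for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)


CollapseMap = dict[str, tuple[str, ...]]  # aa_asv_id -> member nt asv ids


def _sorted_rows(rows: Iterable[ASVRow]) -> tuple[ASVRow, ...]:
    return tuple(sorted(rows, key=lambda r: (-r.total_count, r.sequence)))


def dereplicate(reads: Sequence[tuple[SequenceRecord, str]]) -> ASVTable:
    """Collapse identical reads into nucleotide ASVs with per-layer counts.

    Layer order follows first appearance in the input. nt ASV ids are
    ``NT_0001, ...`` in table order (descending abundance).
    """
    if not reads:
        raise SequenceError("no reads to dereplicate")
    layers: list[str] = []
    counts: dict[str, Counter] = defaultdict(Counter)
    for rec, layer in reads:
        if layer not in layers:
            layers.append(layer)
        bad = set(rec.residues) - set("ACGT")
        if bad:
            raise SequenceError(f"read {rec.id!r} has ambiguous bases {sorted(bad)}")
        counts[rec.residues][layer] += 1
    rows = _sorted_rows(
        ASVRow("", seq, tuple((ly, c[ly]) for ly in layers if ly in c))
        for seq, c in counts.items()
    )
    rows = tuple(
        replace(r, asv_id=f"NT_{i + 1:04d}") for i, r in enumerate(rows)
    )
    return ASVTable("nt", rows, tuple(layers))


def remove_singletons(t: ASVTable, per_layer: bool = False) -> ASVTable:
    """Drop ASVs observed exactly once.

    By default a singleton has total count 1 summed across layers (layers
    were pooled into one amplicon analysis); ``per_layer=True`` instead
    zeroes out layer counts of 1 before re-totalling.
    """
    if not t.rows:
        raise SequenceError("empty ASV table")
    if per_layer:
        kept: list[ASVRow] = []
        for r in t.rows:
            plc = tuple((ly, c) for ly, c in r.per_layer_counts if c > 1)
            if plc:
                kept.append(replace(r, per_layer_counts=plc))
    else:
        kept = [r for r in t.rows if r.total_count > 1]
    removed = len(t.rows) - len(kept)
    if removed:
        log.info("singleton removal: dropped %d of %d ASVs", removed, len(t.rows))
    if not kept:
        log.warning("all ASVs were singletons; table is empty")
    return ASVTable(t.level, _sorted_rows(kept), t.layers)


def collapse_by_translation(
    t: ASVTable, frame: int = 0
) -> tuple[ASVTable, CollapseMap]:
    """Group nucleotide ASVs whose translations are identical.

    The reading frame is fixed by the primer design: the forward primer is
    built in codon phase, so the trimmed insert translates in frame 0. Rows
    whose translation has an internal stop are dropped with a warning.
    Amino-acid ASVs are renamed ``ASV_001, ASV_002, ...`` by descending
    abundance, with an ``s`` suffix when the group merged more than one
    nucleotide variant (synonymous substitutions).
    """
    if t.level != "nt":
        raise SequenceError("collapse_by_translation expects a nucleotide table")
    groups: dict[str, list[ASVRow]] = defaultdict(list)
    dropped = 0
    for r in t.rows:
        try:
            aa = translate(r.sequence, frame)
        except SequenceError:
            dropped += 1
            continue
        if "*" in aa[:-1]:
            log.warning("ASV %s: internal stop codon, dropped", r.asv_id)
            dropped += 1
            continue
        groups[aa].append(r)
    if not groups:
        raise SequenceError("no ASV translatable in the given frame")
    if dropped:
        log.info("translation collapse: dropped %d untranslatable rows", dropped)

    merged: list[ASVRow] = []
    for aa, members in groups.items():
        layer_counts: Counter = Counter()
        for m in members:
            layer_counts.update(dict(m.per_layer_counts))
        merged.append(
            ASVRow(
                "",
                aa,
                tuple((ly, layer_counts[ly]) for ly in t.layers if ly in layer_counts),
                members=tuple(m.asv_id for m in members),
            )
        )
    rows = _sorted_rows(merged)
    rows = tuple(
        replace(
            r,
            asv_id=f"ASV_{i + 1:03d}" + ("s" if len(r.members) > 1 else ""),
        )
        for i, r in enumerate(rows)
    )
    cmap: CollapseMap = {r.asv_id: r.members for r in rows}
    return ASVTable("aa", rows, t.layers), cmap


def abundance_filter(t: ASVTable, min_fraction: float = 0.0002) -> ASVTable:
    """Keep rows whose share of all reads is >= ``min_fraction`` (inclusive
    boundary: a row at exactly the floor is retained)."""
    if not 0.0 <= min_fraction <= 1.0:
        raise SequenceError(f"min_fraction {min_fraction} outside [0, 1]")
    total = t.grand_total
    if total == 0:
        raise SequenceError("table has zero total reads")
    kept = [r for r in t.rows if r.total_count / total >= min_fraction]
    if len(kept) < len(t.rows):
        log.info(
            "abundance filter: dropped %d ASVs below %.4f%%",
            len(t.rows) - len(kept), 100 * min_fraction,
        )
    return ASVTable(t.level, _sorted_rows(kept), t.layers)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def table_to_frame(t: ASVTable) -> pd.DataFrame:
    rows = []
    for r in t.rows:
        d = dict(asv_id=r.asv_id, sequence=r.sequence, total_count=r.total_count)
        for ly in t.layers:
            d[ly] = r.layer_count(ly)
        if t.level == "aa":
            d["members"] = ",".join(r.members)
        rows.append(d)
    return pd.DataFrame(rows)


def write_table(t: ASVTable, path: str) -> None:
    table_to_frame(t).to_csv(path, sep="\t", index=False)


def read_table(path: str, level: str) -> ASVTable:
    df = pd.read_csv(path, sep="\t", dtype={"members": str})
    meta = {"asv_id", "sequence", "total_count", "members"}
    layers = tuple(c for c in df.columns if c not in meta)
    rows = []
    for _, rec in df.iterrows():
        members = ()
        if level == "aa" and isinstance(rec.get("members"), str):
            members = tuple(rec["members"].split(","))
        rows.append(
            ASVRow(
                rec["asv_id"],
                rec["sequence"],
                tuple((ly, int(rec[ly])) for ly in layers if int(rec[ly]) > 0),
                members=members,
            )
        )
    return ASVTable(level, _sorted_rows(rows), layers)
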