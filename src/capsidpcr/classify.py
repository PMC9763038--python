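"""Identity-based ASV classification against a packaged reference panel and
per-layer community composition.

A remote-database homology search is replaced by exhaustive pairwise percent
identity against a small local panel, so classification depends only on the
shipped references, never on a database snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from Bio import Align

from .asv import ASVTable
from .seqcore import SequenceError, SequenceRecord

log = logging.getLogger(__name__)

GROUPS = ("HcRNAV", "Alvernaviridae_like", "other")
HOST_TYPES = ("UA", "CY", "unknown")


@dataclass(frozen=True)
class PanelEntry:
    record: SequenceRecord  # aa
    group: str  # HcRNAV | Alvernaviridae_like | other
    host_range_type: str = "unknown"  # UA | CY | unknown
    accession: str = ""


@dataclass(frozen=True)
class ReferencePanel:
    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        accs = [e.accession for e in self.entries]
        if len(set(accs)) != len(accs):
            raise SequenceError("duplicate accessions in panel")
        if not any(e.group == "HcRNAV" for e in self.entries):
            raise SequenceError("panel needs at least one HcRNAV entry")
        for e in self.entries:
            if e.group not in GROUPS or e.host_range_type not in HOST_TYPES:
                raise SequenceError(f"bad panel annotation on {e.accession!r}")

    def by_group(self, group: str) -> tuple[PanelEntry, ...]:
        return tuple(e for e in self.entries if e.group == group)


@dataclass(frozen=True)
class ClassificationResult:
    asv_id: str
    best_ref_accession: str
    percent_identity: float
    group_label: str  # HcRNAV_derived | Alvernaviridae_like | unassigned


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -1
    a.extend_gap_score = -1
    return a


_ALIGNER = _aligner()


def percent_identity(a: str, b: str) -> float:
    """Global percent identity between two amino-acid strings.

    Equal-length inputs use ungapped column identity. Otherwise a global
    alignment chooses the path (match +1, mismatch 0, linear gap -1; the
    scores steer the path only) and identity = matches / alignment columns.
    """
    if not a or not b:
        raise SequenceError("empty sequence in identity computation")
    if len(a) == len(b):
        matches = sum(x == y for x, y in zip(a, b))
        return 100.0 * matches / len(a)
    aln = _ALIGNER.align(a, b)[0]
    cols = 0
    matches = 0
    sa, sb = str(aln[0]), str(aln[1])
    for x, y in zip(sa, sb):
        cols += 1
        if x == y and x != "-":
            matches += 1
    return 100.0 * matches / cols


def classify_asv(
    asv: SequenceRecord,
    panel: ReferencePanel,
    hc_threshold: float = 85.0,
    related_floor: float = 40.0,
) -> ClassificationResult:
    """Assign one amino-acid ASV to a viral group by best panel identity.

    ``HcRNAV_derived`` requires identity strictly above ``hc_threshold`` to
    some HcRNAV panel entry (identity of exactly 85.0 does not qualify);
    otherwise any panel identity >= ``related_floor`` gives
    ``Alvernaviridae_like``; else ``unassigned``. The best reference is the
    panel-wide identity argmax, ties broken by accession.
    """
    idents = [
        (percent_identity(asv.residues, e.record.residues), e) for e in panel.entries
    ]
    best_pid = max(p for p, _ in idents)
    tied = sorted((e.accession for p, e in idents if p == best_pid))
    best_acc = tied[0]
    hc_best = max((p for p, e in idents if e.group == "HcRNAV"), default=0.0)
    if hc_best > hc_threshold:
        label = "HcRNAV_derived"
    elif best_pid >= related_floor:
        label = "Alvernaviridae_like"
    else:
        label = "unassigned"
    return ClassificationResult(asv.id, best_acc, best_pid, label)


def classify_table(
    t: ASVTable,
    panel: ReferencePanel,
    hc_threshold: float = 85.0,
    related_floor: float = 40.0,
) -> list[ClassificationResult]:
    return [
        classify_asv(
            SequenceRecord(r.asv_id, r.sequence, "aa"), panel,
            hc_threshold, related_floor,
        )
        for r in t.rows
    ]


def classify_table_nt(
    t: ASVTable, panel_nt: Sequence[SequenceRecord], nt_threshold: float = 92.0
) -> list[ClassificationResult]:
    """Optional nucleotide-level rule: an nt ASV with identity > 92% to an
    HcRNAV gene is flagged HcRNAV_derived, reported alongside the protein
    classification."""
    out = []
    for r in t.rows:
        idents = sorted(
            ((percent_identity(r.sequence, ref.residues), ref.id) for ref in panel_nt),
            key=lambda x: (-x[0], x[1]),
        )
        pid, acc = idents[0]
        label = "HcRNAV_derived" if pid > nt_threshold else "unassigned"
        out.append(ClassificationResult(r.asv_id, acc, pid, label))
    return out


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

LayerComposition = dict[str, dict[str, float]]  # layer -> group -> fraction


def compose_layers(
    t: ASVTable,
    results: Sequence[ClassificationResult],
    others_min_fraction: float = 0.0002,
) -> LayerComposition:
    """Per-layer relative abundance of the classified groups.

    Unassigned ASVs and ASVs whose overall share is below
    ``others_min_fraction`` are pooled into ``"Others"``; per layer the
    fractions over {HcRNAV_derived, Alvernaviridae_like, Others} sum to 1.
    """
    labels = {r.asv_id: r.group_label for r in results}
    missing = [r.asv_id for r in t.rows if r.asv_id not in labels]
    if missing:
        raise SequenceError(f"unclassified ASVs: {missing[:5]}")
    total = t.grand_total
    comp: LayerComposition = {}
    for layer in t.layers:
        sums = {"HcRNAV_derived": 0, "Alvernaviridae_like": 0, "Others": 0}
        layer_total = 0
        for r in t.rows:
            n = r.layer_count(layer)
            layer_total += n
            label = labels[r.asv_id]
            if label == "unassigned" or r.total_count / total < others_min_fraction:
                sums["Others"] += n
            else:
                sums[label] += n
        if layer_total == 0:
            log.warning("layer %s has zero reads", layer)
            comp[layer] = {g: 0.0 for g in sums}
        else:
            comp[layer] = {g: v / layer_total for g, v in sums.items()}
    return comp


def composition_to_frame(comp: LayerComposition) -> pd.DataFrame:
    return pd.DataFrame(comp).T.rename_axis("layer")


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            asv_id=r.asv_id,
            best_ref_accession=r.best_ref_accession,
            percent_identity=round(r.percent_identity, 4),
            group_label=r.group_label,
        )
        for r in results
    )


def plot_composition(comp: LayerComposition, path: str) -> None:
    """Stacked-bar plot of per-layer group composition (side effect only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = composition_to_frame(comp)
    ax = df.plot(kind="bar", stacked=True, figsize=(6, 4), width=0.8)
    ax.set_ylabel("relative read abundance")
    ax.set_xlabel("sediment layer")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)


# ---------------------------------------------------------------------------
# Panel I/O: FASTA + sidecar TSV (accession, group, type)
# ---------------------------------------------------------------------------

def write_panel(panel: ReferencePanel, fasta_path: str, tsv_path: str) -> None:
    from .seqcore import write_fasta

    write_fasta(fasta_path, [e.record for e in panel.entries])
    pd.DataFrame(
        dict(
            accession=e.accession,
            seq_id=e.record.id,
            group=e.group,
            host_range_type=e.host_range_type,
        )
        for e in panel.entries
    ).to_csv(tsv_path, sep="\t", index=False)


def read_panel(fasta_path: str, tsv_path: str) -> ReferencePanel:
    from .seqcore import read_fasta

    records = {r.id: r for r in read_fasta(fasta_path, alphabet="aa")}
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    entries = []
    for _, row in df.iterrows():
        if row["seq_id"] not in records:
            raise SequenceError(f"panel TSV references missing id {row['seq_id']!r}")
        entries.append(
            PanelEntry(
                records[row["seq_id"]], row["group"], row["host_range_type"],
                row["accession"],
            )
        )
    return ReferencePanel(tuple(entries))
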