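"""Synthetic layered viral community with known ground truth.

Emulates the study design end to end: a clonally related panel of
capsid-gene references carrying two frozen conserved primer motifs that
flank a planted hypervariable window; UA/CY-typed and related strains
evolved from the panel by a codon-aware substitution model (synonymous
changes everywhere, nonsynonymous changes concentrated in the window);
five sediment layers with planted group proportions; amplicon reads drawn
per layer with per-base substitution errors.

Everything is deterministic under the config seed: the panel, the strains,
the reads and the ground truth. Per-stage generators are derived from the
seed as ``default_rng([seed, stage_index])``.

What is *not* modelled: PCR bias and chimeras, indel errors, paired-end
merging, and any deposition/mixing model of the sediment column.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .classify import PanelEntry, ReferencePanel
from .insilico_pcr import amplify
from .primer_design import (
    ConservedMotif,
    DegeneratePrimer,
    PrimerPair,
    back_translate,
    degeneracy_of,
)
from .seqcore import SequenceError, SequenceRecord, reverse_complement, translate

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]
_AA_OF = {c: translate(c) for c in _CODONS}
# residues whose codon sets keep back-translated degeneracy low (<= 2/position)
_MOTIF_AA = "MWFYHQNKDEC"

DEFAULT_LAYERS = ("0-3cm", "3-6cm", "6-9cm", "9-12cm", "12-15cm")
# (HcRNAV, related, background) per layer: related-dominant shallow layers,
# HcRNAV-dominant deep layers — a qualitative demo profile, not a target.
DEFAULT_PROPORTIONS = (
    (0.05, 0.85, 0.10),
    (0.06, 0.84, 0.10),
    (0.08, 0.82, 0.10),
    (0.55, 0.35, 0.10),
    (0.60, 0.30, 0.10),
)


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic community.

    Rates are per codon per strain draw; ``nonsyn_multiplier`` scales the
    nonsynonymous rate inside the hypervariable window so that within-group
    window divergence is about 10% at the defaults. Read depth and layer
    count follow the study design (five 3-cm layers; 300-nt reads covering
    the whole insert, modelled single-end).
    """

    seed: int = 0
    n_layers: int = 5
    layer_labels: tuple[str, ...] = DEFAULT_LAYERS
    layer_proportions: tuple[tuple[float, float, float], ...] = DEFAULT_PROPORTIONS
    gene_len_codons: int = 130
    fwd_motif_codons: tuple[int, int] = (12, 19)
    rev_motif_codons: tuple[int, int] = (95, 102)
    hypervariable_codons: tuple[int, int] = (30, 54)
    nonsyn_multiplier: float = 33.0
    syn_rate: float = 0.05
    nonsyn_rate: float = 0.003
    type_syn_rate: float = 0.05
    type_nonsyn_window: float = 0.25
    type_nonsyn_outside: float = 0.01
    related_syn_rate: float = 0.2
    related_nonsyn_rate: float = 0.4
    strains_per_hc_ref: int = 2
    strains_per_related_ref: int = 1
    n_background_strains: int = 3
    lognormal_sigma: float = 1.0
    reads_per_layer: int = 100_000
    error_rate: float = 0.001
    read_length: int = 300
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if len(self.layer_labels) != self.n_layers:
            raise SequenceError("layer_labels length != n_layers")
        if len(self.layer_proportions) != self.n_layers:
            raise SequenceError("layer_proportions length != n_layers")
        for props in self.layer_proportions:
            if abs(sum(props) - 1.0) > 1e-9:
                raise SequenceError(f"layer proportions {props} do not sum to 1")
        for r in (self.syn_rate, self.nonsyn_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise SequenceError(f"rate {r} outside [0, 1]")
        fs, fe = self.fwd_motif_codons
        rs, re_ = self.rev_motif_codons
        hs, he = self.hypervariable_codons
        if not (fe <= hs < he <= rs):
            raise SequenceError(
                "hypervariable window must lie strictly between the primer motifs"
            )
        if re_ > self.gene_len_codons:
            raise SequenceError("reverse motif outside the gene")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("layer_labels", "layer_proportions", "fwd_motif_codons",
                    "rev_motif_codons", "hypervariable_codons"):
            if key in raw:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass
class GroundTruth:
    strain_group: dict[str, str]  # strain -> HcRNAV | related | background
    strain_type: dict[str, str]  # strain -> UA | CY | unknown
    layer_abundances: dict[str, dict[str, float]]  # layer -> strain -> frac
    window_insert_aa: tuple[int, int]  # planted window, insert aa coords
    strain_insert_aa: dict[str, str]  # strain -> protein haplotype of insert
    per_read_source: dict[str, str] = field(default_factory=dict)


@dataclass
class CommunityModel:
    """Panel plus everything the read simulator needs."""

    panel: ReferencePanel
    panel_nt: dict[str, str]  # panel seq id -> nt gene
    ancestor_nt: SequenceRecord
    community_nt: dict[str, str]  # community strain id -> nt gene
    truth: GroundTruth
    primer_pair: PrimerPair
    cfg: SimulationConfig


# ---------------------------------------------------------------------------
# Codon-aware evolution
# ---------------------------------------------------------------------------

def _random_orf(n_codons: int, rng: np.random.Generator) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n_codons)]


def _synonymous_alternatives(codon: str) -> list[str]:
    aa = _AA_OF[codon]
    return [c for c in _CODONS if _AA_OF[c] == aa and c != codon]


def _nonsyn_neighbors(codon: str) -> list[str]:
    """Single-nucleotide neighbours that change the residue, excluding stops."""
    out = []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            cand = codon[:pos] + b + codon[pos + 1:]
            if cand not in _STOPS and _AA_OF[cand] != _AA_OF[codon]:
                out.append(cand)
    return out


def evolve(
    codons: Sequence[str],
    rng: np.random.Generator,
    syn_rate: float,
    nonsyn_rate: float,
    window: tuple[int, int] = (0, 0),
    window_multiplier: float = 1.0,
    frozen: Sequence[tuple[int, int]] = (),
) -> list[str]:
    """Codon-aware substitution: a nucleotide change is proposed and accepted
    at the class rate (synonymous vs nonsynonymous), with the nonsynonymous
    rate multiplied inside the window. Frozen intervals (primer motifs) are
    never mutated; stops are never created."""
    out = list(codons)
    for i in range(len(out)):
        if any(s <= i < e for s, e in frozen):
            continue
        ns_rate = nonsyn_rate
        if window[0] <= i < window[1]:
            ns_rate = min(nonsyn_rate * window_multiplier, 1.0)
        if rng.random() < syn_rate:
            alts = _synonymous_alternatives(out[i])
            if alts:
                out[i] = alts[rng.integers(0, len(alts))]
        if rng.random() < ns_rate:
            alts = _nonsyn_neighbors(out[i])
            if alts:
                out[i] = alts[rng.integers(0, len(alts))]
    return out


# ---------------------------------------------------------------------------
# Panel and community generation
# ---------------------------------------------------------------------------

def _planted_pair(cfg: SimulationConfig, ancestor: list[str]) -> PrimerPair:
    """Primer pair built directly from the frozen motifs by back-translation."""
    fs, fe = cfg.fwd_motif_codons
    rs, re_ = cfg.rev_motif_codons
    fwd_motif = ConservedMotif(
        fs, tuple(frozenset([_AA_OF[c]]) for c in ancestor[fs:fe])
    )
    rev_motif = ConservedMotif(
        rs, tuple(frozenset([_AA_OF[c]]) for c in ancestor[rs:re_])
    )
    fseq = back_translate(fwd_motif)
    rseq = reverse_complement(back_translate(rev_motif))
    fwd = DegeneratePrimer(fseq, degeneracy_of(fseq), "forward", fs, fe - fs)
    rev = DegeneratePrimer(rseq, degeneracy_of(rseq), "reverse", rs, re_ - rs)
    span = 3 * (rs - fe)
    return PrimerPair(fwd, rev, (fe, rs), (span, span))


def generate_community(cfg: SimulationConfig) -> CommunityModel:
    """Build the reference panel and the layered community strains.

    The panel mirrors the design setting: three HcRNAV references (two UA,
    one CY) and five related references, all descended from one ancestral
    gene. Community strains are evolved from the panel references at the
    within-group rates; background strains are unrelated random genes that
    carry the same primer motifs (so they amplify but classify nowhere).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.gene_len_codons
    ancestor = _random_orf(n, rng)
    fs, fe = cfg.fwd_motif_codons
    rs, re_ = cfg.rev_motif_codons
    # low-degeneracy motif residues keep the planted primers practical
    for lo, hi in (cfg.fwd_motif_codons, cfg.rev_motif_codons):
        for i in range(lo, hi):
            aa = _MOTIF_AA[rng.integers(0, len(_MOTIF_AA))]
            choices = [c for c in _CODONS if _AA_OF[c] == aa]
            ancestor[i] = choices[rng.integers(0, len(choices))]
    frozen = (cfg.fwd_motif_codons, cfg.rev_motif_codons)
    window = cfg.hypervariable_codons

    def type_evolve(base: Sequence[str]) -> list[str]:
        return evolve(
            base, rng, cfg.type_syn_rate, cfg.type_nonsyn_outside,
            window=window,
            window_multiplier=cfg.type_nonsyn_window / max(cfg.type_nonsyn_outside, 1e-12),
            frozen=frozen,
        )

    def within_evolve(base: Sequence[str]) -> list[str]:
        return evolve(
            base, rng, cfg.syn_rate, cfg.nonsyn_rate,
            window=window, window_multiplier=cfg.nonsyn_multiplier,
            frozen=frozen,
        )

    ua_anc = type_evolve(ancestor)
    cy_anc = type_evolve(ancestor)
    related_anc = evolve(
        ancestor, rng, cfg.related_syn_rate, cfg.related_nonsyn_rate,
        frozen=frozen,
    )

    panel_entries: list[PanelEntry] = []
    panel_nt: dict[str, str] = {}

    def add_ref(name: str, codons: list[str], group: str, htype: str, acc: str):
        nt = "".join(codons)
        aa = translate(nt)
        panel_entries.append(
            PanelEntry(SequenceRecord(name, aa, "aa"), group, htype, acc)
        )
        panel_nt[name] = nt
        return codons

    ref_genes: dict[str, list[str]] = {}
    ref_genes["HcRNAV_UA1"] = add_ref(
        "HcRNAV_UA1", within_evolve(ua_anc), "HcRNAV", "UA", "SYN_HC_UA1")
    ref_genes["HcRNAV_UA2"] = add_ref(
        "HcRNAV_UA2", within_evolve(ua_anc), "HcRNAV", "UA", "SYN_HC_UA2")
    ref_genes["HcRNAV_CY1"] = add_ref(
        "HcRNAV_CY1", within_evolve(cy_anc), "HcRNAV", "CY", "SYN_HC_CY1")
    for k in range(5):
        name = f"Alv_like_{k + 1}"
        ref_genes[name] = add_ref(
            name, within_evolve(related_anc), "Alvernaviridae_like", "unknown",
            f"SYN_REL{k + 1}",
        )

    panel = ReferencePanel(tuple(panel_entries))
    pair = _planted_pair(cfg, ancestor)

    # community strains
    community: dict[str, str] = {}
    group_of: dict[str, str] = {}
    type_of: dict[str, str] = {}
    for ref_name, gene in ref_genes.items():
        entry = next(e for e in panel.entries if e.record.id == ref_name)
        per = (cfg.strains_per_hc_ref if entry.group == "HcRNAV"
               else cfg.strains_per_related_ref)
        for k in range(per):
            sid = f"str_{ref_name}_{k + 1}"
            community[sid] = "".join(within_evolve(gene))
            group_of[sid] = "HcRNAV" if entry.group == "HcRNAV" else "related"
            type_of[sid] = entry.host_range_type
    for k in range(cfg.n_background_strains):
        sid = f"str_bg_{k + 1}"
        gene = _random_orf(n, rng)
        for (lo, hi) in frozen:
            gene[lo:hi] = ancestor[lo:hi]  # motifs planted so it amplifies
        community[sid] = "".join(gene)
        group_of[sid] = "background"
        type_of[sid] = "unknown"

    strain_insert_aa = {}
    for sid, nt in community.items():
        amp = amplify(
            SequenceRecord(sid, nt, "nt"), pair, max_mismatch=cfg.max_mismatch
        )
        if len(amp) != 1:
            raise SequenceError(f"strain {sid} yielded {len(amp)} amplicons")
        strain_insert_aa[sid] = translate(amp[0].insert_seq)

    truth = GroundTruth(
        strain_group=group_of,
        strain_type=type_of,
        layer_abundances={},
        window_insert_aa=(window[0] - fe, window[1] - fe),
        strain_insert_aa=strain_insert_aa,
    )
    return CommunityModel(
        panel, panel_nt, SequenceRecord("ancestor", "".join(ancestor), "nt"),
        community, truth, pair, cfg,
    )


def generate_reference_panel(
    cfg: SimulationConfig,
) -> tuple[ReferencePanel, SequenceRecord]:
    """Panel plus the ancestral gene (convenience wrapper)."""
    model = generate_community(cfg)
    return model.panel, model.ancestor_nt


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_OTHER = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def simulate_reads(
    model: CommunityModel, cfg: SimulationConfig | None = None
) -> tuple[list[tuple[SequenceRecord, str]], GroundTruth]:
    """Draw per-layer amplicon reads from the community.

    Strain weights within a group are lognormal; per layer the groups are
    mixed at the planted proportions and ``reads_per_layer`` reads are drawn
    multinomially. Each read is the strain's amplicon insert with i.i.d.
    per-base substitution errors at ``error_rate``. Inserts are shorter than
    the read length, so one single-end read covers the whole insert.
    """
    cfg = cfg or model.cfg
    rng = np.random.default_rng([cfg.seed, 1])
    strains = sorted(model.community_nt)
    inserts = {}
    for sid in strains:
        amp = amplify(
            SequenceRecord(sid, model.community_nt[sid], "nt"),
            model.primer_pair, max_mismatch=cfg.max_mismatch,
        )
        insert = amp[0].insert_seq
        if len(insert) > cfg.read_length:
            raise SequenceError(
                f"insert of {sid} ({len(insert)} nt) exceeds read length"
            )
        inserts[sid] = insert

    by_group: dict[str, list[str]] = defaultdict(list)
    for sid in strains:
        by_group[model.truth.strain_group[sid]].append(sid)
    weights = {sid: rng.lognormal(0.0, cfg.lognormal_sigma) for sid in strains}

    reads: list[tuple[SequenceRecord, str]] = []
    truth = model.truth
    truth.layer_abundances = {}
    truth.per_read_source = {}
    group_names = ("HcRNAV", "related", "background")
    for li, layer in enumerate(cfg.layer_labels):
        probs = np.zeros(len(strains))
        for g, frac in zip(group_names, cfg.layer_proportions[li]):
            members = by_group.get(g, [])
            if not members:
                continue
            w = np.array([weights[s] for s in members])
            w = w / w.sum() * frac
            for s, p in zip(members, w):
                probs[strains.index(s)] = p
        probs = probs / probs.sum()
        truth.layer_abundances[layer] = dict(zip(strains, probs))
        counts = rng.multinomial(cfg.reads_per_layer, probs)
        r_idx = 0
        for sid, n_reads in zip(strains, counts):
            if n_reads == 0:
                continue
            tpl = inserts[sid]
            L = len(tpl)
            n_err = rng.binomial(n_reads, 1.0 - (1.0 - cfg.error_rate) ** L)
            for _ in range(n_reads - n_err):
                rid = f"{layer}_r{r_idx:06d}"
                r_idx += 1
                reads.append((SequenceRecord(rid, tpl, "nt"), layer))
                truth.per_read_source[rid] = sid
            for _ in range(n_err):
                # at least one error; each base independently flipped
                seq = list(tpl)
                n_sub = max(1, rng.binomial(L, cfg.error_rate))
                for pos in rng.choice(L, size=n_sub, replace=False):
                    alts = _OTHER[seq[pos]]
                    seq[pos] = alts[rng.integers(0, 3)]
                rid = f"{layer}_r{r_idx:06d}"
                r_idx += 1
                reads.append((SequenceRecord(rid, "".join(seq), "nt"), layer))
                truth.per_read_source[rid] = sid
    if not reads:
        raise SequenceError("zero reads simulated")
    return reads, truth


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

def _interval_jaccard(
    detected: Sequence[tuple[int, int]], planted: tuple[int, int]
) -> float:
    det = set()
    for s, e in detected:
        det |= set(range(s, e))
    plant = set(range(*planted))
    if not det and not plant:
        return 1.0
    return len(det & plant) / len(det | plant)


def evaluate_recovery(result, truth: GroundTruth) -> dict:
    """Score pipeline outputs against the planted ground truth.

    ``result`` is a pipeline result object exposing ``composition``,
    ``classifications``, ``aa_table``, ``nt_table``, ``host_types`` and
    ``regions`` (see the pipeline module). Returns a report with the
    per-layer composition L1 error, region-detection Jaccard against the
    planted window, the host-type confusion matrix, and the amino-acid
    haplotype recovery counts.
    """
    group_map = {
        "HcRNAV": "HcRNAV_derived",
        "related": "Alvernaviridae_like",
        "background": "Others",
    }
    report: dict = {}

    # composition: planted per-layer group shares vs measured
    l1 = {}
    for layer, ab in truth.layer_abundances.items():
        planted = Counter()
        for sid, frac in ab.items():
            planted[group_map[truth.strain_group[sid]]] += frac
        measured = result.composition[layer]
        l1[layer] = float(sum(
            abs(measured.get(g, 0.0) - planted.get(g, 0.0))
            for g in set(measured) | set(planted)
        ))
    report["composition_l1"] = l1
    report["composition_l1_max"] = max(l1.values())

    # regions vs planted window
    report["region_jaccard"] = _interval_jaccard(
        result.regions.variable_intervals(), truth.window_insert_aa
    )

    # host typing: truth type of an ASV = type of its reads' majority strain
    asv_reads = _asv_read_sources(result, truth)
    confusion: dict[tuple[str, str], int] = Counter()
    for asv_id, assigned in result.host_types.items():
        sources = asv_reads.get(asv_id)
        if not sources:
            continue
        true_type = truth.strain_type[sources.most_common(1)[0][0]]
        confusion[(true_type, assigned)] += 1
    report["type_confusion"] = {
        f"{t}->{a}": n for (t, a), n in sorted(confusion.items())
    }
    typed = [(t, a) for (t, a), n in confusion.items() for _ in range(n)
             if t in ("UA", "CY")]
    report["type_accuracy"] = (
        100.0 * sum(1 for t, a in typed if t == a) / len(typed) if typed else None
    )

    # collapse correctness: planted protein haplotypes with >= 2 reads
    planted_haps = set()
    hap_counts: Counter = Counter()
    for rid, sid in truth.per_read_source.items():
        hap_counts[truth.strain_insert_aa[sid]] += 1
    planted_haps = {h for h, n in hap_counts.items() if n >= 2}
    recovered = {r.sequence for r in result.aa_table.rows}
    report["n_planted_haplotypes"] = len(planted_haps)
    report["n_recovered_aa_asvs"] = len(recovered)
    report["haplotypes_exact_match"] = recovered == planted_haps
    return report


def _asv_read_sources(result, truth: GroundTruth) -> dict[str, Counter]:
    """Map each aa ASV to the Counter of source strains of its reads,
    matching reads to ASVs by translated sequence."""
    hap_sources: dict[str, Counter] = defaultdict(Counter)
    insert_of = truth.strain_insert_aa
    for rid, sid in truth.per_read_source.items():
        hap_sources[insert_of[sid]][sid] += 1
    out: dict[str, Counter] = {}
    for row in result.aa_table.rows:
        if row.sequence in hap_sources:
            out[row.asv_id] = hap_sources[row.sequence]
    return out
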