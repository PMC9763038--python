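"""End-to-end pipeline: reads -> ASVs -> classification -> composition ->
phylogeny -> host typing -> region calling, with a run manifest that
reconciles record counts across stages.

All thresholds that drive the analysis live in :class:`PipelineConfig`:
the >85% protein-identity rule for HcRNAV-derived ASVs, the optional >92%
nucleotide rule, the inclusive 0.02% abundance floor, and the 1,000-replicate
bootstrap. Randomness (bootstrap resampling) flows from the single config
seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import yaml

from . import asv as asvmod
from .asv import ASVTable, abundance_filter, collapse_by_translation, dereplicate, remove_singletons
from .classify import (
    ClassificationResult,
    LayerComposition,
    PanelEntry,
    ReferencePanel,
    classify_table,
    classify_table_nt,
    compose_layers,
    composition_to_frame,
    results_to_frame,
)
from .insilico_pcr import amplify
from .phylo import Tree, assign_host_range_type, bootstrap_support, masked_newick, neighbor_joining, p_distance_matrix
from .primer_design import PrimerPair
from .regions import (
    PolymorphismProfile,
    RegionAnnotation,
    column_polymorphism,
    profile_to_frame,
    regions_to_frame,
    segment_regions,
)
from .seqcore import SequenceError, SequenceRecord, translate

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    hc_identity: float = 85.0  # strict >
    nt_identity: float = 92.0  # strict >, optional nucleotide-level rule
    related_floor: float = 40.0
    abundance_floor: float = 0.0002  # inclusive >=
    bootstrap_n: int = 1000
    max_mismatch: int = 0
    merge_gap: int = 2
    min_type_identity: float = 85.0
    frame: int = 0
    singletons_per_layer: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abundance_floor <= 1.0:
            raise SequenceError("abundance_floor outside [0, 1]")
        if not (0 <= self.hc_identity <= 100 and 0 <= self.nt_identity <= 100):
            raise SequenceError("identity thresholds outside [0, 100]")
        if self.bootstrap_n < 1:
            raise SequenceError("bootstrap_n must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class PipelineResult:
    nt_table: ASVTable
    nt_table_nosingle: ASVTable
    aa_table: ASVTable
    aa_filtered: ASVTable
    collapse_map: dict
    classifications: list[ClassificationResult]
    nt_classifications: list[ClassificationResult]
    composition: LayerComposition
    tree: Tree | None
    host_types: dict[str, str]
    profile: PolymorphismProfile | None
    regions: RegionAnnotation | None
    manifest: dict


def panel_insert_translations(
    panel: ReferencePanel,
    panel_nt: dict[str, str],
    pair: PrimerPair,
    max_mismatch: int = 0,
) -> dict[str, str]:
    """Translate each panel gene's amplicon insert, putting the references
    into the same coordinates as the ASVs."""
    out = {}
    for e in panel.entries:
        nt = panel_nt.get(e.record.id)
        if nt is None:
            continue
        amps = amplify(
            SequenceRecord(e.record.id, nt, "nt"), pair, max_mismatch=max_mismatch
        )
        if len(amps) == 1:
            out[e.record.id] = translate(amps[0].insert_seq)
    return out


def run_pipeline(
    reads: Sequence[tuple[SequenceRecord, str]],
    panel: ReferencePanel,
    cfg: PipelineConfig,
    panel_nt: dict[str, str] | None = None,
    primer_pair: PrimerPair | None = None,
) -> PipelineResult:
    """Execute dereplicate -> remove singletons -> collapse -> abundance
    filter -> classify -> compose -> tree -> host typing -> region calling.

    When the panel's nucleotide genes and the primer pair are supplied, the
    panel references are placed into amplicon-insert coordinates and joined
    to the phylogeny; otherwise the tree is built over the ASVs alone.
    """
    manifest: dict = {"config": asdict(cfg), "counts": {}}
    c = manifest["counts"]

    nt_table = dereplicate(reads)
    c["reads"] = len(reads)
    c["nt_asvs"] = len(nt_table)

    nt_nosingle = remove_singletons(nt_table, per_layer=cfg.singletons_per_layer)
    c["nt_asvs_after_singletons"] = len(nt_nosingle)
    c["reads_removed_as_singletons"] = nt_table.grand_total - nt_nosingle.grand_total

    aa_table, cmap = collapse_by_translation(nt_nosingle, frame=cfg.frame)
    c["aa_asvs"] = len(aa_table)
    c["reads_dropped_untranslatable"] = nt_nosingle.grand_total - aa_table.grand_total

    aa_filtered = abundance_filter(aa_table, cfg.abundance_floor)
    c["aa_asvs_above_floor"] = len(aa_filtered)

    # When the panel genes and primers are known, re-express the panel in
    # amplicon-insert coordinates: identity is then measured over the region
    # the amplicon actually covers (the local-alignment surrogate), not
    # diluted by the unamplified remainder of the protein.
    ref_inserts: dict[str, str] = {}
    if panel_nt and primer_pair is not None:
        ref_inserts = panel_insert_translations(
            panel, panel_nt, primer_pair, cfg.max_mismatch
        )
    if ref_inserts:
        classify_panel = ReferencePanel(
            tuple(
                PanelEntry(
                    SequenceRecord(e.record.id, ref_inserts[e.record.id], "aa"),
                    e.group, e.host_range_type, e.accession,
                )
                for e in panel.entries
                if e.record.id in ref_inserts
            )
        )
    else:
        classify_panel = panel

    results = classify_table(
        aa_table, classify_panel, cfg.hc_identity, cfg.related_floor
    )
    nt_results = []
    if panel_nt:
        hc_nt = [
            SequenceRecord(e.record.id, panel_nt[e.record.id], "nt")
            for e in panel.entries
            if e.group == "HcRNAV" and e.record.id in panel_nt
        ]
        if hc_nt and primer_pair is not None:
            hc_inserts = [
                SequenceRecord(
                    r.id,
                    amplify(r, primer_pair, max_mismatch=cfg.max_mismatch)[0].insert_seq,
                    "nt",
                )
                for r in hc_nt
            ]
            nt_results = classify_table_nt(nt_nosingle, hc_inserts, cfg.nt_identity)
    composition = compose_layers(aa_table, results, cfg.abundance_floor)
    labels = {r.asv_id: r.group_label for r in results}
    c["hcrnav_derived_aa_asvs"] = sum(
        1 for r in aa_filtered.rows if labels[r.asv_id] == "HcRNAV_derived"
    )

    # --- phylogeny of ASVs above the abundance floor, with panel references
    tree = None
    aln = [
        SequenceRecord(r.asv_id, r.sequence, "aa") for r in aa_filtered.rows
    ]
    lengths = {len(r) for r in aln}
    if ref_inserts and len(lengths) == 1:
        L = lengths.pop()
        aln += [
            SequenceRecord(rid, seq, "aa")
            for rid, seq in sorted(ref_inserts.items())
            if len(seq) == L
        ]
        lengths = {L}
    if len(aln) >= 3 and len(lengths) == 1:
        tree = bootstrap_support(aln, cfg.bootstrap_n, seed=cfg.seed)

    # --- UA/CY typing of HcRNAV-derived ASVs (references + those ASVs only)
    host_types: dict[str, str] = {}
    hc_rows = [r for r in aa_filtered.rows if labels[r.asv_id] == "HcRNAV_derived"]
    hc_ref_ids = {e.record.id for e in panel.entries if e.group == "HcRNAV"}
    typing_aln = [SequenceRecord(r.asv_id, r.sequence, "aa") for r in hc_rows]
    typing_aln += [
        SequenceRecord(rid, seq, "aa")
        for rid, seq in sorted(ref_inserts.items())
        if rid in hc_ref_ids and typing_aln and len(seq) == len(typing_aln[0])
    ]
    if len(typing_aln) >= 3 and hc_rows:
        typing_tree = neighbor_joining(p_distance_matrix(typing_aln))
        for r in hc_rows:
            host_types[r.asv_id] = assign_host_range_type(
                SequenceRecord(r.asv_id, r.sequence, "aa"),
                classify_panel, typing_tree, cfg.min_type_identity,
            )
    else:
        host_types = {r.asv_id: "unknown" for r in hc_rows}

    # --- conserved/variable regions over the HcRNAV-derived ASVs
    profile = annotation = None
    if len(hc_rows) >= 2 and len({len(r.sequence) for r in hc_rows}) == 1:
        profile = column_polymorphism(
            [SequenceRecord(r.asv_id, r.sequence, "aa") for r in hc_rows]
        )
        annotation = segment_regions(profile, cfg.merge_gap)

    # count reconciliation: reads = kept + logged removals
    c["reads_in_aa_table"] = aa_table.grand_total
    assert (
        c["reads"]
        == c["reads_in_aa_table"]
        + c["reads_removed_as_singletons"]
        + c["reads_dropped_untranslatable"]
    )
    return PipelineResult(
        nt_table, nt_nosingle, aa_table, aa_filtered, cmap, results,
        nt_results, composition, tree, host_types, profile, annotation,
        manifest,
    )


def write_outputs(result: PipelineResult, outdir: str) -> None:
    """Write every stage artifact (TSV/Newick/JSON) under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    asvmod.write_table(result.nt_table, os.path.join(outdir, "asv_nt.tsv"))
    asvmod.write_table(result.aa_table, os.path.join(outdir, "asv_aa.tsv"))
    asvmod.write_table(result.aa_filtered, os.path.join(outdir, "asv_aa_filtered.tsv"))
    import pandas as pd

    pd.DataFrame(
        dict(aa_asv_id=k, members=",".join(v))
        for k, v in result.collapse_map.items()
    ).to_csv(os.path.join(outdir, "collapse_map.tsv"), sep="\t", index=False)
    results_to_frame(result.classifications).to_csv(
        os.path.join(outdir, "classification_aa.tsv"), sep="\t", index=False
    )
    if result.nt_classifications:
        results_to_frame(result.nt_classifications).to_csv(
            os.path.join(outdir, "classification_nt.tsv"), sep="\t", index=False
        )
    composition_to_frame(result.composition).to_csv(
        os.path.join(outdir, "composition.tsv"), sep="\t"
    )
    if result.tree is not None:
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(masked_newick(result.tree) + "\n")
    if result.host_types:
        pd.DataFrame(
            dict(asv_id=k, host_range_type=v) for k, v in result.host_types.items()
        ).to_csv(os.path.join(outdir, "host_types.tsv"), sep="\t", index=False)
    if result.profile is not None:
        profile_to_frame(result.profile).to_csv(
            os.path.join(outdir, "polymorphism_profile.tsv"), sep="\t", index=False
        )
    if result.regions is not None:
        regions_to_frame(result.regions).to_csv(
            os.path.join(outdir, "regions.tsv"), sep="\t", index=False
        )
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
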