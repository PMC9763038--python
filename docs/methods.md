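# Methods

This note documents the models and procedures implemented in `capsidpcr`,
the defaults they run with, and what the synthetic validation does and does
not demonstrate.

## Degenerate primer design

A conserved motif is a gap-free window of alignment columns in which every
column holds at most `max_variants` distinct residues (default 1, window
length 7 aa). Back-translation takes, per column, the union of all standard
codons of all residues present, and encodes each codon position with the
minimal IUPAC code covering the observed base union. The encoding is an
exact cover of the base union per position but may over-cover at the codon
level (Leu → `YTN` expands to 8 codons, 6 of which encode Leu); this
over-coverage is one-sided — every true codon is always matched — and is
the standard behaviour of fully degenerate primers. Degeneracy is the
per-position product of base-set sizes, capped at 512 per primer by
default. Pairs must flank the designated hypervariable interval and satisfy
an insert-length range (3× the per-row gap-free residue count between the
motifs, taken as a min–max range). Pairs are ranked by pair degeneracy,
then smaller insert, then leftmost forward motif. Melting temperature is
reported via the Wallace rule, 2(A+T)+4(G+C) averaged over expansions, and
is never a constraint: primer thermodynamics, dimers and CODHOP-style
clamps are out of scope.

## In-silico PCR

A primer binds wherever every template base falls inside the primer's
per-position IUPAC base set, up to `max_mismatch` mismatches (default 0 for
design validation, 1 for community simulation, since environmental
templates diverge from the design panel). Both template strands are
scanned, and both primer orientations are paired, so amplification is
strand-symmetric; all products in the configured insert-length range are
reported with primer regions trimmed, on the forward-primer strand. No
PCR-efficiency, bias or chimera model is included.

## ASV condensation

Reads are exactly dereplicated into nucleotide ASVs with per-layer counts.
This is a deliberate surrogate for error-model denoising: with error-free
or low-error synthetic reads every distinct sequence is its own variant and
dereplication is faithful; with realistic error rates it intentionally
leaves error variants in the table (see *Limitations*). A singleton is an
ASV with total count 1 summed over layers (layers are pooled, as the
amplicon analysis pools them; per-layer singleton removal is available as
an option). The reading frame of an insert is frame 0 by construction —
the forward primer is built in codon phase — so synonymous collapse groups
nucleotide ASVs by identical frame-0 translation; rows with internal stops
are dropped with a logged warning. Amino-acid ASVs are numbered by
descending abundance (`ASV_001`, …) with an `s` suffix when more than one
nucleotide variant merged. The abundance floor keeps ASVs whose share of
all reads is ≥ 0.02 % (inclusive boundary).

## Classification and composition

Remote-database homology search is replaced by exhaustive pairwise percent
identity against the packaged reference panel, making classification a
pure function of the shipped references. Identity between equal-length
sequences is ungapped column identity; otherwise a global alignment
(match +1, mismatch 0, linear gap −1 — scores steer the path only) defines
identity as matches over alignment columns. When the panel's genes and the
primer pair are available, panel entries are first re-expressed in
amplicon-insert coordinates by amplifying each gene in silico, so identity
is measured over the region the amplicon covers — the local-alignment
surrogate — rather than diluted by unamplified sequence. Thresholds:
HcRNAV-derived strictly above 85 % to any HcRNAV entry; related at ≥ 40 %
(the relatedness floor separating panel-related sequences from noise;
configurable); optional nucleotide rule at > 92 %. Hit-count reproduction
against live databases is explicitly not a goal — those numbers depend on
database snapshots. Per-layer composition normalises read counts per layer
over {HcRNAV-derived, *Alvernaviridae*-like, Others}, where Others pools
unassigned ASVs and ASVs below the floor.

## Phylogeny, bootstrap, host typing

Distances are uncorrected amino-acid p-distances (gaps skipped pairwise);
the amplicons are short and closely related, where p-distance is the
standard choice for NJ figures; a Poisson correction (−ln(1−p)) is
available behind a flag. Neighbor joining follows the Saitou–Nei
agglomeration, Q(i,j) = (n−2)d(i,j) − Σₖd(i,k) − Σₖd(j,k), with ties broken
by the lexicographically smallest pair of cluster representatives (each
cluster represented by its smallest leaf label), so trees are reproducible;
negative branch-length estimates are clamped to zero with the deficit
logged. Bootstrap resamples alignment columns with replacement; support
for each internal bipartition of the full-data tree is the percentage of
replicate trees containing it; reports mask supports ≤ 50 but all values
are stored. An HcRNAV-derived ASV is typed UA (or CY) when its nearest
typed reference by identity exceeds the identity floor (85 %) *and* the ASV
sits in a tree clade whose panel references are exclusively of that type;
otherwise it is `unknown`. No ML/Bayesian inference, model selection or
outgroup rooting is provided.

Because the simulator introduces substitutions only, ASV inserts and panel
insert translations share coordinates and are equal length, so no multiple
sequence alignment step is needed anywhere in the pipeline; on real data
with indels an external aligner would have to produce the input alignment.

## Region calling

A column is polymorphic when it holds ≥ 2 distinct non-gap residues (a
deletion is not counted as a residue polymorphism; gap-inclusive counting
is available behind a flag). Maximal runs of polymorphic columns, merged
across ≤ `merge_gap` monomorphic columns (default 2), are candidate
variable regions; a candidate must contain at least two polymorphic columns
— a conserved region may contain a single isolated polymorphism, a variable
region needs two or more (`min_polymorphisms=1` restores the strict
column-run reading). Labels tile the alignment. Intervals are emitted as
0-based half-open BED-like rows suitable for external secondary-structure
or 3D-structure annotation; no structure prediction is performed here.

## Synthetic community

The generator emulates the survey design: one ancestral MCP-like ORF (130
codons) carrying two frozen 7-residue primer motifs (drawn from residues
with ≤ 2 codons, keeping primer degeneracy practical) flanking a planted
hypervariable window of 24 codons; three HcRNAV references (two UA, one
CY) and five related references descend from it, matching an
eight-sequence design panel; community strains evolve from the references;
three background strains are unrelated random ORFs that carry the same
motifs (they amplify but classify nowhere, exercising the "Others" path).

Mutation is codon-aware: per codon, a synonymous replacement is applied
with probability `syn_rate` (0.05) and a nonsynonymous single-nucleotide
neighbour (never a stop) with probability `nonsyn_rate` (0.003), the
latter multiplied by `nonsyn_multiplier` (33) inside the window — about
10 % within-window amino-acid divergence per strain draw. Group-level
divergences are larger: UA/CY type ancestors differ mainly in the window
(nonsynonymous 0.25 per window codon), the related-group ancestor diverges
heavily everywhere (0.4 nonsynonymous per codon, ≈ 60–70 % amplicon
identity — above the 40 % relatedness floor, below the 85 % HcRNAV rule).

Reads: five layers (labelled 0–3 cm … 12–15 cm) with planted
(HcRNAV, related, background) proportions — related-dominant shallow
layers, HcRNAV-dominant deep layers, a qualitative demo profile — strain
weights lognormal (σ = 1) within group, 10⁵ reads per layer by default
drawn multinomially, each read the strain's amplicon insert (228 nt,
shorter than the 300-nt read length, so one single-end read covers the
whole insert and no merging is modelled) with i.i.d. per-base substitution
errors at 10⁻³. No indel errors, chimeras, PCR bias or sediment
mixing/deposition model. All randomness derives from the config seed via
`default_rng([seed, stage])`, giving byte-identical outputs per seed.

**What passing tests show, and what they do not.** Recovery tests
demonstrate that the pipeline's logic is correct under its own model:
planted per-layer proportions are recovered within sampling error when
reads are error-free; the planted window is recovered (Jaccard ≥ 0.8) and
UA/CY types are fully recovered even at the default error rate. They do
not demonstrate robustness to denoising-scale error structure: with
per-base errors and exact dereplication, recurrent error variants form
low-abundance ASVs that the ≥ 0.02 % floor sends to "Others", inflating
that bucket at high depth — on real data this role is played by the
denoiser, which is out of scope here. Nor do they probe indel alignment,
primer-site divergence beyond one mismatch, or amplification bias.

## Numerical and procedural choices

- Coordinates are 0-based half-open throughout; strand is `'+'`/`'-'`.
- Table ordering: ASVs by descending total count, ties by sequence; NJ ties
  by representative label pair; classification ties by accession — every
  output is deterministic.
- Identity at exactly 85.0 % is *not* HcRNAV-derived (strict inequality);
  abundance at exactly 0.02 % *is* retained (inclusive floor).
- Problem sizes in the shipped validation: 10⁵ reads × 5 layers for
  recovery runs, 200 random additive matrices (4–8 leaves) for NJ
  exactness, 500 random templates (≤ 2 kb) for the PCR oracle, bootstrap
  1,000 replicates on an 8-leaf alignment for the support checks.
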