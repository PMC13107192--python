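# Methods

## Scope and data model

`varcontext` annotates curated missense variants with three layers of
context: nucleotide motifs in a window around the variant's coding-sequence
position, amino-acid combinations among the flanking residues, and the
structural neighbourhood of the variant site on a predicted model. The unit
of analysis is a `VariantRecord` — gene, 1-based protein position,
reference and alternate residue, optional 1-based CDS nucleotide position,
carrier/tumour-sample count, source database (`allofus` or `cosmic`) and
class (`disease`, `benign`, `unknown`). Identity is the (gene, position,
alternate residue, source) tuple: the same substitution reported by both
source databases is deliberately kept as two records, so per-source tallies
remain separable; overlap can be recovered by grouping on the first three
fields.

Variants are validated against translated coding sequences before any
analysis: positions must lie inside the protein, the stated reference
residue must match the translation, and a recorded CDS position must fall
inside the codon of the protein position. Failing variants are excluded
with a per-variant reason rather than corrected — a curation mismatch is
evidence of an annotation problem the user should see, not silently repair.
Only substitutions between the 20 standard residues qualify; stop-gain and
stop-loss rows are rejected at parse time.

Two curation filters mirror the upstream study design. The support filter
keeps variants observed in at least `min_carriers` individuals/samples
(default 20, the privacy floor of the population cohort, applied to both
databases for symmetry); it is idempotent and monotone in the threshold.
The class partition splits the set into disease-associated and benign
variants, dropping (and counting) the unknowns. Class labels can be
overwritten from an offline classification TSV keyed by (gene, position,
alternate residue); the package performs no live archive queries, so runs
are hermetic and reproducible.

## Windows and anchors

The nucleotide window is ±`flank_nt` bp (default 20) around an anchor base,
1-based inclusive, clamped to the CDS and never padded, so interior windows
are 2·flank+1 = 41 nt and edge windows strictly shorter. The anchor is the
recorded CDS position when present; variants curated from protein notation
lack one, and then the middle base of the codon is used — every candidate
single-nucleotide change producing the substitution lies within 1 nt of it,
so motif content in a 41-nt window is nearly invariant to the choice. An
`anchor_mode="union"` switch instead takes the union of the three per-base
windows (the whole codon ± flank). By default the *reference* sequence is
scanned; `use_mutant=True` first substitutes a minimally-edited codon
encoding the alternate residue (ties broken lexicographically), which is
the natural nucleotide-level reading of a variant known only by its protein
effect.

The peptide context is the ±`flank_aa` residues (default 3) around the
site, truncated at the protein termini, centre excluded.

## Motif scanning

Recognition sequences are IUPAC strings; matching compiles the pattern to a
character-class regular expression inside a lookahead so overlapping
occurrences are all reported, and is verified in the tests against
brute-force expansion of the pattern into concrete sequences followed by
exact substring search. Scanning is double-stranded by default
(restriction recognition is double-stranded by nature and PAMs are
routinely searched on both strands); minus-strand matches are found by
scanning the reverse complement and mapped back to plus-strand window
coordinates. A palindromic pattern matching the same footprint on both
strands is collapsed to one plus-strand hit, so a double-stranded
recognition event is counted once. A `--forward-only` flag restores
single-strand behaviour.

A motif is associated with a variant only when a match lies *fully inside*
the window — the window width is chosen to capture whole sites, so
partially overlapping matches are ignored — and association is
presence/absence per variant: a motif occurring twice in one window counts
that variant once in the class partition, matching Venn/UpSet semantics,
while raw hit multiplicity is still exported in `hits.tsv`. Motifs with at
least one associated variant are partitioned into exclusive-disease,
exclusive-benign and shared sets.

The motif table is a TSV (`name`, `recognition`, `kind`), not a hard-coded
enzyme library: enzyme catalogues are release-dependent, so the bundled
default carries the eleven named restriction enzymes of interest (nine
GATC isoschizomers plus FaiI YATR and MspJI CNNR, recognition cores only —
cleavage-offset modelling is out of scope) together with common non-GATC
enzymes for background, and fourteen Cas9 PAMs (SpCas9 NGG, SaCas9 NNGRRT,
NmCas9 NNNNGATT, St1Cas9 NNAGAAW, St3Cas9 NGGNG, CjCas9 NNNNACA, FnCas9 YG,
TdCas9 NAAAW, SpCas9-NG NG, SpRY NRN, and the SpCas9-scaffold
high-fidelity variants xCas9 NG, HiFi Cas9 (HF1)/eSpCas9 (1.1)/HypaCas9
NGG). Any REBASE-style table can be supplied instead.

## Flank combinations

Combinations are *unordered multisets* of k ∈ {1,2,3} residues drawn from
the six flanking positions, respecting multiplicity (Leu+Leu requires
leucine at two distinct positions); adjacency is not required, though an
`adjacent_only` dipeptide mode exists for k = 2. The mutated centre residue
is excluded, and reference flank residues are used (the substitution does
not touch them). Counting is per-variant presence: a combination realisable
from several index subsets of one variant's flanks counts once, so a single
repeat-rich flank cannot dominate a class table. Terminal variants
contribute their available residues. Tables report raw counts and
count/class-size frequencies, plus the exclusivity partition over keys with
positive count. No significance testing is attached — the tables are
descriptive, and class-size normalisation is reported alongside raw counts
so both readings are available.

## Structural context

The package makes a qualitative structural reading computable with three
standard, declared operationalisations; none is fitted to data.

**Secondary structure.** Backbone hydrogen bonds are detected with the
Kabsch–Sander electrostatic criterion (E = 0.084·332·(1/r_ON + 1/r_CH −
1/r_OH − 1/r_CN) kcal/mol, bond when E < −0.5; the amide hydrogen is placed
1 Å from N along the previous residue's O→C direction, so the first residue
of a chain or segment cannot donate). Three states are assigned: a residue
is **H** when it is the central residue of an i→i+4 hydrogen-bonded turn
belonging to a run of at least two consecutive turns (an isolated turn
marks nothing); **E** when it belongs to a Kabsch–Sander bridge (parallel
or antiparallel, |i−j| ≥ 3) that extends into a ladder of at least two
consecutive bridges; otherwise **C**. Helix takes precedence where both
fire. On an ideal 12-residue α-helix (φ −57°, ψ −47°) turns exist at
i = 1..8 and the rule yields H exactly on residues 3–10; on an ideal
antiparallel strand pair the full ladder yields E on all but the
outermost residues. Full 8-state assignment, π/3₁₀ distinctions and
bulge handling are intentionally out of scope.

**Burial.** Shrake–Rupley accessible surface area with probe 1.4 Å and 960
deterministic golden-spiral points per atom (isolated-sphere error well
under 2%; 240 points stays under 5%); van der Waals radii per element and
theoretical maximum per-residue areas (Tien et al. 2013 values) ship as
TSVs. RSA = ASA/maxASA clipped to [0,1]; interior below 0.25, surface at or
above — a standard burial cutoff, exposed as `rsa_cutoff`. Residues with
missing atoms are flagged and their ASA computed over present atoms.

**Element position.** A variant in a coil element is a *linker* site; in a
helix or strand element it is *boundary* when within `boundary_width`
residues (default 2) of either element end, else *middle*. The boundary
width is a declared parameter, not inferred from any dataset.

Predicted-model confidence (pLDDT, read from the B-factor column) is
reported per site but never used as a filter: low-confidence segments are
often genuinely disordered linkers, and dropping them would bias the linker
category. Model numbering is assumed to match translation numbering (true
for full-length predicted models); a constant offset handles trimmed models.

## Synthetic data

The generator exists so that every stage has inputs whose correct answer is
known by construction. Coding sequences are ORF-valid (ATG start, single
terminal stop), with bases drawn at a configurable GC content (default 0.5,
uniform) and stop codons rejected in the body. Defaults mirror the emulated
study: 7 genes × 1000 codons (the scale of a STAT-family transcript), 50
variants per class, carrier counts uniform on [20, 200] so the support
filter passes by construction, GATC planted with probability 1.0 in
disease windows and 0.0 in benign windows, and flank residues drawn from
class weight vectors that up-weight Leu/Ile/Met/Phe/Glu/Asp fourfold for
the disease class and Ser/Gly/Thr/Arg fourfold for the benign class.

Variant sites are spaced so windows and flanks never overlap. Motif
planting prefers synonymous codon edits (protein unchanged); when no
synonymous placement exists in the window, a placement avoiding the centre
and flank codons is used and flagged in the ground-truth ledger. Windows
*not* selected for planting are scrubbed of chance occurrences of the motif
on either strand — a 4-mer appears spontaneously in roughly one window in
six, so without scrubbing a configured probability of 0 would be
unrealisable — again by synonymous third-position edits where possible.
All randomness flows through one seeded generator; identical configurations
are bit-reproducible.

The ideal-geometry fixtures are poly-alanine backbones (N, CA, C, O) built
by internal-coordinate chain extension with standard bond lengths/angles:
helix (φ −57°, ψ −47°), extended chain (φ = ψ = 180°, no hydrogen bonds,
every residue surface-exposed), and an antiparallel strand pair (φ −139°,
ψ 135°) whose second strand is a flipped copy placed, in the strand's
principal-axis frame, at a fixed offset chosen once to maximise the
inter-strand Kabsch–Sander bond count (8 bonds, a complete ladder).

What the generator does **not** emulate: real codon-usage bias, mutational
signatures, allele-frequency structure, linkage between nearby variants,
side-chain packing, and the correlation between sequence class and
structural location found in real proteins. Passing recovery tests
therefore demonstrates that the pipeline measures what it claims to
measure on data with a known contrast — not that any particular biological
contrast exists.

## Numerical and design choices

- Coordinates are 1-based inclusive everywhere in the library; the only
  0-based half-open conversion happens in the BED export writer.
- Window clamping (not padding) at CDS edges; truncation only shortens.
- The minimal-edit mutant codon is deterministic (fewest base changes,
  lexicographic tie-break).
- Sphere sampling uses the golden-spiral construction, deterministic for a
  given point count — no RNG in the geometry path.
- Hydrogen-bond search prunes pairs with Cα–Cα distance > 9 Å; the pruning
  bound exceeds the maximal geometrically possible bonded distance.
- The run pipeline sorts every output table on its full key set and writes
  JSON with sorted keys; reruns with identical config and seed are
  byte-identical (the log excludes timestamps for the same reason).
- Problem sizes used in the shipped checks — 1,000 random 60-nt sequences
  for scanner/oracle agreement, 500 random flank sets for combination
  enumeration, 50 and 200 variants per class for the end-to-end recovery
  conditions — are the study conditions of the emulated design; they run in
  seconds and are not tuned to outcomes.

## Known limitations

- Restriction enzymes with bipartite or offset-cleavage recognition are
  matched on the recognition core only.
- Single-transcript model: no isoform resolution, no genomic coordinates,
  no splice or UTR context.
- Three-state secondary structure only; no dimer-interface or
  protein–protein interaction analysis; no stability (ΔΔG) prediction.
- Descriptive statistics only — exclusivity partitions and frequencies
  carry no significance tests, and on small classes chance exclusives are
  expected (visible in the README's five-per-class example).
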