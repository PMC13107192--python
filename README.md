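# varcontext

Genomic and structural context annotation of missense variants in
protein-coding genes, built around the kind of question asked of curated
JAK–STAT pathway variants: do disease-associated and benign substitutions
sit in systematically different nucleotide, peptide and structural
neighbourhoods?

Given coding sequences (FASTA, e.g. CCDS records), a missense-variant table
(gene, protein position, ref/alt residue, carrier support, source database,
class label) and predicted structure models (PDB/mmCIF with pLDDT in the
B-factor field), the package answers three questions per variant class:

1. **Nucleotide context** — which degenerate motifs (restriction-enzyme
   recognition sites, Cas9 PAMs, written in the IUPAC alphabet) occur inside
   the ±20 bp window around each variant, scanning both strands, and which
   motifs are *exclusive* to the disease-associated or the benign class
   (Venn/UpSet partition). For a variant at protein position *p* the window
   is centred on the recorded CDS position (or the middle base of codon *p*,
   i.e. nucleotide 3(p−1)+2) and clamped to the CDS.
2. **Peptide context** — which unordered k-residue combinations (k = 1, 2, 3)
   drawn from the six flanking residues (±3, centre excluded, multiplicities
   respected) occur near each class, counted once per variant, with raw
   counts and per-class frequencies and an exclusivity partition.
3. **Structural context** — three-state secondary structure (H/E/C) from
   backbone hydrogen bonds (Kabsch–Sander criterion, bond when
   E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol),
   element position (linker / boundary / middle with a 2-residue boundary
   width), and burial via Shrake–Rupley accessible surface area with a
   1.4 Å probe, normalised to RSA = ASA/maxASA and thresholded at 0.25.

A seeded synthetic-data generator produces ORF-valid coding sequences,
two-class variant tables with a controllable per-class probability of a
planted motif (default GATC) in each window and class-contrasted flanking
composition, and ideal helix / antiparallel-strand / extended backbone
fixtures — so the whole pipeline is testable end to end without downloads.

## Worked example

```sh
varcontext simulate --seed 5 --n-variants 5 --n-genes 2 --n-codons 200 --out sim/
varcontext run --cds sim/cds.fasta --variants sim/variants.tsv --seed 5 --out run/
varcontext report --run-dir run/
```

prints

```
coding sequences: 2
variants parsed:  10
retained: disease=5 benign=5 (validation-excluded 0, support-excluded 0, unknown-class 0)
motif hits: 1119 over 41 motifs; exclusive to disease: Asi256I, Bsp143I, BssMI, DpnI, DpnII, Lcr047I, MalI, NdeII, NmCas9, Sau3AI
aa patterns k1_combinations: 19
aa patterns k2_combinations: 85
aa patterns k3_combinations: 135
```

The simulated dataset plants GATC in every disease-associated window and
scrubs it from every benign window, so all nine GATC-recognising enzymes in
the bundled table land in the disease-exclusive set — the designed contrast
recovered end to end. (At five variants per class a PAM can be exclusive by
chance, as NmCas9 is here; the acceptance script shows that at 200 per class
such chance exclusives vanish while the planted contrast remains.) The per-window hit lists, the motif Venn partition,
an UpSet-ready membership matrix and the k = 1–3 flank-combination tables
are written under `run/`. Supplying `--structures <dir>` (PDB files named
`<gene_id>.pdb`) adds per-variant secondary-structure state, element
position, RSA/burial and pLDDT plus a per-class contingency summary.

All parameters are flags with the defaults above (`--flank-nt 20`,
`--flank-aa 3`, `--min-carriers 20`, `--boundary-width 2`,
`--rsa-cutoff 0.25`, `--forward-only`, `--mutant-seq`, `--seed`), or a flat
`key = value` config file via `--config` (flags override the file).

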