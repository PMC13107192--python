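"""Codon arithmetic and context-window extraction.

Every variant is anchored to a coding-sequence nucleotide (its recorded
``cds_pos`` when present, otherwise the middle base of its codon) and a
window of ``flank`` bp in each direction is taken around that anchor,
clamped to the coding-sequence bounds. The peptide context is the +/-3
residues around the variant site, truncated at the protein termini.
"""

from __future__ import annotations

from dataclasses import dataclass

from varcontext.io import CdsRecord, VariantRecord

# single-base substitutions can turn one codon into another; used to pick a
# minimally-edited mutant codon when scanning the mutant allele
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.items():
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_FOR_AA:
    CODONS_FOR_AA[_aa].sort()


@dataclass(frozen=True)
class NucWindow:
    """A nucleotide context window, 1-based inclusive CDS coordinates."""

    gene_id: str
    center: int
    start: int
    end: int
    sequence: str
    flank: int = 20

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError("window start must be >= 1")
        if not (self.start <= self.center <= self.end):
            raise ValueError("window center outside [start, end]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("window sequence length inconsistent with bounds")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PeptideFlanks:
    """The residues immediately up- and downstream of a variant site."""

    upstream: str
    downstream: str
    center_aa: str
    flank: int = 3

    def __post_init__(self) -> None:
        if len(self.upstream) > self.flank or len(self.downstream) > self.flank:
            raise ValueError("flank strings longer than the flank size")

    @property
    def residues(self) -> str:
        """All flanking residues (center excluded), upstream first."""
        return self.upstream + self.downstream


def codon_span(protein_pos: int, n_residues: int | None = None) -> tuple[int, int]:
    """1-based inclusive CDS interval of the codon for ``protein_pos``.

    ``n_residues``, when given, bounds the position (stop codon excluded).
    """
    if protein_pos < 1:
        raise ValueError(f"protein_pos must be >= 1, got {protein_pos}")
    if n_residues is not None and protein_pos > n_residues:
        raise ValueError(f"protein_pos {protein_pos} beyond protein length {n_residues}")
    start = 3 * (protein_pos - 1) + 1
    return start, start + 2


def mutant_codon(ref_codon: str, alt_aa: str) -> str:
    """A codon for ``alt_aa`` differing from ``ref_codon`` in as few bases
    as possible (lexicographically first on ties)."""
    candidates = CODONS_FOR_AA[alt_aa]
    return min(candidates, key=lambda c: (sum(a != b for a, b in zip(c, ref_codon)), c))


def _mutant_sequence(variant: VariantRecord, cds: CdsRecord) -> str:
    start, end = codon_span(variant.protein_pos)
    ref_codon = cds.sequence[start - 1 : end]
    new = mutant_codon(ref_codon, variant.alt_aa)
    return cds.sequence[: start - 1] + new + cds.sequence[end:]


def nucleotide_window(
    variant: VariantRecord,
    cds: CdsRecord,
    flank: int = 20,
    anchor_mode: str = "auto",
    use_mutant: bool = False,
) -> NucWindow:
    """Extract the +/-``flank`` bp window around a variant's anchor base.

    Anchoring (``anchor_mode``):

    * ``"auto"`` — the recorded ``cds_pos`` when present, else the middle
      base of the codon;
    * ``"middle"`` — always the middle base of the codon;
    * ``"union"`` — the union of the windows of all three codon positions
      (every candidate single-nucleotide change producing the substitution
      lies inside the codon), reported with the middle base as center.

    The window is clamped to the CDS bounds, never padded. By default the
    reference sequence is returned; ``use_mutant=True`` substitutes a
    minimally-edited codon encoding the alternate residue first.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start_c, end_c = codon_span(variant.protein_pos, len(cds.protein))
    middle = start_c + 1
    if anchor_mode == "auto":
        anchor = variant.cds_pos if variant.cds_pos is not None else middle
        lo, hi = anchor - flank, anchor + flank
    elif anchor_mode == "middle":
        anchor = middle
        lo, hi = anchor - flank, anchor + flank
    elif anchor_mode == "union":
        anchor = middle
        lo, hi = start_c - flank, end_c + flank
    else:
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    lo = max(1, lo)
    hi = min(len(cds.sequence), hi)
    seq = _mutant_sequence(variant, cds) if use_mutant else cds.sequence
    return NucWindow(
        gene_id=cds.gene_id,
        center=anchor,
        start=lo,
        end=hi,
        sequence=seq[lo - 1 : hi],
        flank=flank,
    )


def peptide_flanks(variant: VariantRecord, cds: CdsRecord, flank: int = 3) -> PeptideFlanks:
    """The +/-``flank`` residues around the variant site (center excluded).

    Flanks are truncated at the protein termini; the center residue reported
    is the reference residue.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    pos = variant.protein_pos
    protein = cds.protein
    if pos > len(protein):
        raise ValueError(f"{variant.label}: position beyond protein length {len(protein)}")
    upstream = protein[max(0, pos - 1 - flank) : pos - 1]
    downstream = protein[pos : pos + flank]
    return PeptideFlanks(
        upstream=upstream, downstream=downstream, center_aa=protein[pos - 1], flank=flank
    )


def window_to_bed_row(window: NucWindow) -> tuple[str, int, int]:
    """Convert to BED convention (0-based half-open) at the writer boundary."""
    return (window.gene_id, window.start - 1, window.end)
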