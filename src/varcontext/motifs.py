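"""IUPAC-degenerate motif scanning around variant windows.

Recognition sequences (restriction-enzyme sites and Cas9 PAMs) are written
in the IUPAC degenerate nucleotide alphabet and scanned on both strands of
each variant's nucleotide window. A motif is *associated* with a variant
when at least one match lies fully inside the window; association is
presence/absence per variant, and motifs are then partitioned into
exclusive-disease / exclusive-benign / shared sets by class.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

from varcontext.io import CdsRecord, VariantRecord, VariantSet
from varcontext.windows import NucWindow, nucleotide_window

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full IUPAC alphabet (an involution)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC recognition sequence (restriction site or PAM)."""

    name: str
    recognition: str
    kind: str  # "restriction" | "pam"

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        bad = set(self.recognition.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC codes {sorted(bad)}")
        if self.kind not in ("restriction", "pam"):
            raise ValueError(f"{self.name}: kind must be 'restriction' or 'pam'")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition.upper()) == self.recognition.upper()


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence inside a variant's window.

    ``offset`` is the 1-based start of the match within the window in plus-
    strand coordinates; ``matched`` is the concrete sequence read along the
    reported strand.
    """

    motif: str
    gene_id: str
    variant_key: tuple[str, int, str, str]
    strand: str  # "+" | "-"
    offset: int
    abs_start: int  # 1-based CDS coordinate of the match start (+ strand)
    matched: str


@dataclass
class ClassMotifPartition:
    """Venn partition of motifs over the two variant classes."""

    exclusive_disease: set[str] = field(default_factory=set)
    exclusive_benign: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def all_motifs(self) -> set[str]:
        return self.exclusive_disease | self.exclusive_benign | self.shared


def _pattern_to_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        bases = IUPAC.get(ch)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({''.join(parts)}))")


def iupac_match(pattern: str, seq: str) -> list[tuple[int, str]]:
    """All forward-strand occurrences of an IUPAC pattern in ``seq``.

    Returns ``(offset, matched)`` pairs with 1-based offsets; overlapping
    occurrences are all reported.
    """
    regex = _pattern_to_regex(pattern)
    seq = seq.upper()
    return [(m.start() + 1, m.group(1)) for m in regex.finditer(seq)]


def scan_both_strands(
    motif: MotifDef,
    window: NucWindow,
    variant_key: tuple[str, int, str, str] | None = None,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a window on both strands for one motif.

    Minus-strand matches (the pattern read on the reverse complement) are
    reported in plus-strand window coordinates. A palindromic pattern
    matching the same footprint on both strands is collapsed to a single
    plus-strand hit, so double-stranded recognition is counted once.
    """
    key = variant_key if variant_key is not None else (window.gene_id, 0, "", "")
    seq = window.sequence.upper()
    n = len(seq)
    pat = motif.recognition.upper()
    hits: list[MotifHit] = []
    fwd_footprints: set[int] = set()
    for off, matched in iupac_match(pat, seq):
        fwd_footprints.add(off)
        hits.append(
            MotifHit(
                motif=motif.name,
                gene_id=window.gene_id,
                variant_key=key,
                strand="+",
                offset=off,
                abs_start=window.start + off - 1,
                matched=matched,
            )
        )
    if both_strands:
        L = len(pat)
        for off_rc, matched in iupac_match(pat, reverse_complement(seq)):
            # match at offset j (1-based) on the revcomp occupies plus-strand
            # positions [n - j - L + 2, n - j + 1]
            plus_off = n - off_rc - L + 2
            if plus_off in fwd_footprints:
                continue  # palindromic footprint already reported on +
            hits.append(
                MotifHit(
                    motif=motif.name,
                    gene_id=window.gene_id,
                    variant_key=key,
                    strand="-",
                    offset=plus_off,
                    abs_start=window.start + plus_off - 1,
                    matched=matched,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def sites_near_variants(
    vs: VariantSet,
    cds: list[CdsRecord],
    motifs: list[MotifDef],
    flank: int = 20,
    both_strands: bool = True,
    anchor_mode: str = "auto",
    use_mutant: bool = False,
) -> list[MotifHit]:
    """All motif hits fully contained in any variant's +/-``flank`` window."""
    by_gene = {c.gene_id: c for c in cds}
    hits: list[MotifHit] = []
    for v in vs:
        window = nucleotide_window(
            v, by_gene[v.gene_id], flank=flank, anchor_mode=anchor_mode, use_mutant=use_mutant
        )
        for motif in motifs:
            hits.extend(scan_both_strands(motif, window, v.key, both_strands=both_strands))
    return hits


def partition_hits_by_class(
    hits: list[MotifHit], disease: VariantSet, benign: VariantSet
) -> ClassMotifPartition:
    """Partition motifs by which class of variants they occur near.

    A motif lands in ``exclusive_disease`` when >=1 disease variant but no
    benign variant has a hit (and vice versa); in ``shared`` when both
    classes do. Per-motif variant counts use presence/absence semantics: a
    motif occurring twice in one window counts that variant once.
    """
    disease_keys = disease.keys()
    benign_keys = benign.keys()
    seen: dict[str, dict[str, set[tuple]]] = {}
    for h in hits:
        if h.variant_key in disease_keys:
            cls = "disease"
        elif h.variant_key in benign_keys:
            cls = "benign"
        else:
            raise ValueError(f"hit with unknown variant key {h.variant_key}")
        seen.setdefault(h.motif, {"disease": set(), "benign": set()})[cls].add(h.variant_key)
    part = ClassMotifPartition()
    for motif, by_class in seen.items():
        nd, nb = len(by_class["disease"]), len(by_class["benign"])
        part.counts[motif] = {"disease": nd, "benign": nb}
        if nd and nb:
            part.shared.add(motif)
        elif nd:
            part.exclusive_disease.add(motif)
        else:
            part.exclusive_benign.add(motif)
    return part


def load_motif_table(path=None) -> list[MotifDef]:
    """Load a motif TSV (columns ``name, recognition, kind``).

    Without a path the bundled default table is used: the named restriction
    enzymes (REBASE recognition cores) plus the Cas9 PAM set.
    """
    if path is None:
        source = resources.files("varcontext.data").joinpath("motifs_default.tsv")
        with source.open() as fh:
            return _parse_motif_rows(fh)
    with open(path, newline="") as fh:
        return _parse_motif_rows(fh)


def _parse_motif_rows(fh) -> list[MotifDef]:
    reader = csv.DictReader(fh, delimiter="\t")
    required = {"name", "recognition", "kind"}
    if reader.fieldnames is None or required - set(reader.fieldnames):
        raise ValueError("motif table must have columns name, recognition, kind")
    return [
        MotifDef(row["name"].strip(), row["recognition"].strip().upper(), row["kind"].strip())
        for row in reader
    ]


def motifs_recognizing(motifs: list[MotifDef], recognition: str) -> list[MotifDef]:
    """The motifs in a table whose recognition equals ``recognition``."""
    target = recognition.upper()
    return [m for m in motifs if m.recognition.upper() == target]
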