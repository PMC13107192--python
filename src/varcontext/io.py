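"""Reading and validation of coding sequences and missense-variant tables.

Coding sequences arrive as FASTA with ``>GENE|ACCESSION`` headers (the
accession is typically a CCDS identifier). Variants arrive as a flat TSV
keyed by gene, 1-based protein position, reference and alternate residue,
with a carrier/tumour-sample count, a source database tag and a class label
(disease-associated vs ClinVar-benign vs unknown).

Two filters mirror the curation rules of the study design this package
supports: a minimum-support filter (default: a variant must be seen in at
least 20 carriers/samples, the All of Us privacy floor) and a partition into
disease-associated and benign classes.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
SOURCES = {"allofus", "cosmic"}
CLASSES = {"disease", "benign", "unknown"}

VARIANT_COLUMNS = [
    "gene_id",
    "protein_pos",
    "ref_aa",
    "alt_aa",
    "cds_pos",
    "carrier_count",
    "source",
    "var_class",
]


class ValidationError(ValueError):
    """A record violates a structural invariant (named record and rule)."""


class SchemaError(ValueError):
    """An input table is missing mandatory columns or is malformed."""


@dataclass(frozen=True)
class CdsRecord:
    """One protein-coding sequence with its translation.

    The nucleotide sequence must be a complete open reading frame: length a
    multiple of 3, ATG start, exactly one stop codon at the terminal
    position. ``protein`` is the standard-code translation without the stop.
    """

    gene_id: str
    accession: str
    sequence: str
    protein: str

    @classmethod
    def from_sequence(cls, gene_id: str, accession: str, sequence: str) -> "CdsRecord":
        seq = sequence.upper()
        label = f"{gene_id}|{accession}"
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValidationError(f"{label}: non-ACGT characters {bad}")
        if len(seq) % 3 != 0:
            raise ValidationError(f"{label}: length not multiple of 3 ({len(seq)})")
        if len(seq) < 6:
            raise ValidationError(f"{label}: too short for start + stop codon")
        if not seq.startswith("ATG"):
            raise ValidationError(f"{label}: does not begin with ATG")
        translated = str(Seq(seq).translate())
        if not translated.endswith("*"):
            raise ValidationError(f"{label}: no terminal stop codon")
        body = translated[:-1]
        if "*" in body:
            pos = body.index("*") + 1
            raise ValidationError(f"{label}: internal stop codon at residue {pos}")
        return cls(gene_id=gene_id, accession=accession, sequence=seq, protein=body)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One missense substitution on a coding sequence.

    ``protein_pos`` and ``cds_pos`` are 1-based; ``cds_pos``, when present,
    must fall inside the codon of ``protein_pos``. Identity of a variant is
    the (gene, position, alternate residue, source) tuple: the same
    substitution reported by two source databases is two records.
    """

    gene_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    cds_pos: int | None = None
    carrier_count: int = 0
    source: str = "allofus"
    var_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS:
            raise ValidationError(f"{self.label}: ref_aa {self.ref_aa!r} not a standard residue")
        if self.alt_aa not in AMINO_ACIDS:
            raise ValidationError(f"{self.label}: alt_aa {self.alt_aa!r} not a standard residue")
        if self.ref_aa == self.alt_aa:
            raise ValidationError(f"{self.label}: not missense (ref == alt)")
        if self.protein_pos < 1:
            raise ValidationError(f"{self.label}: protein_pos must be >= 1")
        if self.carrier_count < 0:
            raise ValidationError(f"{self.label}: negative carrier_count")
        if self.source not in SOURCES:
            raise ValidationError(f"{self.label}: unknown source {self.source!r}")
        if self.var_class not in CLASSES:
            raise ValidationError(f"{self.label}: unknown class {self.var_class!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity tuple (gene_id, protein_pos, alt_aa, source)."""
        return (self.gene_id, self.protein_pos, self.alt_aa, self.source)

    @property
    def label(self) -> str:
        return f"{self.gene_id}:{self.ref_aa}{self.protein_pos}{self.alt_aa}({self.source})"


@dataclass
class VariantSet:
    """An ordered collection of unique variants plus provenance notes."""

    variants: list[VariantRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for v in self.variants:
            if v.key in seen:
                raise ValidationError(f"duplicate variant {v.label}")
            seen.add(v.key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def keys(self) -> set[tuple]:
        return {v.key for v in self.variants}

    def with_provenance(self, **notes) -> "VariantSet":
        prov = dict(self.provenance)
        prov.update(notes)
        return VariantSet(variants=list(self.variants), provenance=prov)


def read_cds_fasta(path) -> list[CdsRecord]:
    """Read coding sequences from FASTA with ``>GENE|ACCESSION`` headers.

    Every entry is translated and checked against the open-reading-frame
    invariants; a violating entry raises :class:`ValidationError` naming the
    record and the broken rule.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.id
        if "|" in header:
            gene_id, accession = header.split("|", 1)
        else:
            gene_id, accession = header, header
        records.append(CdsRecord.from_sequence(gene_id, accession, str(entry.seq)))
    return records


def _parse_int(value: str, column: str, line_no: int) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise SchemaError(f"line {line_no}: non-integer {column} {value!r}") from None


def read_variant_table(path) -> VariantSet:
    """Parse a variant TSV into a typed :class:`VariantSet`.

    Rows with ``ref_aa == alt_aa`` or with a stop symbol on either side are
    rejected as non-missense (counted in provenance); unknown class labels
    are mapped to ``unknown`` with a logged warning. Missing mandatory
    columns raise :class:`SchemaError`; a non-integer position raises with
    the offending line number.
    """
    variants: list[VariantRecord] = []
    rejected: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header")
        missing = set(VARIANT_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            ref_aa = (row["ref_aa"] or "").strip().upper()
            alt_aa = (row["alt_aa"] or "").strip().upper()
            if ref_aa == alt_aa:
                rejected.append({"line": line_no, "reason": "not missense"})
                continue
            if ref_aa not in AMINO_ACIDS or alt_aa not in AMINO_ACIDS:
                rejected.append({"line": line_no, "reason": "not a standard-residue substitution"})
                continue
            var_class = (row["var_class"] or "").strip().lower()
            if var_class not in CLASSES:
                logger.warning("line %d: unknown class %r mapped to 'unknown'", line_no, var_class)
                var_class = "unknown"
            cds_raw = (row.get("cds_pos") or "").strip()
            variants.append(
                VariantRecord(
                    gene_id=row["gene_id"].strip(),
                    protein_pos=_parse_int(row["protein_pos"], "protein_pos", line_no),
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    cds_pos=_parse_int(cds_raw, "cds_pos", line_no) if cds_raw else None,
                    carrier_count=_parse_int(row["carrier_count"], "carrier_count", line_no),
                    source=row["source"].strip().lower(),
                    var_class=var_class,
                )
            )
    return VariantSet(
        variants=variants,
        provenance={"path": str(path), "rows_rejected": rejected},
    )


def validate_variants(vs: VariantSet, cds: list[CdsRecord]) -> tuple[VariantSet, list[dict]]:
    """Check every variant against its coding sequence.

    A variant is retained only when its position lies inside the protein,
    its reference residue matches the translation, and any ``cds_pos`` falls
    inside the codon of ``protein_pos``. Returns the retained set and an
    exclusion report (one dict per excluded variant with the reason). A
    variant on a gene with no coding sequence is a hard error.
    """
    by_gene = {c.gene_id: c for c in cds}
    kept: list[VariantRecord] = []
    report: list[dict] = []
    for v in vs:
        if v.gene_id not in by_gene:
            raise ValidationError(f"{v.label}: no coding sequence for gene {v.gene_id!r}")
        protein = by_gene[v.gene_id].protein
        if v.protein_pos > len(protein):
            report.append({"variant": v.label, "reason": "out of range"})
            continue
        actual = protein[v.protein_pos - 1]
        if actual != v.ref_aa:
            report.append(
                {"variant": v.label, "reason": f"reference mismatch (CDS has {actual})"}
            )
            continue
        if v.cds_pos is not None:
            start = 3 * (v.protein_pos - 1) + 1
            if not (start <= v.cds_pos <= start + 2):
                report.append({"variant": v.label, "reason": "cds_pos outside codon"})
                continue
        kept.append(v)
    out = VariantSet(variants=kept, provenance=dict(vs.provenance))
    return out.with_provenance(validation_excluded=report), report


def filter_by_support(vs: VariantSet, min_carriers: int = 20) -> VariantSet:
    """Keep variants seen in at least ``min_carriers`` carriers/samples.

    Idempotent, and monotone in the threshold (a larger threshold yields a
    subset). The default of 20 is the support floor applied to both source
    databases.
    """
    if min_carriers < 0:
        raise ValueError(f"min_carriers must be non-negative, got {min_carriers}")
    kept = [v for v in vs if v.carrier_count >= min_carriers]
    out = VariantSet(variants=kept, provenance=dict(vs.provenance))
    return out.with_provenance(
        min_carriers=min_carriers, support_excluded=len(vs) - len(kept)
    )


def partition_by_class(vs: VariantSet) -> tuple[VariantSet, VariantSet]:
    """Split into (disease, benign) sets; unknown-class variants are dropped.

    The two outputs are disjoint and, together with the dropped unknowns
    (counted in each output's provenance), exhaust the input.
    """
    disease = [v for v in vs if v.var_class == "disease"]
    benign = [v for v in vs if v.var_class == "benign"]
    dropped = len(vs) - len(disease) - len(benign)
    prov = dict(vs.provenance)
    prov["unknown_class_dropped"] = dropped
    return (
        VariantSet(variants=disease, provenance=dict(prov)),
        VariantSet(variants=benign, provenance=dict(prov)),
    )


def merge_classifications(vs: VariantSet, table) -> VariantSet:
    """Overwrite class labels from an offline classification TSV.

    The table (columns ``gene_id, protein_pos, alt_aa, var_class``) plays
    the role of a pre-fetched archive lookup; it is keyed by
    (gene_id, protein_pos, alt_aa) and applies to every source. Duplicate
    keys with conflicting classes are an error; table keys matching no
    variant are logged.
    """
    mapping: dict[tuple, str] = {}
    conflicts: list[tuple] = []
    with open(table, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{table}: empty file, no header")
        required = {"gene_id", "protein_pos", "alt_aa", "var_class"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"{table}: missing mandatory columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            key = (
                row["gene_id"].strip(),
                _parse_int(row["protein_pos"], "protein_pos", line_no),
                row["alt_aa"].strip().upper(),
            )
            cls = row["var_class"].strip().lower()
            if cls not in CLASSES:
                raise SchemaError(f"{table} line {line_no}: unknown class {cls!r}")
            if key in mapping and mapping[key] != cls:
                conflicts.append(key)
            mapping[key] = cls
    if conflicts:
        raise ValidationError(f"conflicting classifications for keys {sorted(set(conflicts))}")
    matched: set[tuple] = set()
    updated = []
    for v in vs:
        key = (v.gene_id, v.protein_pos, v.alt_aa)
        if key in mapping:
            matched.add(key)
            updated.append(replace(v, var_class=mapping[key]))
        else:
            updated.append(v)
    unmatched = set(mapping) - matched
    for key in sorted(unmatched):
        logger.info("classification key %s matched no variant", key)
    out = VariantSet(variants=updated, provenance=dict(vs.provenance))
    return out.with_provenance(classification_table=str(table))
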