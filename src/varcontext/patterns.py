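"""Flanking amino-acid combination analysis.

For each variant the six flanking residues (three upstream, three
downstream, the mutated center excluded) form a multiset; every distinct
k-multiset drawable from it (k = 1, 2, 3, respecting multiplicities) is a
*combination*. Combinations are unordered — adjacency is not required by
default — and are counted once per variant (presence semantics), so a
repeat-rich flank cannot dominate the per-class tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from varcontext.io import CdsRecord, VariantSet
from varcontext.windows import PeptideFlanks, peptide_flanks

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def combination_key(residues) -> str:
    """Canonical '+'-joined sorted form of a residue multiset, e.g. 'D+L+L'."""
    return "+".join(sorted(residues))


def key_to_three_letter(key: str) -> str:
    """'F+M' -> 'Met+Phe' (re-sorted in three-letter alphabetical order)."""
    return "+".join(sorted(THREE_LETTER[r] for r in key.split("+")))


@dataclass
class PatternTable:
    """Per-class counts of k-residue flank combinations.

    ``counts[cls][key]`` is the number of variants of class ``cls`` whose
    flank multiset contains the combination; never exceeds the class size.
    """

    k: int
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    class_sizes: dict[str, int] = field(default_factory=dict)

    def frequency(self, cls: str, key: str) -> float:
        size = self.class_sizes.get(cls, 0)
        if size == 0:
            return 0.0
        return self.counts.get(cls, {}).get(key, 0) / size


def enumerate_residue_combinations(
    flanks: PeptideFlanks, k: int, adjacent_only: bool = False
) -> set[str]:
    """All distinct k-multisets drawable from the flanking residues.

    Multiplicities are respected: 'L+L' is only produced when leucine
    occupies two distinct flank positions. With ``adjacent_only`` (k=2,
    non-default) only combinations of residues adjacent in sequence — the
    dipeptide reading — are produced.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    residues = flanks.residues
    if adjacent_only and k == 2:
        pairs = set()
        up, down = flanks.upstream, flanks.downstream
        for s in (up, down):
            for i in range(len(s) - 1):
                pairs.add(combination_key(s[i : i + 2]))
        return pairs
    return {combination_key(c) for c in itertools.combinations(residues, k)}


def tabulate_patterns(
    vs: VariantSet,
    cds: list[CdsRecord],
    k: int,
    flank: int = 3,
    adjacent_only: bool = False,
) -> PatternTable:
    """Count, per class, how many variants carry each flank combination."""
    by_gene = {c.gene_id: c for c in cds}
    table = PatternTable(k=k)
    for v in vs:
        cls = v.var_class
        table.class_sizes[cls] = table.class_sizes.get(cls, 0) + 1
        flanks = peptide_flanks(v, by_gene[v.gene_id], flank=flank)
        for key in enumerate_residue_combinations(flanks, k, adjacent_only=adjacent_only):
            cls_counts = table.counts.setdefault(cls, {})
            cls_counts[key] = cls_counts.get(key, 0) + 1
    return table


def exclusive_patterns(
    disease_table: PatternTable, benign_table: PatternTable
) -> tuple[set[str], set[str], set[str]]:
    """Split combination keys into (exclusive_disease, exclusive_benign, shared).

    A key with a positive count in exactly one class is exclusive to it.
    Both tables must have the same k.
    """
    if disease_table.k != benign_table.k:
        raise ValueError(
            f"mismatched k: {disease_table.k} vs {benign_table.k}"
        )
    dis = {
        key
        for by_cls in (disease_table.counts.get("disease", {}),)
        for key, n in by_cls.items()
        if n > 0
    }
    ben = {
        key
        for by_cls in (benign_table.counts.get("benign", {}),)
        for key, n in by_cls.items()
        if n > 0
    }
    return dis - ben, ben - dis, dis & ben


def pattern_table_frame(
    disease_table: PatternTable,
    benign_table: PatternTable,
    three_letter: bool = False,
) -> pd.DataFrame:
    """Merge per-class tables into the exported TSV layout.

    Columns: k, combination, disease_count, benign_count, disease_freq,
    benign_freq, exclusivity.
    """
    excl_d, excl_b, shared = exclusive_patterns(disease_table, benign_table)
    dcounts = disease_table.counts.get("disease", {})
    bcounts = benign_table.counts.get("benign", {})
    rows = []
    for key in sorted(set(dcounts) | set(bcounts)):
        if key in excl_d:
            excl = "disease"
        elif key in excl_b:
            excl = "benign"
        else:
            excl = "shared"
        rows.append(
            {
                "k": disease_table.k,
                "combination": key_to_three_letter(key) if three_letter else key,
                "disease_count": dcounts.get(key, 0),
                "benign_count": bcounts.get(key, 0),
                "disease_freq": round(disease_table.frequency("disease", key), 6),
                "benign_freq": round(benign_table.frequency("benign", key), 6),
                "exclusivity": excl,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "k",
            "combination",
            "disease_count",
            "benign_count",
            "disease_freq",
            "benign_freq",
            "exclusivity",
        ],
    )
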