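import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from varcontext.io import VariantRecord, VariantSet
from varcontext.motifs import (
    IUPAC,
    MotifDef,
    iupac_match,
    load_motif_table,
    motifs_recognizing,
    partition_hits_by_class,
    reverse_complement,
    scan_both_strands,
    sites_near_variants,
)
from varcontext.simulate import SyntheticConfig, generate_cds
from varcontext.windows import NucWindow

DNA = st.text(alphabet="ACGT", min_size=0, max_size=60)


def brute_force_matches(pattern: str, seq: str) -> list[tuple[int, str]]:
    """Oracle: expand the degenerate pattern into concrete strings, then
    exact substring search (overlaps allowed)."""
    concrete = ["".join(p) for p in itertools.product(*(IUPAC[c] for c in pattern))]
    found = []
    for i in range(len(seq) - len(pattern) + 1):
        piece = seq[i : i + len(pattern)]
        if piece in concrete:
            found.append((i + 1, piece))
    return found


def _window(seq: str, start: int = 1) -> NucWindow:
    return NucWindow(
        gene_id="G1", center=start, start=start, end=start + len(seq) - 1,
        sequence=seq, flank=len(seq),
    )


class TestIupacMatch:
    @pytest.mark.parametrize(
        "pattern, seq, expected",
        [
            ("NGG", "AGGT", [(1, "AGG")]),
            ("NNGRRT", "TTGAGT", [(1, "TTGAGT")]),
            ("GATC", "TTGATCAA", [(3, "GATC")]),
            ("NN", "ACG", [(1, "AC"), (2, "CG")]),  # overlaps allowed
            ("GATC", "GGG", []),
        ],
    )
    def test_examples(self, pattern, seq, expected):
        assert iupac_match(pattern, seq) == expected

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="invalid IUPAC"):
            iupac_match("NGX", "ACGT")

    def test_matches_brute_force_on_random_sequences(self, rng):
        patterns = [
            m.recognition
            for m in load_motif_table()
            if sum(len(IUPAC[c]) > 1 for c in m.recognition) <= 4
        ]
        bases = np.array(list("ACGT"))
        for _ in range(60):
            seq = "".join(rng.choice(bases, size=60))
            for pattern in patterns:
                assert iupac_match(pattern, seq) == brute_force_matches(pattern, seq)


class TestReverseComplement:
    @given(DNA)
    @settings(derandomize=True)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_degenerate_codes(self):
        assert reverse_complement("NGG") == "CCN"
        assert reverse_complement("NNGRRT") == "AYYCNN"


class TestScanBothStrands:
    def test_palindromic_footprint_collapsed_to_one_plus_hit(self):
        motif = MotifDef("DpnI", "GATC", "restriction")
        hits = scan_both_strands(motif, _window("TTGATCAA"))
        assert len(hits) == 1
        assert (hits[0].offset, hits[0].strand) == (3, "+")

    def test_minus_strand_hit_reported_in_plus_coordinates(self):
        motif = MotifDef("SpCas9", "NGG", "pam")
        hits = scan_both_strands(motif, _window("CCTA"))
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        # revcomp "TAGG" matches NGG at its offset 2 -> plus coords start 1
        assert minus[0].offset == 1
        assert minus[0].matched == "AGG"

    def test_window_shorter_than_pattern_gives_no_hits(self):
        motif = MotifDef("SaCas9", "NNGRRT", "pam")
        assert scan_both_strands(motif, _window("ACGT")) == []

    def test_forward_only_mode(self):
        motif = MotifDef("SpCas9", "NGG", "pam")
        assert scan_both_strands(motif, _window("CCTA"), both_strands=False) == []

    @given(DNA.filter(lambda s: len(s) >= 4))
    @settings(derandomize=True, max_examples=100)
    def test_strand_symmetry(self, seq):
        # minus-strand hits equal plus-strand hits on the reverse complement,
        # coordinate-mapped
        motif = MotifDef("SaCas9", "NNGRRT", "pam")
        hits = scan_both_strands(motif, _window(seq))
        minus = {(h.offset, h.matched) for h in hits if h.strand == "-"}
        n, L = len(seq), len(motif.recognition)
        expected = {
            (n - off - L + 2, matched)
            for off, matched in iupac_match(motif.recognition, reverse_complement(seq))
        }
        plus_footprints = {h.offset for h in hits if h.strand == "+"}
        assert minus == {e for e in expected if e[0] not in plus_footprints}


@pytest.fixture(scope="module")
def scan_setup():
    config = SyntheticConfig(n_genes=1, n_codons=60, seed=7)
    (cds,) = generate_cds(config)
    variant = VariantRecord(
        gene_id=cds.gene_id, protein_pos=20, ref_aa=cds.protein[19],
        alt_aa="A" if cds.protein[19] != "A" else "V",
        carrier_count=30, var_class="disease",
    )
    return cds, VariantSet([variant])


class TestSitesNearVariants:
    def test_gatc_family_hits_once_per_enzyme(self, scan_setup):
        cds, vs = scan_setup
        # plant GATC at a known place inside the +/-20 window of codon 20
        seq = list(cds.sequence)
        anchor = 3 * 19 + 2
        seq[anchor + 4 : anchor + 8] = list("GATC")
        # bypass from_sequence: the edit may break ORF validity, irrelevant here
        cds2 = cds.__class__(cds.gene_id, cds.accession, "".join(seq), cds.protein)
        motifs = motifs_recognizing(load_motif_table(), "GATC")
        hits = sites_near_variants(vs, [cds2], motifs, flank=20)
        per_enzyme = {m.name: 0 for m in motifs}
        for h in hits:
            per_enzyme[h.motif] += 1
        assert all(n >= 1 for n in per_enzyme.values())

    def test_empty_motif_table_gives_no_hits(self, scan_setup):
        cds, vs = scan_setup
        assert sites_near_variants(vs, [cds], []) == []

    def test_association_monotone_in_flank(self, scan_setup):
        cds, vs = scan_setup
        motifs = load_motif_table()
        previous: set = set()
        for flank in (5, 10, 20, 40):
            hits = sites_near_variants(vs, [cds], motifs, flank=flank)
            associated = {(h.variant_key, h.motif) for h in hits}
            assert previous <= associated
            previous = associated


class TestPartition:
    def _vs(self, cls, pos):
        return VariantSet(
            [
                VariantRecord(
                    gene_id="G1", protein_pos=pos, ref_aa="K", alt_aa="R",
                    var_class=cls, carrier_count=30,
                )
            ]
        )

    def _hit(self, motif, key):
        from varcontext.motifs import MotifHit

        return MotifHit(
            motif=motif, gene_id="G1", variant_key=key, strand="+", offset=1,
            abs_start=1, matched="GATC",
        )

    def test_exclusive_and_shared_set_logic(self):
        disease = self._vs("disease", 5)
        benign = self._vs("benign", 9)
        dk, bk = next(iter(disease)).key, next(iter(benign)).key
        hits = [self._hit("A", dk), self._hit("B", dk), self._hit("B", bk)]
        part = partition_hits_by_class(hits, disease, benign)
        assert part.exclusive_disease == {"A"}
        assert part.shared == {"B"}
        assert part.exclusive_benign == set()

    def test_no_hits_gives_three_empty_sets(self):
        part = partition_hits_by_class([], self._vs("disease", 5), self._vs("benign", 9))
        assert part.all_motifs == set()

    def test_unknown_variant_key_is_error(self):
        hits = [self._hit("A", ("G9", 1, "R", "cosmic"))]
        with pytest.raises(ValueError, match="unknown variant key"):
            partition_hits_by_class(hits, self._vs("disease", 5), self._vs("benign", 9))

    def test_sets_disjoint_and_exhaustive(self):
        disease = self._vs("disease", 5)
        benign = self._vs("benign", 9)
        dk, bk = next(iter(disease)).key, next(iter(benign)).key
        hits = [self._hit("A", dk), self._hit("B", bk), self._hit("C", dk), self._hit("C", bk)]
        part = partition_hits_by_class(hits, disease, benign)
        sets = [part.exclusive_disease, part.exclusive_benign, part.shared]
        for a, b in itertools.combinations(sets, 2):
            assert a & b == set()
        assert part.all_motifs == {"A", "B", "C"}


def test_bundled_table_contains_named_enzymes_and_pams():
    motifs = load_motif_table()
    names = {m.name for m in motifs}
    for enzyme in ("DpnI", "Asi256I", "DpnII", "MalI", "Lcr047I", "NdeII",
                   "Bsp143I", "Sau3AI", "FaiI", "MspJI", "BssMI"):
        assert enzyme in names
    pam = {m.name: m.recognition for m in motifs if m.kind == "pam"}
    assert pam["SpCas9"] == "NGG"
    assert pam["SaCas9"] == "NNGRRT"
    assert pam["NmCas9"] == "NNNNGATT"
    assert pam["St1Cas9"] == "NNAGAAW"
    assert pam["St3Cas9"] == "NGGNG"
    assert pam["CjCas9"] == "NNNNACA"
    assert pam["FnCas9"] == "YG"
    assert pam["TdCas9"] == "NAAAW"
    assert pam["SpCas9-NG"] == "NG"
    assert pam["SpRY"] == "NRN"


def test_agrees_with_biopython_restriction_on_gatc(scan_setup):
    # independent route: Bio.Restriction site search for a GATC cutter
    from Bio.Restriction import DpnII
    from Bio.Seq import Seq

    cds, _ = scan_setup
    seq = cds.sequence + "TTGATCAA"  # guarantee at least one site
    ours = [offset for offset, _ in iupac_match("GATC", seq)]
    # DpnII cuts ^GATC, so Bio.Restriction's cut positions are site starts
    assert DpnII.search(Seq(seq)) == ours
    assert ours  # non-vacuous
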