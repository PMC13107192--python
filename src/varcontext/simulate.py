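"""Seeded synthetic inputs with the statistical structure the analysis assumes.

The generator emits three kinds of fixtures:

* ORF-valid coding sequences (ATG start, single terminal stop) with uniform
  or GC-biased background composition;
* a two-class variant table in which a chosen nucleotide motif (default
  GATC) is planted inside the +/-20 bp window with a per-class probability,
  and the six flanking residues are drawn from per-class composition
  weights (disease up-weighting the hydrophobic/acidic Leu, Ile, Met, Phe,
  Glu, Asp; benign up-weighting the polar/flexible Ser, Gly, Thr, Arg);
* ideal helix / antiparallel-strand-pair / extended-chain backbone models
  with known secondary structure and burial.

Planting prefers synonymous codon edits so the peptide-level experiment is
unperturbed by the nucleotide-level one, and windows that were *not*
selected for planting are scrubbed of chance motif occurrences (both
strands, synonymous third-position edits) so the configured per-class motif
probabilities hold exactly, not just in expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from varcontext.io import CdsRecord, VariantRecord, VariantSet
from varcontext.motifs import reverse_complement
from varcontext.structure import Atom, Residue, StructureModel
from varcontext.windows import _CODON_TABLE, CODONS_FOR_AA, codon_span

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TAG", "TGA")

# per-class flank composition weights: baseline 1 per residue, the class's
# characteristic residues up-weighted fourfold
_DISEASE_UP = set("LIMFED")
_BENIGN_UP = set("SGTR")


def _default_weights(upweighted: set[str]) -> dict[str, float]:
    return {aa: (4.0 if aa in upweighted else 1.0) for aa in AA_ORDER}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the analysed design: seven genes at roughly the coding
    length of a STAT transcript, 50 variants per class passing the
    20-carrier support floor, the GATC motif planted in every
    disease-associated window and in no benign window, and class-contrasted
    flank composition.
    """

    n_genes: int = 7
    n_codons: int = 1000
    n_variants_per_class: int = 50
    p_motif_disease: float = 1.0
    p_motif_benign: float = 0.0
    motif: str = "GATC"
    flank_nt: int = 20
    flank_aa: int = 3
    gc_content: float = 0.5
    carrier_range: tuple[int, int] = (20, 200)
    disease_weights: dict[str, float] = field(
        default_factory=lambda: _default_weights(_DISEASE_UP)
    )
    benign_weights: dict[str, float] = field(
        default_factory=lambda: _default_weights(_BENIGN_UP)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_motif_disease", "p_motif_benign"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        for weights in (self.disease_weights, self.benign_weights):
            vals = np.array([weights.get(aa, 0.0) for aa in AA_ORDER])
            if (vals < 0).any() or vals.sum() <= 0:
                raise ValueError("class weights must be non-negative with positive sum")


@dataclass
class SyntheticDataset:
    """Generated inputs plus the ground truth needed for recovery tests."""

    cds: list[CdsRecord]
    variants: VariantSet
    truth: dict


def _weights_vector(weights: dict[str, float]) -> np.ndarray:
    v = np.array([weights.get(aa, 0.0) for aa in AA_ORDER], dtype=float)
    return v / v.sum()


def generate_cds(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[CdsRecord]:
    """ORF-valid random coding sequences, reproducible under the seed.

    Body codons are drawn base-by-base at the configured GC content with
    stop codons rejected; the first codon is ATG and the single stop sits at
    the terminal position.
    """
    if config.n_codons < 3:
        raise ValueError("n_codons must be >= 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gc = config.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    records = []
    for g in range(1, config.n_genes + 1):
        codons = ["ATG"]
        while len(codons) < config.n_codons - 1:
            codon = "".join(rng.choice(bases, size=3, p=base_p))
            if codon not in STOP_CODONS:
                codons.append(codon)
        codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
        records.append(
            CdsRecord.from_sequence(f"GENE{g}", f"SYN{g}.1", "".join(codons))
        )
    return records


def _translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


def _window_bounds(anchor: int, flank: int, length: int) -> tuple[int, int]:
    return max(1, anchor - flank), min(length, anchor + flank)


def _occurrences(seq: list[str], lo: int, hi: int, motif: str) -> list[tuple[int, str]]:
    """1-based starts of motif or its reverse complement fully inside [lo, hi]."""
    window = "".join(seq[lo - 1 : hi])
    found = []
    targets = {motif}
    rc = reverse_complement(motif)
    targets.add(rc)
    for t in targets:
        start = 0
        while True:
            i = window.find(t, start)
            if i < 0:
                break
            found.append((lo + i, t))
            start = i + 1
    return sorted(set(found))


def _protected(codon_idx: int, center_codon: int, flank_aa: int) -> bool:
    return abs(codon_idx - center_codon) <= flank_aa


def _try_plant(
    seq: list[str],
    protein: list[str],
    anchor: int,
    center_codon: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[bool, bool]:
    """Write the motif into the variant's window; prefer synonymous edits.

    Returns (planted, synonymous). Synonymous placement leaves the whole
    protein unchanged; the fallback placement avoids the center and flank
    codons and any stop-codon creation, and updates the protein in place.
    """
    motif = config.motif.upper()
    L = len(motif)
    lo, hi = _window_bounds(anchor, config.flank_nt, len(seq))
    starts = [s for s in range(lo, hi - L + 2)]
    rng.shuffle(starts)
    fallback: int | None = None
    for s in starts:
        span = range(s, s + L)
        codon_indices = sorted({(p - 1) // 3 + 1 for p in span})
        old = seq[s - 1 : s + L - 1]
        seq[s - 1 : s + L - 1] = list(motif)
        new_aas = []
        ok_sense = True
        for ci in codon_indices:
            codon = "".join(seq[3 * (ci - 1) : 3 * ci])
            aa = _translate_codon(codon)
            if aa == "*" and ci != len(protein) + 1:
                ok_sense = False
            new_aas.append((ci, aa))
        synonymous = ok_sense and all(
            ci <= len(protein) and protein[ci - 1] == aa for ci, aa in new_aas
        )
        if synonymous:
            return True, True
        seq[s - 1 : s + L - 1] = old
        if (
            fallback is None
            and ok_sense
            and all(not _protected(ci, center_codon, config.flank_aa) for ci in codon_indices)
            and all(ci <= len(protein) for ci in codon_indices)
        ):
            fallback = s
    if fallback is None:
        return False, False
    s = fallback
    seq[s - 1 : s + L - 1] = list(motif)
    for ci in sorted({(p - 1) // 3 + 1 for p in range(s, s + L)}):
        protein[ci - 1] = _translate_codon("".join(seq[3 * (ci - 1) : 3 * ci]))
    return True, False


def _scrub_window(
    seq: list[str],
    protein: list[str],
    anchor: int,
    center_codon: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> bool:
    """Remove every motif occurrence (both strands) from one window.

    Synonymous third-position edits are tried first; when an occurrence
    offers none, a base outside the protected center/flank codons is edited
    instead (protein updated, stop codons never introduced). Returns True
    when the window is clean.
    """
    motif = config.motif.upper()
    lo, hi = _window_bounds(anchor, config.flank_nt, len(seq))
    for _ in range(max_rounds):
        occ = _occurrences(seq, lo, hi, motif)
        if not occ:
            return True
        start, matched = occ[0]
        span = list(range(start, start + len(matched)))
        rng.shuffle(span)
        edited = False
        # pass 1: synonymous edit at any covered position
        for p in span:
            ci = (p - 1) // 3 + 1
            codon = "".join(seq[3 * (ci - 1) : 3 * ci])
            aa = _translate_codon(codon)
            offset = (p - 1) % 3
            for b in "ACGT":
                if b == codon[offset]:
                    continue
                cand = codon[:offset] + b + codon[offset + 1 :]
                if _translate_codon(cand) != aa:
                    continue
                seq[p - 1] = b
                if (start, matched) not in _occurrences(seq, lo, hi, motif):
                    edited = True
                    break
                seq[p - 1] = codon[offset]
            if edited:
                break
        if edited:
            continue
        # pass 2: non-synonymous edit outside the protected codons
        for p in span:
            ci = (p - 1) // 3 + 1
            if _protected(ci, center_codon, config.flank_aa):
                continue
            codon = "".join(seq[3 * (ci - 1) : 3 * ci])
            offset = (p - 1) % 3
            for b in "ACGT":
                if b == codon[offset]:
                    continue
                cand = codon[:offset] + b + codon[offset + 1 :]
                if _translate_codon(cand) == "*":
                    continue
                seq[p - 1] = b
                if (start, matched) not in _occurrences(seq, lo, hi, motif):
                    protein[ci - 1] = _translate_codon(cand)
                    edited = True
                    break
                seq[p - 1] = codon[offset]
            if edited:
                break
        if not edited:
            return False
    return not _occurrences(seq, lo, hi, motif)


def implant_variants(
    cds: list[CdsRecord],
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Plant two classes of variants with the configured contrasts.

    Variant sites are spaced so nucleotide windows and peptide flanks never
    overlap; flanking codons are resampled from the class's residue
    weights; the motif is planted (or scrubbed) per class probability; and
    carrier counts are drawn from ``carrier_range`` so the default support
    filter passes by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spacing = max(2 * config.flank_aa + 1, (2 * config.flank_nt) // 3 + 2) + 1
    margin = spacing
    slots: list[tuple[int, int]] = []
    for gi, record in enumerate(cds):
        n_res = len(record.protein)
        for pos in range(margin, n_res - margin + 1, spacing):
            slots.append((gi, pos))
    needed = 2 * config.n_variants_per_class
    if len(slots) < needed:
        raise ValueError(
            f"only {len(slots)} non-colliding variant sites available for {needed} "
            f"variants; increase n_genes or n_codons"
        )
    order = rng.permutation(len(slots))[:needed]
    assignments = [
        (slots[i], "disease" if k < config.n_variants_per_class else "benign")
        for k, i in enumerate(order)
    ]

    seqs = [list(r.sequence) for r in cds]
    proteins = [list(r.protein) for r in cds]
    weight_p = {
        "disease": _weights_vector(config.disease_weights),
        "benign": _weights_vector(config.benign_weights),
    }
    aa_array = np.array(list(AA_ORDER))
    p_plant = {"disease": config.p_motif_disease, "benign": config.p_motif_benign}

    entries = []
    for (gi, pos), cls in assignments:
        seq, protein = seqs[gi], proteins[gi]
        # resample the six flanking codons from the class composition
        flank_res = []
        for off in (-3, -2, -1, 1, 2, 3):
            if abs(off) > config.flank_aa:
                continue
            aa = str(rng.choice(aa_array, p=weight_p[cls]))
            codons = CODONS_FOR_AA[aa]
            codon = codons[rng.integers(0, len(codons))]
            ci = pos + off
            seq[3 * (ci - 1) : 3 * ci] = list(codon)
            protein[ci - 1] = aa
            flank_res.append(aa)
        anchor = 3 * (pos - 1) + 2  # middle base of the codon
        plant = bool(rng.random() < p_plant[cls])
        entries.append(
            {
                "gene_index": gi,
                "protein_pos": pos,
                "class": cls,
                "anchor": anchor,
                "plant": plant,
                "flank_residues": flank_res,
            }
        )

    # plant first, then scrub chance occurrences from unplanted windows
    for e in entries:
        if not e["plant"]:
            continue
        planted, synonymous = _try_plant(
            seqs[e["gene_index"]],
            proteins[e["gene_index"]],
            e["anchor"],
            e["protein_pos"],
            config,
            rng,
        )
        if not planted:
            raise ValueError(
                f"could not plant motif near GENE{e['gene_index'] + 1}:{e['protein_pos']}"
            )
        e["synonymous"] = synonymous
    for e in entries:
        if e["plant"]:
            continue
        clean = _scrub_window(
            seqs[e["gene_index"]],
            proteins[e["gene_index"]],
            e["anchor"],
            e["protein_pos"],
            config,
            rng,
        )
        if not clean:
            raise ValueError(
                f"could not scrub motif near GENE{e['gene_index'] + 1}:{e['protein_pos']}"
            )

    final_cds = [
        CdsRecord.from_sequence(r.gene_id, r.accession, "".join(seq))
        for r, seq in zip(cds, seqs)
    ]
    variants = []
    truth_entries = []
    lo_c, hi_c = config.carrier_range
    for e in entries:
        record = final_cds[e["gene_index"]]
        pos = e["protein_pos"]
        ref_aa = record.protein[pos - 1]
        alts = [aa for aa in AA_ORDER if aa != ref_aa]
        alt_aa = alts[rng.integers(0, len(alts))]
        source = ("allofus", "cosmic")[rng.integers(0, 2)]
        variants.append(
            VariantRecord(
                gene_id=record.gene_id,
                protein_pos=pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                cds_pos=e["anchor"],
                carrier_count=int(rng.integers(lo_c, hi_c + 1)),
                source=source,
                var_class=e["class"],
            )
        )
        truth_entries.append(
            {
                "gene_id": record.gene_id,
                "protein_pos": pos,
                "alt_aa": alt_aa,
                "source": source,
                "class": e["class"],
                "motif_planted": e["plant"],
                "synonymous": e.get("synonymous"),
                "flank_residues": e["flank_residues"],
            }
        )
    vs = VariantSet(
        variants=variants,
        provenance={"generator": "varcontext.simulate", "seed": config.seed},
    )
    truth = {
        "motif": config.motif.upper(),
        "p_motif_disease": config.p_motif_disease,
        "p_motif_benign": config.p_motif_benign,
        "seed": config.seed,
        "variants": truth_entries,
    }
    return SyntheticDataset(cds=final_cds, variants=vs, truth=truth)


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate coding sequences and implant variants under one seed."""
    rng = np.random.default_rng(config.seed)
    cds = generate_cds(config, rng)
    return implant_variants(cds, config, rng)


# ---------------------------------------------------------------------------
# ideal backbone geometry

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = np.deg2rad(111.2)
_ANGLE_CA_C_N = np.deg2rad(116.2)
_ANGLE_C_N_CA = np.deg2rad(121.7)

# inter-strand placement of the second strand of the antiparallel pair in
# the strand's principal-axis frame, frozen from a one-off grid search over
# the Kabsch-Sander inter-strand bond count (8 bonds, full ladder)
_STRAND_PAIR_SHIFT = (2.5, -4.25, 0.0)
_STRAND_PAIR_FLIP = (-1.0, -1.0, 1.0)

_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "extended": (-180.0, 180.0),
}


def _place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """NeRF placement of atom D from A-B-C internal coordinates (radians)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(angle),
            bond * np.cos(dihedral) * np.sin(angle),
            bond * np.sin(dihedral) * np.sin(angle),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_chain(n_residues: int, phi_deg: float, psi_deg: float) -> list[dict]:
    """Backbone N, CA, C, O coordinates of an ideal chain."""
    phi, psi = np.deg2rad(phi_deg), np.deg2rad(psi_deg)
    omega = np.pi
    residues: list[dict] = []
    n0 = np.zeros(3)
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    c0 = ca0 + _BOND_CA_C * np.array(
        [-np.cos(_ANGLE_N_CA_C), np.sin(_ANGLE_N_CA_C), 0.0]
    )
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for _ in range(1, n_residues):
        prev = residues[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, omega)
        c_next = _place_atom(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, res in enumerate(residues):
        if i + 1 < len(residues):
            u1 = res["C"] - res["CA"]
            u2 = res["C"] - residues[i + 1]["N"]
            u = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
            res["O"] = res["C"] + _BOND_C_O * u / np.linalg.norm(u)
        else:
            res["O"] = _place_atom(
                res["N"], res["CA"], res["C"], _BOND_C_O, np.deg2rad(120.5), psi + np.pi
            )
    return residues


def _chain_to_residues(
    chain: list[dict], start_index: int, radii: dict[str, float]
) -> list[Residue]:
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O"}
    out = []
    for i, res in enumerate(chain):
        atoms = [
            Atom(name, elements[name], np.array(res[name]), radii[elements[name]], 100.0)
            for name in ("N", "CA", "C", "O")
        ]
        out.append(Residue(index=start_index + i, name="ALA", atoms=atoms, plddt=100.0))
    return out


def build_ideal_coordinates(kind: str, n_residues: int) -> StructureModel:
    """Ideal poly-alanine backbone fixtures with known secondary structure.

    ``helix`` uses alpha-helical dihedrals (phi -57°, psi -47°; 1.5 Å rise,
    ~100° twist per residue follows from the geometry); ``strand_pair``
    builds two antiparallel beta strands of ``n_residues`` each, hydrogen
    bonded across the pair; ``extended`` is an isolated all-trans chain
    with no hydrogen bonds.
    """
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4")
    from varcontext.structure import vdw_radii

    radii = vdw_radii()
    if kind == "helix":
        chain = _build_chain(n_residues, *_DIHEDRALS["helix"])
        return StructureModel(_chain_to_residues(chain, 1, radii), name="ideal-helix")
    if kind == "extended":
        chain = _build_chain(n_residues, *_DIHEDRALS["extended"])
        return StructureModel(_chain_to_residues(chain, 1, radii), name="ideal-extended")
    if kind == "strand_pair":
        raw = _build_chain(n_residues, *_DIHEDRALS["strand"])
        # canonical frame: CA centroid at the origin, principal axes as the
        # coordinate axes with a fixed sign convention, so the frozen
        # inter-strand shift is meaningful for any strand length
        cas = np.array([r["CA"] for r in raw])
        centroid = cas.mean(axis=0)
        _, _, axes = np.linalg.svd(cas - centroid)
        for i in range(3):
            if axes[i, np.argmax(np.abs(axes[i]))] < 0:
                axes[i] = -axes[i]
        chain_a = [{k: axes @ (v - centroid) for k, v in r.items()} for r in raw]
        flip = np.diag(_STRAND_PAIR_FLIP)
        shift = np.array(_STRAND_PAIR_SHIFT)
        chain_b = [{k: flip @ v + shift for k, v in r.items()} for r in chain_a]
        residues = _chain_to_residues(chain_a, 1, radii)
        # index gap of 2 marks the chain break between the strands
        residues += _chain_to_residues(chain_b, n_residues + 3, radii)
        return StructureModel(residues, name="ideal-strand-pair")
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# fixture writers


def write_fasta(cds: list[CdsRecord], path) -> None:
    with open(path, "w") as fh:
        for r in cds:
            fh.write(f">{r.gene_id}|{r.accession}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def write_variant_tsv(vs: VariantSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tprotein_pos\tref_aa\talt_aa\tcds_pos\tcarrier_count\tsource\tvar_class\n"
        )
        for v in vs:
            cds_pos = "" if v.cds_pos is None else str(v.cds_pos)
            fh.write(
                f"{v.gene_id}\t{v.protein_pos}\t{v.ref_aa}\t{v.alt_aa}\t{cds_pos}\t"
                f"{v.carrier_count}\t{v.source}\t{v.var_class}\n"
            )


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_pdb(model: StructureModel, path) -> None:
    """Write a minimal single-chain PDB file (pLDDT in the B-factor field)."""
    with open(path, "w") as fh:
        serial = 1
        for res in model.residues:
            for atom in res.atoms:
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {name} {res.name:<3s} A{res.index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
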