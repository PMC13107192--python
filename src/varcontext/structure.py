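"""Structural localization of variant sites on predicted models.

Makes the qualitative structural reading of variants computable:

* three-state secondary structure (helix / strand / coil-linker) from
  backbone hydrogen bonds detected with the Kabsch–Sander electrostatic
  criterion (a bond when the dipole interaction energy is below
  -0.5 kcal/mol);
* solvent accessibility by the Shrake–Rupley rolling-probe point method,
  normalized by per-residue theoretical maximum areas to a relative solvent
  accessibility (RSA), with interior/surface at RSA 0.25;
* element position: a variant in a coil element is in a *linker*; inside a
  helix or strand it is at the *boundary* when within ``boundary_width``
  residues of the element's ends, otherwise in the *middle*.

Predicted-model confidence (pLDDT, stored in the B-factor field) is carried
through per site but never used as a filter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from varcontext.io import VariantRecord

logger = logging.getLogger(__name__)

BACKBONE = ("N", "CA", "C", "O")

# Kabsch-Sander constants: E = q1*q2*332*(1/rON + 1/rCH - 1/rOH - 1/rCN)
_KS_FACTOR = 0.084 * 332.0
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol

THREE_FROM_ONE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
ONE_FROM_THREE = {v: k for k, v in THREE_FROM_ONE.items()}


def _load_tsv_map(filename: str, key: str, value: str) -> dict[str, float]:
    source = resources.files("varcontext.data").joinpath(filename)
    with source.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return {row[key].upper(): float(row[value]) for row in reader}


def vdw_radii() -> dict[str, float]:
    """Bundled element -> van der Waals radius (Å) table."""
    return _load_tsv_map("vdw_radii.tsv", "element", "radius")


def max_asa_table() -> dict[str, float]:
    """Bundled residue -> theoretical maximum ASA (Å²) table."""
    return _load_tsv_map("max_asa.tsv", "residue", "max_asa")


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) Å
    radius: float
    bfactor: float = 0.0


@dataclass
class Residue:
    """One residue of a single-chain model, 1-based sequence index."""

    index: int
    name: str  # three-letter code
    atoms: list[Atom] = field(default_factory=list)
    complete: bool = True  # all four backbone atoms present
    plddt: float = 0.0

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return ONE_FROM_THREE.get(self.name, "X")


@dataclass
class StructureModel:
    """A single protein chain with coordinates and per-residue confidence."""

    residues: list[Residue] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    def all_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A rigid-body transformed copy (for frame-invariance checks)."""
        out = []
        for r in self.residues:
            atoms = [
                Atom(a.name, a.element, rotation @ a.coord + translation, a.radius, a.bfactor)
                for a in r.atoms
            ]
            out.append(Residue(r.index, r.name, atoms, r.complete, r.plddt))
        return StructureModel(residues=out, name=self.name)


@dataclass(frozen=True)
class SsElement:
    """A maximal run of one secondary-structure state along the chain."""

    state: str  # "H" | "E" | "C"
    start: int  # residue index, inclusive
    end: int

    def __post_init__(self) -> None:
        if self.state not in ("H", "E", "C"):
            raise ValueError(f"invalid state {self.state!r}")
        if self.start > self.end:
            raise ValueError("element start > end")

    def __contains__(self, index: int) -> bool:
        return self.start <= index <= self.end


@dataclass
class StructuralAnnotation:
    """Per-variant structural context."""

    variant_key: tuple
    ss_state: str
    element_position: str  # "linker" | "boundary" | "middle"
    rsa: float
    burial: str  # "interior" | "surface"
    confidence: float


def parse_structure(path) -> StructureModel:
    """Read a single-chain PDB or mmCIF model into a :class:`StructureModel`.

    Residues missing any of the four backbone atoms are flagged incomplete.
    Per-residue confidence is taken from the CA B-factor (predicted-model
    dialect: pLDDT lives in the B-factor column). Van der Waals radii are
    assigned per element from the bundled table.
    """
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: unreadable structure file: {exc}") from None
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no model/chain found")
    chain = st[0][0]
    radii = vdw_radii()
    residues: list[Residue] = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if res.name not in ONE_FROM_THREE and not (info and info.is_amino_acid()):
            continue
        atoms = []
        for at in res:
            element = at.element.name.upper()
            radius = radii.get(element)
            if radius is None:
                logger.warning("unknown element %s; using 1.8 Å radius", element)
                radius = 1.8
            atoms.append(
                Atom(
                    name=at.name,
                    element=element,
                    coord=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                    radius=radius,
                    bfactor=at.b_iso,
                )
            )
        residue = Residue(index=res.seqid.num, name=res.name, atoms=atoms)
        residue.complete = all(residue.atom(n) is not None for n in BACKBONE)
        if not residue.complete:
            logger.warning("residue %s%d missing backbone atoms", res.name, res.seqid.num)
        ca = residue.atom("CA")
        residue.plddt = ca.bfactor if ca is not None else (atoms[0].bfactor if atoms else 0.0)
        residues.append(residue)
    if not residues:
        raise ValueError(f"{path}: no amino-acid residues parsed")
    return StructureModel(residues=residues, name=str(path))


# ---------------------------------------------------------------------------
# hydrogen bonds and secondary structure


def _backbone_arrays(model: StructureModel):
    """Coordinates of N, CA, C, O and the DSSP-style amide H per residue.

    The amide hydrogen of residue i is placed 1.0 Å from N along the
    direction of the previous residue's C=O bond (C minus O, normalized);
    the first residue and residues after a chain break have no donor H.
    Residues with incomplete backbones are masked out.
    """
    n = len(model.residues)
    coords = {name: np.full((n, 3), np.nan) for name in BACKBONE}
    ok = np.zeros(n, dtype=bool)
    for i, r in enumerate(model.residues):
        if not r.complete:
            continue
        ok[i] = True
        for name in BACKBONE:
            coords[name][i] = r.atom(name).coord
    h = np.full((n, 3), np.nan)
    idx = [r.index for r in model.residues]
    for i in range(1, n):
        if not (ok[i] and ok[i - 1]):
            continue
        if idx[i] != idx[i - 1] + 1:
            continue  # chain break: no peptide bond, no amide H
        co = coords["C"][i - 1] - coords["O"][i - 1]
        norm = np.linalg.norm(co)
        if norm == 0:
            continue
        h[i] = coords["N"][i] + co / norm
    return coords, h, ok


def hbond_energy(
    n_d: np.ndarray, h_d: np.ndarray, c_a: np.ndarray, o_a: np.ndarray
) -> float:
    """Kabsch–Sander dipole energy (kcal/mol) of one donor→acceptor pair."""
    r_on = np.linalg.norm(o_a - n_d)
    r_ch = np.linalg.norm(c_a - h_d)
    r_oh = np.linalg.norm(o_a - h_d)
    r_cn = np.linalg.norm(c_a - n_d)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return 0.0  # clashing geometry, not a hydrogen bond
    return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def backbone_hbonds(model: StructureModel) -> np.ndarray:
    """Boolean matrix ``hb[d, a]``: NH of residue d donates to C=O of a.

    Pairs closer than 2 in sequence are excluded, as are donors without a
    defined amide hydrogen.
    """
    coords, h, ok = _backbone_arrays(model)
    n = len(model.residues)
    hb = np.zeros((n, n), dtype=bool)
    has_h = ~np.isnan(h[:, 0])
    # CA-CA prefilter: Kabsch-Sander bonds never span more than ~7 Å
    ca = coords["CA"]
    for d in range(n):
        if not has_h[d]:
            continue
        for a in range(n):
            if not ok[a] or abs(d - a) < 2:
                continue
            if np.linalg.norm(ca[d] - ca[a]) > 9.0:
                continue
            e = hbond_energy(coords["N"][d], h[d], coords["C"][a], coords["O"][a])
            if e < HBOND_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def _helix_mask(hb: np.ndarray) -> np.ndarray:
    """Helical residues: centers of i→i+4 turns in runs of >=2 turns.

    A 4-turn at i means the C=O of residue i accepts the NH of residue i+4.
    Maximal runs of consecutive turns i1..i2 (run length >= 2) mark residues
    i1+2 .. i2+2 — the central residues of the hydrogen-bonded turns — as
    helix. An isolated single turn marks nothing.
    """
    n = hb.shape[0]
    turns = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb[i + 4, i]:
            turns[i] = True
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if turns[i]:
            j = i
            while j + 1 < n and turns[j + 1]:
                j += 1
            if j > i:  # run of at least two consecutive turns
                mask[i + 2 : j + 3] = True
            i = j + 1
        else:
            i += 1
    return mask


def _bridge_pairs(hb: np.ndarray) -> list[tuple[int, int]]:
    """Kabsch–Sander bridges (i, j), i < j, |i-j| >= 3.

    ``A(i, j)`` below: C=O of i accepts NH of j. Parallel bridge:
    [A(i-1, j) and A(j, i+1)] or [A(j-1, i) and A(i, j+1)]; antiparallel:
    [A(i, j) and A(j, i)] or [A(i-1, j+1) and A(j-1, i+1)].
    """
    n = hb.shape[0]

    def A(i: int, j: int) -> bool:
        if not (0 <= i < n and 0 <= j < n):
            return False
        return hb[j, i]

    pairs = []
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (A(i - 1, j) and A(j, i + 1)) or (A(j - 1, i) and A(i, j + 1))
            antiparallel = (A(i, j) and A(j, i)) or (A(i - 1, j + 1) and A(j - 1, i + 1))
            if parallel or antiparallel:
                pairs.append((i, j))
    return pairs


def _strand_mask(hb: np.ndarray) -> np.ndarray:
    """Strand residues: members of bridges extended into ladders.

    Two bridges (i, j) and (i±1, j∓1) or (i±1, j±1) are consecutive; every
    bridge that has a consecutive partner (a ladder of length >= 2)
    contributes both its residues; an isolated bridge is left as coil.
    """
    n = hb.shape[0]
    pairs = _bridge_pairs(hb)
    pair_set = set(pairs)
    mask = np.zeros(n, dtype=bool)
    for i, j in pairs:
        neighbours = [
            (i + 1, j - 1), (i - 1, j + 1),  # antiparallel ladder
            (i + 1, j + 1), (i - 1, j - 1),  # parallel ladder
        ]
        if any((min(p), max(p)) in pair_set for p in neighbours):
            mask[i] = mask[j] = True
    return mask


def assign_secondary_structure(model: StructureModel) -> list[SsElement]:
    """Three-state assignment (H/E/C) merged into maximal elements.

    Helix takes precedence over strand where both criteria fire. The
    returned elements are non-overlapping and cover every residue of the
    chain.
    """
    if not any(r.complete for r in model.residues):
        raise ValueError("no residue with a complete backbone")
    hb = backbone_hbonds(model)
    helix = _helix_mask(hb)
    strand = _strand_mask(hb)
    states = []
    for i in range(len(model.residues)):
        if helix[i]:
            states.append("H")
        elif strand[i]:
            states.append("E")
        else:
            states.append("C")
    elements: list[SsElement] = []
    idx = [r.index for r in model.residues]
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start] or idx[i] != idx[i - 1] + 1:
            elements.append(SsElement(state=states[start], start=idx[start], end=idx[i - 1]))
            start = i
    return elements


# ---------------------------------------------------------------------------
# solvent accessibility


def _sphere_points(n_points: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def shrake_rupley_asa(
    model: StructureModel, probe: float = 1.4, n_points: int = 960
) -> tuple[np.ndarray, dict[int, float]]:
    """Accessible surface area by the Shrake–Rupley point method.

    Each atom's sphere is expanded by the probe radius and sampled with
    ``n_points`` test points; a point is accessible when it lies outside
    every neighbouring atom's expanded sphere. Returns the per-atom ASA
    array (Å², atom order of :meth:`StructureModel.all_atoms`) and the
    per-residue sums keyed by residue index.
    """
    if n_points < 12:
        raise ValueError(f"n_points must be >= 12, got {n_points}")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    atoms = model.all_atoms()
    if not atoms:
        raise ValueError("model has no atoms")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.radius for a in atoms]) + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    asa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbours = [
            j
            for j in tree.query_ball_point(coords[i], max_reach)
            if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        points = coords[i] + radii[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        asa[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.sum() / n_points
    per_residue: dict[int, float] = {}
    k = 0
    for r in model.residues:
        per_residue[r.index] = float(asa[k : k + len(r.atoms)].sum())
        k += len(r.atoms)
    return asa, per_residue


def classify_burial(
    residue_asa: float, residue_name: str, rsa_cutoff: float = 0.25
) -> tuple[float, str]:
    """Relative solvent accessibility and interior/surface call.

    RSA = ASA / maxASA(residue type), clipped to [0, 1]; *interior* below
    the cutoff (default 0.25, a standard burial threshold), *surface* at or
    above it.
    """
    table = max_asa_table()
    name = residue_name.upper()
    if len(name) == 1:
        name = THREE_FROM_ONE.get(name, name)
    if name not in table:
        raise ValueError(f"unknown residue type {residue_name!r}")
    rsa = residue_asa / table[name]
    if rsa > 1.0:
        logger.warning("RSA %.2f > 1 for %s; clipping", rsa, residue_name)
        rsa = 1.0
    rsa = max(0.0, rsa)
    return rsa, ("interior" if rsa < rsa_cutoff else "surface")


def classify_variant_site(
    variant: VariantRecord | int, elements: list[SsElement], boundary_width: int = 2
) -> str:
    """Linker / boundary / middle position of a variant within its element.

    A site in a coil element is *linker*. In a helix or strand element it
    is *boundary* when within ``boundary_width`` residues of either element
    end, otherwise *middle*.
    """
    pos = variant.protein_pos if isinstance(variant, VariantRecord) else int(variant)
    for el in elements:
        if pos in el:
            if el.state == "C":
                return "linker"
            if pos - el.start <= boundary_width or el.end - pos <= boundary_width:
                return "boundary"
            return "middle"
    raise ValueError(f"residue index {pos} not covered by the element list")


def annotate_variants(
    vs,
    model: StructureModel,
    boundary_width: int = 2,
    rsa_cutoff: float = 0.25,
    probe: float = 1.4,
    n_points: int = 960,
    residue_offset: int = 0,
) -> list[StructuralAnnotation]:
    """Full structural annotation of each variant against one model.

    ``residue_offset`` maps protein positions to model numbering (model
    index = protein_pos + offset) for trimmed models; the default assumes
    full-length numbering.
    """
    elements = assign_secondary_structure(model)
    _, res_asa = shrake_rupley_asa(model, probe=probe, n_points=n_points)
    by_index = {r.index: r for r in model.residues}
    annotations = []
    for v in vs:
        idx = v.protein_pos + residue_offset
        if idx not in by_index:
            raise ValueError(f"{v.label}: residue {idx} not in structure model")
        residue = by_index[idx]
        position = classify_variant_site(idx, elements, boundary_width=boundary_width)
        state = next(el.state for el in elements if idx in el)
        rsa, burial = classify_burial(res_asa[idx], residue.name, rsa_cutoff=rsa_cutoff)
        annotations.append(
            StructuralAnnotation(
                variant_key=v.key,
                ss_state=state,
                element_position=position,
                rsa=rsa,
                burial=burial,
                confidence=residue.plddt,
            )
        )
    return annotations


def summarize_structure_by_class(
    annotations: list[StructuralAnnotation], classes: dict[tuple, str]
):
    """Per-class contingency of element position × burial.

    ``classes`` maps variant keys to class labels. Returns a DataFrame with
    counts and within-class fractions for each (class, element_position,
    burial) cell.
    """
    import pandas as pd

    rows = []
    for ann in annotations:
        cls = classes.get(ann.variant_key)
        if cls is None:
            raise ValueError(f"annotation with unknown variant key {ann.variant_key}")
        rows.append(
            {
                "class": cls,
                "element_position": ann.element_position,
                "burial": ann.burial,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["class", "element_position", "burial", "count", "fraction"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["class", "element_position", "burial"], sort=True)
        .size()
        .reset_index(name="count")
    )
    totals = counts.groupby("class")["count"].transform("sum")
    counts["fraction"] = (counts["count"] / totals).round(6)
    return counts
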