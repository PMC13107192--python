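"""Pipeline orchestration: validate, filter, scan, tabulate, annotate, write.

`run_pipeline` composes the stages — sequence/variant IO and filtering,
nucleotide-window motif scanning, flanking-residue combination tables and
(when structure models are supplied) structural annotation — and writes
every tabular output plus a JSON run summary. All randomness in a run flows
through the single seed recorded in the config, and outputs are written in
deterministic order so identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from varcontext import io as vio
from varcontext import motifs as vmotifs
from varcontext import patterns as vpatterns
from varcontext import structure as vstructure

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, parameters and output location of one pipeline run."""

    cds_fasta: str
    variant_table: str
    out_dir: str
    motif_table: str | None = None  # None -> bundled default table
    structure_dir: str | None = None  # PDB/mmCIF files named <gene_id>.<ext>
    classification_table: str | None = None
    flank_nt: int = 20
    flank_aa: int = 3
    min_carriers: int = 20
    boundary_width: int = 2
    rsa_cutoff: float = 0.25
    forward_only: bool = False
    mutant_seq: bool = False
    anchor_mode: str = "auto"
    seed: int = 0

    def resolve(self) -> None:
        for name in ("cds_fasta", "variant_table", "motif_table", "classification_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")
        if self.structure_dir is not None and not Path(self.structure_dir).is_dir():
            raise FileNotFoundError(f"structure_dir: {self.structure_dir}")


def write_upset_matrix(partition, path=None) -> pd.DataFrame:
    """Binary membership matrix (item × class presence), sorted by item.

    Accepts a :class:`~varcontext.motifs.ClassMotifPartition` or a
    ``(exclusive_disease, exclusive_benign, shared)`` triple of key sets.
    Exclusive rows sum to 1, shared rows to 2.
    """
    if isinstance(partition, tuple):
        excl_d, excl_b, shared = partition
    else:
        excl_d = partition.exclusive_disease
        excl_b = partition.exclusive_benign
        shared = partition.shared
    rows = []
    for item in sorted(excl_d | excl_b | shared):
        rows.append(
            {
                "item": item,
                "disease": int(item in excl_d or item in shared),
                "benign": int(item in excl_b or item in shared),
            }
        )
    df = pd.DataFrame(rows, columns=["item", "disease", "benign"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def _hits_frame(hits) -> pd.DataFrame:
    rows = [
        {
            "gene_id": h.gene_id,
            "protein_pos": h.variant_key[1],
            "alt_aa": h.variant_key[2],
            "source": h.variant_key[3],
            "motif": h.motif,
            "strand": h.strand,
            "window_offset": h.offset,
            "cds_start": h.abs_start,
            "matched": h.matched,
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "protein_pos",
            "alt_aa",
            "source",
            "motif",
            "strand",
            "window_offset",
            "cds_start",
            "matched",
        ],
    )
    return df.sort_values(list(df.columns)).reset_index(drop=True)


def _partition_frame(partition) -> pd.DataFrame:
    rows = []
    for motif in sorted(partition.all_motifs):
        if motif in partition.exclusive_disease:
            membership = "exclusive_disease"
        elif motif in partition.exclusive_benign:
            membership = "exclusive_benign"
        else:
            membership = "shared"
        counts = partition.counts.get(motif, {"disease": 0, "benign": 0})
        rows.append(
            {
                "motif": motif,
                "membership": membership,
                "disease_variants": counts["disease"],
                "benign_variants": counts["benign"],
            }
        )
    return pd.DataFrame(
        rows, columns=["motif", "membership", "disease_variants", "benign_variants"]
    )


def _annotation_frame(annotations) -> pd.DataFrame:
    rows = [
        {
            "gene_id": a.variant_key[0],
            "protein_pos": a.variant_key[1],
            "alt_aa": a.variant_key[2],
            "source": a.variant_key[3],
            "ss_state": a.ss_state,
            "element_position": a.element_position,
            "rsa": round(a.rsa, 6),
            "burial": a.burial,
            "plddt": a.confidence,
        }
        for a in annotations
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "protein_pos",
            "alt_aa",
            "source",
            "ss_state",
            "element_position",
            "rsa",
            "burial",
            "plddt",
        ],
    )
    return df.sort_values(["gene_id", "protein_pos", "alt_aa", "source"]).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the full output set.

    Outputs under ``config.out_dir``: hits.tsv, motif_partition.tsv,
    upset_motifs.tsv, aa_patterns_k{1,2,3}.tsv, structure_annotations.tsv
    and structure_summary.tsv (when structures are given), run_summary.json
    and run.log. Returns the run summary.
    """
    config.resolve()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    for key, value in sorted(asdict(config).items()):
        log(f"param {key} = {value}")

    cds = vio.read_cds_fasta(config.cds_fasta)
    log(f"stage seqvar_io: {len(cds)} coding sequences")
    vs = vio.read_variant_table(config.variant_table)
    n_parsed = len(vs)
    log(f"stage seqvar_io: {n_parsed} variants parsed, "
        f"{len(vs.provenance.get('rows_rejected', []))} rows rejected")
    if config.classification_table:
        vs = vio.merge_classifications(vs, config.classification_table)
        log("stage seqvar_io: classifications merged")
    vs, report = vio.validate_variants(vs, cds)
    log(f"stage seqvar_io: {len(report)} variants excluded by validation, {len(vs)} retained")
    n_before = len(vs)
    vs = vio.filter_by_support(vs, config.min_carriers)
    n_support_excluded = n_before - len(vs)
    assert n_before == len(vs) + n_support_excluded
    log(
        f"stage seqvar_io: support filter (>= {config.min_carriers}) removed "
        f"{n_support_excluded}, retained {len(vs)}"
    )
    disease, benign = vio.partition_by_class(vs)
    n_unknown = len(vs) - len(disease) - len(benign)
    log(
        f"stage seqvar_io: class partition disease={len(disease)} benign={len(benign)} "
        f"unknown_dropped={n_unknown}"
    )
    classified = vio.VariantSet(
        variants=list(disease) + list(benign), provenance=dict(vs.provenance)
    )

    motifs = vmotifs.load_motif_table(config.motif_table)
    hits = vmotifs.sites_near_variants(
        classified,
        cds,
        motifs,
        flank=config.flank_nt,
        both_strands=not config.forward_only,
        anchor_mode=config.anchor_mode,
        use_mutant=config.mutant_seq,
    )
    partition = vmotifs.partition_hits_by_class(hits, disease, benign)
    _hits_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    _partition_frame(partition).to_csv(out / "motif_partition.tsv", sep="\t", index=False)
    write_upset_matrix(partition, out / "upset_motifs.tsv")
    log(
        f"stage motif_scan: {len(hits)} hits, {len(partition.all_motifs)} motifs with >=1 hit "
        f"(exclusive_disease={len(partition.exclusive_disease)}, "
        f"exclusive_benign={len(partition.exclusive_benign)}, shared={len(partition.shared)})"
    )

    pattern_tallies = {}
    for k in (1, 2, 3):
        dt = vpatterns.tabulate_patterns(disease, cds, k, flank=config.flank_aa)
        bt = vpatterns.tabulate_patterns(benign, cds, k, flank=config.flank_aa)
        frame = vpatterns.pattern_table_frame(dt, bt)
        frame.to_csv(out / f"aa_patterns_k{k}.tsv", sep="\t", index=False)
        pattern_tallies[f"k{k}_combinations"] = int(len(frame))
        log(f"stage aa_patterns: k={k}, {len(frame)} combinations")

    structure_tallies = {}
    if config.structure_dir:
        annotations = []
        classes = {}
        for v in classified:
            classes[v.key] = v.var_class
        by_gene: dict[str, list] = {}
        for v in classified:
            by_gene.setdefault(v.gene_id, []).append(v)
        for gene_id in sorted(by_gene):
            model_path = None
            for ext in (".pdb", ".cif", ".mmcif"):
                cand = Path(config.structure_dir) / f"{gene_id}{ext}"
                if cand.exists():
                    model_path = cand
                    break
            if model_path is None:
                log(f"stage structure_context: no model for {gene_id}, skipped")
                continue
            model = vstructure.parse_structure(model_path)
            annotations.extend(
                vstructure.annotate_variants(
                    by_gene[gene_id],
                    model,
                    boundary_width=config.boundary_width,
                    rsa_cutoff=config.rsa_cutoff,
                )
            )
        _annotation_frame(annotations).to_csv(
            out / "structure_annotations.tsv", sep="\t", index=False
        )
        summary = vstructure.summarize_structure_by_class(annotations, classes)
        summary.to_csv(out / "structure_summary.tsv", sep="\t", index=False)
        structure_tallies = {"variants_annotated": len(annotations)}
        log(f"stage structure_context: {len(annotations)} variants annotated")

    run_summary = {
        "inputs": {
            "cds_fasta": str(config.cds_fasta),
            "variant_table": str(config.variant_table),
            "n_cds": len(cds),
            "n_variants_parsed": n_parsed,
        },
        "attrition": {
            "validation_excluded": len(report),
            "support_excluded": n_support_excluded,
            "unknown_class_dropped": n_unknown,
            "disease": len(disease),
            "benign": len(benign),
        },
        "motif_scan": {
            "n_motifs": len(motifs),
            "n_hits": len(hits),
            "exclusive_disease": sorted(partition.exclusive_disease),
            "exclusive_benign": sorted(partition.exclusive_benign),
            "shared": sorted(partition.shared),
        },
        "aa_patterns": pattern_tallies,
        "structure": structure_tallies,
        "seed": config.seed,
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return run_summary
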