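"""Pipeline orchestration: run the stages in dependency order and merge
their per-gene outputs into one family report (one row per input protein;
stages that cannot run leave their columns empty, rows are never dropped).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .domain_annotator import DomainAnnotation, annotate_domain
from .dimerization import dimer_summary_table
from .duplication import (
    block_table,
    chain_collinear_anchors,
    classify_duplication,
    event_table,
    ranks_from_models,
)
from .expression import differential_call, expressed_genes, highly_expressed
from .gene_structure import classify_intron_pattern, intron_pattern_table
from .io_formats import read_fasta, read_gff3, read_pairs_tsv, write_table

logger = logging.getLogger("bzipscan")


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: dict, outdir: str | Path) -> pd.DataFrame:
    """Run every stage the config enables; returns the merged family report.

    ``config`` keys: ``proteins`` (FASTA, required), optional ``gff``,
    ``pairs``, ``fpkm``, ``drought``, and parameter overrides
    (``min_anchors``, ``max_gap``, ``tandem_max_gap``, ``min_fc``,
    ``min_fpkm``, ``expressed_threshold``, ``high_threshold``).
    """
    if "proteins" not in config:
        raise PipelineError("config must name a protein FASTA under 'proteins'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = read_fasta(config["proteins"])
    report = pd.DataFrame({"protein_id": [rec.id for rec in records]})
    params = {k: v for k, v in config.items() if not isinstance(v, (dict, list))}

    logger.info("stage annotate: %d proteins", len(records))
    annotations: list[DomainAnnotation] = []
    ann_rows = []
    for rec in records:
        ann = annotate_domain(rec)
        if ann is None:
            continue
        annotations.append(ann)
        ann_rows.append(annotation_row(ann))
    ann_df = pd.DataFrame(ann_rows, columns=ANNOTATION_COLUMNS)
    write_table(ann_df, outdir / "annotations.tsv", params)
    report = report.merge(ann_df, on="protein_id", how="left")

    logger.info("stage classify")
    from .specificity import classify_proteome

    groups_df, counts = classify_proteome(annotations, records)
    write_table(groups_df, outdir / "groups.tsv", params)
    report = report.merge(
        groups_df[["protein_id", "group", "binding_site"]], on="protein_id", how="left"
    )

    logger.info("stage dimerize")
    dimer_df = dimer_summary_table(annotations)
    write_table(dimer_df, outdir / "dimer.tsv", params)
    report = report.merge(
        dimer_df[["protein_id", "asn_a_count", "propensity"]],
        on="protein_id",
        how="left",
    )

    models = None
    if config.get("gff"):
        logger.info("stage introns")
        models = read_gff3(config["gff"])
        model_of = {m.gene_id: m for m in models}
        length_of = {rec.id: len(rec) for rec in records}
        patterns = []
        for ann in annotations:
            model = model_of.get(ann.protein_id)
            if model is None or not model.valid:
                continue
            patterns.append(
                classify_intron_pattern(model, ann, length_of[ann.protein_id])
            )
        introns_df = intron_pattern_table(patterns)
        write_table(introns_df, outdir / "introns.tsv", params)
        report = report.merge(
            introns_df[["gene_id", "pattern_type"]].rename(
                columns={"gene_id": "protein_id"}
            ),
            on="protein_id",
            how="left",
        )

    if config.get("pairs"):
        if models is None:
            raise PipelineError("duplication stage requires 'gff' for gene ranks")
        logger.info("stage duplications")
        gene_ranks = ranks_from_models(models)
        pairs = read_pairs_tsv(config["pairs"], known_ids=set(gene_ranks))
        blocks = chain_collinear_anchors(
            pairs,
            gene_ranks,
            min_anchors=config.get("min_anchors", 5),
            max_gap=config.get("max_gap", 25),
        )
        events = classify_duplication(
            pairs, blocks, gene_ranks, tandem_max_gap=config.get("tandem_max_gap", 1)
        )
        write_table(block_table(blocks), outdir / "blocks.tsv", params)
        events_df = event_table(events)
        write_table(events_df, outdir / "events.tsv", params)
        dup_label = {}
        for e in events:
            for gene in e.pair:
                dup_label.setdefault(gene, e.label)
        report["duplication"] = report["protein_id"].map(dup_label)

    if config.get("fpkm"):
        logger.info("stage expression")
        fpkm = pd.read_csv(config["fpkm"], sep="\t", index_col=0)
        sets = expressed_genes(fpkm, config.get("expressed_threshold", 1.0))
        high, preferential = highly_expressed(fpkm, config.get("high_threshold", 20.0))
        report["expressed_any"] = report["protein_id"].isin(sets["any_tissue"])
        report["expressed_all"] = report["protein_id"].isin(sets["all_tissues"])
        high_in = {
            g: ";".join(sorted(t for t, genes in high.items() if g in genes))
            for g in fpkm.index
        }
        report["high_tissues"] = report["protein_id"].map(high_in)
        if config.get("drought"):
            drought = pd.read_csv(config["drought"], sep="\t", index_col=0)
            for tissue in ("root", "leaf"):
                ctrl, trt = f"{tissue}_control", f"{tissue}_drought"
                if ctrl in drought.columns and trt in drought.columns:
                    calls = differential_call(
                        drought[ctrl],
                        drought[trt],
                        min_fc=config.get("min_fc", 2.0),
                        min_fpkm=config.get("min_fpkm", 1.0),
                    )
                    report[f"drought_{tissue}"] = report["protein_id"].map(calls)

    write_table(report, outdir / "family_report.tsv", params)
    return report


ANNOTATION_COLUMNS = [
    "protein_id", "basic_start", "basic_end", "n_pos", "rk_pos",
    "hinge_start", "hinge_end", "zipper_start", "n_heptads",
    "heptad_string", "d_residues",
]


def annotation_row(ann: DomainAnnotation) -> dict:
    return {
        "protein_id": ann.protein_id,
        "basic_start": ann.basic.basic_start,
        "basic_end": ann.basic.basic_end,
        "n_pos": ann.basic.n_pos,
        "rk_pos": ann.basic.rk_pos,
        "hinge_start": ann.hinge_start,
        "hinge_end": ann.hinge_end,
        "zipper_start": ann.zipper_start,
        "n_heptads": ann.n_heptads,
        "heptad_string": "|".join(
            "".join(sorted(h.residues, key="gabcdef".index)) for h in ann.heptads
        ),
        "d_residues": ann.d_residues,
    }
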