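"""Intron typing within the bZIP basic+hinge region and splice-phase labels.

Splice-phase naming: P0, P1 and P2 denote splicing after the third,
second and first nucleotide of a codon respectively.  This is the *inverse* of the
classical intron-phase naming, and equals the GFF3 phase value of the
CDS segment downstream of the intron (P0<->0, P1<->1, P2<->2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .domain_annotator import DomainAnnotation
from .io_formats import GeneModel

PHASES = ("P0", "P1", "P2")
PATTERN_TYPES = ("type1_no_intron", "type2_hinge", "type3_basic", "type4_both")


@dataclass
class IntronPattern:
    gene_id: str
    pattern_type: str
    # (region, phase, coding_offset) for each intra-domain intron
    introns: list[tuple[str, str, int]] = field(default_factory=list)
    atypical: bool = False


def cds_to_protein_length(cds_len: int) -> int:
    """Protein length encoded by a complete CDS (terminal stop excluded)."""
    if cds_len < 6:
        raise ValueError(f"CDS length {cds_len} too short for start + stop codons")
    if cds_len % 3 != 0:
        raise ValueError(f"CDS length {cds_len} not divisible by 3")
    return cds_len // 3 - 1


def protein_interval_to_coding_nt(
    start_res: int, end_res: int, protein_length: int | None = None
) -> tuple[int, int]:
    """Map a 1-based residue interval to its coding-nucleotide interval.

    Residue r occupies coding nucleotides 3r-2 .. 3r.
    """
    if start_res < 1 or end_res < start_res:
        raise ValueError(f"invalid residue interval {start_res}..{end_res}")
    if protein_length is not None and end_res > protein_length:
        raise ValueError(
            f"residue {end_res} beyond protein length {protein_length}"
        )
    return 3 * start_res - 2, 3 * end_res


def coding_breakpoints(model: GeneModel) -> list[int]:
    """Cumulative coding-nucleotide offsets upstream of each intron."""
    breaks = []
    c = 0
    for start, end in model.cds_segments[:-1]:
        c += end - start + 1
        breaks.append(c)
    return breaks


def intron_phase(model: GeneModel, intron_index: int) -> str:
    """Phase label of one intron (0-based index, in translation order)."""
    if not model.valid:
        raise ValueError(f"gene model {model.gene_id} flagged invalid")
    breaks = coding_breakpoints(model)
    if not 0 <= intron_index < len(breaks):
        raise ValueError(
            f"gene {model.gene_id}: intron index {intron_index} out of range "
            f"(model has {len(breaks)} introns)"
        )
    return phase_label(breaks[intron_index])


def phase_label(coding_offset: int) -> str:
    """P0/P1/P2 label from the coding-nucleotide count upstream of a splice."""
    rem = coding_offset % 3
    return {0: "P0", 2: "P1", 1: "P2"}[rem]


def _region_contains(coding_offset: int, start_res: int, end_res: int) -> bool:
    # half-open in nucleotides: a boundary splice (after the last nt of the
    # preceding region) is assigned to the downstream region
    return 3 * (start_res - 1) <= coding_offset <= 3 * end_res - 1


def classify_intron_pattern(
    model: GeneModel, annotation: DomainAnnotation, protein_length: int
) -> IntronPattern:
    """Type the intra-domain (basic + hinge) intron pattern of one gene.

    Introns falling outside the basic and hinge residue intervals are
    ignored for typing.  More than two intra-domain introns, or two in
    the same region, are flagged atypical.
    """
    model_protein_len = cds_to_protein_length(model.cds_length)
    if model_protein_len != protein_length:
        raise ValueError(
            f"gene {model.gene_id}: CDS encodes {model_protein_len} aa but protein "
            f"{annotation.protein_id} has {protein_length} aa"
        )
    basic_span = (annotation.basic.basic_start, annotation.basic.basic_end)
    hinge_span = (annotation.hinge_start, annotation.hinge_end)
    introns: list[tuple[str, str, int]] = []
    for c in coding_breakpoints(model):
        if _region_contains(c, *basic_span):
            introns.append(("basic", phase_label(c), c))
        elif hinge_span[1] >= hinge_span[0] and _region_contains(c, *hinge_span):
            introns.append(("hinge", phase_label(c), c))
    regions = Counter(region for region, _, _ in introns)
    atypical = False
    if not introns:
        pattern = "type1_no_intron"
    elif regions == Counter({"hinge": 1}):
        pattern = "type2_hinge"
    elif regions == Counter({"basic": 1}):
        pattern = "type3_basic"
    elif regions == Counter({"basic": 1, "hinge": 1}):
        pattern = "type4_both"
    else:
        pattern = "atypical"
        atypical = True
    return IntronPattern(
        gene_id=model.gene_id, pattern_type=pattern, introns=introns, atypical=atypical
    )


def intron_count_stats(
    models: list[GeneModel], group_calls: dict[str, str] | None = None
) -> tuple[dict[int, int], pd.DataFrame | None]:
    """Histogram of CDS intron counts, plus per-group intronless fractions.

    The second element is None unless ``group_calls`` (gene id -> group
    label) is supplied.
    """
    histogram = dict(sorted(Counter(m.n_introns for m in models).items()))
    per_group = None
    if group_calls is not None:
        rows = []
        by_group: dict[str, list[GeneModel]] = {}
        for model in models:
            group = group_calls.get(model.gene_id)
            if group is not None:
                by_group.setdefault(group, []).append(model)
        for group in sorted(by_group):
            members = by_group[group]
            intronless = sum(m.n_introns == 0 for m in members)
            rows.append(
                {
                    "group": group,
                    "n_genes": len(members),
                    "n_intronless": intronless,
                    "intronless_fraction": intronless / len(members),
                }
            )
        per_group = pd.DataFrame(
            rows, columns=["group", "n_genes", "n_intronless", "intronless_fraction"]
        )
    return histogram, per_group


def intron_pattern_table(patterns: list[IntronPattern]) -> pd.DataFrame:
    rows = []
    for p in patterns:
        rows.append(
            {
                "gene_id": p.gene_id,
                "pattern_type": p.pattern_type,
                "introns": ";".join(f"{r}:{ph}:{c}" for r, ph, c in p.introns),
                "atypical": p.atypical,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "pattern_type", "introns", "atypical"])
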