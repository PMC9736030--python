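"""Seeded generators for every input the pipeline consumes, with ground truth.

Every generator threads one :class:`numpy.random.Generator` (no global
state) and emits a truth table sufficient to score the corresponding
pipeline stage.  Design constraints that keep planted truth recoverable
at noise 0:

- background residues never include Asn upstream of the zipper, so the
  planted N-x7-R/K motif is the unique basic-region hit that matters;
- background residues in the hinge and in the pre-anchor part of
  heptad 1 exclude L/I/V/F/M, so the planted anchor is the first
  canonical hydrophobic the annotator can accept;
- per window column, background excludes every group's fixed template
  letter at that column (rejection by construction), so planted group
  labels stay unambiguous;
- planted d residues are always canonical hydrophobics (Leu with the
  configured probability, else I/V/F/M), so heptad tiling never
  truncates a planted zipper;
- planted a residues exclude hydrophobics by default for the same
  anchor-uniqueness reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_annotator import HEPTAD_LABELS, MAX_HEPTADS
from .io_formats import GeneModel, ProteinRecord, write_fasta, write_gff3, write_table
from .specificity import GROUPS, N_COLUMN, RK_COLUMN, WINDOW_LENGTH, templates

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_D = "LIVFM"
CHARGED = "KRDE"
# uncharged pool for non-interactive g/e slots: no E/D/K/R (charged), no Q
# (acidic-like in pair typing), no N, no hydrophobic-d letters
UNCHARGED_GE = "ASTGHYWC"
# a-position pool when neither Asn nor charged is planted
UNCHARGED_A = "QASTH"

HINGE_LENGTH = {group: 3 if group == "A" else 2 for group in GROUPS}

DEFAULT_TISSUES = (
    "root", "stem", "leaf", "petal", "anther", "stigma", "ovule", "seed", "fiber",
)


class SimulationError(ValueError):
    """Raised for impossible or inconsistent simulation plans."""


@dataclass
class SimConfig:
    """Parameters of a synthetic family; ``seed`` is mandatory."""

    seed: int
    n_proteins: int = 200
    group_proportions: dict[str, float] | None = None
    group_counts: dict[str, int] | None = None
    heptad_range: tuple[int, int] = (2, 9)
    flank_range: tuple[int, int] = (8, 25)
    # planted per-heptad frequencies
    asn_at_a: dict[int, float] = field(default_factory=lambda: {2: 0.589, 5: 0.574})
    asn_at_a_default: float = 0.15
    charged_at_a: float = 0.16
    leu_at_d: float = 0.59
    interactive_ge: dict[int, float] = field(default_factory=lambda: {1: 0.4264})
    interactive_ge_default: float = 0.15
    # genome layout
    n_chromosomes: int = 6
    genes_per_chromosome: int = 250
    n_tandem: int = 7
    n_blocks: int = 10
    block_size: int = 6
    n_dispersed: int = 8
    inverted_fraction: float = 0.3
    block_gap_max: int = 3
    max_gap: int = 25
    # expression plan
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_not_expressed: int = 12
    n_all_tissues: int = 76
    n_high_root: int = 21
    n_high_leaf: int = 23
    n_drought_up: int = 20
    n_drought_down: int = 20
    drought_fc: float = 4.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimulationError("SimConfig.seed is mandatory")
        if self.group_proportions is not None:
            total = sum(self.group_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise SimulationError(f"group proportions sum to {total}, expected 1")
        for name in ("asn_at_a_default", "charged_at_a", "leu_at_d",
                     "interactive_ge_default", "inverted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        for d in (self.asn_at_a, self.interactive_ge):
            for h, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise SimulationError(f"frequency {v} at heptad {h} outside [0, 1]")
        lo, hi = self.heptad_range
        if not 2 <= lo <= hi <= MAX_HEPTADS:
            raise SimulationError(f"heptad_range {self.heptad_range} outside 2..9")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _template_of(group: str):
    for tpl in templates():
        if tpl.group == group:
            return tpl
    raise SimulationError(f"unknown group {group!r}; expected one of {GROUPS}")


def _forbidden_at(col: int) -> set[str]:
    """Every group's fixed letters at a window column (spurious-match guard)."""
    letters: set[str] = set()
    for tpl in templates():
        allowed = tpl.columns[col - 1]
        if allowed is not None:
            letters |= set(allowed)
    return letters


_FORBIDDEN_BY_COL = None


def _forbidden_by_col() -> list[set[str]]:
    global _FORBIDDEN_BY_COL
    if _FORBIDDEN_BY_COL is None:
        _FORBIDDEN_BY_COL = [_forbidden_at(c) for c in range(1, WINDOW_LENGTH + 1)]
    return _FORBIDDEN_BY_COL


def _background(rng: np.random.Generator, forbidden: set[str]) -> str:
    pool = [aa for aa in AA20 if aa not in forbidden]
    return pool[rng.integers(len(pool))]


def _planted_window(group: str, rng: np.random.Generator) -> list[str | None]:
    """Instantiate the 30-column signature window for a group.

    Fixed template columns are copied; the anchor columns are forced to
    the structural residues (N at 12; R/K at 20, avoiding K unless the
    template demands it so group I stays unambiguous).  '*' columns are
    left None for zone-aware filling.
    """
    tpl = _template_of(group)
    window: list[str | None] = [None] * WINDOW_LENGTH
    for col, allowed in enumerate(tpl.columns, start=1):
        if allowed is None:
            continue
        choices = sorted(allowed)
        window[col - 1] = choices[int(rng.integers(len(choices)))]
    window[N_COLUMN - 1] = "N"
    rk = window[RK_COLUMN - 1]
    if rk is None or rk not in "RK":
        window[RK_COLUMN - 1] = "R"
    return window


def _pick(rng: np.random.Generator, letters: str) -> str:
    return letters[int(rng.integers(len(letters)))]


def generate_protein(
    group: str,
    n_heptads: int,
    cfg: SimConfig | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    protein_id: str = "p1",
    planted: dict[str, dict[int, str]] | None = None,
) -> tuple[ProteinRecord, dict]:
    """Generate one annotatable family protein plus its truth row.

    ``planted`` optionally pins specific residues, e.g.
    ``{"a": {2: "N"}, "d": {1: "L"}}`` (heptad index -> letter).  A
    request that conflicts with a template-fixed column is an error.
    """
    if cfg is None:
        cfg = SimConfig(seed=seed if seed is not None else 0)
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if not 2 <= n_heptads <= MAX_HEPTADS:
        raise SimulationError(f"n_heptads={n_heptads} outside 2..{MAX_HEPTADS}")
    planted = planted or {}

    hinge_len = HINGE_LENGTH[group]
    flank_len = int(rng.integers(cfg.flank_range[0], cfg.flank_range[1] + 1))
    window = _planted_window(group, rng)
    forbidden = _forbidden_by_col()

    # absolute 1-based coordinates
    win_start = flank_len + 1
    n_pos = flank_len + N_COLUMN
    basic_start, basic_end = n_pos - 7, n_pos + 8
    hinge_start = basic_end + 1
    hinge_end = basic_end + hinge_len
    g1 = hinge_end + 1
    d1 = g1 + 4
    length = g1 + 7 * n_heptads - 1

    # planted zipper residues -----------------------------------------------
    a_res: dict[int, str] = {}
    d_res: dict[int, str] = {}
    e_res: dict[int, str] = {}
    g_res: dict[int, str] = {}
    interactive: dict[int, bool] = {}
    for h in range(1, n_heptads + 1):
        d_res[h] = "L" if rng.random() < cfg.leu_at_d else _pick(rng, "IVFM")
        p_asn = cfg.asn_at_a.get(h, cfg.asn_at_a_default)
        u = rng.random()
        if u < p_asn:
            a_res[h] = "N"
        elif u < p_asn + cfg.charged_at_a:
            a_res[h] = _pick(rng, CHARGED)
        else:
            a_res[h] = _pick(rng, UNCHARGED_A)
    for h in range(1, n_heptads):
        p_int = cfg.interactive_ge.get(h, cfg.interactive_ge_default)
        interactive[h] = bool(rng.random() < p_int)
        if interactive[h]:
            g_res[h] = _pick(rng, CHARGED)
            e_res[h + 1] = _pick(rng, CHARGED)
        else:
            g_res[h] = _pick(rng, UNCHARGED_GE)
            e_res[h + 1] = _pick(rng, UNCHARGED_GE)
    e_res[1] = _pick(rng, UNCHARGED_GE)
    g_res[n_heptads] = _pick(rng, UNCHARGED_GE)
    for label, store in (("a", a_res), ("d", d_res), ("e", e_res), ("g", g_res)):
        for h, letter in planted.get(label, {}).items():
            if label == "d" and letter not in CANONICAL_D:
                raise SimulationError(
                    f"planted d residue {letter!r} is not canonical (L/I/V/F/M)"
                )
            store[h] = letter

    # assemble the sequence --------------------------------------------------
    chars: list[str] = []
    for pos in range(1, length + 1):
        col = pos - win_start + 1  # window column or out of range
        in_window = 1 <= col <= WINDOW_LENGTH
        template_char = window[col - 1] if in_window else None
        if pos < g1:  # flank, basic region, hinge
            if template_char is not None:
                chars.append(template_char)
                continue
            banned = {"N"}
            if pos > basic_end:  # hinge: keep hydrophobics out
                banned |= set(CANONICAL_D)
            if in_window:
                banned |= forbidden[col - 1]
            chars.append(_background(rng, banned))
            continue
        # zipper
        h = (pos - g1) // 7 + 1
        label = HEPTAD_LABELS[(pos - g1) % 7]
        plan_char = {"a": a_res, "d": d_res, "e": e_res, "g": g_res}.get(label, {}).get(h)
        if template_char is not None:
            requested = (planted.get(label) or {}).get(h)
            if requested is not None and requested != template_char:
                raise SimulationError(
                    f"group {group} fixes {template_char!r} at window column {col} "
                    f"({label} of heptad {h}); cannot plant {requested!r}"
                )
            chars.append(template_char)
            # template overrides the plan; record the realized residue
            if label in "adeg":
                {"a": a_res, "d": d_res, "e": e_res, "g": g_res}[label][h] = template_char
            continue
        if plan_char is not None:
            chars.append(plan_char)
            continue
        banned = {"N"}
        if pos < d1:
            banned |= set(CANONICAL_D)
        if in_window:
            banned |= forbidden[col - 1]
        chars.append(_background(rng, banned))

    sequence = "".join(chars)
    record = ProteinRecord(protein_id, sequence)
    truth = {
        "protein_id": protein_id,
        "group": group,
        "length": length,
        "basic_start": basic_start,
        "basic_end": basic_end,
        "n_pos": n_pos,
        "rk_pos": n_pos + 8,
        "hinge_start": hinge_start,
        "hinge_end": hinge_end,
        "zipper_start": g1,
        "n_heptads": n_heptads,
        "a_residues": "".join(a_res[h] for h in range(1, n_heptads + 1)),
        "d_residues": "".join(d_res[h] for h in range(1, n_heptads + 1)),
        "e_residues": "".join(e_res[h] for h in range(1, n_heptads + 1)),
        "g_residues": "".join(g_res[h] for h in range(1, n_heptads + 1)),
        "interactive_pairs": "".join(
            "1" if interactive[h] else "0" for h in range(1, n_heptads)
        ),
    }
    return record, truth


def generate_proteome(cfg: SimConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a family of proteins with a per-protein truth table."""
    rng = cfg.rng()
    if cfg.group_counts is not None:
        labels = [g for g, n in sorted(cfg.group_counts.items()) for _ in range(n)]
        if len(labels) != cfg.n_proteins:
            raise SimulationError(
                f"group_counts sum to {len(labels)} but n_proteins={cfg.n_proteins}"
            )
    else:
        props = cfg.group_proportions or {g: 1 / len(GROUPS) for g in GROUPS}
        groups = sorted(props)
        draws = rng.multinomial(cfg.n_proteins, [props[g] for g in groups])
        labels = [g for g, n in zip(groups, draws) for _ in range(n)]
    lo, hi = cfg.heptad_range
    records, rows = [], []
    for i, group in enumerate(labels, 1):
        n_heptads = int(rng.integers(lo, hi + 1))
        rec, truth = generate_protein(
            group, n_heptads, cfg=cfg, rng=rng, protein_id=f"bzip{i:04d}"
        )
        records.append(rec)
        rows.append(truth)
    return records, pd.DataFrame(rows)


# --- gene models ------------------------------------------------------------

PHASE_RESIDUE_DELTA = {"P0": 0, "P1": -1, "P2": -2}  # c = 3r + delta


@dataclass(frozen=True)
class IntronPlanEntry:
    pattern_type: str  # type1_no_intron | type2_hinge | type3_basic | type4_both
    basic_phase: str | None = None
    hinge_phase: str | None = None
    n_extra: int = 0


def make_intron_plan(gene_ids: list[str]) -> dict[str, IntronPlanEntry]:
    """Cycle every pattern type x phase combination over the gene list."""
    cycle = [IntronPlanEntry("type1_no_intron")]
    cycle += [IntronPlanEntry("type2_hinge", hinge_phase=p) for p in ("P0", "P1", "P2")]
    cycle += [IntronPlanEntry("type3_basic", basic_phase=p) for p in ("P0", "P1", "P2")]
    cycle += [
        IntronPlanEntry("type4_both", basic_phase=p, hinge_phase=q)
        for p, q in (("P0", "P1"), ("P1", "P2"), ("P2", "P0"))
    ]
    return {g: cycle[i % len(cycle)] for i, g in enumerate(gene_ids)}


def _phase_breakpoint(
    rng: np.random.Generator, phase: str, start_res: int, end_res: int
) -> int:
    """A coding offset realizing ``phase`` inside a residue region.

    The region owns offsets [3*(start_res-1), 3*end_res - 1]; for P0 the
    splice sits after the last nucleotide of a codon, so eligible codons
    run from start_res-1 to end_res-1.
    """
    if phase == "P0":
        r = int(rng.integers(start_res - 1, end_res))
    else:
        r = int(rng.integers(start_res, end_res + 1))
    return 3 * r + PHASE_RESIDUE_DELTA[phase]


def generate_gene_models(
    protein_truth: pd.DataFrame,
    intron_plan: dict[str, IntronPlanEntry],
    rng: np.random.Generator,
    layout: pd.DataFrame | None = None,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Build gene models realizing the planted intron plan.

    ``layout`` (gene_id, chromosome, rank, is_family) places genes and
    adds single-exon filler genes; without it, family genes are laid out
    on one chromosome in truth order.  Returns models (family + fillers)
    and the per-family-gene intron truth table.
    """
    truth_by_id = {row.protein_id: row for row in protein_truth.itertuples()}
    if layout is None:
        layout = pd.DataFrame(
            {
                "gene_id": protein_truth["protein_id"],
                "chromosome": "chr01",
                "rank": np.arange(1, len(protein_truth) + 1),
                "is_family": True,
            }
        )
    models: list[GeneModel] = []
    rows = []
    spacing = 5000
    for entry in layout.itertuples():
        start = 1 + (entry.rank - 1) * spacing
        strand = "+" if entry.rank % 2 == 1 else "-"
        if not entry.is_family:
            models.append(
                GeneModel(
                    gene_id=entry.gene_id,
                    chromosome=entry.chromosome,
                    strand=strand,
                    rank=int(entry.rank),
                    cds_segments=[(start, start + 299)],
                )
            )
            continue
        truth = truth_by_id[entry.gene_id]
        plan = intron_plan.get(entry.gene_id, IntronPlanEntry("type1_no_intron"))
        aa_len = int(truth.length)
        cds_len = 3 * (aa_len + 1)
        breaks: list[int] = []
        planted: list[tuple[str, str, int]] = []
        if plan.hinge_phase is not None and int(truth.hinge_end) < int(truth.hinge_start):
            raise SimulationError(f"gene {entry.gene_id}: hinge region absent")
        if plan.pattern_type in ("type3_basic", "type4_both"):
            c = _phase_breakpoint(
                rng, plan.basic_phase, int(truth.basic_start), int(truth.basic_end)
            )
            breaks.append(c)
            planted.append(("basic", plan.basic_phase, c))
        if plan.pattern_type in ("type2_hinge", "type4_both"):
            c = _phase_breakpoint(
                rng, plan.hinge_phase, int(truth.hinge_start), int(truth.hinge_end)
            )
            breaks.append(c)
            planted.append(("hinge", plan.hinge_phase, c))
        zipper_nt_start = 3 * int(truth.hinge_end) + 3
        for _ in range(plan.n_extra):
            lo, hi = zipper_nt_start, cds_len - 3
            if hi <= lo:
                break
            c = int(rng.integers(lo, hi + 1))
            if c not in breaks:
                breaks.append(c)
        breaks.sort()
        lengths = [b - a for a, b in zip([0] + breaks, breaks + [cds_len])]
        intron_lens = [int(rng.integers(60, 201)) for _ in range(len(breaks))]
        if strand == "+":
            segments = []
            pos = start
            for i, seg_len in enumerate(lengths):
                segments.append((pos, pos + seg_len - 1))
                pos += seg_len
                if i < len(intron_lens):
                    pos += intron_lens[i]
        else:
            genomic = []  # ascending order = reversed translation order
            pos = start
            for i, seg_len in enumerate(reversed(lengths)):
                genomic.append((pos, pos + seg_len - 1))
                pos += seg_len
                if i < len(intron_lens):
                    pos += intron_lens[len(intron_lens) - 1 - i]
            segments = list(reversed(genomic))
        models.append(
            GeneModel(
                gene_id=entry.gene_id,
                chromosome=entry.chromosome,
                strand=strand,
                rank=int(entry.rank),
                cds_segments=segments,
            )
        )
        rows.append(
            {
                "gene_id": entry.gene_id,
                "pattern_type": plan.pattern_type,
                "introns": ";".join(f"{r}:{p}:{c}" for r, p, c in planted),
                "n_introns": len(breaks),
            }
        )
    return models, pd.DataFrame(rows, columns=["gene_id", "pattern_type", "introns", "n_introns"])


# --- genome layout ----------------------------------------------------------


def generate_genome_layout(
    cfg: SimConfig, family_ids: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, list[tuple[str, str]], pd.DataFrame]:
    """Plant tandem arrays, collinear blocks and dispersed homolog pairs.

    Returns (layout, pairs, pair truth).  The layout assigns every rank
    slot on every chromosome to either a family gene or a filler gene,
    so gene order read back from the GFF3 reproduces the planted ranks.
    """
    chroms = [f"chr{i:02d}" for i in range(1, cfg.n_chromosomes + 1)]
    capacity = cfg.genes_per_chromosome
    next_rank = {c: 1 for c in chroms}
    assigned: dict[tuple[str, int], str] = {}
    pairs: list[tuple[str, str]] = []
    truth_rows = []

    needed = 2 * (cfg.n_tandem + cfg.n_blocks * cfg.block_size + cfg.n_dispersed)
    if needed > len(family_ids):
        raise SimulationError(
            f"layout needs {needed} family genes for planted events, "
            f"only {len(family_ids)} available"
        )
    pool = list(family_ids)

    def take_gene() -> str:
        return pool.pop(0)

    def take_ranks(chrom: str, count: int, gaps: list[int]) -> list[int]:
        ranks = [next_rank[chrom]]
        for gap in gaps:
            ranks.append(ranks[-1] + gap)
        next_rank[chrom] = ranks[-1] + 1
        if next_rank[chrom] > capacity + 1:
            raise SimulationError(
                f"chromosome {chrom} overfull: needs rank {ranks[-1]} "
                f"but capacity is {capacity}"
            )
        return ranks

    # tandem arrays: adjacent ranks on one chromosome
    for t in range(cfg.n_tandem):
        chrom = chroms[t % len(chroms)]
        r1, r2 = take_ranks(chrom, 2, [1])
        a, b = take_gene(), take_gene()
        assigned[(chrom, r1)] = a
        assigned[(chrom, r2)] = b
        pair = tuple(sorted((a, b)))
        pairs.append(pair)
        truth_rows.append(
            {"gene_a": pair[0], "gene_b": pair[1], "label": "tandem", "block_id": ""}
        )

    # collinear blocks on distinct chromosome pairs
    from itertools import combinations

    chrom_pairs = list(combinations(chroms, 2))
    used_pairs: set[tuple[str, str]] = set()
    for b in range(cfg.n_blocks):
        ca, cb = chrom_pairs[b % len(chrom_pairs)]
        if (ca, cb) in used_pairs:
            # separate repeat blocks on the same chromosome pair beyond max_gap
            next_rank[ca] += cfg.max_gap + 1
            next_rank[cb] += cfg.max_gap + 1
        used_pairs.add((ca, cb))
        m = cfg.block_size
        gaps_a = [int(rng.integers(1, cfg.block_gap_max + 1)) for _ in range(m - 1)]
        gaps_b = [int(rng.integers(1, cfg.block_gap_max + 1)) for _ in range(m - 1)]
        ranks_a = take_ranks(ca, m, gaps_a)
        ranks_b = take_ranks(cb, m, gaps_b)
        inverted = bool(rng.random() < cfg.inverted_fraction)
        genes_a = [take_gene() for _ in range(m)]
        genes_b = [take_gene() for _ in range(m)]
        for i in range(m):
            assigned[(ca, ranks_a[i])] = genes_a[i]
            assigned[(cb, ranks_b[i])] = genes_b[i]
        block_id = f"plant{b + 1}"
        for i in range(m):
            j = m - 1 - i if inverted else i
            pair = tuple(sorted((genes_a[i], genes_b[j])))
            pairs.append(pair)
            truth_rows.append(
                {
                    "gene_a": pair[0],
                    "gene_b": pair[1],
                    "label": "segmental",
                    "block_id": block_id,
                }
            )

    # dispersed background pairs, kept unchainable by >max_gap separation
    for d in range(cfg.n_dispersed):
        ca, cb = chrom_pairs[(d * 3 + 1) % len(chrom_pairs)]
        next_rank[ca] += cfg.max_gap + 1
        next_rank[cb] += cfg.max_gap + 1
        (ra,) = take_ranks(ca, 1, [])
        (rb,) = take_ranks(cb, 1, [])
        a, b = take_gene(), take_gene()
        assigned[(ca, ra)] = a
        assigned[(cb, rb)] = b
        pair = tuple(sorted((a, b)))
        pairs.append(pair)
        truth_rows.append(
            {"gene_a": pair[0], "gene_b": pair[1], "label": "dispersed", "block_id": ""}
        )

    # scatter remaining family genes over vacant slots, fill the rest
    vacant = [
        (c, r) for c in chroms for r in range(1, capacity + 1) if (c, r) not in assigned
    ]
    order = rng.permutation(len(vacant))
    for idx, gene in zip(order, pool):
        assigned[vacant[int(idx)]] = gene
    filler_n = 0
    for slot in vacant:
        if slot not in assigned:
            filler_n += 1
            assigned[slot] = f"fill{filler_n:04d}"

    family = set(family_ids)
    layout = pd.DataFrame(
        [
            {
                "gene_id": assigned[(c, r)],
                "chromosome": c,
                "rank": r,
                "is_family": assigned[(c, r)] in family,
            }
            for c in chroms
            for r in range(1, capacity + 1)
        ]
    )
    pair_truth = pd.DataFrame(
        truth_rows, columns=["gene_a", "gene_b", "label", "block_id"]
    )
    return layout, pairs, pair_truth


# --- expression -------------------------------------------------------------


def generate_fpkm(
    cfg: SimConfig, gene_ids: list[str], rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Tissue FPKM matrix, drought condition matrix and expression truth.

    Classes are planted deterministically above/below the 1 and 20 FPKM
    thresholds with safety margins, so threshold filters recover them
    exactly; drought fold changes are planted at ``drought_fc`` with
    mild log-normal noise.
    """
    n = len(gene_ids)
    tissues = list(cfg.tissues)
    if cfg.n_not_expressed + cfg.n_all_tissues > n:
        raise SimulationError("expression plan exceeds the gene count")
    order = [gene_ids[int(i)] for i in rng.permutation(n)]
    not_expressed = set(order[: cfg.n_not_expressed])
    all_tissues = set(
        order[cfg.n_not_expressed : cfg.n_not_expressed + cfg.n_all_tissues]
    )
    values = pd.DataFrame(0.0, index=gene_ids, columns=tissues)
    expressed_class = {}
    for gene in gene_ids:
        if gene in not_expressed:
            values.loc[gene] = rng.uniform(0.01, 0.8, len(tissues))
            expressed_class[gene] = "none"
        elif gene in all_tissues:
            values.loc[gene] = rng.uniform(1.2, 15.0, len(tissues))
            expressed_class[gene] = "all"
        else:
            row = rng.uniform(0.01, 0.8, len(tissues))
            k = int(rng.integers(1, len(tissues)))  # expressed in 1..n-1 tissues
            hot = rng.choice(len(tissues), size=k, replace=False)
            row[hot] = rng.uniform(1.2, 15.0, k)
            values.loc[gene] = row
            expressed_class[gene] = "any"

    # highly expressed / tissue-preferential plants (from the all-tissues set)
    all_list = sorted(all_tissues)
    if cfg.n_high_root + cfg.n_high_leaf > len(all_list):
        raise SimulationError("too few all-tissue genes for the high-expression plan")
    high_root = set(all_list[: cfg.n_high_root])
    high_leaf = set(all_list[cfg.n_high_root : cfg.n_high_root + cfg.n_high_leaf])
    for gene in high_root:
        values.loc[gene, "root"] = rng.uniform(22.0, 60.0)
    for gene in high_leaf:
        values.loc[gene, "leaf"] = rng.uniform(22.0, 60.0)

    # drought condition matrix
    drought_cols = ["root_control", "root_drought", "leaf_control", "leaf_drought"]
    drought = pd.DataFrame(0.0, index=gene_ids, columns=drought_cols)
    if 2 * (cfg.n_drought_up + cfg.n_drought_down) > n:
        raise SimulationError("drought plan exceeds the gene count")
    shuffled = [gene_ids[int(i)] for i in rng.permutation(n)]
    up = set(shuffled[: cfg.n_drought_up])
    down = set(shuffled[cfg.n_drought_up : cfg.n_drought_up + cfg.n_drought_down])
    drought_label = {}
    for gene in gene_ids:
        for tissue in ("root", "leaf"):
            control = max(float(rng.lognormal(1.0, 0.6)), 1.5)
            noise = float(np.exp(rng.normal(0.0, 0.15)))
            if gene in up:
                treated = control * cfg.drought_fc * noise
            elif gene in down:
                treated = control / cfg.drought_fc * noise
            else:
                treated = control * float(np.exp(rng.normal(0.0, 0.1)))
            drought.loc[gene, f"{tissue}_control"] = control
            drought.loc[gene, f"{tissue}_drought"] = treated
        drought_label[gene] = "up" if gene in up else "down" if gene in down else "unchanged"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "expressed_class": [expressed_class[g] for g in gene_ids],
            "high_root": [g in high_root for g in gene_ids],
            "high_leaf": [g in high_leaf for g in gene_ids],
            "drought": [drought_label[g] for g in gene_ids],
        }
    )
    return values, drought, truth


# --- end-to-end bundle ------------------------------------------------------


def simulate(cfg: SimConfig, outdir: str | Path | None = None):
    """Generate every pipeline input plus truth tables; optionally write them.

    Returns a dict with records, models, layout, pairs, matrices and the
    truth tables.  With ``outdir`` the standard file bundle is written
    (proteins.fasta, genes.gff3, pairs.tsv, fpkm.tsv, drought.tsv,
    truth/*.tsv).
    """
    rng = cfg.rng()
    records, protein_truth = generate_proteome(cfg)
    family_ids = list(protein_truth["protein_id"])
    layout, pairs, pair_truth = generate_genome_layout(cfg, family_ids, rng)
    intron_plan = make_intron_plan(family_ids)
    models, intron_truth = generate_gene_models(protein_truth, intron_plan, rng, layout)
    fpkm, drought, expr_truth = generate_fpkm(cfg, family_ids, rng)
    bundle = {
        "records": records,
        "protein_truth": protein_truth,
        "layout": layout,
        "pairs": pairs,
        "pair_truth": pair_truth,
        "models": models,
        "intron_truth": intron_truth,
        "fpkm": fpkm,
        "drought": drought,
        "expression_truth": expr_truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        write_fasta(records, outdir / "proteins.fasta")
        write_gff3(models, outdir / "genes.gff3")
        pd.DataFrame(pairs, columns=["gene_a", "gene_b"]).to_csv(
            outdir / "pairs.tsv", sep="\t", index=False, header=False
        )
        fpkm.rename_axis("gene_id").reset_index().to_csv(
            outdir / "fpkm.tsv", sep="\t", index=False
        )
        drought.rename_axis("gene_id").reset_index().to_csv(
            outdir / "drought.tsv", sep="\t", index=False
        )
        params = {"seed": cfg.seed, "n_proteins": cfg.n_proteins}
        write_table(protein_truth, outdir / "truth" / "proteins.tsv", params)
        write_table(pair_truth, outdir / "truth" / "pairs.tsv", params)
        write_table(intron_truth, outdir / "truth" / "introns.tsv", params)
        write_table(expr_truth, outdir / "truth" / "expression.tsv", params)
        write_table(layout, outdir / "truth" / "layout.tsv", params)
    return bundle
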