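"""Leucine-zipper dimerization property prediction.

Per-position residue frequencies over the a/d/e/g heptad positions,
per-heptad Asn-at-a frequencies, electrostatic classification of
g<->e' pairs (the g residue of heptad *i* against the e residue of
heptad *i+1*, an intra-sequence proxy for the inter-helical pair of a
parallel dimer), and a per-protein propensity summary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .domain_annotator import DomainAnnotation

BASIC = frozenset("KR")
ACIDIC = frozenset("ED")
# Q is counted acidic-like for pair typing only (E<->Q is listed among the
# repulsive acidic pairs); it is excluded from the charged tallies at a.
ACIDIC_LIKE = frozenset("Q")
CHARGED = frozenset("KRDE")
HYDROPHOBIC = frozenset("LIVFM")

PAIR_TYPES = (
    "repulsive_basic",
    "repulsive_acidic",
    "attractive_basic_acidic",
    "attractive_acidic_basic",
    "incomplete",
)

PROPENSITIES = (
    "homodimer_favoring",
    "heterodimer_favoring",
    "mixed",
    "indeterminate",
)


@dataclass(frozen=True)
class DimerSummary:
    protein_id: str
    asn_a_count: int
    charged_a_count: int
    leu_d_fraction: float
    pair_counts: dict[str, int]
    propensity: str


def residue_class(aa: str) -> str:
    """Classify one residue letter for dimerization analysis."""
    if len(aa) != 1:
        raise ValueError(f"expected a single residue letter, got {aa!r}")
    if aa in BASIC:
        return "basic"
    if aa in ACIDIC:
        return "acidic"
    if aa in ACIDIC_LIKE:
        return "acidic_like"
    if aa == "N":
        return "polar_N"
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    return "other"


def classify_ge_pair(g_res: str, e_res: str) -> str:
    """Type one (g of heptad i, e of heptad i+1) electrostatic pair."""
    g_cls = residue_class(g_res)
    e_cls = residue_class(e_res)
    acidic_ish = ("acidic", "acidic_like")
    if g_cls == "basic" and e_cls == "basic":
        return "repulsive_basic"
    if g_cls in acidic_ish and e_cls in acidic_ish:
        return "repulsive_acidic"
    if g_cls == "basic" and e_cls == "acidic":
        return "attractive_basic_acidic"
    if g_cls == "acidic" and e_cls == "basic":
        return "attractive_acidic_basic"
    return "incomplete"


def _ge_pairs(annotation: DomainAnnotation) -> list[tuple[int, str, str]]:
    """All evaluable (heptad index, g_res, e'_res) pairs of one zipper."""
    pairs = []
    heptads = annotation.heptads
    for h, nxt in zip(heptads, heptads[1:]):
        g = h.residues.get("g")
        e = nxt.residues.get("e")
        if g is not None and e is not None:
            pairs.append((h.index, g, e))
    return pairs


def position_frequency_table(annotations: list[DomainAnnotation]) -> pd.DataFrame:
    """Residue frequencies at the a, d, e and g positions, pooled over heptads.

    Rows are residue letters, columns are positions; each column sums to 1
    over the occupied slots of that position.
    """
    if not annotations:
        raise ValueError("position_frequency_table requires at least one annotation")
    counters: dict[str, Counter] = {p: Counter() for p in "adeg"}
    for ann in annotations:
        for heptad in ann.heptads:
            for pos in "adeg":
                res = heptad.residues.get(pos)
                if res is not None:
                    counters[pos][res] += 1
    residues = sorted(set().union(*[set(c) for c in counters.values()]))
    data = {
        pos: [counters[pos][r] / total if (total := sum(counters[pos].values())) else 0.0
              for r in residues]
        for pos in "adeg"
    }
    return pd.DataFrame(data, index=residues)


def asn_frequency_per_heptad(annotations: list[DomainAnnotation]) -> pd.Series:
    """Fraction of proteins with Asn at the a position, per heptad index.

    The denominator for heptad h is the number of proteins whose zipper
    has an occupied a slot in heptad h.
    """
    num: Counter = Counter()
    den: Counter = Counter()
    for ann in annotations:
        for heptad in ann.heptads:
            res = heptad.residues.get("a")
            if res is None:
                continue
            den[heptad.index] += 1
            if res == "N":
                num[heptad.index] += 1
    idx = sorted(den)
    return pd.Series([num[h] / den[h] for h in idx], index=idx, name="asn_at_a", dtype=float)


def ge_pair_frequency_per_heptad(annotations: list[DomainAnnotation]) -> pd.DataFrame:
    """Per-heptad-index frequency of each g<->e' pair type.

    Row h describes the pairs formed by the g of heptad h with the e of
    heptad h+1.  Pair-type frequencies sum to 1 per row; the
    ``interactive`` column is 1 - freq(incomplete).
    """
    counts: dict[int, Counter] = {}
    for ann in annotations:
        for h, g, e in _ge_pairs(ann):
            counts.setdefault(h, Counter())[classify_ge_pair(g, e)] += 1
    rows = []
    for h in sorted(counts):
        total = sum(counts[h].values())
        row = {"heptad": h, "n_pairs": total}
        for pt in PAIR_TYPES:
            row[pt] = counts[h][pt] / total
        row["interactive"] = 1.0 - row["incomplete"]
        rows.append(row)
    return pd.DataFrame(rows, columns=["heptad", "n_pairs", *PAIR_TYPES, "interactive"])


def dimer_propensity(annotation: DomainAnnotation) -> DimerSummary:
    """Summarise one zipper's dimerization-relevant counts and propensity.

    Thresholds (>=2 Asn at a for homodimer-favoring, >=1 repulsive pair
    or >=2 charged a residues for heterodimer-favoring) are reporting
    conventions; all raw counts are emitted so users can re-threshold.
    """
    a_residues = [
        h.residues["a"] for h in annotation.heptads if "a" in h.residues
    ]
    d_residues = [
        h.residues["d"] for h in annotation.heptads if "d" in h.residues
    ]
    asn_a = sum(r == "N" for r in a_residues)
    charged_a = sum(r in CHARGED for r in a_residues)
    leu_d = sum(r == "L" for r in d_residues) / len(d_residues) if d_residues else 0.0
    pair_counts = Counter({pt: 0 for pt in PAIR_TYPES})
    for _, g, e in _ge_pairs(annotation):
        pair_counts[classify_ge_pair(g, e)] += 1
    repulsive = pair_counts["repulsive_basic"] + pair_counts["repulsive_acidic"]
    homo = asn_a >= 2 and repulsive == 0
    hetero = repulsive >= 1 or charged_a >= 2
    if homo and hetero:
        propensity = "mixed"
    elif homo:
        propensity = "homodimer_favoring"
    elif hetero:
        propensity = "heterodimer_favoring"
    else:
        propensity = "indeterminate"
    return DimerSummary(
        protein_id=annotation.protein_id,
        asn_a_count=asn_a,
        charged_a_count=charged_a,
        leu_d_fraction=leu_d,
        pair_counts=dict(pair_counts),
        propensity=propensity,
    )


def dimer_summary_table(annotations: list[DomainAnnotation]) -> pd.DataFrame:
    rows = []
    for ann in annotations:
        s = dimer_propensity(ann)
        row = {
            "protein_id": s.protein_id,
            "asn_a_count": s.asn_a_count,
            "charged_a_count": s.charged_a_count,
            "leu_d_fraction": s.leu_d_fraction,
            "propensity": s.propensity,
        }
        row.update(s.pair_counts)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "asn_a_count", "charged_a_count", "leu_d_fraction",
            *PAIR_TYPES, "propensity",
        ],
    )
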