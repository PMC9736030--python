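"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written from the primitive definitions
(modular arithmetic, exhaustive enumeration, plain loops) and stays
independent of the implementation paths it checks.
"""

from __future__ import annotations

import itertools
from collections import Counter

CANONICAL = set("LIVFM")


# --- basic region -----------------------------------------------------------


def brute_force_basic_hits(seq: str) -> list[tuple[int, int]]:
    """All (n_pos, rk_pos) index pairs satisfying the motif, by full scan."""
    hits = []
    for i in range(1, len(seq) + 1):
        for j in range(1, len(seq) + 1):
            if j == i + 8 and i - 7 >= 1 and seq[i - 1] == "N" and seq[j - 1] in "RK":
                hits.append((i, j))
    return hits


# --- heptad registration ----------------------------------------------------


def heptad_oracle(seq: str, anchor: int) -> list[tuple[int, int, dict[str, str]]]:
    """Heptads via independent modular-arithmetic position assignment.

    Every residue from the g of heptad 1 onward gets the label
    ``"gabcdef"[(pos - g1) % 7]``; heptads are then cut at multiples of
    7, dropped if they lack a d position, capped at nine, and truncated
    when two consecutive d residues are non-canonical.
    """
    g1 = anchor - 4
    label_of = {pos: "gabcdef"[(pos - g1) % 7] for pos in range(g1, len(seq) + 1)}
    chunks = []
    for k in range(1, 10):
        start = g1 + 7 * (k - 1)
        if start > len(seq):
            break
        residues = {
            label_of[p]: seq[p - 1] for p in range(start, min(start + 7, len(seq) + 1))
        }
        if "d" not in residues:
            break
        chunks.append((k, start, residues))
        if len(residues) < 7:
            break
    kept = []
    bad_streak = 0
    for chunk in chunks:
        kept.append(chunk)
        if chunk[2]["d"] in CANONICAL:
            bad_streak = 0
        else:
            bad_streak += 1
            if bad_streak == 2:
                kept = kept[:-2]
                break
    return kept


# --- collinear chaining -----------------------------------------------------


def _chain_valid(ranks: list[tuple[int, int]], max_gap: int, orientation: str) -> bool:
    for (xa, xb), (ya, yb) in zip(ranks, ranks[1:]):
        if not 0 < ya - xa <= max_gap:
            return False
        db = yb - xb
        if orientation == "same" and not 0 < db <= max_gap:
            return False
        if orientation == "inverted" and not -max_gap <= db < 0:
            return False
    return True


def oracle_best_chain(
    rank_pairs: list[tuple[int, int]], max_gap: int
) -> tuple[list[int], str]:
    """Exhaustive enumeration of every monotone chain over <= ~15 anchors.

    ``rank_pairs`` must be sorted ascending; returns the index tuple of
    the longest valid chain (same orientation preferred on ties, then
    the lexicographically smallest index sequence).
    """
    n = len(rank_pairs)
    best: tuple[list[int], str] = ([], "same")
    for orientation in ("same", "inverted"):
        found: list[int] | None = None
        for size in range(n, 0, -1):
            for combo in itertools.combinations(range(n), size):
                if _chain_valid([rank_pairs[i] for i in combo], max_gap, orientation):
                    found = list(combo)
                    break
            if found is not None:
                break
        if found is not None and len(found) > len(best[0]):
            best = (found, orientation)
    return best


def oracle_blocks(
    rank_pairs: list[tuple[int, int]], min_anchors: int, max_gap: int
) -> list[tuple[list[tuple[int, int]], str]]:
    """Iterative longest-first extraction using exhaustive chain search."""
    remaining = sorted(rank_pairs)
    blocks = []
    while True:
        chain, orientation = oracle_best_chain(remaining, max_gap)
        if len(chain) < min_anchors:
            break
        blocks.append(([remaining[i] for i in chain], orientation))
        chosen = set(chain)
        remaining = [a for i, a in enumerate(remaining) if i not in chosen]
    return blocks


# --- g<->e' pairs -----------------------------------------------------------


def oracle_pair_type(g: str, e: str) -> str:
    """Independent re-statement of the four electrostatic pair classes."""
    if g in "KR" and e in "KR":
        return "repulsive_basic"
    if g in "EDQ" and e in "EDQ":
        return "repulsive_acidic"
    if g in "KR" and e in "ED":
        return "attractive_basic_acidic"
    if g in "ED" and e in "KR":
        return "attractive_acidic_basic"
    return "incomplete"


def oracle_ge_frequencies(annotations) -> dict[int, Counter]:
    """Per-heptad pair-type counts by plain enumeration of every protein."""
    counts: dict[int, Counter] = {}
    for ann in annotations:
        heptads = list(ann.heptads)
        for i in range(len(heptads) - 1):
            g = heptads[i].residues.get("g")
            e = heptads[i + 1].residues.get("e")
            if g is None or e is None:
                continue
            h = heptads[i].index
            counts.setdefault(h, Counter())[oracle_pair_type(g, e)] += 1
    return counts


# --- group matching ---------------------------------------------------------


def oracle_match(window: str, parsed_templates) -> tuple[str, int]:
    """Exhaustively score every group; returns (winner, matched count).

    ``parsed_templates`` is the package's template list (the data is the
    contract); the matching logic here is an independent loop.
    """
    results = []
    for tpl in parsed_templates:
        matched = 0
        ok = True
        for col in range(1, 31):
            allowed = tpl.columns[col - 1]
            if allowed is None:
                continue
            ch = window[col - 1]
            if ch in allowed:
                matched += 1
            elif col == 12 and "N" not in allowed and ch == "N":
                pass
            elif col == 20 and not (set(allowed) & set("RK")) and ch in "RK":
                pass
            else:
                ok = False
                break
        if ok:
            results.append((matched, -tpl.priority, tpl.group))
    if not results:
        return "unclassified", 0
    matched, _, group = max(results)
    return group, matched
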