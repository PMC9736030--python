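"""DNA-binding specificity group calling from the basic/hinge signature window.

Each annotated protein is projected onto a 30-column window centred on
its N-x7-R/K anchors (invariant Asn at column 12, R/K at column 20) and
matched against per-group column templates.  A group matches iff every
fixed template column is satisfied; among matching groups the one with
the most literally matched fixed columns wins, ties broken by a fixed
priority order.

Two templates (A and J) pin a residue onto an anchor column that the
motif definition makes structurally impossible in an extracted window
(A expects K where the invariant Asn sits; J expects I where R/K sits).
The templates are kept exactly as shipped rather than re-anchored; for those
columns only, the window's structural anchor residue (N at column 12,
R or K at column 20) satisfies the template without counting toward the
match score.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .domain_annotator import DomainAnnotation
from .io_formats import ProteinRecord

WINDOW_LENGTH = 30
N_COLUMN = 12
RK_COLUMN = 20

GROUPS = ("A", "B", "C", "D", "E", "F/K", "G/M/S", "H", "I", "J")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class SignatureWindow:
    """The 30-column basic+hinge context string of an annotated protein."""

    columns: str

    def __post_init__(self) -> None:
        if len(self.columns) != WINDOW_LENGTH:
            raise ValueError(
                f"signature window must have {WINDOW_LENGTH} columns, "
                f"got {len(self.columns)}"
            )


@dataclass(frozen=True)
class GroupCall:
    group: str
    binding_site: str
    matched_positions: int


@dataclass(frozen=True)
class GroupTemplate:
    group: str
    # per-column allowed residue sets; None = wildcard
    columns: tuple[frozenset[str] | None, ...]
    priority: int
    binding_site: str

    @property
    def n_fixed(self) -> int:
        return sum(c is not None for c in self.columns)


def _parse_template(pattern: str) -> tuple[frozenset[str] | None, ...]:
    cols: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "*":
            cols.append(None)
            i += 1
        elif ch == "(":
            j = pattern.index(")", i)
            letters = frozenset(c for c in pattern[i + 1 : j] if c.isalpha())
            cols.append(letters)
            i = j + 1
        else:
            cols.append(frozenset(ch))
            i += 1
    if len(cols) != WINDOW_LENGTH:
        raise ValueError(f"template {pattern!r} spans {len(cols)} columns, expected 30")
    return tuple(cols)


def load_templates() -> list[GroupTemplate]:
    """Load the versioned group-template table shipped with the package."""
    with resources.files("bzipscan.data").joinpath("group_templates.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    templates = [
        GroupTemplate(
            group=row.group,
            columns=_parse_template(row.template),
            priority=int(row.priority),
            binding_site=row.binding_site,
        )
        for row in df.itertuples()
    ]
    assert {t.group for t in templates} == set(GROUPS)
    return templates


_TEMPLATES: list[GroupTemplate] | None = None


def templates() -> list[GroupTemplate]:
    global _TEMPLATES
    if _TEMPLATES is None:
        _TEMPLATES = load_templates()
    return _TEMPLATES


def extract_signature_window(
    annotation: DomainAnnotation, seq: str
) -> SignatureWindow:
    """Project a protein onto the 30-column window around its motif anchors.

    Columns 1-11 are the 11 residues upstream of the invariant Asn,
    columns 12-20 are N-x7-R/K, columns 21-30 the next 10 residues.
    Out-of-sequence columns are padded with '-'.
    """
    n = annotation.basic.n_pos
    chars = []
    for pos in range(n - 11, n + 19):
        chars.append(seq[pos - 1] if 1 <= pos <= len(seq) else "-")
    return SignatureWindow("".join(chars))


def _column_satisfied(
    allowed: frozenset[str], window_char: str, column: int
) -> tuple[bool, bool]:
    """Return (satisfied, literal) for one fixed template column."""
    if window_char in allowed:
        return True, True
    # anchor-column tolerance for templates that conflict with the motif
    if column == N_COLUMN and "N" not in allowed and window_char == "N":
        return True, False
    if column == RK_COLUMN and not (allowed & {"R", "K"}) and window_char in "RK":
        return True, False
    return False, False


def match_group(window: SignatureWindow) -> GroupCall:
    """Match a signature window against all group templates.

    A group matches iff all its fixed columns are satisfied; among
    matching groups the one with the most literally matched fixed
    columns wins, ties broken by template priority.
    """
    best: tuple[int, int] | None = None  # (-matched, priority)
    best_call: GroupCall | None = None
    for tpl in templates():
        matched = 0
        ok = True
        for col, allowed in enumerate(tpl.columns, start=1):
            if allowed is None:
                continue
            satisfied, literal = _column_satisfied(allowed, window.columns[col - 1], col)
            if not satisfied:
                ok = False
                break
            matched += literal
        if not ok:
            continue
        key = (-matched, tpl.priority)
        if best is None or key < best:
            best = key
            best_call = GroupCall(tpl.group, tpl.binding_site, matched)
    if best_call is None:
        return GroupCall(UNCLASSIFIED, "unknown", 0)
    return best_call


def classify_proteome(
    annotations: list[DomainAnnotation], records: list[ProteinRecord]
) -> tuple[pd.DataFrame, pd.Series]:
    """Call a group for every annotated protein.

    Returns the per-protein membership table and the per-group counts
    (a partition of the annotated set).
    """
    seq_of = {rec.id: rec.sequence for rec in records}
    rows = []
    for ann in annotations:
        window = extract_signature_window(ann, seq_of[ann.protein_id])
        call = match_group(window)
        rows.append(
            {
                "protein_id": ann.protein_id,
                "group": call.group,
                "binding_site": call.binding_site,
                "matched_positions": call.matched_positions,
                "window": window.columns,
            }
        )
    table = pd.DataFrame(
        rows, columns=["protein_id", "group", "binding_site", "matched_positions", "window"]
    )
    counts = (
        table["group"].value_counts().sort_index()
        if not table.empty
        else pd.Series(dtype=int)
    )
    return table, counts
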