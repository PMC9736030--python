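"""Locate the bZIP domain architecture in a protein sequence.

The domain is modelled as three abutting parts:

- a 16-residue *basic region* ending at the R/K of the invariant
  N-x7-R/K motif (7 residues upstream of the Asn, then N-x7-R/K);
- a short *hinge* linker;
- a *leucine zipper* of 2-9 heptad repeats whose positions are labelled
  ``g a b c d e f`` in that order along the sequence, with the first
  canonical hydrophobic residue anchored at the ``d`` position.

All positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import ProteinRecord

HEPTAD_LABELS = "gabcdef"
CANONICAL_D = set("LIVFM")
BASIC_REGION_LENGTH = 16
MAX_HEPTADS = 9
# window (residues after basic_end) searched for the zipper anchor
HINGE_SEARCH_WINDOW = 16
# fraction of d positions that must be canonical hydrophobics
MIN_CANONICAL_D_FRACTION = 0.5
MIN_HEPTADS = 2


@dataclass(frozen=True)
class BasicRegionHit:
    """An occurrence of the invariant N-x7-R/K motif with its 16-residue span."""

    n_pos: int
    rk_pos: int
    basic_start: int
    basic_end: int

    def __post_init__(self) -> None:
        assert self.rk_pos == self.n_pos + 8
        assert self.basic_end - self.basic_start + 1 == BASIC_REGION_LENGTH
        assert self.basic_end == self.rk_pos


@dataclass(frozen=True)
class Heptad:
    """One 7-residue repeat; ``start`` is the sequence index of the g residue.

    ``residues`` maps the position labels present in the sequence (a
    terminal heptad may be partial) to their residue letters.
    """

    index: int
    start: int
    residues: dict[str, str]

    @property
    def d(self) -> str | None:
        return self.residues.get("d")

    def has_canonical_d(self) -> bool:
        return self.d in CANONICAL_D


@dataclass
class DomainAnnotation:
    protein_id: str
    basic: BasicRegionHit
    hinge_start: int
    hinge_end: int
    heptads: list[Heptad] = field(default_factory=list)

    @property
    def n_heptads(self) -> int:
        return len(self.heptads)

    @property
    def zipper_start(self) -> int:
        return self.heptads[0].start

    @property
    def hinge_length(self) -> int:
        return self.hinge_end - self.hinge_start + 1

    @property
    def d_residues(self) -> str:
        return "".join(h.d or "-" for h in self.heptads)


def find_basic_region(seq: str) -> list[BasicRegionHit]:
    """Return all N-x7-R/K motif hits with room for the 16-residue basic region.

    A hit requires ``seq[n] == 'N'``, ``seq[n+8] in 'RK'`` and ``n >= 8``
    (1-based), so that the basic region ``[n-7, n+8]`` fits the sequence.
    Hits are returned left to right.
    """
    hits: list[BasicRegionHit] = []
    for n_pos in range(8, len(seq) - 8 + 1):  # 1-based n_pos, rk within seq
        if seq[n_pos - 1] == "N" and seq[n_pos + 8 - 1] in "RK":
            hits.append(
                BasicRegionHit(
                    n_pos=n_pos,
                    rk_pos=n_pos + 8,
                    basic_start=n_pos - 7,
                    basic_end=n_pos + 8,
                )
            )
    return hits


def register_heptads(seq: str, zipper_anchor: int) -> list[Heptad]:
    """Tile heptads from an anchor residue placed at the d position of heptad 1.

    The g position of heptad 1 starts 4 residues before the anchor and
    heptads abut every 7 residues.  Tiling stops at the sequence end,
    after heptad 9, or when two consecutive heptads both carry a
    non-canonical d residue (both are then discarded: the zipper ended
    before them).  A terminal partial heptad is kept iff it includes its
    d position.
    """
    if not 1 <= zipper_anchor <= len(seq):
        raise ValueError(f"zipper anchor {zipper_anchor} outside sequence")
    if seq[zipper_anchor - 1] not in CANONICAL_D:
        raise ValueError(
            f"zipper anchor residue {seq[zipper_anchor - 1]!r} at {zipper_anchor} "
            "is not a canonical hydrophobic (L/I/V/F/M)"
        )
    g1 = zipper_anchor - 4
    if g1 < 1:
        raise ValueError(
            f"zipper anchor at {zipper_anchor} leaves no room for g..c positions"
        )
    heptads: list[Heptad] = []
    bad_run = 0
    for index in range(1, MAX_HEPTADS + 1):
        g = g1 + 7 * (index - 1)
        if g > len(seq):
            break
        residues = {
            HEPTAD_LABELS[off]: seq[g + off - 1]
            for off in range(7)
            if g + off <= len(seq)
        }
        if "d" not in residues:
            break  # partial heptad without its d position is dropped
        heptad = Heptad(index=index, start=g, residues=residues)
        heptads.append(heptad)
        if heptad.has_canonical_d():
            bad_run = 0
        else:
            bad_run += 1
            if bad_run == 2:
                del heptads[-2:]
                break
        if len(residues) < 7:
            break  # sequence ended inside this heptad
    return heptads


def annotate_domain(rec: ProteinRecord) -> DomainAnnotation | None:
    """Annotate the bZIP domain of a protein, or return None (no-call).

    For each basic-region hit (left to right) the hinge window
    downstream of the basic region is scanned for the first L/I/V/F/M
    residue that, used as the heptad-1 d anchor, yields at least
    :data:`MIN_HEPTADS` heptads with at least half their d positions
    canonical.  The first hit that succeeds wins.  The g of heptad 1
    must fall after the basic region, so effective anchor offsets are
    5..16 residues past the basic region end.
    """
    seq = rec.sequence
    for hit in find_basic_region(seq):
        for offset in range(1, HINGE_SEARCH_WINDOW + 1):
            anchor = hit.basic_end + offset
            if anchor > len(seq) or seq[anchor - 1] not in CANONICAL_D:
                continue
            if anchor - 4 <= hit.basic_end:
                continue  # g position would overlap the basic region
            heptads = register_heptads(seq, anchor)
            if len(heptads) < MIN_HEPTADS:
                continue
            canonical = sum(h.has_canonical_d() for h in heptads)
            if canonical / len(heptads) < MIN_CANONICAL_D_FRACTION:
                continue
            return DomainAnnotation(
                protein_id=rec.id,
                basic=hit,
                hinge_start=hit.basic_end + 1,
                hinge_end=heptads[0].start - 1,
                heptads=heptads,
            )
    return None


def annotation_from_coordinates(
    rec: ProteinRecord, n_pos: int, zipper_start: int, n_heptads: int
) -> DomainAnnotation:
    """Rebuild a :class:`DomainAnnotation` from stored coordinates.

    Used when reloading annotation tables: the heptads are re-registered
    deterministically from the sequence and truncated to ``n_heptads``.
    """
    seq = rec.sequence
    hit = BasicRegionHit(
        n_pos=n_pos, rk_pos=n_pos + 8, basic_start=n_pos - 7, basic_end=n_pos + 8
    )
    anchor = zipper_start + 4
    heptads = register_heptads(seq, anchor)[:n_heptads]
    if len(heptads) != n_heptads:
        raise ValueError(
            f"{rec.id}: stored n_heptads={n_heptads} but only {len(heptads)} register"
        )
    return DomainAnnotation(
        protein_id=rec.id,
        basic=hit,
        hinge_start=hit.basic_end + 1,
        hinge_end=zipper_start - 1,
        heptads=heptads,
    )
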