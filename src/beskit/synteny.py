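"""Paired-end synteny calling against a reference genome.

A clone whose two end reads both earned unique hits is classified per
reference species and search mode:

* ``SINGLE_END`` — only one end assigned;
* ``DISCORDANT`` — ends on different chromosomes;
* ``MACRO_ONLY`` — same chromosome (macro-synteny) but the microsynteny
  span/orientation test fails;
* ``MICRO`` — same chromosome, inter-end space of 10-300 kb (inclusive
  bounds) and tail-to-tail orientation (opposite strands, 3' ends internal).

"Space between both ends" is the inner gap between the two aligned
reference intervals — the coordinate difference between the right
interval's start and the left interval's end, clamped at zero for
overlapping intervals. In protein mode the subject of a unique assignment
is a gene; its chromosome comes from the gene→chromosome column of the
protein map, while coordinates and strand come from the (genome-projected)
hit itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .filtering import Mode, UniqueAssignment
from .io import BlastHit, End

MIN_SPAN = 10_000
MAX_SPAN = 300_000


class Classification(Enum):
    SINGLE_END = "single_end"
    DISCORDANT = "discordant"
    MACRO_ONLY = "macro_only"
    MICRO = "micro"


@dataclass(frozen=True)
class ClonePairing:
    """The (up to two) unique end assignments of one clone in one species/mode."""

    clone_id: str
    species: str
    forward: UniqueAssignment | None = None
    reverse: UniqueAssignment | None = None

    def __post_init__(self) -> None:
        if self.forward is None and self.reverse is None:
            raise ValueError(f"{self.clone_id}: pairing with no assigned end")
        modes = {a.mode for a in (self.forward, self.reverse) if a is not None}
        if len(modes) > 1:
            raise ValueError(f"{self.clone_id}: mixed search modes in one pairing")

    @property
    def is_paired(self) -> bool:
        return self.forward is not None and self.reverse is not None

    @property
    def mode(self) -> Mode:
        return (self.forward or self.reverse).mode


@dataclass(frozen=True)
class SyntenyCall:
    clone_id: str
    species: str
    mode: Mode
    classification: Classification
    chrom: str = ""
    span_bp: int = 0
    orientation_ok: bool = False
    ref_lo: int | None = None  # outer extent on the reference, 1-based inclusive
    ref_hi: int | None = None


def _chrom_of(a: UniqueAssignment, gene_chrom: Mapping[str, str] | None) -> str:
    if a.mode is Mode.PROTEIN:
        if gene_chrom is None:
            raise ValueError("protein-mode synteny needs a gene→chromosome mapping")
        return gene_chrom[a.gene_id]
    return a.hit.subject_id


def pair_ends(assignments: Iterable[UniqueAssignment], species: str) -> list[ClonePairing]:
    """Group unique assignments by clone; single-end clones stay flagged.

    Read IDs follow the ``<clone>_T7|SP6`` convention handled upstream, so
    the clone and end are recovered from each assignment's read id.
    """
    by_clone: dict[str, dict[End, UniqueAssignment]] = {}
    for a in assignments:
        clone, _, end_token = a.read_id.rpartition("_")
        if end_token.upper() not in ("T7", "SP6"):
            raise ValueError(f"read id {a.read_id!r} does not follow the <clone>_T7|SP6 convention")
        end = End.FORWARD if end_token.upper() == "T7" else End.REVERSE
        slot = by_clone.setdefault(clone, {})
        if end in slot:
            raise ValueError(f"two assignments for clone {clone} end {end.value}")
        slot[end] = a
    return [
        ClonePairing(clone_id=clone, species=species,
                     forward=slot.get(End.FORWARD), reverse=slot.get(End.REVERSE))
        for clone, slot in sorted(by_clone.items())
    ]


def same_chromosome(pairing: ClonePairing, gene_chrom: Mapping[str, str] | None = None) -> bool:
    """Macro-synteny test: both end hits on the same reference chromosome."""
    if not pairing.is_paired:
        raise ValueError(f"{pairing.clone_id}: same_chromosome needs both ends")
    return _chrom_of(pairing.forward, gene_chrom) == _chrom_of(pairing.reverse, gene_chrom)


def compute_span(hit_f: BlastHit, hit_r: BlastHit, check_chrom: bool = True) -> int:
    """Inner gap (bp) between two same-chromosome reference intervals.

    With each hit normalised to [lo, hi] and the pair ordered left/right,
    the span is ``lo_right - hi_left``, clamped at 0 for overlapping hits.
    """
    if check_chrom and hit_f.subject_id != hit_r.subject_id:
        raise ValueError("span undefined across chromosomes")
    (lo1, hi1), (lo2, hi2) = sorted(
        [(hit_f.s_lo, hit_f.s_hi), (hit_r.s_lo, hit_r.s_hi)]
    )
    return max(0, lo2 - hi1)


def tail_to_tail(hit_f: BlastHit, hit_r: BlastHit, check_chrom: bool = True) -> bool:
    """Opposing strands with both 3' ends internal.

    Ordering the two hits left/right by reference coordinate, the geometry
    holds iff the left hit is on the plus strand and the right hit on the
    minus strand — each read then points into the gap. Which physical end
    (T7/Sp6) is the left partner is irrelevant: end labelling of a clone is
    arbitrary, so the mirror configuration is accepted.
    """
    if check_chrom and hit_f.subject_id != hit_r.subject_id:
        raise ValueError("orientation undefined across chromosomes")
    left, right = sorted([hit_f, hit_r], key=lambda h: (h.s_lo, h.s_hi))
    return left.strand == "+" and right.strand == "-"


def call_synteny(pairing: ClonePairing, min_span: int = MIN_SPAN, max_span: int = MAX_SPAN,
                 gene_chrom: Mapping[str, str] | None = None) -> SyntenyCall:
    """Classify one clone pairing; span bounds are inclusive."""
    base = dict(clone_id=pairing.clone_id, species=pairing.species, mode=pairing.mode)
    if not pairing.is_paired:
        return SyntenyCall(classification=Classification.SINGLE_END, **base)
    if not same_chromosome(pairing, gene_chrom):
        return SyntenyCall(classification=Classification.DISCORDANT, **base)
    hit_f, hit_r = pairing.forward.hit, pairing.reverse.hit
    chrom = _chrom_of(pairing.forward, gene_chrom)
    span = compute_span(hit_f, hit_r, check_chrom=False)
    oriented = tail_to_tail(hit_f, hit_r, check_chrom=False)
    micro = oriented and min_span <= span <= max_span
    return SyntenyCall(
        classification=Classification.MICRO if micro else Classification.MACRO_ONLY,
        chrom=chrom, span_bp=span, orientation_ok=oriented,
        ref_lo=min(hit_f.s_lo, hit_r.s_lo), ref_hi=max(hit_f.s_hi, hit_r.s_hi), **base,
    )


def call_all(pairings: Sequence[ClonePairing], min_span: int = MIN_SPAN,
             max_span: int = MAX_SPAN,
             gene_chrom: Mapping[str, str] | None = None) -> list[SyntenyCall]:
    return [call_synteny(p, min_span, max_span, gene_chrom) for p in pairings]


_MACRO = {Classification.MACRO_ONLY, Classification.MICRO}


def intersect_modes(calls_a: Sequence[SyntenyCall], calls_b: Sequence[SyntenyCall],
                    ) -> tuple[int, list[str]]:
    """Clones reaching macro-synteny (same chromosome) in both search modes.

    Symmetric: the count is identical in either direction.
    """
    species = {c.species for c in list(calls_a) + list(calls_b)}
    if len(species) > 1:
        raise ValueError(f"intersect_modes across species {sorted(species)}")
    macro_a = {c.clone_id for c in calls_a if c.classification in _MACRO}
    macro_b = {c.clone_id for c in calls_b if c.classification in _MACRO}
    common = sorted(macro_a & macro_b)
    return len(common), common


def synteny_table(calls: Iterable[SyntenyCall]) -> pd.DataFrame:
    rows = [
        (c.clone_id, c.species, c.mode.value, c.classification.value, c.chrom,
         c.span_bp, c.orientation_ok)
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["clone_id", "species", "mode", "classification", "chrom", "span_bp",
                 "orientation_ok"],
    )
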