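"""Tandem-repeat (SSR/microsatellite) mining for motif periods 1-10.

Detection compares the sequence against itself at each candidate period p:
positions where ``s[i] == s[i+p]`` form match runs, adjacent runs merge while
the merged segment's purity stays above ``1 - max_mismatch_frac``, and each
surviving segment becomes a locus of length ``run + p``. Non-primitive
motifs (e.g. ACAC at period 4) are dropped — the same array is reported at
its smallest period. Overlapping calls of different periods resolve to the
higher-purity, then longer, call.

Motif classes merge a motif with its reverse complement ("GA/TC") but not
with its rotations (TG/CA and AC/GT stay distinct classes). The class label
is normalised with the lexicographically smaller motif first, so the label
is a pure, involutive function of the motif; survey tables in the
literature sometimes print the predominant observed motif first instead,
which permutes the label but denotes the same class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._intervals import overlap_length
from .io import BESRead

PERIOD_NAMES = {
    1: "Monomer", 2: "Dimer", 3: "Trimer", 4: "Tetramer", 5: "Pentamer",
    6: "Hexamer", 7: "Heptamer", 8: "Octomer", 9: "Nanomer", 10: "Decamer",
}

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(motif: str) -> str:
    return motif.translate(_RC)[::-1]


def canonical_class(motif: str) -> str:
    """Reverse-complement-merged class label "X/Y" for a motif.

    X is the lexicographically smaller of the motif and its reverse
    complement; involutive: ``canonical_class(revcomp(m)) == canonical_class(m)``.
    Rotated motifs map to distinct classes.
    """
    if not 1 <= len(motif) <= 10:
        raise ValueError(f"motif length {len(motif)} outside 1-10")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    rc = _revcomp(motif)
    x = min(motif, rc)
    return f"{x}/{_revcomp(x)}"


def is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repeat of a shorter unit."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


@dataclass(frozen=True)
class SSRLocus:
    """One tandem array: coordinates (0-based half-open), motif and quality.

    ``purity`` is the fraction of period-offset comparisons inside the locus
    that match (1.0 for a perfect array).
    """

    read_id: str
    start: int
    end: int
    motif: str
    copies: float
    purity: float

    def __post_init__(self) -> None:
        if self.end - self.start < 2 * len(self.motif):
            raise ValueError("locus shorter than two motif copies")

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.motif)


def default_min_copies(period: int) -> int:
    """Minimum copy number by period: 4 for mono/di, 3 for longer motifs."""
    return 4 if period <= 2 else 3


def _phase_compatible(seq: str, cur_start: int, run_start: int, p: int,
                      max_mismatch_frac: float) -> bool:
    """Can a later match run belong to the same tandem array as ``cur``?

    The run's leading unit must equal the array motif rotated to the run's
    phase, up to one substitution per unit for p >= 2 (a point substitution
    inside a unit legitimately breaks one offset comparison); monomer runs
    must match exactly, since a single base carries no phase structure.
    """
    shift = (run_start - cur_start) % p
    motif = seq[cur_start : cur_start + p]
    expected = motif[shift:] + motif[:shift]
    unit = seq[run_start : run_start + p]
    mismatches = sum(1 for x, y in zip(expected, unit) if x != y)
    limit = 0 if p == 1 else max(1, int(p * max_mismatch_frac))
    return mismatches <= limit


def _merge_runs(seq: str, runs: list[tuple[int, int, int]], p: int,
                beta: float | None, min_purity: float) -> list[tuple[int, int, int]]:
    """Chain period-p match runs across substitution gaps.

    Scoring: +1 per matching offset comparison, -beta per bridged mismatch
    (beta = (1-f)/f, so a chain at purity exactly 1-f scores zero). Runs are
    absorbed lazily: a pending tail is committed once its cumulative score
    turns positive, abandoned once it drops below -6*beta (or breaks phase),
    in which case the pending runs restart as their own chain. ``beta=None``
    (perfect mode) returns the runs unchanged.
    """
    if beta is None or len(runs) <= 1:
        return list(runs)
    max_mismatch_frac = 1.0 - min_purity
    segs: list[tuple[int, int, int]] = []
    cur = list(runs[0])
    pend_gap = pend_match = 0
    pend_start: int | None = None
    last_end = cur[1]
    j = 1
    while j < len(runs):
        a2, b2, r = runs[j]
        in_phase = _phase_compatible(seq, cur[0], a2, p, max_mismatch_frac)
        pend_gap += a2 - last_end
        pend_match += r
        last_end = b2
        score = pend_match - beta * pend_gap
        if (in_phase and score > 0
                and (cur[2] + pend_match) / (b2 - cur[0]) >= min_purity):
            cur = [cur[0], b2, cur[2] + pend_match]
            pend_gap = pend_match = 0
            pend_start = None
            j += 1
        elif not in_phase or score <= -6 * beta:
            segs.append(tuple(cur))
            restart = pend_start if pend_start is not None else j
            cur = list(runs[restart])
            last_end = cur[1]
            pend_gap = pend_match = 0
            pend_start = None
            j = restart + 1
        else:
            if pend_start is None:
                pend_start = j
            j += 1
    segs.append(tuple(cur))
    if pend_start is not None:
        segs.extend(tuple(runs[k]) for k in range(pend_start, len(runs)))
    return segs


def find_tandem_repeats(sequence: str, read_id: str = "", max_period: int = 10,
                        min_copies: int | None = None, min_length: int = 12,
                        max_mismatch_frac: float = 0.2) -> list[SSRLocus]:
    """Maximal tandem arrays of period <= ``max_period`` in ``sequence``.

    ``min_copies=None`` applies the per-period default. Returns loci sorted
    by start coordinate; overlaps across periods already resolved.
    """
    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    candidates: list[SSRLocus] = []
    for p in range(1, min(max_period, n // 2) + 1):
        e = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        if not e.any():
            continue
        edges = np.flatnonzero(np.diff(e.astype(np.int8)))
        starts = [0] if e[0] else []
        starts += [int(x) + 1 for x in edges[e[edges + 1]]] if len(edges) else []
        ends = [int(x) + 1 for x in edges[~e[edges + 1]]] if len(edges) else []
        if e[-1]:
            ends.append(len(e))
        runs: list[tuple[int, int, int]] = [
            (a, b, b - a) for a, b in zip(sorted(starts), sorted(ends))
        ]
        beta = ((1.0 - max_mismatch_frac) / max_mismatch_frac
                if max_mismatch_frac > 0 else None)
        merged = _merge_runs(seq, runs, p, beta, 1.0 - max_mismatch_frac)
        # Pure maximal runs also compete: overlap resolution prefers higher
        # purity, so a mismatch-bridged segment only wins where its pure
        # fragments fall below the length/copy thresholds.
        seen = set(merged)
        merged = merged + [r for r in runs if r not in seen]
        need = min_copies if min_copies is not None else default_min_copies(p)
        for a, b, m in merged:
            length = b - a + p
            copies = length / p
            if length < min_length or copies < need:
                continue
            motif = seq[a : a + p]
            if set(motif) - set("ACGT") or not is_primitive(motif):
                continue
            candidates.append(
                SSRLocus(read_id=read_id, start=a, end=a + length, motif=motif,
                         copies=copies, purity=m / (b - a))
            )
    # overlap resolution: higher purity, then longer, then leftmost/shortest period
    candidates.sort(key=lambda l: (-l.purity, -(l.end - l.start), l.start, l.period))
    kept: list[SSRLocus] = []
    for loc in candidates:
        if all(loc.end <= k.start or loc.start >= k.end for k in kept):
            kept.append(loc)
    kept.sort(key=lambda l: l.start)
    return kept


def find_ssrs_in_reads(reads: Sequence[BESRead], **kwargs) -> list[SSRLocus]:
    out: list[SSRLocus] = []
    for r in reads:
        out.extend(find_tandem_repeats(r.bases, read_id=r.read_id, **kwargs))
    return out


def flank_eligible(read: BESRead, locus: SSRLocus, min_flank: int = 50,
                   other_loci: Sequence[SSRLocus] = ()) -> bool:
    """True iff >= ``min_flank`` clean bases flank the locus on each side.

    Clean = unmasked and outside any SSR locus. Masking must run before this
    filter; a repeat-masked flank does not count toward primer real estate.
    """
    n = len(read.bases)
    if not (0 <= locus.start and locus.end <= n):
        raise ValueError(f"locus [{locus.start},{locus.end}) outside read of length {n}")
    dirty = list(read.mask) + [
        (l.start, l.end) for l in other_loci if not (l.start == locus.start and l.end == locus.end)
    ]
    left = locus.start - overlap_length(dirty, 0, locus.start)
    right = (n - locus.end) - overlap_length(dirty, locus.end, n)
    return left >= min_flank and right >= min_flank


def flank_sequences(read: BESRead, locus: SSRLocus) -> tuple[str, str]:
    """The raw left and right flank sequences of a locus (for primer design)."""
    return read.bases[: locus.start], read.bases[locus.end :]


@dataclass
class SSRReport:
    """Per-period, per-class counts plus flank/primer accounting.

    ``total`` counts loci; ``n_reads`` counts distinct reads carrying at
    least one locus (survey texts quote both, and they differ whenever a
    read holds several SSRs).
    """

    by_period: dict[str, dict[str, int]] = field(default_factory=dict)
    total: int = 0
    n_reads: int = 0
    eligible_count: int = 0
    primer_candidate_count: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (period, cls, count)
            for period, classes in self.by_period.items()
            for cls, count in classes.items()
        ]
        return pd.DataFrame(rows, columns=["period_group", "class", "count"])


def summarize_ssrs(loci: Sequence[SSRLocus], eligible: Sequence[SSRLocus] | None = None,
                   other_threshold: int = 5) -> SSRReport:
    """Tabulate loci by period group and canonical class.

    Classes with fewer than ``other_threshold`` loci roll into "Other" within
    their period group. ``eligible`` (the flank-passing subset) feeds the
    eligible/primer-candidate counts; primer candidacy here means
    flank-eligible with both flanks available for export.
    """
    report = SSRReport()
    counts: dict[int, dict[str, int]] = {}
    for loc in loci:
        counts.setdefault(loc.period, {}).setdefault(loc.canonical_class, 0)
        counts[loc.period][loc.canonical_class] += 1
    for p in sorted(counts):
        named: dict[str, int] = {}
        other = 0
        for cls in sorted(counts[p], key=lambda c: (-counts[p][c], c)):
            if counts[p][cls] >= other_threshold:
                named[cls] = counts[p][cls]
            else:
                other += counts[p][cls]
        if other:
            named["Other"] = other
        report.by_period[PERIOD_NAMES[p]] = named
    report.total = len(loci)
    report.n_reads = len({l.read_id for l in loci})
    if eligible is not None:
        report.eligible_count = len(eligible)
        report.primer_candidate_count = len(eligible)
    return report


def ssr_table(loci: Iterable[SSRLocus], eligible_ids: set[tuple[str, int, int]] | None = None,
              ) -> pd.DataFrame:
    rows = []
    for l in loci:
        rows.append(
            (l.read_id, l.start, l.end, l.motif, l.canonical_class, round(l.copies, 2),
             round(l.purity, 3),
             bool(eligible_ids and (l.read_id, l.start, l.end) in eligible_ids))
        )
    return pd.DataFrame(
        rows, columns=["read_id", "start", "end", "motif", "class", "copies", "purity", "eligible"]
    )
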