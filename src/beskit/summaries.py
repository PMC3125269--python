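"""Survey statistics: sequencing accounting, GC/Q20 metrics, synteny tables
and the marker-polymorphism summary.

All printed percentages and ratios go through :func:`percent` /
:func:`ratio`, which round half-up at the requested precision; every
emitted table keeps its raw count rows next to the derived values so each
percentage is recomputable (and audited) from its two counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Collection, Iterable, Mapping, Sequence

import pandas as pd

from .filtering import Mode, UniqueAssignment
from .io import NO_PRODUCT, BESRead, GenotypeRecord
from .synteny import Classification, SyntenyCall, intersect_modes


def _half_up(value: Decimal, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator/denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percent of a zero denominator")
    return _half_up(Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator)), decimals)


def ratio(numerator: float, denominator: float, decimals: int = 2) -> float:
    """numerator/denominator rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("ratio over a zero denominator")
    return _half_up(Decimal(str(numerator)) / Decimal(str(denominator)), decimals)


@dataclass
class SummaryTable:
    """Ordered count rows plus derived-percentage specifications.

    ``derived`` maps an output label to ``(numerator_row, denominator_row,
    decimals)``; :meth:`audit` re-derives every percentage from its rows and
    fails loudly on any mismatch, so a table can never print a percentage
    its own counts do not support.
    """

    title: str
    rows: dict[str, int] = field(default_factory=dict)
    derived: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def derived_values(self) -> dict[str, float]:
        out = {}
        for label, (num, den, decimals) in self.derived.items():
            if self.rows[den] == 0:
                continue
            out[label] = percent(self.rows[num], self.rows[den], decimals)
        return out

    def audit(self) -> None:
        for label, (num, den, _) in self.derived.items():
            if num not in self.rows or den not in self.rows:
                raise ValueError(f"{self.title}: derived {label!r} references a missing row")
        self.derived_values()

    def to_dict(self) -> dict:
        return {"title": self.title, "rows": dict(self.rows),
                "derived": self.derived_values()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(k, v, "") for k, v in self.rows.items()]
        rows += [(k, "", v) for k, v in self.derived_values().items()]
        return pd.DataFrame(rows, columns=["label", "count", "percent"])


def sequencing_accounting(reads: Sequence[BESRead]) -> SummaryTable:
    """Clone/read/bp accounting with the both-ends-sequenced percentage."""
    ends_by_clone: dict[str, set] = {}
    for r in reads:
        ends_by_clone.setdefault(r.clone_id, set()).add(r.end)
    both = sum(1 for ends in ends_by_clone.values() if len(ends) == 2)
    table = SummaryTable(title="sequencing accounting")
    table.rows = {
        "clones": len(ends_by_clone),
        "clones_both_ends": both,
        "clones_one_end": len(ends_by_clone) - both,
        "reads": len(reads),
        "total_bp": sum(len(r.bases) for r in reads),
    }
    if ends_by_clone:
        table.derived["both_end_pct"] = ("clones_both_ends", "clones", 0)
    table.audit()
    return table


def gc_content(reads: Iterable[BESRead] | Iterable[str] | str) -> float:
    """Percent G+C over unambiguous bases (ambiguity codes excluded entirely)."""
    if isinstance(reads, (str, BESRead)):
        reads = [reads]
    gc = atgc = 0
    for r in reads:
        seq = (r.bases if isinstance(r, BESRead) else r).upper()
        for c in seq:
            if c in "GC":
                gc += 1
                atgc += 1
            elif c in "AT":
                atgc += 1
    if atgc == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / atgc


def q20_length(read: BESRead, threshold: int = 20) -> int:
    """Number of bases called at phred quality >= ``threshold``."""
    if read.quals is None:
        raise ValueError(f"{read.read_id}: no quality values")
    return sum(1 for q in read.quals if q >= threshold)


def mean_q20(reads: Sequence[BESRead], threshold: int = 20) -> float:
    if not reads:
        raise ValueError("no reads")
    return sum(q20_length(r, threshold) for r in reads) / len(reads)


def synteny_summary(species: str, mode: Mode, read_ids_with_hits: Collection[str],
                    assignments: Mapping[str, UniqueAssignment | None],
                    calls: Sequence[SyntenyCall],
                    other_mode_calls: Sequence[SyntenyCall] = ()) -> SummaryTable:
    """The eight-row per-species synteny accounting table.

    Rows: reads with hits, reads with unique hits, clones with one/both
    hit-bearing ends, clones with both ends uniquely assigned, same-chromosome
    (macro) clones, clones macro-syntenic in the other search mode too, and
    microsynteny clones. Derived: macro percent of paired-unique clones and
    micro percent of macro clones.
    """
    for c in calls:
        if c.species != species or c.mode is not mode:
            raise ValueError(f"call for {c.species}/{c.mode} in {species}/{mode} summary")
    clones: dict[str, int] = {}
    for rid in read_ids_with_hits:
        clone = rid.rpartition("_")[0]
        clones[clone] = clones.get(clone, 0) + 1
    paired_unique = sum(
        1 for c in calls if c.classification is not Classification.SINGLE_END
    )
    macro = sum(
        1 for c in calls
        if c.classification in (Classification.MACRO_ONLY, Classification.MICRO)
    )
    micro = sum(1 for c in calls if c.classification is Classification.MICRO)
    both_modes, _ = intersect_modes(calls, other_mode_calls) if other_mode_calls else (0, [])
    table = SummaryTable(title=f"{species} {mode.value} synteny")
    table.rows = {
        "Total BES with hits": len(read_ids_with_hits),
        "BES with unique hits": sum(1 for a in assignments.values() if a is not None),
        "BAC with one end": sum(1 for n in clones.values() if n == 1),
        "Paired BAC-ends": sum(1 for n in clones.values() if n == 2),
        "Paired BAC-ends with unique hits": paired_unique,
        "Unique hits paired BAC-ends matched on the same chromosome": macro,
        "Also identified by the other mode": both_modes,
        "Microsynteny identified": micro,
    }
    table.derived = {
        "same_chromosome_pct": (
            "Unique hits paired BAC-ends matched on the same chromosome",
            "Paired BAC-ends with unique hits", 0),
        "microsynteny_pct": (
            "Microsynteny identified",
            "Unique hits paired BAC-ends matched on the same chromosome", 0),
    }
    table.audit()
    return table


@dataclass(frozen=True)
class PolymorphismSummary:
    """Marker panel outcome counts; failed/monomorphic/polymorphic partition
    the tested loci, duplicated loci are counted separately (a duplicated
    locus is usually also polymorphic)."""

    n_tested: int
    n_polymorphic: int
    n_failed: int
    n_monomorphic: int
    n_duplicated: int
    allele_range: tuple[int, int] | None

    def __post_init__(self) -> None:
        if self.n_polymorphic + self.n_failed + self.n_monomorphic != self.n_tested:
            raise ValueError("polymorphism classes must partition the tested loci")

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        return {
            "polymorphic_pct": percent(self.n_polymorphic, self.n_tested, decimals),
            "failed_pct": percent(self.n_failed, self.n_tested, decimals),
            "monomorphic_pct": percent(self.n_monomorphic, self.n_tested, decimals),
        }


def polymorphism_summary(genotypes: Sequence[GenotypeRecord]) -> PolymorphismSummary:
    """Classify each tested marker from its parent genotypes.

    Failed: no parent produced a product (or nothing was observed at all);
    monomorphic: a single allele size across all parents; polymorphic:
    two or more allele sizes; duplicated: some diploid parent shows more
    than two alleles. The allele-number range is over polymorphic loci.
    """
    if not genotypes:
        raise ValueError("no genotype records")
    by_marker: dict[str, list[GenotypeRecord]] = {}
    for g in genotypes:
        by_marker.setdefault(g.marker_id, []).append(g)
    n_poly = n_failed = n_mono = n_dup = 0
    allele_counts: list[int] = []
    for marker, recs in by_marker.items():
        observed: set[int] = set()
        duplicated = False
        for r in recs:
            if r.alleles == NO_PRODUCT:
                continue
            observed.update(r.alleles)
            if isinstance(r.alleles, list) and len(r.alleles) > 2:
                duplicated = True
        if duplicated:
            n_dup += 1
        if not observed:
            n_failed += 1
        elif len(observed) == 1:
            n_mono += 1
        else:
            n_poly += 1
            allele_counts.append(len(observed))
    return PolymorphismSummary(
        n_tested=len(by_marker), n_polymorphic=n_poly, n_failed=n_failed,
        n_monomorphic=n_mono, n_duplicated=n_dup,
        allele_range=(min(allele_counts), max(allele_counts)) if allele_counts else None,
    )


def genome_coverage_pct(total_bp: int, genome_size_bp: float, decimals: int = 0) -> float:
    """Sequenced fraction of an assumed genome size, as a percent."""
    return percent(total_bp, genome_size_bp, decimals)
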