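"""Three-step BLAST-hit filtration to at most one unique assignment per read.

Pipeline per read: (0) global e-value cutoff (default 1e-5); (1) keep only
hits at the minimal e-value; (2) among those, keep the hits with the highest
HSP score (percent identity x alignment length); (3) the read survives iff
exactly one *subject* remains. In protein mode, peptide subjects are first
collapsed to their gene (one gene encodes several peptides), so two
surviving peptides of one gene still make a unique gene hit. Residual ties
across distinct subjects after step 2 leave the read non-unique; breaking
such ties any other way would invent information.

Every step returns a subset of its input, and the result is independent of
input hit order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import pandas as pd

from .io import BlastHit

EVALUE_CUTOFF = 1e-5


class Mode(Enum):
    NUCLEOTIDE = "blastn"
    PROTEIN = "blastx"


@dataclass(frozen=True)
class UniqueAssignment:
    """The single surviving hit of a read, at nucleotide or gene level."""

    read_id: str
    mode: Mode
    hit: BlastHit
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.mode is Mode.PROTEIN and not self.gene_id:
            raise ValueError(f"{self.read_id}: protein-mode assignment without gene_id")

    @property
    def subject(self) -> str:
        """Subject identity used for synteny: chromosome (NT) or gene (protein)."""
        return self.gene_id if self.mode is Mode.PROTEIN else self.hit.subject_id


def apply_evalue_cutoff(hits: Sequence[BlastHit], cutoff: float = EVALUE_CUTOFF) -> list[BlastHit]:
    """Keep hits with e-value <= cutoff, preserving order."""
    return [h for h in hits if h.evalue <= cutoff]


def filter_min_evalue(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Step 1: the subset attaining the minimal e-value (ties all kept)."""
    if not hits:
        return []
    best = min(h.evalue for h in hits)
    return [h for h in hits if h.evalue == best]


def tiebreak_hsp(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Step 2: the subset attaining the maximal HSP score (%identity x length)."""
    if not hits:
        return []
    best = max(h.hsp_score for h in hits)
    return [h for h in hits if h.hsp_score == best]


def collapse_protein_to_gene(hits: Sequence[BlastHit], protein_to_gene: Mapping[str, str],
                             strict: bool = False) -> list[tuple[BlastHit, str]]:
    """Attach each peptide hit's gene ID; subject identity becomes the gene.

    Unmapped protein IDs are dropped with a warning by default, or raise in
    ``strict`` mode.
    """
    out: list[tuple[BlastHit, str]] = []
    unmapped: list[str] = []
    for h in hits:
        gene = protein_to_gene.get(h.subject_id)
        if gene is None:
            unmapped.append(h.subject_id)
        else:
            out.append((h, gene))
    if unmapped:
        msg = f"{len(unmapped)} hits to unmapped protein IDs (e.g. {unmapped[0]!r})"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg, stacklevel=2)
    return out


def _canon(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Deterministic internal order so results never depend on input order."""
    return sorted(
        hits,
        key=lambda h: (h.evalue, -h.hsp_score, h.subject_id, h.s_lo, h.s_hi, h.q_start),
    )


def assign_unique(hits_for_one_read: Sequence[BlastHit], mode: Mode,
                  protein_to_gene: Mapping[str, str] | None = None,
                  cutoff: float = EVALUE_CUTOFF, strict: bool = False,
                  ) -> UniqueAssignment | None:
    """Run the full filtration for one read; an assignment iff one subject survives.

    Protein mode requires ``protein_to_gene``; collapsing happens before
    uniqueness is judged, so multiple peptides of one gene count as one
    subject.
    """
    hits = _canon(apply_evalue_cutoff(hits_for_one_read, cutoff))
    if not hits:
        return None
    read_ids = {h.query_id for h in hits}
    if len(read_ids) != 1:
        raise ValueError(f"hits from several reads passed together: {sorted(read_ids)}")
    if mode is Mode.PROTEIN:
        if protein_to_gene is None:
            raise ValueError("protein mode requires a protein→gene mapping")
        pairs = collapse_protein_to_gene(hits, protein_to_gene, strict=strict)
    else:
        pairs = [(h, "") for h in hits]
    if not pairs:
        return None
    survivors = filter_min_evalue([h for h, _ in pairs])
    survivors = tiebreak_hsp(survivors)
    gene_of = {id(h): g for h, g in pairs}
    subjects = {gene_of[id(h)] if mode is Mode.PROTEIN else h.subject_id for h in survivors}
    if len(subjects) != 1:
        return None
    best = survivors[0]  # _canon order: best evalue, then hsp, then stable keys
    return UniqueAssignment(read_id=best.query_id, mode=mode, hit=best,
                            gene_id=gene_of[id(best)] if mode is Mode.PROTEIN else "")


def assign_all(hits: Sequence[BlastHit], mode: Mode,
               protein_to_gene: Mapping[str, str] | None = None,
               cutoff: float = EVALUE_CUTOFF) -> dict[str, UniqueAssignment | None]:
    """Filtration for every read present in ``hits``; None marks ambiguity.

    Reads with no hit at all simply do not appear in the result.
    """
    by_read: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_read.setdefault(h.query_id, []).append(h)
    return {
        rid: assign_unique(rhits, mode, protein_to_gene, cutoff)
        for rid, rhits in sorted(by_read.items())
    }


def filtration_table(assignments: Mapping[str, UniqueAssignment | None]) -> pd.DataFrame:
    """Per-read filtration outcome TSV body (status unique/ambiguous)."""
    rows = []
    for rid in sorted(assignments):
        a = assignments[rid]
        if a is None:
            rows.append((rid, "", "", "", "", "", "ambiguous"))
        else:
            rows.append(
                (rid, a.mode.value, a.subject, a.hit.s_lo, a.hit.s_hi,
                 a.hit.evalue, "unique")
            )
    return pd.DataFrame(
        rows, columns=["read_id", "mode", "subject", "s_lo", "s_hi", "evalue", "status"]
    )
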