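"""Readers and writers for every external format the pipeline touches.

Formats: FASTA end-reads (with optional companion ``.qual`` phred files),
repeat-library FASTA with ``#class`` header tags, 12-column BLAST tabular
output with ``#`` comment lines, BED6 for synteny blocks, and TSV genotype
tables.

End-read naming: the deposited data does not fix how the sequencing-primer
end (T7 = forward, Sp6 = reverse) is encoded in read names, so the header
convention is a configurable regex. The default expects ``<clone>_T7`` /
``<clone>_SP6`` (case-insensitive end token).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.FastaIO import SimpleFastaParser

from ._intervals import Interval, normalize

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

DEFAULT_HEADER_RE = re.compile(r"^(?P<clone>.+)_(?P<end>T7|SP6)$", re.IGNORECASE)

#: Sentinel used in genotype tables for a marker/parent pair that yielded no
#: specific PCR product.
NO_PRODUCT = "NO_PRODUCT"


class End(Enum):
    """Which end of the BAC insert a read comes from (T7 forward, Sp6 reverse)."""

    FORWARD = "T7"
    REVERSE = "SP6"


class FormatError(ValueError):
    """Raised for malformed records in any supported external format."""


@dataclass
class BESRead:
    """One BAC-end read: sequence, optional phred qualities and mask intervals.

    ``mask`` is a sorted, merged list of 0-based half-open intervals marking
    repetitive (or otherwise excluded) sequence. Bases are stored uppercase;
    soft-masked (lowercase) input is imported into ``mask``.
    """

    read_id: str
    clone_id: str
    end: End
    bases: str
    quals: list[int] | None = None
    mask: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.read_id}: {len(self.quals)} quality values for "
                f"{len(self.bases)} bases"
            )
        self.mask = normalize(self.mask, len(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def with_mask(self, intervals: Iterable[Interval]) -> "BESRead":
        """Copy of the read with ``intervals`` merged into its mask."""
        return replace(self, mask=normalize(list(self.mask) + list(intervals), len(self.bases)))


@dataclass(frozen=True)
class BlastHit:
    """One 12-column BLAST tabular alignment line.

    Subject coordinates are 1-based inclusive; ``s_start > s_end`` encodes a
    minus-strand hit. ``hsp_score`` is the tie-break score used by the hit
    filtration: percent identity (0-100 scale) times alignment length.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"{self.query_id}: q_start {self.q_start} > q_end {self.q_end}")
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value {self.evalue}")
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"{self.query_id}: percent identity {self.pct_identity}")

    @property
    def hsp_score(self) -> float:
        return self.pct_identity * self.aln_length

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass(frozen=True)
class GenotypeRecord:
    """Observed alleles (fragment sizes, bp) of one marker in one diploid parent.

    ``alleles`` is either a list of allele sizes, the :data:`NO_PRODUCT`
    sentinel (failed PCR), or an empty list (missing data). More than two
    alleles in a single parent flags a duplicated locus downstream.
    """

    marker_id: str
    parent_id: str
    alleles: list[int] | str

    def __post_init__(self) -> None:
        if isinstance(self.alleles, str):
            if self.alleles != NO_PRODUCT:
                raise ValueError(f"bad allele sentinel {self.alleles!r}")
        else:
            for a in self.alleles:
                if a < 0:
                    raise ValueError(
                        f"{self.marker_id}/{self.parent_id}: negative allele size {a}"
                    )


def _soft_mask_intervals(seq: str) -> list[Interval]:
    out = []
    start = None
    for i, c in enumerate(seq):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(seq)))
    return out


def read_fasta(
    path: str | Path,
    header_re: re.Pattern | str = DEFAULT_HEADER_RE,
    qual_path: str | Path | None = None,
    on_error: str = "raise",
) -> list[BESRead]:
    """Read BAC-end reads from FASTA, importing lowercase runs as soft mask.

    Headers must match ``header_re`` (groups ``clone`` and ``end``); the end
    token T7 maps to :attr:`End.FORWARD` and SP6 to :attr:`End.REVERSE`.
    ``qual_path`` may point to a companion phred ``.qual`` file with matching
    record ids. ``on_error`` is ``"raise"`` or ``"skip"`` for malformed
    headers / non-IUPAC records.
    """
    if isinstance(header_re, str):
        header_re = re.compile(header_re)
    quals: dict[str, list[int]] = {}
    if qual_path is not None:
        for rec in SeqIO.parse(str(qual_path), "qual"):
            quals[rec.id] = list(rec.letter_annotations["phred_quality"])

    reads: list[BESRead] = []
    seen: set[tuple[str, End]] = set()
    with open(path) as fh:
        for recno, (title, seq) in enumerate(SimpleFastaParser(fh), start=1):
            read_id = title.split()[0]
            m = header_re.match(read_id)
            if m is None:
                if on_error == "skip":
                    continue
                raise FormatError(f"record {recno} ({read_id!r}): header does not match convention")
            bad = set(seq.upper()) - IUPAC_DNA
            if bad:
                if on_error == "skip":
                    continue
                raise FormatError(
                    f"record {recno} ({read_id!r}): non-IUPAC characters {sorted(bad)}"
                )
            end = End.FORWARD if m.group("end").upper() == "T7" else End.REVERSE
            key = (m.group("clone"), end)
            if key in seen:
                raise FormatError(f"record {recno}: duplicate clone/end {key}")
            seen.add(key)
            reads.append(
                BESRead(
                    read_id=read_id,
                    clone_id=m.group("clone"),
                    end=end,
                    bases=seq.upper(),
                    quals=quals.get(read_id),
                    mask=_soft_mask_intervals(seq),
                )
            )
    return reads


def write_fasta(reads: Sequence[BESRead], path: str | Path, qual_path: str | Path | None = None,
                line_width: int = 60) -> None:
    """Write reads as FASTA, encoding mask intervals as lowercase (soft mask)."""
    with open(path, "w") as fh:
        for r in reads:
            seq = list(r.bases.upper())
            for s, e in r.mask:
                for i in range(s, e):
                    seq[i] = seq[i].lower()
            fh.write(f">{r.read_id}\n")
            text = "".join(seq)
            for i in range(0, len(text), line_width):
                fh.write(text[i : i + line_width] + "\n")
    if qual_path is not None:
        with open(qual_path, "w") as fh:
            for r in reads:
                if r.quals is None:
                    continue
                fh.write(f">{r.read_id}\n")
                for i in range(0, len(r.quals), 20):
                    fh.write(" ".join(str(q) for q in r.quals[i : i + 20]) + "\n")


_BLAST_COLS = 12


def parse_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse 12-column BLAST tabular output (``-m9`` dialect, '#' comments).

    Strand is inferred from subject coordinate order; the HSP tie-break score
    is available on every hit. Lines with a wrong field count or unparsable
    numbers raise :class:`FormatError` naming the line.
    """
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _BLAST_COLS:
                raise FormatError(f"line {lineno}: expected {_BLAST_COLS} fields, got {len(fields)}")
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Sequence[BlastHit], path: str | Path, comment: str | None = None) -> None:
    """Write hits in the 12-column tabular dialect (used by the simulator)."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_length,
                        h.mismatches, h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end,
                        f"{h.evalue:.2g}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )


def write_synteny_bed(calls: Sequence, path: str | Path) -> int:
    """Write synteny calls carrying reference coordinates as BED6.

    Coordinates convert from 1-based inclusive to BED's 0-based half-open.
    Calls without a chromosome/extent (single-end, discordant) are skipped.
    Returns the number of lines written; output is sorted by (chrom, start).
    """
    rows = []
    for c in calls:
        chrom = getattr(c, "chrom", None)
        lo, hi = getattr(c, "ref_lo", None), getattr(c, "ref_hi", None)
        if not chrom or lo is None or hi is None:
            continue
        rows.append((chrom, lo - 1, hi, c.clone_id, 0, "+"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return len(rows)


def read_genotype_table(path: str | Path) -> list[GenotypeRecord]:
    """Read a marker×parent genotype TSV (columns marker, parent, allele1, allele2).

    A blank allele cell is missing; the token ``NP`` means no PCR product.
    Extra allele columns (allele3, ...) are accepted for duplicated loci.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"marker", "parent"}
    if not required <= set(df.columns):
        raise FormatError(f"genotype table needs columns {sorted(required)}")
    allele_cols = [c for c in df.columns if c.startswith("allele")]
    records: list[GenotypeRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        key = (row["marker"], row["parent"])
        if key in seen:
            raise FormatError(f"duplicate (marker, parent) row {key}")
        seen.add(key)
        tokens = [row[c].strip() for c in allele_cols if row[c].strip()]
        if any(t.upper() == "NP" for t in tokens):
            alleles: list[int] | str = NO_PRODUCT
        else:
            try:
                alleles = [int(t) for t in tokens]
            except ValueError as exc:
                raise FormatError(f"row {idx + 2}: bad allele size in {tokens}") from exc
            if any(a < 0 for a in alleles):
                raise FormatError(f"row {idx + 2}: negative allele size")
        records.append(GenotypeRecord(marker_id=key[0], parent_id=key[1], alleles=alleles))
    return records


def write_genotype_table(records: Sequence[GenotypeRecord], path: str | Path) -> None:
    n_allele_cols = max(
        (len(r.alleles) for r in records if isinstance(r.alleles, list)), default=2
    )
    n_allele_cols = max(n_allele_cols, 2)
    cols = ["marker", "parent"] + [f"allele{i + 1}" for i in range(n_allele_cols)]
    rows = []
    for r in records:
        if r.alleles == NO_PRODUCT:
            vals = ["NP"] + [""] * (n_allele_cols - 1)
        else:
            vals = [str(a) for a in r.alleles] + [""] * (n_allele_cols - len(r.alleles))
        rows.append([r.marker_id, r.parent_id] + vals)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_repeat_library(path: str | Path) -> list:
    """Read a repeat library FASTA; ``#class`` tags in headers give the class.

    Header convention: ``>name#DNA/TcMar-Tc1 optional description``. A header
    without a tag gets class ``Unknown``. Returns RepeatElement objects.
    """
    from .masking import RepeatElement

    elems = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            token = title.split()[0]
            if "#" in token:
                name, rclass = token.split("#", 1)
            else:
                name, rclass = token, "Unknown"
            elems.append(RepeatElement(name=name, repeat_class=rclass, consensus=seq.upper()))
    return elems


def write_repeat_library(elems: Sequence, path: str | Path, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for e in elems:
            fh.write(f">{e.name}#{e.repeat_class}\n")
            for i in range(0, len(e.consensus), line_width):
                fh.write(e.consensus[i : i + line_width] + "\n")


def read_protein_gene_map(path: str | Path) -> pd.DataFrame:
    """Read the protein-ID → gene-ID mapping TSV (columns protein, gene[, chrom])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"protein", "gene"} <= set(df.columns):
        raise FormatError("protein→gene map needs columns protein, gene")
    return df
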