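"""Library-based repeat masking and the masked-read self-alignment census.

The masker is a seed-and-extend local aligner: shared k-mer seeds between a
read and a repeat-library consensus (either strand) are extended along the
diagonal with +1/-1 scoring and an x-drop stop. Every extension whose
identity and length clear the thresholds contributes its read interval to
the mask. Defaults (seed_k=11, min_identity=0.80, min_hit_len=30) emulate
cross_match-style masking behaviour at survey scale. Extensions are
ungapped; the divergence model this pipeline targets (point substitutions
between repeat copies and their consensus) does not require gapped
extension, and indel-containing copies simply mask as two shorter hits.

Masking records intervals and never rewrites bases, so downstream steps can
choose a hard- or soft-masked view.

Significance of self-alignment hits uses the ungapped Karlin-Altschul
statistic for +1/-1 scoring on a uniform base composition
(lambda = ln 3, K ~ 0.333): E = K * m * n * exp(-lambda * S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from ._intervals import Interval, complement, normalize, total_length
from .io import BESRead

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class RepeatElement:
    """One repeat family: a named consensus with a repeat-class label."""

    name: str
    repeat_class: str
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        if not self.repeat_class:
            raise ValueError(f"{self.name}: empty repeat class")


@dataclass(frozen=True)
class MaskParams:
    """Aligner thresholds: seed word length, identity/length cutoffs, x-drop."""

    seed_k: int = 11
    min_identity: float = 0.80
    min_hit_len: int = 30
    xdrop: int = 15

    def __post_init__(self) -> None:
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


class CensusClass(Enum):
    LOW = "LOW"          # <= 10 self-alignment hits
    MODERATE = "MODERATE"  # 11..50
    HIGH = "HIGH"        # > 50


@dataclass(frozen=True)
class CensusResult:
    read_id: str
    hit_count: int

    @property
    def census_class(self) -> CensusClass:
        return classify_hit_count(self.hit_count)


def classify_hit_count(hit_count: int) -> CensusClass:
    """Bin a self-alignment hit count.

    The census histogram bins are "fewer than 10" and "more than 10"/"more
    than 50"; counts of exactly 10 and exactly 50 fall to the lower bin.
    """
    if hit_count < 0:
        raise ValueError("negative hit count")
    if hit_count > 50:
        return CensusClass.HIGH
    if hit_count > 10:
        return CensusClass.MODERATE
    return CensusClass.LOW


# ---------------------------------------------------------------------------
# seed-and-extend core

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _xdrop_extend(eq: np.ndarray, lo: int, hi: int, xdrop: int) -> tuple[int, int, int]:
    """Extend the all-match seed [lo, hi) within the match/mismatch vector ``eq``.

    Returns (start, end, score) of the best-scoring segment found by x-drop
    extension left of ``lo`` and right of ``hi`` with +1/-1 scoring.
    """
    score = hi - lo
    end = hi
    if hi < len(eq):
        s = np.where(eq[hi:], 1, -1).cumsum()
        runmax = np.maximum.accumulate(s)
        stop = np.argmax(runmax - s > xdrop) if np.any(runmax - s > xdrop) else len(s)
        if stop > 0:
            seg = s[:stop]
            best = int(seg.max())
            if best > 0:
                end = hi + int(seg.argmax()) + 1
                score += best
    start = lo
    if lo > 0:
        s = np.where(eq[lo - 1 :: -1], 1, -1).cumsum()
        runmax = np.maximum.accumulate(s)
        stop = np.argmax(runmax - s > xdrop) if np.any(runmax - s > xdrop) else len(s)
        if stop > 0:
            seg = s[:stop]
            best = int(seg.max())
            if best > 0:
                start = lo - (int(seg.argmax()) + 1)
                score += best
    return start, end, score


@dataclass(frozen=True)
class LocalHit:
    """A local alignment of a read interval to a library/target sequence."""

    target: str
    strand: str
    read_start: int
    read_end: int
    matches: int
    score: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def identity(self) -> float:
        return self.matches / self.length if self.length else 0.0


class SeedIndex:
    """k-mer index over a set of target sequences, both strands."""

    def __init__(self, targets: dict[str, str], k: int):
        self.k = k
        self.targets: dict[tuple[str, str], np.ndarray] = {}
        self.index: dict[bytes, list[tuple[str, str, int]]] = {}
        for name, seq in targets.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                enc = _encode(s)
                self.targets[(name, strand)] = enc
                b = s.upper().encode("ascii")
                for pos in range(0, len(s) - k + 1):
                    kmer = b[pos : pos + k]
                    if b"N" in kmer:
                        continue
                    self.index.setdefault(kmer, []).append((name, strand, pos))

    def scan(self, read: str, params: MaskParams,
             skip_target: str | None = None) -> list[LocalHit]:
        """All qualifying ungapped local alignments of ``read`` to the targets."""
        k = self.k
        enc_read = _encode(read)
        n = len(read)
        b = read.upper().encode("ascii")
        done: set[tuple[str, str, int]] = set()
        hits: list[LocalHit] = []
        for i in range(0, n - k + 1):
            kmer = b[i : i + k]
            for name, strand, pos in self.index.get(kmer, ()):
                if name == skip_target:
                    continue
                diag = i - pos
                key = (name, strand, diag)
                if key in done:
                    continue
                done.add(key)
                tgt = self.targets[(name, strand)]
                m = len(tgt)
                i0, i1 = max(0, diag), min(n, m + diag)
                eq = (enc_read[i0:i1] == tgt[i0 - diag : i1 - diag]) & (enc_read[i0:i1] != 255)
                lo, hi, score = _xdrop_extend(eq, i - i0, i - i0 + k, params.xdrop)
                length = hi - lo
                matches = int(eq[lo:hi].sum())
                if length >= params.min_hit_len and matches / length >= params.min_identity:
                    hits.append(
                        LocalHit(target=name, strand=strand, read_start=i0 + lo,
                                 read_end=i0 + hi, matches=matches, score=score)
                    )
        return hits


def build_library_index(library: Sequence[RepeatElement], params: MaskParams) -> SeedIndex:
    if not library:
        raise ValueError("empty repeat library")
    return SeedIndex({e.name: e.consensus for e in library}, params.seed_k)


# ---------------------------------------------------------------------------
# public masking operations


def mask_with_library(read: BESRead, library: Sequence[RepeatElement] | SeedIndex,
                      params: MaskParams = MaskParams()) -> BESRead:
    """Return the read with repeat-library alignments added to its mask.

    Strand-symmetric; bases are unchanged; intervals are merged with any
    pre-existing mask. A read with no qualifying alignment is returned with
    its mask unchanged (idempotent).
    """
    index = library if isinstance(library, SeedIndex) else build_library_index(library, params)
    hits = index.scan(read.bases, params)
    return read.with_mask((h.read_start, h.read_end) for h in hits)


def mask_reads(reads: Sequence[BESRead], library: Sequence[RepeatElement],
               params: MaskParams = MaskParams()) -> list[BESRead]:
    index = build_library_index(library, params)
    return [mask_with_library(r, index, params) for r in reads]


def screen_contaminants(reads: Sequence[BESRead], contaminant_library: Sequence[RepeatElement],
                        min_identity: float = 0.95, min_cov: float = 0.8,
                        params: MaskParams | None = None,
                        ) -> tuple[list[BESRead], list[BESRead]]:
    """Split reads into (kept, removed) by similarity to vector/host sequence.

    A read is removed iff its qualifying local alignments to the contaminant
    library (identity >= min_identity) cover at least ``min_cov`` of its
    length.
    """
    if not contaminant_library:
        raise ValueError("empty contaminant library")
    p = params or MaskParams(min_identity=min_identity)
    if p.min_identity != min_identity:
        p = MaskParams(seed_k=p.seed_k, min_identity=min_identity,
                       min_hit_len=p.min_hit_len, xdrop=p.xdrop)
    index = build_library_index(contaminant_library, p)
    kept, removed = [], []
    for r in reads:
        hits = index.scan(r.bases, p)
        covered = total_length(normalize([(h.read_start, h.read_end) for h in hits],
                                         len(r.bases)))
        (removed if len(r.bases) and covered / len(r.bases) >= min_cov else kept).append(r)
    return kept, removed


def masked_fraction(reads: Sequence[BESRead]) -> float:
    """Percent of base pairs covered by mask intervals over the whole read set."""
    total = sum(len(r.bases) for r in reads)
    if total == 0:
        raise ValueError("zero total sequence length")
    masked = sum(total_length(r.mask) for r in reads)
    return 100.0 * masked / total


def cross_mask_fraction(library_a: Sequence[RepeatElement], library_b: Sequence[RepeatElement],
                        params: MaskParams = MaskParams()) -> float:
    """Mask library_a's consensus sequences with library_b; percent bp masked.

    Asymmetric by construction: measures how much of one repeat library's
    content the other library recognises.
    """
    if not library_a or not library_b:
        raise ValueError("empty library")
    from .io import End

    pseudo = [BESRead(read_id=e.name, clone_id=e.name, end=End.FORWARD, bases=e.consensus)
              for e in library_a]
    masked = mask_reads(pseudo, list(library_b), params)
    return masked_fraction(masked)


def nonrepetitive_eligible(read: BESRead, min_run: int = 100) -> tuple[bool, Interval | None]:
    """Longest contiguous unmasked run; eligible iff strictly longer than ``min_run``."""
    runs = complement(read.mask, len(read.bases))
    if not runs:
        return False, None
    longest = max(runs, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return (longest[1] - longest[0]) > min_run, longest


def evalue_ungapped(score: int, m: int, n: int,
                    lam: float = math.log(3.0), k_const: float = 0.333) -> float:
    """Karlin-Altschul E-value for an ungapped +1/-1 local alignment score."""
    if m <= 0 or n <= 0:
        return math.inf
    return k_const * m * n * math.exp(-lam * score)


def _unmasked_segments(read: BESRead) -> list[tuple[int, str]]:
    return [(s, read.bases[s:e]) for s, e in complement(read.mask, len(read.bases))]


def self_hit_census(reads: Sequence[BESRead], evalue_cutoff: float = 1e-5,
                    params: MaskParams = MaskParams(), max_diags_per_pair: int = 8,
                    ) -> list[CensusResult]:
    """All-vs-all alignment of masked reads; counts significant partners.

    Only unmasked sequence participates. For each read, ``hit_count`` is the
    number of *other* reads with at least one local alignment whose ungapped
    Karlin-Altschul E-value (search space = the two reads' unmasked lengths)
    is <= ``evalue_cutoff``. Reads left with repetitive sequence the library
    missed show up with high counts.
    """
    k = params.seed_k
    # index unmasked segments of every read, forward strand only in the index;
    # strand symmetry is handled by also scanning each read's reverse complement
    seg_index: dict[bytes, list[tuple[int, int, int]]] = {}
    segments: list[list[tuple[int, str]]] = []
    unmasked_len: list[int] = []
    for ridx, read in enumerate(reads):
        segs = _unmasked_segments(read)
        segments.append(segs)
        unmasked_len.append(sum(len(s) for _, s in segs))
        for sidx, (_, seq) in enumerate(segs):
            b = seq.upper().encode("ascii")
            for pos in range(0, len(seq) - k + 1):
                kmer = b[pos : pos + k]
                if b"N" not in kmer:
                    seg_index.setdefault(kmer, []).append((ridx, sidx, pos))

    counts = [0] * len(reads)
    seen_pairs: set[tuple[int, int]] = set()
    for ridx, read in enumerate(reads):
        for strand in ("+", "-"):
            for _, seq in segments[ridx]:
                q = seq if strand == "+" else revcomp(seq)
                enc_q = _encode(q)
                b = q.upper().encode("ascii")
                tried: dict[int, int] = {}
                for i in range(0, len(q) - k + 1):
                    for oidx, sidx, pos in seg_index.get(b[i : i + k], ()):
                        if oidx == ridx:
                            continue
                        pair = (min(ridx, oidx), max(ridx, oidx))
                        if pair in seen_pairs:
                            continue
                        if tried.get(oidx, 0) >= max_diags_per_pair:
                            continue
                        tried[oidx] = tried.get(oidx, 0) + 1
                        tseq = segments[oidx][sidx][1]
                        enc_t = _encode(tseq)
                        diag = i - pos
                        i0, i1 = max(0, diag), min(len(q), len(tseq) + diag)
                        eq = (enc_q[i0:i1] == enc_t[i0 - diag : i1 - diag]) & (enc_q[i0:i1] != 255)
                        _, _, score = _xdrop_extend(eq, i - i0, i - i0 + k, params.xdrop)
                        ev = evalue_ungapped(score, unmasked_len[ridx], unmasked_len[oidx])
                        if ev <= evalue_cutoff:
                            seen_pairs.add(pair)
                            counts[ridx] += 1
                            counts[oidx] += 1
    return [CensusResult(read_id=r.read_id, hit_count=c) for r, c in zip(reads, counts)]


def census_table(results: Iterable[CensusResult]):
    """Census results as a DataFrame (read_id, hit_count, census_class)."""
    import pandas as pd

    return pd.DataFrame(
        [(r.read_id, r.hit_count, r.census_class.value) for r in results],
        columns=["read_id", "hit_count", "census_class"],
    )
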