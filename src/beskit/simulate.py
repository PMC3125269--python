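"""Synthetic data with recorded ground truth for every pipeline input.

The generator emulates a large-insert (BAC) end-sequencing survey of a
genome without a reference assembly:

* a *source* genome with implanted repeat families (diverged copies of
  random consensus sequences) and perfect SSR arrays;
* a *reference* genome: the source split into chromosomes and shuffled by
  segmental rearrangements (inter-chromosomal translocations, optionally
  inverted, and intra-chromosomal inversions), tracked as a block map;
* paired end reads from clone inserts (default 100-200 kb, so that a
  collinear clone's inter-end gap falls inside the 10-300 kb microsynteny
  window), both ends sequenced at a configurable rate (default 0.92), read
  lengths in 101-832 bp with mean about 546 bp, and plateau-with-tail
  phred qualities;
* emulated 12-column BLAST tabular hits projecting each read through the
  block map, with configurable miss/paralog/tie noise — in protein mode the
  subjects are peptides of bucketed genes, with the protein→gene(→chromosome)
  table emitted alongside;
* a marker×parent genotype table with configurable polymorphic / failed /
  duplicated fractions.

Everything is deterministic under the config seed; the TruthRegistry
records what was implanted so recovery can be measured exactly.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import BESRead, BlastHit, End
from .masking import RepeatElement, revcomp

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One implanted repeat family: consensus length, copies, divergence."""

    consensus_len: int = 400
    copy_number: int = 30
    divergence: float = 0.10  # substitution rate of copies vs consensus


@dataclass(frozen=True)
class HitNoise:
    miss_rate: float = 0.0      # true hit omitted
    paralog_rate: float = 0.0   # weaker decoy hit on another chromosome
    tie_rate: float = 0.0       # equal-score duplicate forcing ambiguity

    def __post_init__(self) -> None:
        for v in (self.miss_rate, self.paralog_rate, self.tie_rate):
            if not 0 <= v <= 1:
                raise ValueError("hit-noise rates must be in [0, 1]")


# Survey-like SSR class mix: dimers dominate (TG/AC/GA-type motifs), then
# tetramers and longer motifs; monomer runs are rare.
DEFAULT_SSR_MIX = {
    "A": 0.01, "TG": 0.20, "AC": 0.18, "GA": 0.09, "TA": 0.07, "AG": 0.07,
    "AT": 0.05, "AAT": 0.03, "CAT": 0.02, "CACA": 0.0, "TCTG": 0.04,
    "AGAC": 0.04, "TGTA": 0.05, "TCAAA": 0.03, "ATTTG": 0.02,
    "ACGTAC": 0.04, "ACGTACG": 0.01, "ACGGTCAT": 0.02, "ACGTACGTA": 0.01,
    "ACGTACGTAC": 0.03,
}


@dataclass
class SimConfig:
    """All simulator knobs; the defaults are the survey conditions emulated."""

    seed: int
    genome_len: int = 2_000_000
    n_chromosomes: int = 4
    gc: float = 0.42
    repeat_families: list[RepeatFamilySpec] = field(
        default_factory=lambda: [
            RepeatFamilySpec(600, 40, 0.08),
            RepeatFamilySpec(400, 60, 0.12),
            RepeatFamilySpec(250, 50, 0.05),
        ]
    )
    repeat_target_fraction: float | None = 0.595
    ssr_per_kb: float = 0.07
    ssr_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SSR_MIX))
    n_clones: int = 2_000
    insert_range: tuple[int, int] = (100_000, 200_000)
    both_end_rate: float = 0.92
    read_len_range: tuple[int, int] = (101, 832)
    read_len_mean: float = 546.0
    read_len_sd: float = 110.0
    rearrangement_rate: float = 2.0  # breakpoint events per Mb
    rearrangement_seg_range: tuple[int, int] = (50_000, 250_000)
    inversion_prob: float = 0.3  # intra-chromosomal inversions among events
    hit_noise: HitNoise = field(default_factory=HitNoise)
    dual_peptide_rate: float = 0.1  # protein mode: two peptides of one gene

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for frac in (self.gc, self.both_end_rate, self.inversion_prob):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0 < self.insert_range[0] <= self.insert_range[1]:
            raise ValueError("bad insert range")
        if self.insert_range[1] >= self.genome_len:
            raise ValueError("insert longer than the genome")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per simulation stage."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass(frozen=True)
class Block:
    """One collinear segment of the source genome placed on the reference."""

    chrom: str
    ref_start: int  # 0-based on the reference chromosome
    src_start: int
    src_end: int
    strand: str

    def map_interval(self, s: int, e: int) -> tuple[int, int]:
        """Map src [s, e) (within the block) to 1-based inclusive ref coords."""
        if not (self.src_start <= s and e <= self.src_end):
            raise ValueError("interval outside block")
        if self.strand == "+":
            return self.ref_start + (s - self.src_start) + 1, self.ref_start + (e - self.src_start)
        return self.ref_start + (self.src_end - e) + 1, self.ref_start + (self.src_end - s)


@dataclass
class CloneTruth:
    clone_id: str
    insert_start: int
    insert_end: int
    ends: list[str]  # subset of ["T7", "SP6"]
    read_spans: dict[str, tuple[int, int]] = field(default_factory=dict)  # src coords
    blocks: dict[str, int] = field(default_factory=dict)  # end -> block index (-1 straddling)
    chroms: dict[str, str] = field(default_factory=dict)

    @property
    def intact(self) -> bool:
        """Both reads inside one and the same collinear block."""
        ids = set(self.blocks.values())
        return len(self.ends) == 2 and len(ids) == 1 and -1 not in ids

    @property
    def interchromosomal(self) -> bool:
        return len(set(self.chroms.values())) > 1


@dataclass
class TruthRegistry:
    """Ground truth for everything the generators implanted."""

    repeat_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    repeat_library: list[RepeatElement] = field(default_factory=list)
    ssr_loci: list[tuple[int, int, str]] = field(default_factory=list)  # src coords
    blocks: list[Block] = field(default_factory=list)
    clones: dict[str, CloneTruth] = field(default_factory=dict)
    read_status: dict[str, dict[str, str]] = field(default_factory=dict)  # mode -> read -> status
    genotype_classes: dict[str, str] = field(default_factory=dict)

    def block_of(self, s: int, e: int) -> int:
        """Index of the block fully containing src [s, e), or -1."""
        for i, b in enumerate(self.blocks):
            if b.src_start <= s and e <= b.src_end:
                return i
        return -1

    def to_json(self, path: str | Path) -> None:
        payload = {
            "repeat_library": [asdict(e) for e in self.repeat_library],
            "repeat_intervals": self.repeat_intervals,
            "ssr_loci": self.ssr_loci,
            "blocks": [asdict(b) for b in self.blocks],
            "clones": {k: asdict(v) for k, v in self.clones.items()},
            "read_status": self.read_status,
            "genotype_classes": self.genotype_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4, dtype=np.uint8), size=length, p=p)


_IDX = {c: i for i, c in enumerate("ACGT")}


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    out = arr.copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


class _Occupancy:
    """Sorted non-overlapping intervals with O(log n) placement queries."""

    def __init__(self) -> None:
        self.starts: list[int] = []
        self.ends: list[int] = []

    def fits(self, start: int, end: int) -> bool:
        i = bisect.bisect_right(self.starts, start)
        if i > 0 and self.ends[i - 1] > start:
            return False
        return i >= len(self.starts) or self.starts[i] >= end

    def add(self, start: int, end: int) -> None:
        i = bisect.bisect_right(self.starts, start)
        self.starts.insert(i, start)
        self.ends.insert(i, end)


def _place(rng: np.random.Generator, occupied: _Occupancy, length: int,
           genome_len: int, tries: int = 500) -> int | None:
    for _ in range(tries):
        start = int(rng.integers(0, genome_len - length))
        if occupied.fits(start, start + length):
            occupied.add(start, start + length)
            return start
    return None


def simulate_genomes(config: SimConfig) -> tuple[str, dict[str, str], TruthRegistry]:
    """Source genome, rearranged reference chromosomes and the truth registry.

    Repeats and SSRs are implanted into the source *before* the reference is
    derived, so both genomes share them; the reference is the source cut
    into chromosomes and shuffled by segmental rearrangements recorded as a
    block map. Deterministic under the config seed.
    """
    registry = TruthRegistry()
    rng = config.rng(1)
    genome = _random_seq(rng, config.genome_len, config.gc)
    occupied = _Occupancy()

    # repeat families
    families = [
        (RepeatElement(name=f"rep{i+1}", repeat_class="Unknown",
                       consensus=_to_str(_random_seq(rng, spec.consensus_len, config.gc))),
         spec)
        for i, spec in enumerate(config.repeat_families)
    ]
    target = (None if config.repeat_target_fraction is None
              else config.repeat_target_fraction * config.genome_len)
    if target is not None and config.repeat_target_fraction > 0.8:
        raise ValueError("repeat_target_fraction too high to pack")
    implanted_bp = 0
    fam_idx = 0
    copies_left = {elem.name: spec.copy_number for elem, spec in families}
    consecutive_failures = 0
    while consecutive_failures < len(families):
        elem, spec = families[fam_idx % len(families)]
        fam_idx += 1
        if target is None:
            if copies_left[elem.name] <= 0:
                if all(v <= 0 for v in copies_left.values()):
                    break
                continue
        elif implanted_bp >= target:
            break
        cons = np.array([_IDX[c] for c in elem.consensus], dtype=np.uint8)
        copy = _mutate(rng, cons, spec.divergence)
        if rng.random() < 0.5:
            copy = (3 - copy)[::-1]  # reverse complement in 2-bit space
        start = _place(rng, occupied, len(copy), config.genome_len)
        if start is None:
            consecutive_failures += 1
            continue
        consecutive_failures = 0
        if target is None:
            copies_left[elem.name] -= 1
        genome[start : start + len(copy)] = copy
        registry.repeat_intervals.append((start, start + len(copy), elem.name))
        implanted_bp += len(copy)
    if target is not None and implanted_bp < 0.9 * target:
        raise ValueError("infeasible repeat packing for this genome length")
    registry.repeat_library = [e for e, _ in families]

    # SSR loci (perfect arrays, boundaries sharpened so they do not extend)
    n_ssr = int(round(config.ssr_per_kb * config.genome_len / 1000))
    motifs = [m for m in config.ssr_mix if config.ssr_mix[m] > 0]
    probs = np.array([config.ssr_mix[m] for m in motifs])
    probs = probs / probs.sum()
    for _ in range(n_ssr):
        motif = motifs[int(rng.choice(len(motifs), p=probs))]
        p = len(motif)
        copies = int(max(int(np.ceil(14 / p)), rng.integers(4, 13)))
        length = copies * p
        start = _place(rng, occupied, length + 2, config.genome_len - 2)
        if start is None:
            continue
        start += 1  # leave room for the boundary-breaking bases
        arr = np.array([_IDX[c] for c in motif * copies], dtype=np.uint8)
        genome[start : start + length] = arr
        # break the period at both boundaries so the implant is maximal
        if genome[start - 1] == genome[start - 1 + p]:
            genome[start - 1] = (genome[start - 1 + p] + 1) % 4
        end = start + length
        if end + 1 <= config.genome_len and genome[end] == genome[end - p]:
            genome[end] = (genome[end - p] + 1) % 4
        registry.ssr_loci.append((start, end, motif))

    source = _to_str(genome)
    reference = _derive_reference(config, registry, source)
    return source, reference, registry


def _split_at(blocks: list[Block], ref_point: int) -> list[Block]:
    """Split the block list of one chromosome at a reference offset."""
    out: list[Block] = []
    pos = 0
    for b in blocks:
        length = b.src_end - b.src_start
        if pos < ref_point < pos + length:
            t = ref_point - pos
            if b.strand == "+":
                out.append(Block(b.chrom, 0, b.src_start, b.src_start + t, "+"))
                out.append(Block(b.chrom, 0, b.src_start + t, b.src_end, "+"))
            else:
                out.append(Block(b.chrom, 0, b.src_end - t, b.src_end, "-"))
                out.append(Block(b.chrom, 0, b.src_start, b.src_end - t, "-"))
        else:
            out.append(b)
        pos += length
    return out


def _chrom_len(blocks: list[Block]) -> int:
    return sum(b.src_end - b.src_start for b in blocks)


def _derive_reference(config: SimConfig, registry: TruthRegistry, source: str,
                      ) -> dict[str, str]:
    rng = config.rng(2)
    n = config.n_chromosomes
    bounds = [round(i * config.genome_len / n) for i in range(n + 1)]
    chroms: dict[str, list[Block]] = {
        f"chr{i+1}": [Block(f"chr{i+1}", 0, bounds[i], bounds[i + 1], "+")]
        for i in range(n)
    }
    n_events = int(round(config.rearrangement_rate * config.genome_len / 1e6))
    names = list(chroms)
    for _ in range(n_events):
        lo, hi = config.rearrangement_seg_range
        seg_len = int(rng.integers(lo, hi + 1))
        donors = [c for c in names if _chrom_len(chroms[c]) > seg_len + 2]
        if not donors:
            continue
        a = donors[int(rng.integers(len(donors)))]
        alen = _chrom_len(chroms[a])
        x = int(rng.integers(0, alen - seg_len))
        y = x + seg_len
        blocks = _split_at(_split_at(chroms[a], x), y)
        pos = 0
        left, seg, right = [], [], []
        for b in blocks:
            blen = b.src_end - b.src_start
            (left if pos + blen <= x else seg if pos + blen <= y else right).append(b)
            pos += blen
        invert = rng.random() < 0.5
        if invert:
            seg = [Block(b.chrom, 0, b.src_start, b.src_end,
                         "-" if b.strand == "+" else "+") for b in reversed(seg)]
        if rng.random() < config.inversion_prob or n == 1:
            # intra-chromosomal inversion in place (always inverted)
            if not invert:
                seg = [Block(b.chrom, 0, b.src_start, b.src_end,
                             "-" if b.strand == "+" else "+") for b in reversed(seg)]
            chroms[a] = left + seg + right
        else:
            btargets = [c for c in names if c != a]
            btgt = btargets[int(rng.integers(len(btargets)))]
            chroms[a] = left + right
            z = int(rng.integers(0, _chrom_len(chroms[btgt]) + 1))
            bblocks = _split_at(chroms[btgt], z)
            pos = 0
            bleft, bright = [], []
            for b in bblocks:
                (bleft if pos + (b.src_end - b.src_start) <= z else bright).append(b)
                pos += b.src_end - b.src_start
            seg = [Block(btgt, 0, b.src_start, b.src_end, b.strand) for b in seg]
            chroms[btgt] = bleft + seg + bright

    final: list[Block] = []
    reference: dict[str, str] = {}
    for chrom in names:
        pos = 0
        parts = []
        rebuilt = []
        for b in chroms[chrom]:
            rebuilt.append(Block(chrom, pos, b.src_start, b.src_end, b.strand))
            piece = source[b.src_start : b.src_end]
            parts.append(piece if b.strand == "+" else revcomp(piece))
            pos += b.src_end - b.src_start
        reference[chrom] = "".join(parts)
        final.extend(rebuilt)
    registry.blocks = final
    return reference


def _read_quals(rng: np.random.Generator, length: int) -> list[int]:
    """Plateau-with-tails toy quality model; only the >=20 threshold matters."""
    q = np.full(length, 40, dtype=int)
    head = min(3, length)
    q[:head] = [12, 18, 30][:head]
    tail = min(10, length)
    q[length - tail :] = np.linspace(32, 4, tail, dtype=int)
    jitter = rng.integers(-3, 4, size=length)
    return list(np.clip(q + jitter, 2, 60))


def simulate_bes(config: SimConfig, source: str, registry: TruthRegistry,
                 ) -> list[BESRead]:
    """Paired end reads from random clone inserts, with truth updates.

    The forward (T7) read runs 5'→3' from the insert's left boundary on the
    top strand; the reverse (Sp6) read runs from the right boundary on the
    bottom strand, so the two reads face each other across the insert.
    """
    rng = config.rng(3)
    reads: list[BESRead] = []
    for i in range(config.n_clones):
        clone = f"clone{i:05d}"
        ins_len = int(rng.integers(config.insert_range[0], config.insert_range[1] + 1))
        ins_start = int(rng.integers(0, config.genome_len - ins_len))
        ins_end = ins_start + ins_len
        if rng.random() < config.both_end_rate:
            ends = ["T7", "SP6"]
        else:
            ends = [("T7", "SP6")[int(rng.integers(2))]]
        truth = CloneTruth(clone_id=clone, insert_start=ins_start, insert_end=ins_end,
                           ends=ends)
        for end in ends:
            lmin, lmax = config.read_len_range
            rl = int(np.clip(round(rng.normal(config.read_len_mean, config.read_len_sd)),
                             lmin, lmax))
            rl = min(rl, ins_len)
            if end == "T7":
                s, e = ins_start, ins_start + rl
                bases = source[s:e]
            else:
                s, e = ins_end - rl, ins_end
                bases = revcomp(source[s:e])
            read_id = f"{clone}_{end}"
            reads.append(
                BESRead(read_id=read_id, clone_id=clone,
                        end=End.FORWARD if end == "T7" else End.REVERSE,
                        bases=bases, quals=_read_quals(rng, rl))
            )
            truth.read_spans[end] = (s, e)
            bidx = registry.block_of(s, e)
            truth.blocks[end] = bidx
            truth.chroms[end] = registry.blocks[bidx].chrom if bidx >= 0 else "?"
        registry.clones[clone] = truth
    return reads


def _gene_for(chrom: str, ref_lo: int, bucket: int = 50_000) -> str:
    return f"G_{chrom}_{ref_lo // bucket:04d}"


def emulate_blast_hits(config: SimConfig, registry: TruthRegistry, mode: str = "blastn",
                       species: str = "refA",
                       ) -> tuple[list[BlastHit], dict[str, tuple[str, str]]]:
    """Tabular hits a similarity search would report for the simulated reads.

    Stands in for running the aligner: each read overlapping a collinear
    block yields a true hit at its block-mapped reference location (e-value
    far below the 1e-5 cutoff); noise adds misses, weaker paralog decoys
    and equal-score ties per :class:`HitNoise`. Reads dominated by implanted
    repeats yield scattered ambiguous hits instead. In ``blastx`` mode
    subjects are peptide IDs and the returned mapping carries
    peptide → (gene, chromosome).

    Returns ``(hits, protein_map)``; the registry records each read's
    expected filtration status under ``mode``.
    """
    rng = config.rng(5 if mode == "blastn" else 6)
    noise = config.hit_noise
    chroms = sorted({b.chrom for b in registry.blocks})
    # prefix sums over the (non-overlapping) repeat implants for O(log n)
    # repeat-coverage queries per read
    rep_iv = sorted((rs, re_) for rs, re_, _ in registry.repeat_intervals)
    rep_starts = np.array([iv[0] for iv in rep_iv])
    rep_ends = np.array([iv[1] for iv in rep_iv])
    rep_cum = np.concatenate([[0], np.cumsum(rep_ends - rep_starts)]) if rep_iv else np.zeros(1)

    def rep_cov(x: int) -> int:
        """Total implanted-repeat bp in source [0, x)."""
        if not rep_iv:
            return 0
        i = int(np.searchsorted(rep_starts, x, side="left"))
        total = int(rep_cum[i])
        if i > 0 and rep_ends[i - 1] > x:
            total -= int(rep_ends[i - 1] - x)
        return total
    hits: list[BlastHit] = []
    protein_map: dict[str, tuple[str, str]] = {}
    status = registry.read_status.setdefault(mode, {})

    def subject_for(chrom: str, lo: int, second_peptide: bool = False) -> str:
        if mode == "blastn":
            return chrom
        gene = _gene_for(chrom, lo)
        pep = f"{gene}.p{2 if second_peptide else 1}"
        protein_map[pep] = (gene, chrom)
        return pep

    def emit(read_id: str, chrom: str, lo: int, hi: int, strand: str, ident: float,
             evalue: float, second_peptide: bool = False) -> BlastHit:
        length = hi - lo + 1
        mism = int(round((100 - ident) / 100 * length))
        s1, s2 = (lo, hi) if strand == "+" else (hi, lo)
        h = BlastHit(
            query_id=read_id, subject_id=subject_for(chrom, lo, second_peptide),
            pct_identity=round(ident, 2), aln_length=length, mismatches=mism,
            gap_opens=0, q_start=1, q_end=length, s_start=s1, s_end=s2,
            evalue=evalue, bit_score=round(1.8 * length * ident / 100, 1),
        )
        hits.append(h)
        return h

    for clone in sorted(registry.clones):
        truth = registry.clones[clone]
        for end in truth.ends:
            read_id = f"{clone}_{end}"
            s, e = truth.read_spans[end]
            rep_bp = rep_cov(e) - rep_cov(s)
            if rep_bp > 0.5 * (e - s):
                # repeat-dominated read: scattered hits, first two tied
                ev = 10.0 ** -float(rng.uniform(6, 9))
                tied_ident = 85.0 + float(rng.uniform(0, 5))
                n_scatter = int(rng.integers(12, 25))
                for j in range(n_scatter):
                    # the first two hits tie exactly (e-value, identity and
                    # length) on distinct chromosomes, so such a read can
                    # never earn a unique hit
                    if j < 2 and len(chroms) > 1:
                        c = chroms[j]
                    else:
                        c = chroms[int(rng.integers(len(chroms)))]
                    lo = int(rng.integers(1, 10_000_000))
                    emit(read_id, c, lo, lo + 120, "+",
                         tied_ident if j < 2 else 85.0 + float(rng.uniform(0, 5)),
                         ev if j < 2 else ev * 10 ** float(rng.uniform(1, 3)))
                status[read_id] = "repetitive"
                continue
            bidx = truth.blocks[end]
            if bidx < 0:
                status[read_id] = "no_hit"
                continue
            if rng.random() < noise.miss_rate:
                status[read_id] = "no_hit"
                continue
            block = registry.blocks[bidx]
            lo, hi = block.map_interval(s, e)
            read_strand = "+" if end == "T7" else "-"
            strand = "+" if block.strand == read_strand else "-"
            ident = float(rng.uniform(94, 99.9))
            evalue = 10.0 ** -float(rng.uniform(40, 120))
            true_hit = emit(read_id, block.chrom, lo, hi, strand, ident, evalue)
            second = (mode == "blastx" and rng.random() < config.dual_peptide_rate)
            if second:
                emit(read_id, block.chrom, lo, hi, strand, ident, evalue,
                     second_peptide=True)
            if rng.random() < noise.tie_rate:
                c = chroms[(chroms.index(block.chrom) + 1) % len(chroms)]
                alt_lo = int(rng.integers(1, 5_000_000))
                emit(read_id, c, alt_lo, alt_lo + (hi - lo), strand, ident, evalue)
                status[read_id] = "ambiguous"
            else:
                status[read_id] = "unique"
            if rng.random() < noise.paralog_rate:
                c = chroms[int(rng.integers(len(chroms)))]
                alt_lo = int(rng.integers(1, 5_000_000))
                emit(read_id, c, alt_lo, alt_lo + 150, "+",
                     88.0 + float(rng.uniform(0, 4)), max(evalue * 1e20, 1e-10))
    return hits, protein_map


def simulate_genotypes(config: SimConfig, n_markers: int = 193, n_parents: int = 10,
                       polymorphic_frac: float = 0.653, failed_frac: float = 0.295,
                       duplicated_frac: float = 15 / 193):
    """Marker×parent genotype records with known class truth.

    Marker classes are drawn multinomially (monomorphic = remainder);
    polymorphic markers carry 2-12 alleles across the parents, and the
    duplicated subset gives one parent 3-4 alleles.
    """
    from .io import NO_PRODUCT, GenotypeRecord

    if polymorphic_frac + failed_frac > 1:
        raise ValueError("class fractions sum above 1")
    rng = config.rng(7)
    records: list[GenotypeRecord] = []
    truth: dict[str, str] = {}
    parents = [f"P{j+1}" for j in range(n_parents)]
    classes = rng.choice(
        ["polymorphic", "failed", "monomorphic"], size=n_markers,
        p=[polymorphic_frac, failed_frac, 1 - polymorphic_frac - failed_frac],
    )
    poly_idx = [i for i, c in enumerate(classes) if c == "polymorphic"]
    n_dup = min(len(poly_idx), int(round(duplicated_frac * n_markers)))
    dup_set = set(rng.choice(poly_idx, size=n_dup, replace=False)) if n_dup else set()
    for i, cls in enumerate(classes):
        marker = f"M{i+1:03d}"
        base = int(rng.integers(90, 300))
        if cls == "failed":
            for p in parents:
                records.append(GenotypeRecord(marker, p, NO_PRODUCT))
            truth[marker] = "failed"
            continue
        if cls == "monomorphic":
            for p in parents:
                records.append(GenotypeRecord(marker, p, [base, base]))
            truth[marker] = "monomorphic"
            continue
        n_alleles = int(rng.integers(2, 13))
        pool = [base + 2 * k for k in range(n_alleles)]
        slots = pool + [pool[int(rng.integers(n_alleles))]
                        for _ in range(2 * n_parents - n_alleles)]
        rng.shuffle(slots)
        duplicated = i in dup_set
        for j, p in enumerate(parents):
            alleles = sorted(slots[2 * j : 2 * j + 2])
            if duplicated and j == 0:
                extra = [base + 2 * n_alleles + 2, base + 2 * n_alleles + 4]
                alleles = sorted(alleles + extra[: int(rng.integers(1, 3))])
            records.append(GenotypeRecord(marker, p, alleles))
        truth[marker] = "duplicated" if duplicated else "polymorphic"
    registry_classes = truth
    return records, registry_classes
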