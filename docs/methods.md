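# Methods notes

This note records what each stage computes, the conventions and defaults it
uses, and the design choices made where the procedure was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Repeat masking

Masking is library-based local alignment: shared 11-mers between a read and
a repeat consensus (either strand) seed ungapped extensions along the
diagonal with +1/−1 scoring and an x-drop stop (default 15). An extension
whose aligned interval reaches `min_hit_len` (30 bp) at identity
`min_identity` (0.80) adds that read interval to the mask. Intervals are
kept sorted and merged; bases are never rewritten, so downstream stages
choose a soft- or hard-masked view. Masking is idempotent, strand-symmetric
and monotone in `min_identity` (lowering the threshold can only add hits).

*Why ungapped only.* The divergence regime the package targets — repeat
copies differing from their family consensus by point substitutions — never
needs gap extension; an indel-bearing copy masks as two shorter hits whose
union still covers it. Keeping the extension ungapped makes the aligner a
few lines of vectorised arithmetic whose behaviour is easy to verify against
a full Smith–Waterman oracle (Bio.Align in the test suite), which confirms
≥95 % of implanted repeat bases recovered at ≤20 % divergence with ≤2 %
background false masking.

*Contaminant screening* uses the same machinery: a read is discarded when
qualifying alignments to the vector/host library (default identity ≥0.95)
cover ≥`min_cov` (0.8) of it.

*Self-alignment census.* After masking, reads are aligned all-vs-all on
their unmasked sequence only; a partner counts when some alignment's
E-value is ≤1e-5 under the ungapped Karlin–Altschul statistic for ±1
scoring on uniform composition (λ = ln 3, K ≈ 0.333, search space = the two
reads' unmasked lengths). Counts bin as ≤10 / 11–50 / >50; the boundary
counts 10 and 50 fall to the lower bin because the survey's histogram bins
are phrased as "more than 10" and "more than 50". The published census
percentages cannot be reproduced because their denominator (the read set
actually aligned) is unstated; the census is therefore validated on
synthetic truth and bin boundaries.

*Cross-library masking* treats one library's consensus sequences as the
read set and masks them with the other library; it is asymmetric by
construction (a ⊂ b masks a fully, not conversely).

*Non-repetitive eligibility.* A read proceeds to homology search iff its
longest contiguous unmasked run is strictly longer than 100 bp ("more than
100 bp").

## SSR mining

For each period p ≤ 10 the detector compares the sequence with itself at
offset p; maximal runs of agreement are tandem-array cores. Runs are chained
across substitution gaps with +1 per agreeing position and −β per bridged
mismatch, β = (1−f)/f for mismatch budget f (default 0.2, so β = 4); a
pending tail commits when its cumulative score turns positive, and is
abandoned below −6β or when the next run is out of phase with the array
motif (its leading unit must match the rotated motif up to one substitution;
monomer runs must match exactly). Chained segments *and* their pure maximal
runs both become candidates; overlaps resolve to the higher-purity, then
longer, call — so a mismatch-bridged segment only wins where its pure
fragments fall below the length/copy thresholds (12 bp minimum, ≥4 copies
for periods 1–2, ≥3 for 3–10; all configurable). Purity is the fraction of
offset comparisons that agree. Non-primitive motifs (ACAC at period 4) are
dropped; the array is reported at its smallest period. With f = 0 the
detector reduces to exact maximal-run enumeration, which is the form checked
against an independent brute-force enumerator in the tests.

Motif classes merge a motif with its reverse complement but not with its
rotations; the label is normalised with the lexicographically smaller motif
first so that the class is a pure, involutive function of the motif. Survey
tables elsewhere sometimes print the predominant observed motif first; that
permutes the label, not the class.

Flank eligibility (primer candidacy) requires ≥50 clean bases on each side
of the locus within the read, where clean means unmasked and outside any
SSR locus — masking runs before flank selection, so repeat-masked flanks do
not count toward primer real estate. Thermodynamic primer design is out of
scope; the flanks themselves are exportable.

## Hit filtration

Per read: keep hits with E ≤ 1e-5; keep the minimal-E subset; within it keep
the maximal HSP score, defined as percent identity (0–100 scale, as printed
in tabular output) × alignment length; accept the read iff exactly one
subject remains. The cutoff is applied before the minimum (the outcome is
identical whenever the minimum passes the cutoff). Each tabular line is an
independent hit; HSPs of one subject are not chained. In protein mode the
peptide→gene map is applied before uniqueness, so two peptides of one gene
are a unique gene hit; unmapped peptide IDs drop with a warning (or raise in
strict mode). Residual ties across distinct subjects leave the read
unassigned — any other resolution would invent information. Hits are
canonically ordered internally, so results are independent of input order;
the suite checks the whole pipeline against exhaustive rule evaluation on
random ≤8-hit sets.

## Synteny calling

Unique assignments pair by clone (read IDs follow `<clone>_T7|SP6`).
Classification per clone: SINGLE_END; DISCORDANT (different chromosomes);
MACRO_ONLY (same chromosome); MICRO when additionally the inter-end space
is within [10 kb, 300 kb] — bounds inclusive, a documented choice where the
rule's phrasing does not say — and the ends are tail-to-tail.

*Span.* "Space between the ends" is the inner gap: with each hit's
reference interval normalised to [lo, hi] and the pair ordered left/right,
span = lo₂ − hi₁, clamped at 0 for overlapping intervals (the alternative
outer-span reading is deliberately not used; at a 10–300 kb window the
one-base ambiguity of gap conventions is immaterial).

*Orientation.* Tail-to-tail means the left hit is on the plus strand and
the right hit on the minus strand — each read's 3′ end then points into the
gap. Which physical end (T7/Sp6) is left is irrelevant, since end labelling
of a clone is arbitrary; of the eight strand × order configurations exactly
two qualify.

*Protein mode.* A unique assignment's subject is a gene; its chromosome
comes from the peptide→gene→chromosome table, while span and orientation
use the hit's coordinates. The hit emulator writes protein-mode subject
coordinates already projected to the genome (a real BLASTX run reports
protein-space coordinates; projecting through the gene annotation is the
step this idealisation stands in for).

Mode intersection counts clones that reached same-chromosome status in both
search modes and is symmetric. Cross-mode pairing (one end unique only in
nucleotide mode, the other only in protein mode) is deliberately not done;
the modes are analysed separately.

## Survey statistics

All printed percentages and ratios round half-up at their printed precision
(`decimal`-based, so 12.5 % → 13 %). Summary tables carry their raw count
rows next to derived-percentage specifications and re-derive every
percentage on emission (`audit()`), so a table cannot print a percentage its
counts do not support. GC content counts G+C over unambiguous bases only
(ambiguity codes leave numerator and denominator). Q20 length is the number
of bases with phred ≥20. A marker panel classifies each marker as failed
(no parent produced a product), monomorphic (one allele size observed) or
polymorphic (≥2); the three classes partition the tested loci. A locus is
duplicated when some diploid parent shows more than two alleles — the
operational criterion for a duplicated genome region in a genotyping panel
— and duplicated loci are counted separately because they are usually also
polymorphic. Genome coverage uses a configurable assumed genome size
(default 2.4 Gb), not a constant.

## Synthetic data

The generator emulates the survey's data regime; its defaults are the
emulated study conditions, chosen once:

| parameter | default | emulates |
|---|---|---|
| genome_len / n_chromosomes | 2 Mb / 4 | desk-scale stand-in for a 2.4 Gb genome |
| gc | 0.42 | survey GC content |
| repeat_target_fraction | 0.595 | masked fraction of the read set |
| repeat families | 3 families, 250–600 bp, 5–12 % divergence | dominant transposon-like families |
| ssr_per_kb | 0.07 | ≈6.8 k SSRs in 96 Mb |
| insert_range | 100–200 kb | BAC inserts; inner gaps land inside the 10–300 kb window |
| both_end_rate | 0.92 | clones with both ends sequenced |
| read lengths | 101–832 bp, mean ≈546 (truncated normal, sd 110) | Q20 read-length range and mean |
| rearrangement_rate | 2 events/Mb, 50–250 kb segments, 30 % inversions | chromosomal shuffling between lineages |
| hit_noise | (0, 0, 0) | noiseless baseline; miss/paralog/tie dials |

The source genome gets repeat copies (substitution-mutated, either strand,
non-overlapping) and perfect SSR arrays whose boundaries are sharpened so
each implant is maximal. The reference genome is the source split into
chromosomes and shuffled by segmental events — inter-chromosomal
translocations (optionally inverted) and intra-chromosomal inversions —
tracked as a block map from source to reference coordinates. Reads are
copied from the source (forward read from the insert's left boundary on the
top strand, reverse read from the right boundary on the bottom strand, so
pairs face inward); qualities are a plateau-with-decaying-tails toy model in
which only the ≥20 threshold matters. Emulated hits project each read
through the block map at E ≪ 1e-5; repeat-dominated reads (>50 % implanted
repeat) instead get scattered hits whose two best tie exactly on distinct
chromosomes, so they can never earn a unique assignment. The registry
records implants, blocks, clone geometry and each read's expected
filtration status, and everything is deterministic under the seed.

*What passing recovery tests do and do not show.* On noiseless emulated
hits, microsynteny sensitivity is exact (1.0) for intact conserved clones
and inter-chromosomal breakpoint clones are all discordant — this validates
the filtration/pairing/classification machinery against known truth, not
alignment itself (no aligner is run to produce the hits; real BLAST output
enters through the same parser). A clone straddling an *intra*-chromosomal
inversion breakpoint remains on one chromosome by construction, so
DISCORDANT is not the expected call for it and such clones are excluded
from the discordance claim. Real data additionally contain base-calling
error, chimeric clones, segmental duplication and E-value statistics that
the emulator does not model.

## Numerical and degenerate-input choices

Rounding is half-up everywhere a value is printed. Intervals are 0-based
half-open internally; BLAST subject coordinates stay 1-based inclusive with
minus strand encoded by descending order. Empty inputs: empty FASTA → empty
list; empty hit file → empty assignment table (exit 0); zero-length
denominators raise rather than emit NaN. Census hit counts of exactly 10
and 50 go to the lower bin. Mask intervals are re-normalised after every
operation. Seeds below 2³¹ feed per-stage independent generator streams, so
each stage is reproducible in isolation.

## Known limitations

The masker is a survey-scale tool, not a genome-scale RepeatMasker
replacement: it is O(reads × library) with Python-level seeding. The
tandem-repeat detector's purity model counts offset agreements rather than
alignment to a consensus, so compound arrays sharing a phase base can merge
into one locus. E-values in the census use ungapped statistics with uniform
composition. The emulated BLASTX dialect simplifies protein-space
coordinates (see above). De-novo repeat family reconstruction, primer
thermodynamics and linkage-map construction are out of scope.
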