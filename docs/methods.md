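# Methods

## Scope and model

`mitochar` treats an annotated circular genome as the unit of analysis:
a nucleotide sequence with declared circular topology plus an ordered
list of gene features, each with a category (PCG, tRNA, rRNA, other), a
strand label, and one or more 1-based inclusive coordinate segments.
The strand vocabulary is the gene-centric J/N convention used in plant
mitogenome tables: J means the gene reads 5′→3′ on the stored sequence,
N on its reverse complement. Internally J/N map to forward/reverse
complement; coordinates are 1-based inclusive everywhere (GenBank
convention), and any half-open arithmetic converts at the module
boundary. Multi-segment features cover both cis-spliced and
trans-spliced genes; a feature spanning the origin is represented as two
segments with a wrap flag.

The "other" category holds the cytochrome-maturation and transport
genes (ccmB/ccmC/ccmFc/ccmFn/mttB) that mitogenome tables count
separately from PCGs even though they are protein-coding. The
codon-usage layer therefore treats {PCG, other} as codon-bearing by
default; this is what makes the coding complement of the bundled
reference tables sum to 37,521 bp = 12,507 codons. ORFs and maturase
genes are categorized as PCG, matching the 40-gene accounting of the
reference system.

## Composition and skews

AT-skew = (A−T)/(A+T) and GC-skew = (G−C)/(G+C) are computed from raw
counts; the percentage normalizations in the textbook definitions cancel
algebraically, so no rounding enters the ratio. Ambiguity codes are
excluded from both numerator and denominator and tallied separately; an
empty denominator raises an error rather than returning a silent zero.
Reported skews round half-away-from-zero to 4 decimal places and
percentages to 2, mirroring print precision; raw values are retained in
machine output. Per-class statistics (PCG/tRNA/rRNA) concatenate the
strand-oriented sequence of every member feature — N-strand genes
contribute their reverse complement — because skews attributed to gene
classes in the literature are gene-centric, not raw-strand slices. The
report header of the composition table records this convention via the
class definitions themselves.

A transcription note: the published per-circle base tallies of the
reference system sum exactly to the small circle's length but fall
110 bp short of the large circle's; the remainder is carried as
unassigned bases, which is also the convention under which the published
AT content (54.94%) reproduces. The published whole-genome "A+T =
54.82%" equals the sum of the two rounded base percentages (27.26 +
27.56), not the unrounded ratio; the library computes from counts and
the rounding conventions above.

## Gene geometry

Gene length is the exon sum over segments. Spacers use one fixed
convention: genes ordered by first-segment start; spacer =
start(next) − end(prev) − 1 with end(prev) the maximum end over the
previous gene's segments; on a circle one additional wrap spacer adds
the genome length to the downstream start. This convention reproduces
the reference tables' printed −110, −73 and −817 values. Published
tables are not internally consistent about which segment end they
measured some spacers from (a handful of rows near trans-spliced genes
differ), so declared-versus-computed disagreements are reported as
warnings, never errors.

Overlap pairs are consecutive pairs with negative spacer **that
physically share bases**: a trans-spliced gene whose distant segment
reaches past the next gene's start produces a negative spacer with zero
shared sequence, which is an artifact of the ordering convention, not an
overlap. Each reported pair carries both `overlap_bp` (−spacer, the
published convention — 817 for a tRNA nested inside rps4) and
`shared_bp` (the bases actually shared — 65 for that tRNA's own span).

Coding fraction is additive over gene lengths without merging overlaps,
matching how published gene-content totals are tallied. The reference
tables' own aggregate "45,639 bp of genes" is not reconstructable from
their row sums (50,572 bp); the acceptance script reports both the
fixture-derived fraction and the fraction of the published aggregate.

## Codon usage

The universal genetic code (translation table 1) applies throughout, as
it does for angiosperm mitochondrial genes. CDS assembly concatenates
J-strand segments in listed order, or reverse-complements each segment
and concatenates in reverse listed order for N-strand genes. Frames
start at position 1; trailing partial codons are dropped with a logged
warning and tallied, so 3 × codons + dropped = total CDS length always
holds. Codons containing ambiguity codes are excluded and counted.

RSCU families are the synonymous families of the code, with the three
stop codons forming one 3-codon family by default — required for stop
codons to participate in optimal-codon lists as they do in the
mitogenome literature; `include_stops=False` gives the common
alternative. Unobserved families get blank RSCU, never 0.
Classification is strict: RSCU > 1 optimal, < 1 non-optimal, exactly 1
no preference (ATG/Met and TGG/Trp always land here when observed).
Note the reference paper's own "32 optimal codons" list includes ATG and
TGG, contradicting its RSCU > 1 criterion; this implementation follows
the strict criterion and does not reproduce that count. ACG starts are
reported as non-canonical but valid (C-to-U editing restores ATG in
plant mitochondria; no editing inference is attempted).

## Repeat census

`find_ssrs` implements MISA-style semantics: maximal perfect runs of a
1–6 bp unit, default thresholds {1:10, 2:6, 3:5, 4:5, 5:5, 6:5} copies,
no mismatch tolerance (an interrupted mononucleotide run is two runs).
A run is attributed to the smallest unit that generates it (an (AT)n run
is never also reported as a 4-mer), and motifs are canonicalized to the
lexicographically least rotation while the observed phase is retained.
Circular sequences are scanned with an origin-spanning window of
max-unit × max-threshold bases; sub-runs of an origin-wrapping record
are deduplicated by circular containment. Adjacent runs within 100 bp
(MISA's compound default) share a `compound_group` tag but remain
separate records. Gene assignment is any-overlap against the annotation
set.

`find_tandem_repeats` extends the same exact-period detection to 7–100 bp
units with at least two full copies and 24 bp of repeated sequence,
resolving overlapping calls longest-first. This is a deliberate
simplification: alignment-based minisatellite models with mismatches and
indels are out of scope, and the scanner is documented as finding
perfect duplications only.

The repeat fraction sums the spans of non-overlapping records over the
total length; mixed scans should pass through `resolve_overlaps` first.

## Supermatrix preparation

`build_supermatrix` concatenates named genes per species in a globally
fixed order (default: the 24 mitochondrial PCGs conventionally used for
angiosperm phylogenomics — 3 atp, 3 cox, cob, 9 nad, 4 rps, 4 ccm) and
records a partition map that tiles the concatenation exactly. Gene-name
matching is case-insensitive with a small synonym table (cytB/cob etc.)
since annotations vary. Missing genes either drop the species (with a
warning) or gap-fill with a '-' block of the gene's modal length.
Output is invariant to input-map iteration order. Alignment, model
selection and tree inference are external: the module writes FASTA,
relaxed sequential PHYLIP and a RAxML-style `DNA, gene = start-end`
partition file, and never calls those tools.

## Synthetic genomes

The generator plants genes and repeats on a seeded random background.
Base probabilities are solved in closed form from the target AT content
and skews (p(A) = AT/2·(1+skew) etc.), so whole-genome skews hit their
targets in expectation rather than by post-hoc editing; at 50 kb the
realized skew is within ±0.01 of target, at 10 kb within binomial noise
(~±0.03). Coding features get init codon + sense codons drawn from a
codon profile (by default induced by the background base probabilities)
+ stop codon; segment layouts are auto-placed with a 1 bp margin and up
to 500 retries before a packing error lists the collision. Explicit
segment coordinates bypass the margin rule, which is how deliberate
overlaps are planted. Repeats are stamped last at reserved loci, and
their flanking bases are adjusted so the perfect run ends exactly at the
planted coordinates — the ground truth is then exact, not approximate.
Ground truth records the *final* state: if an explicit overlap or an
in-gene repeat overwrites part of an earlier plant, the truth holds the
re-extracted coding sequence.

Species sets for supermatrix tests evolve a common ancestor per gene
with independent per-site substitutions to a uniformly chosen other base
(Jukes–Cantor-style draw); for two lineages at per-site rate p, the
expected pairwise difference fraction is 2p − (4/3)p².

The bundled template (`ncadamba_like.yaml`) mirrors the reference
system's structure at one-tenth linear scale — two circles of 10,984 and
30,514 bp with 14 and 69 genes, the published overlap pairs planted at
explicit coordinates, trans-spliced multi-segment genes on both strands,
and in-gene mono-repeats of the kinds the published census reports.
tRNA lengths are kept at natural size (they are already small); PCG
lengths scale to the nearest codon. One-tenth scale keeps every
simulation-backed test in milliseconds while preserving all the
structural features the pipeline must handle.

What the simulator does **not** emulate: real intergenic sequence
composition heterogeneity, RNA editing, imperfect/nested repeats,
chloroplast-derived insertions, and read-level artifacts (assembly is
out of scope). Passing tests on synthetic genomes therefore demonstrate
the correctness of the bookkeeping and the detectors' contracts on
perfect structures, not robustness to biological mess; the
sequence-free reference tables provide the complementary real-data
check of all coordinate arithmetic.

## Numerical and degenerate-input choices

- Rounding of reported values is half-away-from-zero (decimal
  arithmetic), 4 d.p. for skews, 2 d.p. for percentages.
- Empty classes, empty sequences, and zero denominators raise or flag
  (`undefined` column) — never silent zeros.
- Ties in feature ordering (equal first-segment starts) break by max
  end, ascending; spacer computation re-sorts, so input row order never
  matters.
- CDS shorter than 6 nt are flagged `too_short` and excluded from the
  start/stop audit.
- The greedy longest-first overlap resolution for repeat records breaks
  span ties by start position.

## Known limitations

- The minisatellite scanner finds perfect tandem duplications only.
- GenBank reading infers categories from feature keys (CDS→PCG,
  tRNA→tRNA, rRNA→rRNA) unless a `category:` note qualifier overrides;
  protein-coding "other" genes round-trip only through files this
  package wrote or tables carrying explicit categories.
- The published per-gene GC-content column is stored for validation but
  no per-gene GC comparison is attempted where the source cells were
  typographically ambiguous (left blank in the bundled transcription).
- Whole-sequence statistics of the deposited accessions themselves
  (exact SSR category counts, per-codon RSCU of the real genome) require
  the accession sequences, which the package deliberately does not
  download; they are exercised instead through the simulator and the
  printed-input pathways.
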