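# Methods

## Coordinate conventions

All coordinates are 0-based half-open internally. GTF (1-based closed) is
converted at the I/O boundary; BED and bedGraph pass through unchanged. A
gene's TSS is `start` on the plus strand and `end − 1` on the minus strand.
A peak's centre is the floor midpoint of its interval; MACS-style summit
columns are deliberately ignored so BED3 and scored BED behave identically.

## Peak-region classification

Each peak receives a single label from its centre with the precedence
promoter > exon > intron > intergenic, applied over all genes jointly (a
centre in one gene's promoter and another gene's exon is a promoter hit).
The promoter is the strand-aware window of `promoter_span` bp immediately
upstream of the TSS; the default span is 3,000 bp, the default of classical
peak-annotation tools for plant genomes, and configurable because no single
value is canonical. UTRs are not modelled separately: exonic bases count as
exon, downstream sequence as intergenic. The genome-background breakdown
applies the same precedence to every base via interval-set arithmetic; a
brute-force per-base count on a toy genome is the test oracle.

## Expression groups and metagene profiles

Genes with FPKM > 0 in a sample are ranked descending (ties broken
lexicographically by gene id for determinism) and cut into ten contiguous
groups whose sizes differ by at most one; L1 is the highest-expression
group, and FPKM = 0 genes form the separate "unexpressed" group.

Metagene profiles use 70 bins: twenty 50-bp bins over the 1-kb upstream
flank, thirty bins over the gene body split into three equal parts (integer
remainders go to the rightmost bins), and twenty 50-bp bins downstream.
Minus-strand genes are reversed so bin 0 is always the 5′ flank. TSS
matrices cover [TSS − 1 kb, TSS + 1 kb) in 40 strand-oriented 50-bp bins,
zero-padded at chromosome edges; k-means grouping (k = 4 by default) uses
k-means++ with ten restarts and a fixed seed, and cluster labels are
renumbered by descending cluster mean so the labelling is reproducible.

## Concurrence and mark association

The association window of a gene is the strand-aware span
[TSS − `window_up`, gene end) with `window_up` = 1,000 bp by default; a gene
"has the mark" iff at least one peak centre falls inside it. The same
window assigns differential regions and module-membership mark flags, so
all stages agree on what "marked" means. Species-level FPKM activity
cutoffs (0.24 and 0.17 for the two cotton genomes in the motivating data
set) are plumbed through as configurable parameters; the synthetic world
uses 0 (any positive FPKM is active).

## Strand inference

The candidate body [s, e) is split into thirds at `s + L//3` and
`s + (2L)//3`; a boundary position belongs to the region on its right.
Eligible peaks are those with centres inside the candidate span extended by
2,000 bp on each side. The published description measures the 2-kb rule
from the transcript centre in one place and from the transcript ends in
another; these disagree for candidates longer than ~4 kb, and the
span-extension reading is used because the centre reading would make
legitimate upstream promoter peaks ineligible for long candidates. Among
eligible peaks the highest score wins, ties broken by centre-to-centre
distance then leftmost position — the tie-break is a determinism choice,
not a biological claim.

Per-sample calls are made independently and reconciled: agreement keeps the
strand, a `+`/`-` conflict demotes the candidate to `unknown` pending EST
evidence. ESTs then merge fragments (one EST overlapping two candidates by
≥1 bp with a gap ≤ 5,000 bp chain-merges them left-to-right) and set the
strand; an EST is a direct observation of the transcribed strand, so it
overrides the peak inference on conflict, recorded as `est_override`.
Candidates left at `middle`/`unknown` are kept in the output with an
ambiguity flag rather than discarded, keeping the semi-manual-resolution
cases machine-visible. The merge gap bound of 5,000 bp is a package default;
no published bound exists.

## Differential enrichment

Peak callers' treatment/control comparisons are replaced by a fully
specified region-restricted test: both density tracks are scaled to the
smaller library total; per candidate region (the merged union of both
samples' peaks) the scaled count in one sample is tested with a one-sided
Poisson tail against the other sample's scaled count plus a pseudocount of
one as the rate, in both directions, at alpha = 1e-5. This keeps the
up/down region labels the downstream statistics need while being exactly
testable against brute-force Poisson sums. Expression consistency counts a
direction-up gene as consistently up iff its FPKM in the up-sample is at
least `fold` (default 2) times the other sample's and above the activity
cutoff — the published analysis does not define "highly expressed", so the
fold rule is an explicit, configurable choice. The tissue-specificity
screen computes per-gene z-scores across samples of log(FPKM + 1) (the log
stabilises variance across the FPKM range; `log_transform=False` disables
it) and flags genes with z ≥ 2; sd = 0 genes are excluded.

## Orthology

Reciprocal best hits: per query the lowest-E-value hit wins, ties broken by
higher bitscore then lexicographic subject id; a pair is kept iff it is
mutual and both E-values pass the cutoff (1e-55 by default, matching the
strict bidirectional-BLAST convention of the motivating study). The
chromosome ratio matrix row-normalises pair counts (pairs from chromosome i
to chromosome j over all pairs involving i); the alternative normalisation
by genes per chromosome is not the default because the "share of
orthologous pairs" reading fits the published description of roughly half
the pairs linking corresponding chromosomes. "High conservation" (ratios
close to or over 50%) is quantified as ≥ 0.45, configurable, since the
boundary of "close to" is not fixed anywhere.

## Module contingency and the Fisher test

A module is the edge-list neighbourhood of an anchor gene; members carry
expressed (FPKM above cutoff) and marked (association window) flags, and
negative co-expression edges are included unless `positive_only` is set.
The 2×2 table puts the module subset's marked/unmarked split in row 1 and
the genome-wide marked/unmarked counts in row 2, used as given: subtracting
the module members from a background of ~70,000 genes changes the p-value
by less than 1e-4 and is not done. The two-sided p is the
minimum-likelihood summation over the hypergeometric support, computed from
`scipy.stats.hypergeom.logpmf` with a 1e-7 relative tolerance when
comparing point probabilities to the observed one (the same guard R's
fisher.test uses); mid-p is not offered. Degenerate margins return p = 1
with a warning. Exact-rational enumeration (`math.comb` fractions) is the
independent oracle for all margins ≤ 50, and `scipy.stats.fisher_exact`
cross-checks the genome-scale tables.

## Synthetic world

The generator emulates the structural features the pipeline depends on, not
sequence-level realism:

- **Genome/annotation** — by default two 2-Mb chromosomes and 300
  non-overlapping genes (1–4 kb, 1–5 exons, random strands) with a minimum
  inter-gene gap of 2,400 bp. The gap exceeds the 1-kb association window
  plus peak placement slack, so a gene's peak can never fall in a
  neighbour's window — mark flags are then exactly the generator's
  Bernoulli draws, which is what makes the 3-standard-deviation recovery
  tests clean.
- **Expression** — an exact `frac_expressed` share (default 0.8) of genes
  gets log-normal FPKM; 20% of expressed genes are root- or stem-biased
  4-fold. Values are rounded to the written precision at generation time so
  files and memory agree byte-for-byte.
- **Peaks** — each gene is marked with a probability given by its
  expression decile (defaults decreasing 0.95 → 0.50 for L1..L10, 0.30 for
  unexpressed, mirroring the observed coupling of the mark to active
  transcription); peak centres sit ~200 bp downstream of the TSS (clipped
  into the gene body), so averaged profiles peak downstream of the TSS as
  observed. Noise peaks (exactly `n_noise_peaks`) are placed in intergenic
  space at least 3 kb from any gene so they stay out of every association
  and candidate-eligibility window. Density tracks are peak coverage plus
  low gamma background in 50-bp bins.
- **Novel genes** — hidden stranded genes strictly intergenic relative to
  the known annotation, each emitting unstranded fragments (one by default:
  the "clean" setting for recovery tests), a TSS-proximal peak (~150 bp
  offset) in root and, with probability 0.7, in stem, and Poisson-many
  stranded ESTs, some spanning fragment gaps.
- **Modules** — planted with exact (size, n_expressed, n_marked)
  composition by sampling from the four expressed×marked pools; marked
  members are preferentially drawn from expressed genes. Infeasible
  compositions raise an error rather than being silently approximated. The
  default spec plants the two module sizes used in the worked contingency
  examples (43 and 37 members).
- **Hit tables** — planted pairs get E-values log-uniform in [1e-120,
  1e-60]; decoys log-uniform in [1e-54, 1e-10], so the 1e-55 cutoff
  separates them decisively and reciprocal-best-hit recovery of the planted
  pairing is exact.

Everything derives from one `numpy.random.default_rng(seed)` and all
writers emit sorted records with fixed float formats, so a fixed seed gives
byte-identical outputs — the end-to-end determinism the pipeline tests
assert.

What the world does *not* model: read-level noise, mappability, peak-width
variation with signal strength, overlapping genes, alternative isoforms,
and genome-scale gene counts. Passing recovery tests therefore demonstrate
the correctness of the decision rules and statistics, not performance on
real chromatin data.

## Problem sizes

Tests run worlds of 40–300 genes plus one 2,000-gene world (four 8-Mb
chromosomes) for the decile-frequency and concurrence checks; strand
recovery is averaged over ten 80-gene worlds. These sizes give binomial
standard errors small enough for the 3-SD bands to be informative while the
whole suite stays fast on a single CPU.

## Known limitations

- The differential caller is region-restricted and Poisson-based; it does
  not model local background (no sliding local-lambda) and is not intended
  as a general peak caller.
- Strand inference degrades when peak offsets approach the candidate
  length; the `middle` band is reported, not resolved.
- The genome-background breakdown treats overlapping annotation by
  precedence only; fractional assignment is out of scope.
- The conservation-ratio denominator choice (pairs vs genes per
  chromosome) changes the matrix for unbalanced genomes; both are exposed,
  only the pair normalisation is tested against planted truth.
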