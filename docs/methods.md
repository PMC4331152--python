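# Methods

`mirkit` re-implements, at desk scale, the computational pipeline used to
compare miRNA populations between cultivated cassava (cultivars KU50 and
Arg7) and its wild progenitor (W14): hairpin-precursor discovery, read-count
normalization and differential expression, complementarity-based target
prediction, RLM-RACE cleavage-site classification, and miRNA:target
co-expression. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Precursor discovery and structure filters

Known mature sequences are matched exactly against both genome strands.
Around every matched locus, candidate windows are cut with every
combination of upstream/downstream flank lengths (default
{20, 60, 100, 150, 200, 250} nt, i.e. 36 windows per locus), folded,
trimmed of free tails, and filtered twice:

* **Stem filter** — at least 18 bp in matched regions, exactly one terminal
  loop, folding energy ≤ −18 kcal/mol. "Matched regions" defaults to the
  whole trimmed stem; counting only the mature:star duplex is available via
  `RunConfig.matched_region = "duplex"`.
* **Duplex filter** — on the mature:star duplex implied by the structure:
  ≤ 4 mismatches, ≤ 2 bulged or asymmetrically unpaired nucleotides, and no
  run of more than 2 consecutive mismatches in the seed region. The seed
  region defaults to mature positions 2–8 (1-based, configurable). A G:U
  pair counts as paired; a mismatch is a pair of opposed unpaired positions;
  bulges are unpaired nucleotides with no opposed unpaired partner.
  Terminal unpaired mature positions, whose opposition is undefined, count
  as mismatches, assigned left-to-right inside internal gaps.

A locus is reported when at least one window passes both filters; the
lowest-energy passing window becomes the locus's precursor.

### Fallback folder

When no external dot-bracket report is supplied, structures come from a
built-in base-pair-maximization dynamic program (pair set {AU, GC, GU},
minimum hairpin loop 3 nt). Because the max-pair optimum set of a long
window is massively degenerate, the objective is lexicographic:

1. maximize base pairs (the classic Nussinov optimum);
2. minimize the number of terminal loops;
3. maximize stacked adjacent pairs.

All three are packed into one integer (`pairs·2²⁰ − loops·2¹⁰ + stacks`), so
the recursion stays a plain maximum and the traceback is deterministic. The
tie-breaks select a contiguous helix out of co-optimal structures; they
never change the pair count, which is what the enumeration property tests
compare. The pseudo-energy is −(2·GC + 1·AU + 1·GU) kcal/mol over paired
positions. It is cruder than a thermodynamic MFE but is applied against the
same −18 threshold; external folder output, when supplied, is authoritative
and its printed energies are used unchanged. Sequence-length bounds are not
enforced (windows up to 521 nt occur with the default flank set).

## Homology, conservation, novelty, read mapping

* **Homology search** — seeded (word size 7) ungapped extension with
  match +1 / mismatch −2 and X-drop 12; significance is a Karlin–Altschul
  E-value with λ solved numerically for that scheme and K = 0.621 (the
  tabulated blastn value). Hits with significance < 1e-10 are kept. This is
  a reproducible stand-in for an external local-alignment tool; the
  threshold is used as printed.
* **Conservation rule** — a miRNA is *not* conserved in an assembly only
  when no homologous sequence is found **and** fewer than 10 normalised
  reads map to the mature (≤ 2 substitutions, no indels); any mapped reads
  alone are sufficient evidence of conservation.
* **Novelty rule** — a candidate is *new* when its best local-alignment
  identity against every known mature, normalized by the candidate length,
  is ≤ 70%. Local alignment uses match +1 / mismatch −1 / gap −1; the
  denominator choice (candidate length) is ours, as is mature-only (rather
  than hairpin) comparison.
* **Read mapping** — end-to-end containment with ≤ 2 substitutions and no
  indels; multi-reference reads are counted on every reference they hit,
  matching the attribution rule for multi-locus reads.

## Quantification and differential expression

NNR (normalised number of reads) is `N_miRNA · C / N_sample`, with
`N_sample` the library's qualified read total and `C` the mean `N_sample`
over all libraries. A cell with NNR < 50 is silent; NNR = 50 is expressed
(boundary inclusive). Two exact properties are tested: NNR depends only on
per-library relative composition and `C` (depth rebalancing cancels), and a
global rescale of all counts and depths scales NNR linearly — so
fold-change calls are scale-invariant. The often-assumed stronger claim
that NNR itself is invariant under global rescaling is false for this
formula, since `C` scales too.

A miRNA is differentially expressed in an organ when the fold change
between the cultivar level and the progenitor level is ≥ 2 and the larger
side is expressed. The cultivar level defaults to the mean NNR of KU50 and
Arg7 (`de_mode = "mean"`); requiring each cultivar individually to pass is
available (`"both"`), since the original comparison's combiner is not
recoverable. Folds use a pseudocount of 1 on both sides:
`(larger + 1)/(smaller + 1)`, so silent-vs-expressed contrasts still rank.

## Target prediction

A modified local-alignment dynamic program aligns the full miRNA against
each mRNA window read 3′→5′: Watson–Crick +1.0 (0 mismatch units), G:U +0.5
(0.5 units, configurable), mismatch −1.0 (1 unit), gap −2.0 (1 unit).
Window ends are free; among score-optimal alignments the lowest-cost one is
returned with a deterministic diagonal-first traceback. Sites with ≤ 3
mismatch units are reported; overlapping candidate windows are deduplicated
keeping the best final score.

The final score adds two determinant rewards to the raw alignment score: +2
when the seed block (miRNA positions 2–13, 1-based, configurable) contains
no mismatch and no gap, and up to +1 for the A/U fraction of the 10 mRNA
nucleotides flanking the seed-pairing subinterval (5 per side, clipped;
these flanks can overlap the site itself). The exact coefficient set of the
original scoring tool is not published; this scheme implements the named
determinants (seed, local AU content, ≤ 3 mismatches) with documented,
configurable weights.

For speed, a vectorized ungapped cost profile prescreens window starts; the
dynamic program runs only where the ungapped cost is ≤ 10 units. A site of
cost ≤ 3 with one bulge always leaves one register with ungapped cost below
the screen; contrived multi-gap sites near the cap could in principle be
missed, planted and random sites are unaffected.

## Cleavage-site classification

A clone records the mRNA coordinate of the 5′ end of the 3′ cleavage
remnant. Relative to the pair's complementary region (CR, bulge-free, same
length as the miRNA), a position classifies as:

* **CR** with offset counted from the miRNA 5′ end (which pairs the CR's 3′
  boundary on the mRNA): coordinate `e − p` is offset `p` for CR `[s, e)`;
* **upstream** (5′ of the CR) with offset `+n` = distance from the CR 5′
  boundary;
* **downstream** (3′ of the CR) with offset `−n`, `n` counted from the CR 3′
  boundary. The sign convention (+ upstream, − downstream) follows the way
  RACE tables are printed, although it inverts genomic intuition.

Half-integer coordinates `k + 0.5` encode 5′ ends resolved only to the two
nucleotides they straddle; they classify to the ordered offset pair (and
render as "10th/11th"), with the zone taken from the lower-coordinate
nucleotide. A pair is *canonical* when at least one CR cleavage falls at
offsets 10–12 (either side of a boundary pair qualifies). Experiment-level
tallies count pairs with any clone (sliced), canonical pairs, and sliced
pairs with no CR clone at all. The built-in fixture encodes the 15 assayed
pairs (the unnamed 15th, cloneless pair is a synthetic placeholder), with
CR placements drawn per seed so classification must recompute zones; the
round-trip property holds for arbitrary placements.

## Co-expression

Each miRNA:target pair is classified over the six genotype×organ
conditions. Default: Pearson correlation of log2(x+1) values, calling
negative/positive when |r| ≥ 0.5 **and** p ≤ 0.05. The significance guard
matters because with n = 6 points P(|r| ≥ 0.5) ≈ 0.31 under the null; the
guard brings the null call rate to ≈ 5%, and anti/in-phase planted profiles
(|r| ≈ 1) are always called. Pairs silent/unexpressed everywhere on either
side (NNR < 50, FPKM < 3) and constant profiles return "none" with a
reason. An alternative "ratio_sign" mode votes on the signs of per-organ
log2(cultivar/progenitor) ratios (pseudocount 1); neither mode is claimed
to be the original study's (undocumented) procedure.

## Synthetic data generator

The generator emulates the study design — six small-RNA libraries
(3 genotypes × 2 organs), one genome, one unigene set, expression tables,
and the RACE fixture — with recorded ground truth.

* **Genome** — each precursor is a constructed inverted repeat: a 21-nt
  near-balanced-composition mature arm, a 12-nt low-pairing loop and the
  reverse-complement star (optionally with ≤ 2 injected non-pairing
  substitutions). Precursors sit inside purine-only {A, G} buffers (260 nt
  by default, parameterizable), which admit no internal base pair in either
  reading orientation; each (precursor, buffer) draw is rejection-sampled
  until the fallback folder returns exactly the planted stem in both
  orientations of the full-buffer window. Every discovery window is a
  substring of that tested window, so planted-set recovery is guaranteed
  per instance rather than merely probable. Background between planted
  regions is i.i.d. uniform; every third precursor is planted on the minus
  strand; multi-copy planting exercises multi-mapping attribution.
* **Libraries** — planted matures with Poisson counts around expected
  abundances (exact mode for identity tests); background reads are random
  genome substrings of 18–25 nt at a configurable rate (default 0.1 of a
  100 000-read depth; the original per-library depths are unpublished, so
  this desk-scale default is a documented choice). Expression classes are
  planted per miRNA: 2.5-fold differential (comfortably outside the
  2-fold call threshold's 1.9×/2.1× guard band, with expected counts in the
  thousands so Poisson noise stays inside it), exact nulls, and
  absent-in-progenitor patterns.
* **Unigenes** — per planted target, the reverse complement of the mature
  with a recorded number of injected mismatches (non-pairing substitutions)
  and G:U wobbles at interior positions; decoys are resampled until no
  mature has an ungapped site of cost ≤ 4 anywhere.
* **Expression tables** — per-pair miRNA/target profiles over the six
  conditions with planted anti-phase, in-phase or independent log2
  structure and configurable Gaussian noise.

**What the generator does not emulate:** sequencing error and adapters,
realistic 4-letter flanking context around precursors (the purine buffers
are an engineered construction required by the pair-maximization folder),
isomiR heterogeneity, transcriptome-scale unigene sets, and thermodynamic
folding landscapes. Passing recovery tests therefore demonstrates the
correctness of the decision rules and bookkeeping, not the sensitivity of
hairpin discovery on real genomic sequence with a thermodynamic folder.

## Problem sizes and determinism

Tests and the acceptance checks run at desk scale by choice: 5 planted
precursors per genome, 20 genomes for recovery, flank set {20, 60} with
80-nt buffers in the recovery property (default flanks elsewhere), 500
random cases for each enumeration property (folding oracle at ≤ 14 nt,
alignment oracle at miRNA ≤ 12), 40 seeds for differential-expression
recovery, 1000 white-noise pairs for the co-expression null rate. All
randomness flows through seeded `numpy.random.default_rng`; identical seeds
give byte-identical generator output. The folding DP is JIT-compiled with
numba (first call compiles in a few seconds).

## Known limitations

* The pseudo-energy scale of the fallback folder is not thermodynamic; the
  −18 kcal/mol threshold applied to it is a labelled approximation.
* The homology E-value uses fixed Karlin–Altschul parameters for one
  scoring scheme and uniform base composition.
* Boundary ("p/p+1") cleavage records are an encoding of resolution
  ambiguity in the source data; whether upstream/downstream offsets were
  originally anchored at the CR boundary or the canonical cut site is not
  recoverable, and the fixture is self-consistent under boundary anchoring.
* Genome-scale counts (family totals, target-set sizes, the
  negative/positive co-expression split) require the original deposited
  libraries and are out of desk-scale reach by design.
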