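# Methods

## The strand model

A MeDIP-Seq peak is a genomic window with Y first-mate reads, split into
Y₊ forward and Y₋ reverse-complement alignments. Read counts at a locus
are modelled as Poisson. The question the classifier answers is not
"what is the rate on each strand?" but "is a *single* integer rate λ
simultaneously plausible for both strand counts?" — if yes, the peak's
methylation is consistent with a symmetric, double-stranded origin; if
no, it is called on the strand with more reads.

Candidate rates are the integers from min(Y₊,Y₋) to max(Y₊,Y₋)
inclusive. For a count Y, the likelihood set at cutoff α is

    LS_α(Y) = { λ : l(λ)/l(Λ) ≥ α },   Λ = argmax over the candidates.

Because the candidate range always contains Y, the maximiser is Y itself
(the Poisson likelihood is unimodal in λ), the ratio at Λ is exactly 1,
and both observed counts are always members of their own sets. The
decision is: intersection nonempty ⇒ both strands; otherwise plus or
minus by the larger count. Equal counts give identical sets, so a tie
always lands in "both" and no tie-break branch exists.

θ = Y₊/Y is reported as a descriptive statistic only. An alternative
parameterisation would score Y₊ against rate λθ and Y₋ against λ(1−θ),
but that formulation cannot admit rates near Y₊ into the plus set when
θ < 1 and is incompatible with the canonical worked example
(Y₊=60, Y₋=40 ⇒ LS₊={45..60}, LS₋={40..55}); each strand count is
therefore compared against Poi(λ) directly over the shared candidate
range.

Numerical choices: all likelihoods are evaluated in log space with the
log-gamma function for factorials; the ratio test is a log-difference
against log α with exact "≥" at the cutoff (the boundary rate 45 in the
example has ratio ≈ 0.104 and must be included). The λ = 0 boundary is
exact: probability 1 for Y = 0, probability 0 otherwise. If every
candidate has zero likelihood (possible only when the candidate set is
supplied externally and excludes the observed count's support), the
likelihood set is empty.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.1 | likelihood-ratio cutoff; smaller α widens the sets and shifts calls toward "both strands" |
| min_depth | 0 (library), 12 (CLI) | peaks with fewer total first-mate reads are reported UNCLASSIFIED, never dropped |
| min_mapq | 10 | alignment filter |
| count mode | overlap | a read counts toward a peak if its span overlaps by ≥1 bp; `fiveprime` restricts to reads whose 5′ end lies inside |

The CLI's min_depth of 12 reflects the depth below which likelihood sets
are so wide that single-stranded calls are rarely possible (at Y₊+Y₋ ≈ 10
even a 5:1 split often yields intersecting sets); the library default of
0 leaves thresholding to the caller. A zero-read peak is UNCLASSIFIED
with a low-depth flag rather than an error.

## Alignment handling

Only primary, mapped, **first-in-pair** alignments carry the captured
strand's identity, so second mates, secondary and supplementary records
are excluded; mapping quality < 10 and flagged duplicates are removed
(duplicate *marking* is upstream's job). Improper pairs are kept by
default, with a switch to drop them. A file with mapped reads but no
paired-end flags is rejected outright: single-end data cannot yield a
first-mate strand signal. Strand is read from the reverse-complement
flag. The per-cycle base-frequency QC tallies A/C/G/T/N at each read
position; in a strand-preserving MeDIP library the C and G columns
diverge because first mates read the methylated (cytosine-bearing)
strand.

## Overlap semantics and derived features

All intervals are 0-based half-open with strand ∈ {+, −, both}; GFF3's
1-based closed coordinates are converted on read. Two intervals overlap
when they share a seqname, ≥1 bp of coordinates, and compatible strands
("both" matches everything). `count_overlaps(Q, S)` returns, per query,
the number of subject intervals overlapping it — instance counting, no
flattening of overlapping gene models.

From a GFF3 annotation: upstream/downstream flanks extend 2 kb from the
gene's 5′/3′ end on the gene's strand (reversed arithmetic on the minus
strand, clipped at declared sequence boundaries); exons come from the
annotation; introns are the gaps between consecutive exons of each
transcript; identical intervals from different isoforms are
deduplicated. Splice donor windows sit at exon→intron boundaries (the
intron's 5′ end in transcription orientation, i.e. the higher genomic
coordinate for minus-strand transcripts) and acceptor windows at
intron→exon boundaries, ±100 bp by default. The window width is a free
choice — annotation conventions vary and nothing in the decision rule
depends on it — and is exposed as a flag. Sense/antisense is realised as
peak-strand versus window-strand comparison on the single window per
junction: the asymmetry being tested is one of strandedness, not of
position relative to the junction.

The splice asymmetry test counts single-stranded peaks overlapping
donor (resp. acceptor) windows on the same strand (sense) versus the
opposite strand (antisense) and applies a two-tailed one-sample
proportion test of "half the overlaps on each side", normal
approximation with Yates continuity correction (equivalent to R's
`prop.test`). Zero overlaps yield an undefined (NaN) p-value.

## Downstream statistics

**Gene-anatomy distribution.** Feature sets differ enormously in
abundance, so overlap counts are normalised per 1000 feature instances.
With count c over n instances the exposure is n/1000 and the conjugate
gamma-Poisson posterior is Gamma(a₀+c, b₀+n/1000), default prior
a₀ = b₀ = 0.001 (vague; the posterior mean is then within a fraction of
a percent of the raw rate c/(n/1000) for any realistic count). The 95 %
interval is taken from the empirical 2.5/97.5 percentiles of 10,000
posterior draws from a seeded generator — simulation rather than the
closed-form quantile so that derived quantities (e.g. the normalised
percentages) can reuse the same draws; tests confirm convergence to the
closed form within 0.5 % at 10⁵ draws. The percentage column normalises
the posterior-mean rates over the feature sets to 100.

**Concordance with single-base calls.** Stranded 5mC calls (a trivial
transform of a Bismark cytosine report; calls supported by fewer than 3
methylated reads are dropped) are tallied per peak and strand. For each
peak class the per-peak (plus, minus) count pairs enter a paired
two-tailed t-test of equality. Degenerate inputs: with fewer than two
call-containing peaks the test is reported not applicable; when all
per-peak differences are identical the statistic has no finite sampling
form, and the implementation reports the exact null (t=0, p=1) for a
zero difference and p=0 otherwise.

**Peak-width bias check.** Peaks are split into three width groups at
the 50 % and 95 % quantiles (so 50/45/5 % of peaks — the widest group is
the one most likely to mix single- and double-stranded signal) and the
group × class contingency table is tested for independence with
Pearson's chi-squared (no continuity correction; a warning is attached
when any expected cell is below 1).

## The synthetic-data generator

`simulate(SimulationConfig(seed=…), out_dir)` writes a genome FASTA,
GFF3 annotation, caller-style peak BED, coordinate-sorted indexed BAM of
first-mate alignments, an as-sequenced FASTQ, a stranded 5mC call table
and a truth table. It emulates the three methylation scenarios of a
strand-preserving library:

* a **both-strands** peak draws Poisson(depth_mean) first mates on each
  strand; a **single-stranded** peak draws Poisson(depth_mean) on the
  methylated strand and Poisson(ε·depth_mean) on the other, with
  ε = `cross_contamination` = 0.02 by default — a small, nonzero
  antibody/background leak that makes recovery non-trivial (ε = 0 gives
  the idealised textbook picture);
* single-stranded peaks are hosted at splice junctions of simulated
  genes while unused junctions remain (antisense to the host gene with
  probability `antisense_bias`), the rest placed uniformly without
  overlap; double-stranded peaks are placed uniformly;
* the genome sequence under each peak is re-drawn with cytosine
  enrichment on the methylated strand (40 % C on that strand versus 30/30
  balanced C/G under symmetric peaks), which reproduces the per-cycle
  C:G imbalance of real MeDIP FASTQ files;
* background reads fall uniformly at `background_rate` = 0.3 reads/kb.

Defaults: 2 sequences × 250 kb, 16 genes of 3–6 exons (exons 150–400 bp,
introns 0.8–2 kb), 200 peaks of 250–350 bp with class fractions
0.4/0.4/0.2 (plus/minus/both), per-strand depth mean 50, read length 50.
Depth 50 with ε = 0.02 mirrors a well-powered MeDIP experiment at peaks;
the depth dependence of the rule is itself a study object (at
depth_mean ≈ 2 most single-stranded truth collapses into
both/unclassified). All randomness flows through one seeded numpy
generator in documented draw order; a seed reproduces every output
byte-identically.

What the generator does **not** emulate: fragment-length variation
(reads are emitted as already-aligned, fixed-length records — the
aligner is outside the test surface), sequencing errors, mappability
structure, bisulfite conversion chemistry, or correlated peak shapes.
Passing recovery tests on this generator therefore demonstrates the
correctness and calibration of the decision rule and of the downstream
counting machinery under its stated Poisson assumptions — not robustness
to alignment artefacts in real libraries.

## Problem sizes in the test suite

The bundled tests run the classifier exhaustively over all count pairs
up to 200 against a brute-force enumerator, property checks over 10⁴
randomised pairs, end-to-end recovery on a 500-peak simulation at depth
50 (≥95 % single-stranded truth recovered), the overlap engine against a
naive all-pairs scan on 200×2000 random intervals, credible intervals
against closed-form gamma quantiles at 10⁵ draws, and splice-asymmetry
direction recovery at antisense_bias = 0.9 on a 300-peak, 30-gene
simulation.

## Known limitations

* The rule classifies strandedness of *enrichment*, not methylation
  level; a peak's class says nothing about the fraction of molecules
  methylated.
* Counts are integers and the candidate grid is integer-valued; for
  very deep peaks (counts ≫ 10⁴) the likelihood sets become narrow
  relative to 1 and the integer grid is the resolution limit.
* Peaks are classified independently; overlapping or adjacent caller
  peaks are neither merged nor re-centred (an optional resize hook is
  deliberately not a default).
* The proportion and t-tests are the classical large-sample forms;
  with a handful of overlaps the splice test's normal approximation is
  crude (the continuity correction mitigates but does not remove this).
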