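# Methods

## Pairing model and counting convention

A triplex-forming unit is a single base triplet XY:Z — a Watson–Crick pair
XY plus a third-strand base Z in the major groove.  Pairing is keyed on the
purine of the duplex pair, because only purines expose a second
hydrogen-bonding face.  The favorable units are Hoogsteen TA:U and CG:C and
reverse-Hoogsteen TA:A and CG:G; everything else contributes nothing.
Alignments are ungapped, counted under exactly one mode, and unfavorable
interior positions do not terminate an alignment (the validated 21-unit
target contains an interrupting C).

Several details of this convention are not forced by the motif table alone;
they are pinned jointly by the six experimentally validated unit counts of
the calibration oligo set (16, 21, 10, 11, 10 and 9 favorable bonds):

- **Orientation.** Antiparallel: overlap position *i* (from the alignment
  offset on the target) pairs `target[offset+i]` with
  `third[len(third)-1-i]`.  The molecular model of the validated triplex is
  antiparallel; it is the only orientation that reproduces all six counts.
- **No mode mixing.** Under reverse-Hoogsteen counting, a third-strand C
  over a C·G pair is *not* favorable even though Hoogsteen CG:C exists.
  This is what makes the optimized oligo 21/22 rather than 22/22.
- **Purine-strand keying with relaxation.** A duplex window is scored
  against whichever strand the miRNA registers on (the scanner tries both
  genomic strands); a pyrimidine on that strand simply yields an
  unfavorable unit.  Polypurine-run detection exists as an annotation aid,
  but the reporting criterion is the unit count, never run purity.
- **Ambiguity codes** (N, IUPAC) are never favorable and never abort an
  alignment — conservative behaviour on real assemblies.

"Direct" and "indirect" binding are exposed as the two orientations
(antiparallel = direct); both are on by default and either can be disabled.
This identification is a documented interpretation, isolated behind the
`orientations` option.

## Scoring and energies

Score is `points_per_unit × n_units` with `points_per_unit = 20`, derived
from the single published anchor (a 7-unit alignment scores 140, the
reporting threshold).  There is no positional weighting and no length
normalization.

Binding energy is the sum of a per-unit energy over favorable positions
only.  The packaged default table
(`src/triplexscan/data/energy_defaults_synthetic.tsv`) carries **synthetic
stand-in values** — distinct, negative, with the G-keyed motifs stronger
than the A-keyed ones.  They are parameters, not computed quantities: any
result that depends on absolute energies is configuration-sensitive by
design, while the relative machinery (summation, dominance ranking) is
independent of the particular values.  An optional energy reporting cut-off
exists alongside the score threshold and is disabled by default.

## Genome scanning

For a fixed (miRNA, mode, orientation), each third-strand position demands
one specific purine on the target, so the per-offset unit count is a sum of
equality indicators over the encoded sequence and the per-offset energy the
matching weighted sum; both are computed with vectorized array operations
across all full-overlap offsets, with edge (overhanging) registrations
evaluated explicitly at true sequence boundaries.  Both genomic strands are
scanned; coordinates are 0-based half-open on the forward strand (BED
convention), with the reported strand naming the strand the miRNA registers
against.  The human-readable prediction report uses the same half-open
convention.

**Reporting policy.**  Around any real site, many shifted registrations
also clear the 7-unit threshold (a 1-bp shift of the validated target still
counts 10 units), so raw reporting would emit a stack of overlapping hits
per physical site.  Reports within one family (same contig, strand, miRNA,
mode, orientation) are therefore reduced by greedy non-maximum suppression:
candidates ranked by (more units, lower energy, smaller start), and any
candidate overlapping an accepted one is dropped.  `--report-all` disables
this.  Suppression among exactly tied overlapping candidates keeps the
rank-first one; this choice is deterministic but not mirror-symmetric,
which is why the strand-symmetry test runs with suppression off.

**Segmentation.**  Long sequences can be scanned in overlapping segments
(overlap ≥ longest miRNA − 1).  Candidate collection happens per segment
before suppression; candidates are deduplicated by
(interval, strand, miRNA, mode, orientation) and suppression runs globally,
so the segmented result is identical to the whole-sequence scan by
construction (and verified by test).

## Dominance grading

Within one scan run, site *i*'s dominance count is the number of sites *j*
with `score_j > score_i` and `energy_j < energy_i` — strict in both
dimensions; ties and Pareto-incomparable pairs do not dominate.  The count
is computed by a descending-score sweep with a Fenwick tree over compressed
energy ranks (tie groups held out before insertion), verified against the
quadratic definition.  Grades 1–5 are nested fractions of the population
(defaults 1e-5 … 1e-1); the grade-5 cut-off extrapolates the published
ten-fold pattern one step and is configurable.  Grading is applied to the
thresholded (score ≥ 140) population of one run, i.e. relative
intra-genomically.

Note that only for a totally ordered population are dominance counts exact
ranks, making each grade's share equal to its cut-off (plus one-site
rounding).  With ties or incomparable pairs the counts shrink, so a grade
can hold more than its nominal share — e.g. every maximal-score site has
count 0.  This is inherent to the dominance definition, not an
implementation artifact.

For arbitrary (score, energy) queries, the dominance-count surface is
tabulated on a grid and interpolated bilinearly.  The default grid uses the
exact unique observed values per axis, so grid nodes (including every
observed site) reproduce the discrete grades exactly; above 1024 unique
values per axis it falls back to regular bins (20 score points / 0.5
kcal/mol, range-capped at 1024 nodes), where node queries remain exact and
off-node queries are approximate.  Out-of-hull queries are clamped to the
nearest boundary cell and flagged; a query dominating the whole population
clamps to the zero-count corner and grades 1.

## miRNA characterization

Composition profiles are exact counts over the RNA alphabet (T → U).  The
headline classes are purine:pyrimidine imbalance (> 75% of either), and
extreme GC or GU content (< 25% or > 75%).  Hits are weighted per site —
a miRNA with many top-graded sites contributes per site — and compared to
the full catalogue with the two-sample proportion test (Yates-corrected
chi-squared on the 2×2 table, equivalent to R's `prop.test`), via
`scipy.stats.chi2_contingency`.  Degenerate margins return p = 1 with a
warning.  The genome-scale published percentages require a full genome and
catalogue; at package scale the tests demonstrate the qualitative
enrichment on planted structure and verify type-I behaviour on uniform
hits.

## Expression enrichment

Per cohort, Spearman rank correlation (average ranks for ties, two-sided p
from the t approximation; `scipy.stats.spearmanr` semantics, computed
vectorized as Pearson on ranks for bulk work) is evaluated for each
(miRNA, gene-probe) pair; probes map many-to-one onto genes and each probe
is a separate record.  Constant vectors are flagged and excluded.

Cohorts are combined with an equal-weight inverse-normal (Stouffer)
meta-analysis on one-sided p-values oriented by each cohort's correlation
sign; the combined two-sided p and the sign of the combined z are reported.
The combination method is a package choice (the analysis it reimplements
does not specify one); sample-size weights are available via an argument.
A single cohort maps back to its own two-sided p; concordant evidence
sharpens; strong opposite signs cancel.

A gene is anchored when a top-grade site lies within the ±5000 bp window of
the gene body (0-based half-open intervals; a gap of exactly 5000 bp is
inclusive; strand-symmetric).  Among anchored pairs with meta p < 0.01
(raw, uncorrected — the enrichment comparison itself is the significance
statement), the positive:negative fold is reported together with the
proportion test of the split against 50/50.  Zero negative pairs yield an
infinite fold with a flag.  Gene-level and pair-level counts are both
reported, since a gene can be anchored by several miRNAs.

## Synthetic fixtures

`perfect_target` reverses the miRNA (U → T): every purine position then
faces its own identity under the antiparallel reverse-Hoogsteen
registration, which is the attainable maximum since pyrimidine third-strand
positions cannot form purine-motif units against any target base.
`plant_genome` substitutes such targets into uniform random background
(strand-aware) and emits a truth table of coordinates and expected unit
counts.  `simulate_cohorts` builds two cohorts from a Gaussian copula:
planted genes mix their miRNA's latent normal vector with fresh noise.  The
latent Pearson correlation is chosen by inverting Moran's finite-sample
expectation of the sample Spearman coefficient, so the generator targets
the *sample* correlation its contract promises rather than the population
value (at n = 100 the naive conversion undershoots by ≈ 0.017 at
ρ_s = 0.6).  Values are mapped affinely to a log-intensity-like scale
(location 8, scale 2), preserving ranks.

What the generators deliberately omit: realistic genome composition
(repeats, isochores, CpG structure), microarray noise physics, batch
effects and missingness.  Recovery tests therefore validate the machinery,
not field performance.

## Problem sizes and numerical choices

The test suite runs planted-recovery on 100 kb backgrounds with ~10 miRNAs,
segmentation equivalence on a 1 Mb background at a 12-unit scan threshold
(the equivalence property is threshold-independent; the default 7-unit
threshold admits roughly a fifth of all offsets for purine-rich miRNAs on
random DNA, which inflates bookkeeping without sharpening the check), null
calibration of the meta-analysis on 10⁴ independent pairs at two cohorts of
60 samples, and planted-effect enrichment recovery over 100 seeds at
ρ_s = 0.4 with 40 planted among 80 anchored pairs.  Best-alignment
tie-breaks are (more units, lower energy, smaller offset, Hoogsteen before
reverse-Hoogsteen, antiparallel before parallel).  Meta p-values are
clamped into (0, 1]; dominance grids cap at 1024 nodes per axis.

## Known limitations

- Absolute energies are placeholders; only relative statements survive a
  table change.
- No gaps/bulges, no protonation-state (pH) chemistry for C⁺·G·C, no
  chromatin accessibility filtering, no spliced-transcript alignment.
- Grade populations are per scan run; grades from different runs are not
  comparable without refitting.
- The suppression policy at exactly tied overlapping registrations is a
  documented convention; the original duplicate-report policy of the tool
  this reimplements is unknown.
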