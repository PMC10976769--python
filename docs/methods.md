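# Methods

This note documents the models and procedures implemented in `mirfam`, the
assumptions behind them, the tunable parameters, and what the synthetic-data
generators do and do not emulate.

## Scope and data model

The package analyses a deeply conserved plant miRNA family (miR166 and its
relatives) at six levels: family census across species, sequence conservation,
distance-based phylogenetics, precursor secondary structure, degradome-based
target calling, and qPCR relative expression. All sequences are held as RNA
(`ACGU`; `T` is normalised to `U` on read, ambiguity codes are rejected rather
than guessed). Every coordinate in memory and on disk is 1-based inclusive,
matching the convention of degradome cleavage-site tables; TSV files carry a
`#` header line saying so. Identical run configuration (including the seed)
produces byte-identical output for every stochastic stage.

## Census

The packaged table (`mirfam/data/mir166_census.tsv`) lists per-species
precursor and mature miR166 counts for 49 species from bryophytes to eudicots,
with division, family and monocot/dicot labels. `clade_summary` partitions a
division's species into mature > precursor, mature = precursor and
mature < precursor classes; the three counts always sum to the species count,
and extreme-count species are reported as complete, lexicographically sorted
tie lists, which makes the summary permutation-invariant. Alfalfa itself
(4 precursors / 8 matures, from dedicated small-RNA and degradome sequencing
rather than miRBase) ships as a separate one-row fixture and is excluded from
cross-species summaries by default, because its counts are not
methodologically comparable with the miRBase-derived rows.

## Conservation

*Pairwise identity* is computed on a global (Needleman–Wunsch) alignment with
match +1, mismatch 0 and linear gap −1, as matches / aligned columns × 100;
gap columns count in the denominator, so the measure is symmetric and equals
100 exactly only for identical sequences. Ties in the traceback prefer the
diagonal move, making the reported alignment deterministic. The aligner is
certified in the tests against exhaustive enumeration of all global alignments
at small size.

*Progressive multiple alignment* builds a guide tree by Neighbor-Joining on
pairwise-identity distances (d = 100 − %id) and merges profiles postorder with
sum-of-pairs scoring under the same match/mismatch/gap scheme. Residues are
never lost and the alignment has at least as many columns as the longest
input. This is a deliberately simple aligner: the family's mature strands are
21–22 nt and near-identical, so guide-tree order matters far more than
refinement heuristics.

*Information content* per column is IC = 2 − H (bits), with H the Shannon
entropy of the A/C/G/U frequencies over non-gap rows; all-gap columns are
flagged and recorded as 0. No small-sample correction is applied by default;
`small_sample_correction=True` subtracts the standard e(n) = 3/(2·ln2·n)
term. *Conserved positions* are 1-based columns whose dominant base frequency
reaches a threshold (default 0.9; the threshold must exceed 0.5 so the
dominant base is unique).

## Phylogenetics

Distances are p-distances (mismatches / compared sites) with pairwise deletion
of gap columns; a pair with no comparable columns is an error naming the pair.
A Jukes–Cantor correction (−3/4·ln(1 − 4p/3)) is available by switch.

Neighbor-Joining follows Saitou & Nei with the Studier–Keppler Q criterion.
Q-ties are broken by the smallest (i, j) index pair in the current matrix, so
the tree is deterministic. Negative branch lengths are clamped to zero with
the deficit moved to the sibling branch, preserving path lengths through the
joined pair. The final three lineages join on a trifurcating root via the
closed-form three-point solution, giving an unrooted tree with 2n − 3 edges.
On additive matrices the reconstruction is exact: the test battery checks
max |path length − input distance| < 1e-9 over random additive trees with
n ≤ 12.

Bootstrap supports resample alignment columns with replacement. All replicate
draws are taken as a single (replicates × columns) block from one seeded
generator, so replicate r is reproducible independent of chunking. Support of
an internal edge is the percentage of replicate NJ trees containing the same
leaf bipartition (bipartitions are canonicalised to the side excluding the
lexicographically first taxon).

## Precursor folding

`fold_mfe` is a Zuker-style dynamic program over a Turner-style
nearest-neighbour model at 37 °C (kcal/mol): Watson–Crick stack energies from
the Xia et al. (1998) measurements, G:U wobble stacks from the Mathews et al.
(1999) compilation, hairpin/bulge/internal-loop initiation tables with
Jacobson–Stockmayer size extrapolation (1.75·RT·ln(n/n_ref)), a Ninio-style
internal-loop asymmetry penalty (0.5/nt, capped at 3.0), an affine multiloop
cost (3.4 closing + 0.4 per branch + 0.0 per unpaired nt), and a +0.5 terminal
penalty at every helix end closed by AU/UA/GU/UG. Deliberate simplifications:
no terminal-mismatch or dangling-end terms, no special 1×1/1×2 internal-loop
tables, no coaxial stacking (single-nucleotide bulges do keep the flanking
stack, per the standard convention). Structural constraints: minimum hairpin
loop 3 nt, G:U allowed everywhere, interior loops capped at 30 nt for the
search, and no lonely pairs by default — every helix must hold at least two
stacked pairs, as in mfold-class folders (`allow_lonely_pairs=True` lifts
this).

Correctness is certified structurally, not against published energies: for
random sequences up to 25 nt the DP's minimum equals exhaustive enumeration of
all valid structures scored by an independent loop-decomposition evaluator
built on the same parameter tables (`energy_of_structure`). The parameters are
shared by construction — the oracle certifies the *search*. Against an
independent reference folder with a richer parameter set (ViennaRNA), forced
perfect hairpins agree to within ~15% relative energy, which is the expected
scale of the omitted terms.

`is_stem_loop` accepts a fold when its MFE structure has exactly one terminal
loop — the miRNA-typical single hairpin. `locate_arm` requires the mature
strand to occur exactly once in the precursor and to lie entirely on one side
of the terminal loop; a loop-spanning mature is an explicit error rather than
a guess, as is a multi-hairpin precursor.

## Degradome target calling

Duplex complementarity uses the standard plant-miRNA penalty scheme: mismatch
1 point, G:U wobble 0.5, bulged nucleotide 1, each doubled when the event lies
opposite miRNA positions 2–13 (5'→3'); the reported duplex is the
minimal-penalty gapped antisense alignment (global DP over the site window,
window length within miRNA length ± 4). The default reporting threshold is
5.0 points. Site discovery screens every offset with a vectorised ungapped
scan at threshold + 2 and refines candidates with the gapped DP — exact for
ungapped sites, which covers essentially all biologically reported plant
miRNA sites; a heavily bulged site whose ungapped penalty exceeds the screen
margin would be missed (known limitation).

The slice position is the transcript coordinate paired with miRNA nucleotide
10; if position 10 is bulged or mismatched there is no canonical slice and
the site is dropped with a warning. Peak categories follow the classical
degradome convention, computed over the transcript's positive-count
positions: 0 = site equals a unique maximum; 1 = equals a tied maximum;
2 = below the maximum but above the median; 4 = exactly one read;
3 = otherwise (more than one read, at or below the median). The median is
taken over positions with ≥ 1 read (zeros excluded; switchable
interpretation). Note an edge case implied by these definitions: a profile
with uniform counts > 1 classifies every site as category 1 (everything is a
tied maximum). The p-value is a deterministic exceedance fraction — the share
of positive positions with count ≥ the site count — which is antitone in the
site count and lies in (0, 1]. It is a descriptive rank statistic, not a
calibrated tail probability under a null model.

## Expression (2^−ΔΔCt)

Technical replicates are averaged first; ΔCt = Ct(gene) − Ct(reference)
within each sample and biological replicate. Reference genes follow plant
qPCR practice for this assay family: U6 for mature miRNAs in both tissues,
EF-1α for mRNA targets in roots, 18S rRNA for mRNA targets in leaves (the
mapping is a configurable dict keyed by molecule class × tissue). ΔΔCt is
taken against each gene × tissue × treatment group's own 0 h calibrator
(cross-treatment calibration by flag); RQ = 2^−ΔΔCt and log2FC = −ΔΔCt, with
amplification efficiency fixed at 2.0. Because the condition mean is
differenced against the calibrator mean directly, the calibrator's aggregate
RQ is exactly 1. SE is the standard error of −ΔΔCt over biological
replicates, with the calibrator mean treated as a constant; it therefore
understates total estimation noise by roughly √2 when the calibrator has the
same replication — the parameter-recovery tests use the mean-absolute-error
bound 3·σ_Ct·√(2/n_reps) rather than per-condition SE coverage for this
reason.

Significance letters use Tukey's HSD over per-replicate ΔCt values (all-pairs
Welch t-tests by switch; with only two groups the t-test is used regardless).
The compact letter display assigns one letter per maximal clique of the
"not significantly different" graph (Bron–Kerbosch; group counts are small),
ordered by descending group mean expression, so non-different conditions
always share a letter and different ones never do. Groups with a single
replicate withhold letters with a warning.

## Synthetic data

`SimSpec` defaults mirror the study design the package targets: 4 precursors
with 35-nt stems, 8-nt loops and 21-nt matures; 2 tissues × 3 treatments
(osmotic stress, NO donor, NO scavenger) × 4 timepoints (0/6/12/24 h) with
3 biological × 3 technical replicates and Ct noise σ = 0.1 cycles; degradome
background Poisson(λ = 1) per position on 1-kb transcripts with ~50× spikes
at planted slice positions. Precursors are built as 5' arm + loop + reverse
complement of the arm, with independent per-site mutations that favour
pair-preserving (G:U-forming) substitutions 2:1 so mutated precursors still
fold; the mature is read off the finished precursor, so it is always an exact
substring on a recorded arm. The mature-strand ancestor is the canonical
plant miR166 3p sequence, so simulated families carry the family's
diagnostic conserved positions (9G, 11C, 12U, 16U). Ct tables are generated
as reference Ct ~ N(20, σ) and target Ct = reference level + baseline −
planted log2FC + N(0, σ) per technical measurement.

What the generators do *not* emulate — and hence what passing tests do not
show about real data: sequencing-read noise and mapping artefacts, degradome
overdispersion beyond Poisson (a negative-binomial switch is noted as future
work), miRNA/target sites with bulges, partial hairpins with large internal
loops, amplification-efficiency differences between genes, and biological
replicate-level variance components beyond measurement noise.

## Problem sizes

The test suite runs the full certification batteries (500 random sequences
against the folding oracle, 100 additive matrices, 100 degradome simulations,
100 Ct tables). `scripts/acceptance.py` re-derives the same quantities at
moderately scaled sizes (200 oracle sequences, 50 simulations of each
stochastic stage) — chosen as comfortable single-CPU sizes that leave the
Monte-Carlo rates' precision well below the margins being checked.

## Known limitations

- The energy model's simplifications shift absolute ΔG by roughly 5–15%
  relative to full Turner 2004 implementations; comparisons of package
  energies against published mfold/Vienna numbers should use a tolerance of
  that order.
- The progressive aligner has no iterative refinement; it is intended for
  small, highly similar families, not divergent genome-scale alignments.
- NJ bootstrap resamples columns of the given alignment; alignment
  uncertainty itself is not propagated.
- The degradome p-value is descriptive (exceedance rank), not a calibrated
  p-value; published degradome p-values from other tools are not comparable.
- Tests certify behaviour on synthetic data with planted truth; real
  degradome libraries and qPCR plates violate the generators' independence
  assumptions in ways the limitations above enumerate.
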