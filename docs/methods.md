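# Methods

This note documents the models and procedures `sagqc` implements, the
defaults and why, the numerical choices, and what the synthetic-data tests
do and do not demonstrate about real data.

## Decontamination model

The pipeline treats contamination screening of a single-cell amplified
genome (SAG) as a set of independent, whole-contig decisions. Each filter
is evaluated on every contig (no short-circuiting), and a contig is clean
only if it passes all of them. The three bins — clean, contaminated,
suspicious — partition the input; "suspicious" is a manual-review holding
tier, never a silent deletion.

### Seed-contig GC reference

A naive assembly-wide GC average is biased by the contamination one is
trying to remove. The reference GC is therefore computed on *seed contigs*:

- `n50` mode (default): the descending-length prefix of contigs whose
  cumulative length first reaches ≥ 50% of the assembly. Ties in length are
  broken by contig ID for determinism.
- `marker_contigs` mode: all contigs carrying ≥ 1 single-copy marker gene.
- `group_marker_contigs` mode: marker-bearing contigs pooled across a group
  of same-taxon SAGs, yielding one shared reference applied to each member.

The seed average is length-weighted by default — it then approximates the
genome-wide GC rather than a small-contig-dominated mean — with an
unweighted switch.

### GC window

`gc_window` is a half-width, default 10. Two readings of a "±10% GC range"
are defensible; both are shipped:

- `absolute` (default): pass iff |GC − seed mean| ≤ 10 percentage points.
- `relative`: pass iff GC ∈ seed mean × [0.9, 1.1].

The interval is closed: boundary values pass. GC itself is (G+C)/(A+C+G+T)
with N excluded from both sides; an all-N contig has undefined GC and goes
to the suspicious bin rather than being silently judged.

### Size filter

Defaults: pass at ≥ 2000 bp, discard at ≤ 500 bp, and a suspicious tier in
between — sub-2 kb contigs can still carry informative genes and deserve
review rather than deletion. Both thresholds are configurable with the
invariant `suspicious_floor < min_length`.

### Gene-taxonomy majority filter

Genes vote at domain level (phylum when `target_phylum` is set). A contig
fails when non-target votes / classified votes ≥ `majority_threshold`
(default 0.5, so an exact half fails). Unclassified genes abstain; a contig
with no classified gene passes vacuously and is flagged
`no_taxonomic_evidence`. A threshold of 1.0 is the filter-off limit: the
non-target fraction cannot exceed 1, so nothing fails there. This keeps the
neutral-configuration identity (infinite GC window + threshold 1.0 + floor
size threshold ⇒ clean bin = everything not demoted) exact.

### Duplicate-marker resolution

For each single-copy marker seen on > 1 contig, the retained carrier
maximizes (length, then total gene count, then lexicographically smallest
ID); the other carriers are demoted to suspicious. The two quality criteria
(size, gene content) have no stated priority in general practice; ranking
size first is this package's pinned tie-break and is configurable only by
editing, deliberately — determinism matters more here than flexibility.

### Bin assignment

Failing GC or taxonomy, or falling at/below the discard floor, is hard
evidence: contaminated. Size-suspicious, duplicate-demoted, all-N and
ordination-flagged contigs with no harder evidence: suspicious. Everything
else: clean. Consequences asserted in tests: bins partition the input;
re-running on the clean bin with the same seed mean is idempotent;
tightening any threshold never admits a new clean contig.

## Tetranucleotide ordination

Each contig is summarized by canonical 4-mer counts: the 256 tetramers
collapse into 136 classes by merging each 4-mer with its reverse complement
(the 16 palindromes stand alone), so the feature vector is invariant to the
arbitrary strand of assembly. Windows slide by 1; windows containing N are
skipped; contigs with < 1 valid window are excluded and flagged
`tnf_unavailable`.

The contigs × 136 table is ordinated by simple correspondence analysis:
divide by the grand total, subtract the outer product of the margins, scale
by inverse square-root margins, SVD, and return row principal coordinates
`F = D_r^{-1/2} U Σ`. An unconstrained canonical correspondence analysis is
exactly this CA (one test cross-checks eigenvalues against R vegan's
`cca()` with no constraints). Numerical conventions:

- all-zero columns are dropped (they carry no information and would divide
  by zero);
- an identical-row table has zero inertia and returns zero coordinates with
  a warning instead of failing;
- per-axis sign is fixed by making the largest-magnitude column loading
  positive, so outputs are reproducible;
- at full rank the inter-row Euclidean distances of the principal
  coordinates equal the chi-square distances between table rows, and the
  total inertia equals the table's chi-square statistic over its grand
  total — both asserted to ~1e-9 against direct computation.

Outlier screening replaces visual plot inspection with a quantitative rule:
on the two leading axes, a contig is flagged when its distance from the
reference (provisional clean bin) median exceeds 3.5 in MAD units
(MAD × 1.4826 ≈ a robust standard deviation; 3.5 is the conventional cutoff
for that scale). Axes with zero MAD are skipped. Flags only ever route
contigs to the suspicious tier — the manual-inspection semantics are
preserved.

## Assembly statistics

`average` is total length / contig count rounded half away from zero;
`n50` is the length of the contig at which the descending cumulative length
first reaches ≥ 50% of the total (this prefix is also the `n50` seed set).
The bundled transcription of a published per-SAG summary table is used as
an arithmetic consistency fixture: since the source states no rounding
rule, the check accepts a printed average within 1 bp of the exact
quotient. 29 of its 32 rows satisfy that; the remaining three (AAA259D14,
AAA382A03, AAA833F18) are inconsistent with their own count and total under
any rounding rule and are flagged as source-table inconsistencies, not
reproduced.

## Marker completeness

Completeness = 100 × |markers present| / |marker set|, rounded half-up to
one decimal (matching the published formatting); presence is binary, copy
numbers are reported separately, and hits outside the set are ignored with
a logged count. Marker *detection* (HMM search) is out of scope: the module
consumes a marker-hit table, which real analyses can feed from AMPHORA2- or
BUSCO-style output and synthetic runs feed from ground truth. The bundled
104- and 191-ID universes are synthetic placeholders (the 191 a superset of
the 104, as for the real archaeal sets they stand in for); real set
memberships live in the literature's supplements and should be supplied by
the user.

## Isoelectric points

Charge model: `Z(pH) = Σ_b n_b/(1+10^(pH−pKa_b)) − Σ_a n_a/(1+10^(pKa_a−pH))`
over side chains of C, D, E, H, K, R, Y plus the two termini (each counted
`n_termini` times, default 1, included by default). The default pKa table
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1) follows the EMBOSS convention and ships as an editable data file;
it is a tool convention, not a measured constant set.

Z is strictly decreasing in pH whenever an ionizable group is present, so
the pI bracket found by the pH 0→14 scan (step 0.2) is unique; bisection
then refines until |Z| < 1e-3. The solver returns the full-precision root
(reports format to 2 decimals) because rounding first would break the
|Z(pI)| < 1e-3 invariant for large proteins, whose charge slope at the pI
is steep. Proteins with only one ionization polarity (e.g. poly-K with
termini disabled) have no zero crossing; their pI is undefined and they are
excluded from profiles with a logged reason. There is a closed-form oracle
for the one-acid/one-base case — pI = pKa midpoint, e.g. glycylglycine at
(8.6+3.6)/2 = 6.10 — used as an exact test anchor.

Profiles report median, mean, mode (center of the tallest 0.2-wide
histogram bin over [0,14], ties toward low pH) and the acidic fraction
(pI < 7), since which single summary best captures an acid-shifted
"salt-in" proteome is itself ambiguous.

## Parsimony statistics

Site classes over the non-missing states of a column: constant (≤ 1
distinct), parsimony-informative (≥ 2 states each in ≥ 2 taxa), else
variable-uninformative. Missing/ambiguity symbols (`- ? X N` by default)
are treated as fully missing, the common parsimony-software convention;
in the Fitch pass a missing leaf takes the full set of states observed at
that site. Fitch length folds child state-sets by intersection-else-union
(+1 change per union); polytomies are folded sequentially. The score is
invariant to root placement (asserted by rerooting tests), so arbitrarily
rooted Newick input is fine.

CI = Σm/Σs and RI = (Σg−Σs)/(Σg−Σm), with per-site m = distinct observed
states − 1, g = observed taxa − largest state class, s = Fitch changes;
sites with g = m are excluded from the RI sums (they cannot retain
synapomorphy). CI is undefined (reported missing) when Σs = 0. All of
this is validated against an exhaustive minimal-labeling enumeration on
random ≤ 6-taxon instances — small enough that brute force over all
internal-node labelings is exact.

Published alignment statistics of the study this toolkit accompanies (site
counts, parsimony scores, CI/RI of specific matrices) require the original
alignments, which were never deposited; they are therefore not reproduced
here. The oracle and property tests cover the statistics' correctness
instead.

## Synthetic data: what it emulates and what it does not

`simulate_sag` generates the study conditions the filters assume:

- **Composition.** Order-3 Markov chains (default) whose per-context
  transition probabilities are Dirichlet perturbations (concentration 50)
  around the requested base composition. This gives each class a genuine
  tetranucleotide signature — so the ordination separates classes for
  compositional reasons, not merely GC — while keeping the realized GC
  within ~0.01 of the request. Order-0 (i.i.d. bases) is retained for
  analytic checks.
- **Defaults as conditions.** 60 target contigs at GC 0.45 and 15
  contaminant contigs (20% contamination) at GC 0.60 — a 0.15 offset,
  comfortably outside the ±10-point window; log-normal lengths (median
  5 kb, σ 0.6) rejection-resampled above 500 bp so no mass piles on the
  discard boundary; 1 gene/kb on both classes with target vs contaminant
  domain/phylum labels; round(completeness × 104) markers implanted
  uniformly on target contigs ≥ 600 bp, optional duplicates split across
  two contigs. Identical configs give byte-identical output.
- **Not emulated:** MDA amplification bias and chimera formation, read- and
  assembly-level artifacts, partially contaminated (chimeric) contigs,
  shared composition between related organisms, and annotation error in
  the taxonomy labels. Passing the recovery tests therefore demonstrates
  that the filters implement their definitions and separate classes under
  the stated statistical structure — not that real SAG contamination, which
  can be compositionally subtler, is detected at the same rates.

`simulate_proteome` draws i.i.d. residues from a near-uniform composition
with D+E at 0.11 baseline; `acidic_bias` multiplies the D/E frequencies
before renormalization, giving a monotone, qualitative analogue of the
halophile proteome contrast (real proteomes have correlated, non-i.i.d.
composition). `simulate_matrix` draws sites independently, constant with
probability 1 − p_variable, else a guaranteed non-constant assignment, and
records ground-truth site classes by the same definitions the classifier
uses.

## Problem sizes and reproducibility

The default test and acceptance workloads are sized for a laptop-class
single core: 75-contig assemblies, 500-protein proteomes, 20 random count
tables, 200 brute-forced ≤ 6-taxon parsimony instances. They complete in
well under a minute while exercising every code path; all randomness flows
from explicit integer seeds, and the pipeline writes a manifest with a
config hash so identical configurations are verifiably identical runs
(byte-identical tabular outputs, asserted in tests).

## Known limitations

- Whole-contig decisions only; a chimeric contig is kept or discarded as a
  unit.
- No coverage-based evidence (no read data in scope).
- The ordination flag cutoff (3.5 robust deviations) is a convention; on
  very tight reference clouds it can flag legitimate compositional
  outliers such as rRNA-rich contigs — by design these are only routed to
  review.
- Completeness inherits the marker set's biases; the bundled universes are
  placeholders for testing, not biological marker sets.
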