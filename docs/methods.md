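# Methods

## Exchange matrices and mutability

A variant record is one nonsynonymous change event: ancestral codon →
derived codon at a 1-based residue position, with the set of populations in
which the derived allele occurs. Direction comes from the population
structure: only variants seen in exactly one population are kept, the allele
present in all populations being taken as ancestral. Events are
deduplicated on (protein, position, derived amino acid) — the same inherited
mutation appears in many individuals but is one event. Natural-set records
needing more than one base change are rejected (a single SNP cannot produce
them); disease-set records keep two-base changes flagged, drop three-base
changes (in curated disease data these are almost always errors), and drop
records that also occur in the natural set. All filters are idempotent and
order-free.

Counts of X→Y events form the 20×20 directional matrix. Mutability is
row-sum over the amino acid's *absolute occurrence count* in the proteome,
so the occurrence-weighted mean mutability is identically
total_events / total_residues; this absolute-count convention reproduces the
magnitudes conventionally printed for human data (arginine ≈ 0.031,
proteome mean ≈ 0.01 at ~10⁵ events over ~10⁷ residues). A proportions
denominator is available for sensitivity analysis (`as_proportions=True`).
Aggregate protein mutability is the unweighted mean of per-residue
mutabilities over a sequence.

## CpG classes

Amino acids are classed RED when any codon contains the CG dinucleotide,
else YELLOW when any codon starts with G (a preceding codon ending in C
completes a boundary CpG), else BLUE. The YELLOW rule deliberately follows
the G-initial reading only; codons *ending* in C (whose CpG lies in the next
codon) are not promoted to YELLOW — the classification is about the amino
acid's own codons. The class is display metadata; the simulator computes
actual CpG context base-by-base, including across codon boundaries.

## Statistical contrasts

Each reachable cell (plus any multi-base cell with counts) is tested with a
two-sided Fisher exact test on [[A_xy, A_total−A_xy], [B_xy, B_total−B_xy]]
— the cell against all other events of its dataset. Conditioning on the
source amino acid's row totals is available as an option
(`conditioning="row"`); the totals convention is the default because the
question asked is about each exchange's share of the whole mutation
spectrum. P-values are corrected with the Benjamini–Yekutieli step-up
(factor c(m)=Σ1/i; valid under arbitrary dependence, matching R's
`p.adjust(method="BY")`), implemented via statsmodels and verified in tests
against the hand-executed formula; Fisher p-values are verified against an
exact integer hypergeometric enumeration. Cells are classified at α = 0.01
into MORE_IN_A / MORE_IN_B / NOT_SIGNIFICANT, with single-base-reachable
cells empty in A reported as ABSENT_IN_A regardless of significance (absence
in the larger dataset is informative in itself).

Correlation strength labels follow the conventional bands: |r| > 0.7 strong,
0.4 < |r| ≤ 0.7 moderate, otherwise weak (the 0.3–0.4 band, unnamed in the
convention, is reported as weak). The conservation-shift comparison uses a
two-sided Mann–Whitney U by default — its p-values floor in the
"< 2.2×10⁻¹⁶" style for large shifted samples — with Kolmogorov–Smirnov as
an option.

## Rate matrices

Counts convert to an instantaneous rate matrix in the
Dayhoff-counts-plus-frequencies style: Q_ij ∝ C_ij/π_i off the diagonal
(counts symmetrized first when direction is ignored, which forces detailed
balance), diagonal = −row sum, scaled so −Σ_i π_i Q_ii = 1 (one expected
event per unit time). The formula sits in one helper (`_counts_to_q`) so the
estimator can be swapped wholesale. The same construction applies at 61
sense-codon states; counts on non-adjacent codon pairs are rejected, and
every adjacent pair is labelled creates/destroys/neutral by its effect on
within-codon CpG content for rate summaries.

Published empirical matrices ship in the standard lower-triangular
exchangeability text format (19 rows + frequency line, ARNDCQEGHILKMFPSTWYV
order) and are reconstructed as Q_ij = s_ij π_j, normalized. PCA vectorizes
all off-diagonal rates in fixed row-major order, centers and standardizes
each coordinate (standardization is optional), and fixes component signs by
making the largest-magnitude loading positive, so coordinates are
deterministic. Frequencies do not enter the PCA vector by default.

## The synthetic cohort

The generator defines the study conditions:

* **Proteome** — 2,000 proteins, gamma-distributed lengths (shape 3, mean
  500; ≈10⁶ residues), residues i.i.d. from the bundled human composition
  (published human proteome frequencies scaled to 10.5 M residues), codons
  uniform within each synonymous family. Real coding sequences have codon
  bias and composition autocorrelation; none of that is modelled, so tests
  passing here show correctness of the estimators under the stated model,
  not robustness to codon-usage confounding (a usage table can be supplied).
* **Mutation model** — every single-base, nonsynonymous, non-stop codon
  change is a candidate event with weight 1, ×κ if the base change is a
  transition (κ = 2, the human-typical transition/transversion ratio), and
  additionally ×λ for the CpG deamination channel: C→T with a G following,
  or G→A with a C preceding, contexts evaluated across codon boundaries
  within a protein. λ defaults to 20, the middle of the 10–50× range
  measured for CpG dinucleotides in human DNA. Events are drawn i.i.d. from
  this weight distribution; drawing with replacement followed by the
  pipeline's per-site deduplication mirrors how real recurrent mutations
  collapse to single events. Each event is seen in one of five populations
  (uniform); a 2% contamination fraction is seen in two, exercising the
  single-population filter.
* **Ground truth** — the exact per-amino-acid expected event rate (sum of
  candidate weights from that amino acid over total weight, per residue) is
  recorded, so mutability recovery is testable as a rank correlation, not
  just qualitatively.
* **Annotations** — relative accessibility is a two-component uniform
  mixture giving 73% of sites at or above the 5% exposure cutoff;
  conservation is Beta with mean 0.48 (concentration 5); 15.5% of sites
  carry at least one functional flag. These match the background values
  reported for human structural data and make the contrast statistics
  realistic, but sites are independent — no spatial or domain structure.
* **Disease set** — events re-weighted by exp(2·conservation +
  |Δmass|/100 + 0.5·|Δhydro| + 1·buried), plus 0.8% two-base and 0.03%
  three-base random changes (the rates observed in curated disease data).
  With all β = 0 the set is an unbiased draw from the same event space,
  which the null tests verify.

All randomness flows from one `numpy.random.default_rng` seed per
operation; identical seeds give byte-identical outputs.

## Numerical and design notes

* Exposure boundary: a residue exactly at the cutoff is *exposed* (≥ 5%).
* Physicochemical thresholds are strict inequalities (|Δmass| < 50 Da,
  |Δhydro| < 1); summaries are event-weighted, matching "% of mutations".
  Masses are free-amino-acid molecular weights; Ile/Leu are the only pair
  with equal mass, and zero deltas count as non-increase.
* Mutability uses absolute occurrence counts (see above); occurrence tables
  are an explicit input because any given proteome snapshot is
  irreproducible — the bundled table is a human-like default.
* Empirical-matrix frequencies are renormalized when they sum to within 1%
  of 1 and rejected otherwise.
* Problem sizes in tests and the acceptance script (10⁶-residue proteome,
  10⁵ events, 20 replicates; 10⁴-per-set disease contrast) are chosen as the
  smallest scales at which the recovery statistics are stable.

## Limitations

* The generator has no linkage, demography, selection coefficients or
  allele frequencies; the "populations" are labels, not genetic structure.
* Site annotations are independent of the sequence, so structure-mutation
  interactions (e.g. buried residues being more hydrophobic) are absent.
* The codon-level rate analysis conditions on the proteome's codon
  frequencies; with uniform within-family codon usage these differ from
  human usage, shifting absolute codon rates but not the CpG ordering.
* DCFreq here is the direct count/frequency estimator; no correction for
  multiple hits or time calibration is attempted (appropriate for
  short-timescale, direction-resolved counts).
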