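# Methods

This note documents the models, defaults and design decisions behind
axoprot, in the order the pipeline runs them.

## Physical chemistry

Peptide and protein masses are residue-mass sums: neutral mass =
Σ residue masses + one water + fixed-modification deltas; an ion of charge
z has m/z = (neutral + z·proton)/z, so the MALDI default (monoisotopic,
z = 1) yields [M+H]⁺. The residue table ships as a plain-text data file
(standard monoisotopic and average values for the 20 proteinogenic
residues) and can be replaced via a file path; this pins the constants
every downstream number depends on. Nonstandard codes (B, Z, X, U, O) are
rejected with the offending position rather than silently averaged — a
wrong mass guess corrupts PMF matching invisibly. No fixed modification is
applied by default; carbamidomethyl-Cys (+57.02146 Da) is available as a
switch because alkylation is a sample-preparation fact, not an assumption
the calculator should make.

Isoelectric points use the Henderson–Hasselbalch net-charge model
Q(pH) = Σ sign·(1 + 10^(sign·(pH − pKa)))⁻¹ over both termini and the
D, E, C, Y (−) and H, K, R (+) side chains, with the Bjellqvist pKa set
(the de facto standard for 2DE pI prediction; also a replaceable data
file). Q is strictly decreasing, so the root is unique; it is found by
bisection on [0, 14] to a bracket width of 1e-3 pH, refined further until
|Q| < 1e-2 because very long chains have steep Q near the root.

## Digestion

Trypsin is the only shipped rule: cleave C-terminal to K or R, blocked
when the next residue is proline (the classic Keil convention, the
community default; the proline exception can be switched off). Chain
termini are not cleavage sites, so terminal peptides count only retained
*internal* sites toward their missed-cleavage number. Coordinates are
0-based half-open everywhere, and the zero-missed peptide set tiles the
parent exactly — both are asserted as properties. Defaults: ≤ 1 missed
cleavage (standard MALDI-PMF practice) and a 700–4000 Da theoretical-peak
window (a typical MALDI acquisition range).

## PMF identification

Matching is one-to-one and greedy: all (peak, theoretical mass) pairs
within tolerance are consumed in ascending |Δmass|, ties broken by lower
theoretical mass then lower observed m/z, which makes the matching
deterministic and order-independent. "Within tolerance" is evaluated at
the theoretical mass (relevant for ppm units). The default tolerance is
100 ppm, a declared assumption appropriate for an externally calibrated
MALDI-TOF.

The score is a binomial chance-match model rather than a Mowse-style
frequency table: transparent, testable against direct tail summation, and
sufficient for ranking. The per-peak chance probability is
q = min(1, 2·tol_Da·T/W) where T is the candidate's theoretical peak count
and W the search window — the observed m/z span with a 1000 Da floor to
avoid degenerate q on narrow spectra; a ppm tolerance is converted to Da
at the centre of the observed span. The tail P(X ≥ k) is summed in log
space (gammaln + logsumexp), so scores of several hundred remain exact.
Acceptance thresholds (score ≥ 4 and ≥ 4 matched peaks) are common PMF
practice, configurable, and echoed in every CLI run header. Replicate
consensus accepts a protein identified in ≥ 2 of the repeated runs
(min_hits = 2 of ≥ 2 replicates), mirroring the repeated-analysis rule of
the reference workflow.

Isoform discrimination: a diagnostic mass is a digest mass with no
in-tolerance counterpart in any competing isoform's digest. Assignment is
deliberately conservative — the called isoform must have ≥ 1 diagnostic
hit while every competitor has exactly zero — matching a
mutually-exclusive-usage hypothesis without inventing a likelihood ratio.
Anything else returns "ambiguous".

## Spot quantification

ppm normalization divides each raw spot quantity by the gel total
(× 10⁶), so every gel sums to 1e6 exactly. Cross-gel matching replaces
interactive gel software with a pinned rule: candidate links between spots
of different gels are proposed out to twice the tolerance pairwise
(because two spots both within tolerance of a shared centroid can be up to
2× apart), processed in ascending normalized distance
d = max(|ΔpI|/pi_tol, |Δlog₁₀MW|/logmw_tol), and a merge is accepted only
if no gel contributes two members and every member lies strictly within
tolerance of the merged centroid. Tie-breaks use position then gel and
spot ids, so SSP labels are invariant to input file order (tested by
permutation). Defaults pi_tol = 0.2 pH, logmw_tol = 0.04 reflect the
reproducibility of well-run replicate gels.

Replicate averaging applies the same "at least twice" logic to detection:
a spot seen in < 2 of a tissue's 3 gels is treated as absent (quantity 0)
for that tissue; means are taken over the replicates where it was
detected, and quantities are never imputed. Mass normalization divides
ppm by molecular mass in kDa — the interpretation of "normalized by
molecular mass" adopted here — isolated in one function so it can be
swapped; it cannot change any within-protein tissue ratio, and raw ppm is
always retained alongside. The divisor should be the theoretical MW of the
identified sequence, falling back to apparent gel MW.

## Differential classification

f/c = q_flagella / q_cilia at full precision; reports round half-even to
two decimals. Exclusive detection prints the dash sentinel, never
infinity. Predominance uses the strict inequality (> 5-fold, not ≥),
so a ratio of exactly 5 is shared; the boundary is tested. Printed
published ratios are reproduced within ±0.02 because the printed input
quantities are themselves rounded. The three predominance groups are:
exclusive (one tissue only, no isoform partner), isoform-differential
(exclusive, with the partner isoform detected in the other tissue), and
enriched (detected in both). An optional minimum-quantity filter exists
(default off) for the acknowledged fuzziness of calls on very-low-content
proteins; no specific cutoff is assumed.

## Synthetic data

The generator emulates: random proteomes (60 proteins, lengths 200–450)
with isoform pairs differing by a few substitutions, placed so that
diagnostic in-window tryptic masses exist on both sides (verified at
generation; substitutions never swap I↔L, which are isobaric); per-tissue
abundances lognormal (median 5000 ppm, log-sd 1.2) renormalized to 1e6 per
tissue, with a class mix echoing real comparative tables (≈55% shared,
exclusive rows outnumbering finite-ratio enriched rows, flagella side
larger); triplicate gels with Gaussian pI jitter (σ 0.05 pH), lognormal MW
jitter (σ 0.01 log₁₀ units), multiplicative lognormal quantity noise
(σ 0.2 — densitometry noise is multiplicative), and dropout of spots whose
noisy quantity falls below 100 ppm; spectra with 70% peptide detection,
25 ppm mass error and 5 uniform contaminant peaks. The true class is
computed from the *final* normalized abundances, so truth and generated
data cannot disagree by construction.

Deliberately not emulated: gel-image artifacts (streaking, co-migration
trains, saturation), PTM-shifted spot series, correlated replicate biases,
intensity-dependent mass accuracy, and real sequence composition
(homology, low-complexity regions). Passing recovery tests therefore shows
the pipeline's statistical logic is sound under the stated noise model,
not that real gels of arbitrary quality will reach the same rates.

Determinism: every generator output is a pure function of parameters and
seed; the global seed fans out through fixed per-component seed streams
(proteome 0, gels 1, spectra 2), so components are independently
reproducible and identical seeds give byte-identical FASTA output.

## Problem sizes and acceptance experiments

The test suite runs the published-table worked examples (69 quantity
pairs), property batteries (digestion vs a brute-force cleavage oracle on
1000 random sequences; classification reciprocity/partition on 10 000
random pairs; binomial scores vs direct tail sums at 1e-9 relative), and
stochastic recovery experiments sized to run in seconds on one CPU: a
noiseless end-to-end run must reproduce every true class; 20 seeded noisy
runs must recover ≥ 90% of classes for proteins with true ratio outside
[1/8, 8]; 200 simulated spectra against a 100-protein proteome must put
the true protein at rank 1 in ≥ 95%; and ≥ 95% of isoform-pair spectra
containing a diagnostic peak must be assigned correctly. The cross-gel
matcher must recover ≥ 95% of true spot correspondences at positional
jitter of half the matching tolerance (50 seeds).

## Known limitations

- Only trypsin ships; the rule table is extensible but untested for other
  enzymes.
- No MS/MS, no intensity weighting, no target-decoy FDR — the score is a
  ranking device, not a calibrated error rate.
- The binomial model treats peaks as independent; dense spectra of very
  large proteins mildly inflate scores.
- Spot matching assumes positions are comparable across gels (i.e. gels
  are run and calibrated identically); it has no warping model.
- pI prediction ignores conformation, modification and neighbour effects;
  on real 2DE gels observed pI can deviate by several tenths of a pH unit.
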