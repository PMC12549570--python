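# Methods

## Problem setting

An affinity-enrichment RF experiment yields, per LC-MS feature, an m/z,
charge, retention time, optional MS/MS-derived sequence, and a vector of
per-sample normalizable abundances across five serology-defined groups
(RF+/CCP+ RA, RF−/CCP+ RA, RF−/CCP− RA, RF− disease controls, RF+ disease
controls; 27/5/22/28/4 samples in the main design). The analysis answers
three questions: which peptides are differentially abundant between RA and
controls, which of those are immunoglobulin variable-region peptides that
discriminate the groups, and how much of each heavy-chain isotype the
enriched RF carries.

## Identification merging

Two engines contribute sequences: a database search with a Mascot-like
score, and de novo sequencing with an ALC% confidence (mean per-residue
confidence). Rules, applied per feature:

1. De novo records are kept only with ALC% strictly above 80 and a sequence
   of ≥ 3 residues.
2. Features whose database hit is Ig-related with score ≥ 30 are removed
   from the de novo candidate pool (their sequence is settled).
3. The database sequence wins at score ≥ 30; otherwise the best surviving de
   novo sequence (highest ALC, then longest, then lexicographic); a sub-30
   database hit with no de novo alternative is retained but flagged
   low-confidence rather than dropped, so it can still be aligned to
   germline databases downstream.

De novo sequences report isoleucine as leucine (the residues are isobaric),
so all comparisons involving de novo sequences collapse I/L by default;
database-derived sequences are compared verbatim.

## Region annotation

Constant-region matching is exact substring search in the heavy-chain
constant references. A peptide unique to one isotype group (IgA1, IgA2,
IgG1–4, IgM; near-identical duplicate accessions such as P01857/P0DOX5
collapse into one group) enters protein-level quantification; shared
peptides contribute nowhere. Constant matches take precedence: a
constant-region peptide is never scored against V genes.

Variable-region assignment aligns the peptide locally against every
germline V/J gene (Smith–Waterman, BLOSUM62, affine gap cost 11 + g — the
conventional protein-BLAST parameterization) and converts aligned germline
residues to IMGT unique-numbering positions. Significance uses the
Karlin–Altschul expectation E = K·m·n·e^(−λS) with the gapped BLOSUM62
parameters λ = 0.267, K = 0.041, m the peptide length and n the total V/J
database residue count. The best gene (ties: alphabetical) is accepted when
E ≤ 1 and S > 30; the assignment is CDR-labelled only when ≥ 3 aligned
residues fall inside a CDR span, FR+CDR when the span crosses a boundary.
Both the looser E-only verdict and the full verdict are recorded per
peptide. Fixed IMGT region coordinates: FR1 1–26, CDR1 27–38, FR2 39–55,
CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128.

The Smith–Waterman engine is Biopython's `PairwiseAligner` (local mode);
deterministic tie-breaking over co-optimal tracebacks prefers fewer gaps,
then the earliest germline start, then the earliest peptide start. The test
suite checks exact score equality against an independent hand-written Gotoh
dynamic program on hundreds of random peptide/germline pairs.

### Germline fixtures

The packaged reference sets are synthetic curated stand-ins, shipped as
`*_synthetic.fasta`: fifteen germline-like V genes across heavy/kappa/lambda
(IMGT-gapped, so per-residue IMGT positions are recoverable by stripping
gaps), the six heavy J genes (anchored so FR4 ends at position 128), and
nine constant-region entries in seven isotype groups built from seeded-RNG
sequences with a controlled block structure: a 60-residue block shared by
the four IgG subclasses, a 50-residue block shared by IgA1/IgA2, and
two-substitution duplicate pairs (P01857/P0DOX5, P01871/P0DOX6). This
structure deliberately produces both unique and shared digest peptides, so
uniqueness logic is exercised. Real IMGT/UniProt directories in the same
FASTA dialect load by path.

## Normalization and differential testing

Normalization follows the median-reference / MAD-filtered log-ratio scheme
of label-free quantification suites: the reference sample is the one whose
total detected abundance is closest to the across-sample median; per sample,
log-ratios to the reference over co-detected features are filtered to within
3 MAD of their median and the scaling factor is exp(mean retained
log-ratio). A uniform k-fold dilution of a sample is recovered exactly; 5%
contamination with 100× spikes moves the factor by < 2% (tested).

Missing abundances remain missing throughout — excluded from rank tests and
group means, never imputed as zero — because label-free missingness is
abundance-dependent (left-censored), and zero-imputation would bias low
groups downward.

Per peptide: Kruskal–Wallis (tie-corrected, χ² reference) across all groups;
Dunn's post-hoc z for the declared contrast (default RF+/CCP+ RA vs RF−
control) with tie correction Σ(t³−t)/(12(N−1)); Holm–Šídák step-down
adjustment across all peptides of the contrast (the adjustment family is the
peptide level; within-peptide pairwise multiplicity is not additionally
corrected). Fold change is the ratio of group means of normalized
abundances; a zero denominator is replaced by the smallest positive
abundance in the matrix (flagged). Calls: *up* = adj p < 0.05 ∧ FC > 5,
*down* = adj p < 0.05 ∧ FC < 0.2; volcano coordinates are log2 FC and
−log10 adj p with p floored at the smallest positive float.

Kruskal–Wallis and Holm–Šídák are computed via scipy/statsmodels; Dunn's
test is implemented directly (no installed package provides it). All three
are verified against closed-form textbook arithmetic in the tests.

## Sparse PLS-DA

X is samples × peptides (normalized abundances, per-peptide mean-imputed
for this analysis only, centred and unit-scaled); Y is the centred one-hot
group indicator. Per component: the dominant left singular vector of XᵀY is
soft-thresholded so exactly keepX variables keep non-zero weight
(threshold = the (keepX+1)-th largest |w|), renormalized; scores t = Xw;
both blocks are deflated by regression on t. Prediction uses
B = W(PᵀW)⁻¹Cᵀ and the maximum-distance rule (largest predicted indicator
wins; ties to the first class in sorted order). The sign convention (largest
loading positive) makes fits deterministic. With keepX = p the first
component equals the dense PLS-DA component (tested).

Model selection mirrors the three-step protocol: per-component keepX is
tuned sequentially over {1, 2, 3, 5, 10, 20, 50} by stratified 3-fold ×
50-repeat CV minimizing the balanced error rate under maximum distance, then
the depth H ∈ [2, 5] with minimal BER is chosen (parsimony tie-breaks:
smaller keepX, smaller H). Occurrence is the fraction of CV *repeats* in
which a peptide is selected by any fold's model (counting each fold×repeat
model instead is available by configuration; the repeat-level default makes
occurrence = 1 attainable and matches "present in more than half of the
repeats"). One seeded generator drives all fold assignments, so identical
seeds give identical tuning, occurrence and BER.

Discriminative peptides are the conjunction: adj p < 0.05 ∧ FC > 5 ∧
occurrence > 0.5 ∧ variable-region annotation ∧ the disease-control group
attains the minimum of the per-group median Z-scores.

## Isotype quantification and positivity

Per sample × isotype, abundance is the sum of normalized abundances of the
unique constant-region peptides of that group (missing values skipped; an
isotype with no detected peptide in a sample stays missing). Group
comparisons reuse the Kruskal–Wallis/Dunn machinery at the protein level and
are reported unadjusted (the Holm–Šídák family is defined at the peptide
level). Positivity: the cut-off per isotype is the maximum abundance among
reference-group samples and a sample is positive only when strictly above
it — so the reference group is negative against its own cut-off by
construction, and positivity is invariant under any uniform monotone
rescaling of all samples.

## Cross-experiment feature matching

Unidentified MS/MS-bearing features are matched one-to-one between two
experiments when |Δm/z| < 0.01 Th, |ΔRT| < 1 min, equal charge, and (by
default, configurable) MS/MS present in both. Collisions resolve greedily by
smallest |Δm/z|, then |ΔRT|, then the unordered id pair; this greedy
procedure provably yields the lexicographically minimal maximal matching, is
symmetric under exchanging the sets, and is verified against an exhaustive
enumeration oracle on a thousand random instances. No RT alignment is
attempted — the fixed ±1 min window assumes comparable chromatography.

## Synthetic cohort generator

The generator defines the study conditions and is the substrate of every
end-to-end check. Defaults: group sizes 27/5/22/28/4; 120 background
peptides (random sequences absent from the constant references); 80
Ig-derived peptides sampled from the Lys-C + chymotrypsin digest (cleavage
C-terminal to K including K-P, and to F/Y/W/L except before proline; ≤ 1
missed cleavage, length 5–30) of the packaged references, split evenly
between constant- and variable-region origins; 10 CDR-variant peptides
(1–3 point substitutions inside CDR spans of CDR-overlapping V peptides, so
they genuinely fall outside the database and are only reachable de novo,
reported with I→L); fold change 8; noise CV 0.3 (log-normal); per-sample
scale factors uniform on 0.5–2×; values below the 20th abundance percentile
censored to missing with probability 0.25; 30% of non-designated features
unsequenced.

Effect layout: 20 designated variable-region peptides carry the fold change
in the RF(+) groups; 6 of the non-discriminative ones also in RF−/CCP− RA; 8
"discriminative-truth" peptides carry it in every group except the RF−
disease-control reference (so the control group genuinely has the lowest
median Z); all constant-region peptides are elevated per isotype in the
RF(+) groups. Designated peptides are drawn from V-derived peptides of ≥ 8
residues — shorter peptides cannot carry variable-region alignment evidence
under the S > 30 criterion — and discriminative truth additionally from the
unmutated (database-identifiable) pool, because a CDR variant's
identifiability depends on its stochastic ALC draw. Designated peptides are
exempt from the unsequenced fraction and drawn from the upper base-intensity
range so censoring does not erase them; identification scores are
Normal(55, 18) clipped to [5, 150] for database records and Uniform(75, 99)
ALC for de novo records, giving realistic sub-threshold tails.

What the generator does *not* emulate: spectra and chromatographic peak
shapes, retention-time drift between experiments (the replicate generator
jitters within half the matching windows instead), engine-specific score
distributions beyond a monotone score/correctness relation, shared-peptide
abundance ambiguity, and biological covariance between peptides of one
protein (peptides are independent given their effects). Passing end-to-end
tests therefore demonstrate that the analysis recovers effects under its own
statistical assumptions — not performance on real data, where missingness,
RT drift and identification error are less well behaved.

## Numerical and design choices

- Alignment parameters (BLOSUM62, 11 + g, λ = 0.267, K = 0.041) are the
  conventional defaults of protein-BLAST-family tools; they are declared
  constants, not fitted.
- Acceptance for variable-region status is E ≤ 1 ∧ S > 30, with the
  E-only (FR/CDR1-2 style) verdict logged alongside for inspection.
- Equal-scoring germline ties resolve alphabetically; equal-|w| ties in
  soft-thresholding resolve by the strict-inequality rule (entries equal to
  the threshold drop out, a measure-zero event for continuous data).
- Dunn z uses the normal reference; p-values are two-sided.
- Group sizes as small as the 4-sample RF+ control group are handled by the
  stratified-fold fallback (a class with fewer members than folds spreads
  across the first folds, logged).
- Problem sizes in the tests and the acceptance script (20 cohort replicates
  for differential recovery, 10 for the discriminative pipeline, 16 noise
  datasets for the chance-level check, 1,000 matching instances) were chosen
  to keep Monte-Carlo error comfortably below the decision margins while
  running in tens of seconds on one core.

## Known limitations

- The E-value calibration assumes the Karlin–Altschul regime, which is
  approximate for very short peptides (< 7 residues); such peptides rarely
  clear S > 30 anyway.
- The sPLS-DA keepX grid is coarse by design; BER differences below
  Monte-Carlo resolution resolve by parsimony rather than by significance
  testing.
- Constant-region quantification ignores shared peptides entirely rather
  than apportioning them, so summed abundances are a lower bound per
  isotype.
- D-segment assignment is out of scope: peptide-level evidence is too short
  for D genes, and the analysis reports FR/CDR allocation only.
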