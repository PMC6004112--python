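# Methods

This note records the models implemented in `hsta`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
validation does and does not demonstrate.

## Reference preparation: protein-guided back-alignment

coxI is a protein-coding mitochondrial gene, so reference sets are aligned
at the amino-acid level and the nucleotides are threaded back through the
protein alignment ("back-alignment"): each residue column expands to its
source codon, each protein gap to `---`.  The resulting nucleotide MSA has
gaps only in whole codons and columns that respect the reading frame.
Invariants enforced and tested: ungapping any row reproduces the input
sequence byte-for-byte, and the nucleotide alignment length is exactly
three times the protein alignment length.

* **Genetic code.**  Default invertebrate mitochondrial (NCBI table 5),
  since the locus is mitochondrial and the reference organisms are
  invertebrates; the standard code is selectable.  Under the mito code
  `TGA` is tryptophan and `AGA/AGG` are serine, so code choice changes
  which frames appear stop-free.
* **Reading frame.**  When unknown, the frame with the fewest internal
  stops is chosen (ties to the longest translation, then the lowest
  frame).  Frameshifted references are out of scope.
* **Internal stops** translate to `X` with a warning rather than a
  rejection: public reference sets contain pseudogene-like entries, and a
  single bad codon should not discard an otherwise useful reference.
* **Protein MSA.**  A protein alignment is normally an *input*.  For
  self-contained operation the package ships a small progressive aligner
  (pairwise Needleman–Wunsch, BLOSUM62, linear gap cost −6, UPGMA guide
  tree on 3-mer distances, profile-profile merging with average-of-pairs
  column scores).  It is adequate for the closely related coding sequences
  handled here and keeps tests free of external binaries; it is not a
  general-purpose MSA tool.

Coordinates are 1-based inclusive alignment columns throughout.

## The profile HMM

Per-taxon nucleotide profiles use a Plan-7-style architecture: match
states with position-specific emissions over {A,C,G,T}, insert states
emitting background, delete states, and local fragment entry/exit.

**Estimation.**  Match columns are those with gap fraction strictly below
0.5 (a column at exactly 0.5 is an insert column — the tie rule is pinned
by a test).  Emissions are `(count + 1) / (total + 4)` (Laplace
pseudocount 1.0, configurable); `N` is excluded from counts and emits with
background probability (log-odds 0) in queries.  Transitions are counted
from each row's match/insert/delete path with a pseudocount on every
structurally allowed transition.  The background is uniform 0.25 by
default.  These concrete defaults stand in for an upstream tool's
unstated "default parameters".

**Local model.**  Entry into match state `k` (0-based, `M` states) has
probability `2(M-k) / (M(M+1))` and exit from state `k` probability
`1/(M-k)`.  Together these make the alignment fragment `[k, l]` *exactly*
uniform over the `M(M+1)/2` possible fragments — a closed-form version of
uniform local entry/exit.  Because local alignments begin and end on match
states, the last delete state is unreachable and its incoming transitions
are structurally zero.  Flanking residues are emitted by begin/end loop
states whose self-loop probability equals the geometric null model's
(`tau = L/(L+1)`), so flank emissions cancel in the odds ratio.

**Scoring.**  `forward_bits` is the full forward path sum in log space,
reported as log2 odds (bits).  The recursion is vectorized over states;
the delete chain at a fixed position is solved in one pass by factoring
out the delete-delete logs and using a prefix log-sum-exp.  The same
machinery with `max` gives `viterbi_bits` and the traceback used to place
reads into reference-alignment coordinates.  There is no filter pipeline:
with tens of profiles, exact forward is affordable (an `L x 3M` dynamic
program per read-profile pair).

The exact semantics are pinned by a brute-force oracle in the test suite
that enumerates *every* local alignment path of small profiles in plain
probability space; the DP must agree to 1e-9 bits.

**A property of forward scores worth knowing.**  Concatenating background
flanks to a query leaves the best *path* essentially unchanged (Viterbi
scores move by well under a bit), but the *forward* score inflates by
roughly the log of the flank length: each flank-absorbing extension step
has expected odds ratio exactly 1 under background, so the extra path mass
forms a near-geometric series no matter how sharp the profile is.  This is
inherent to path-sum local scores, not an implementation artifact.  It is
harmless for classification because the decision statistic is a score
*difference* between profiles, which moves by only a small fraction of its
value (both behaviors are under test).

**E-values.**  Each profile is calibrated by scoring `n` shuffles of its
consensus (default 200, minimum 100 for a stable fit) and fitting a Gumbel
by maximum likelihood; `E(s) = n_targets * (1 - F_Gumbel(s))`, evaluated
via `expm1` so the tail stays positive and strictly monotone.  The
calibration seed is recorded in the profile JSON, making scans exactly
reproducible.

## The classifier

Hits below the E-value gate are discarded; a query whose best hit fails
the gate is **Unclassified**.  Among significant hits the log Bayes Factor
is `S_1 - logsumexp(S_2..S_n)` (overflow-safe).  `ln(BF) > 3.0` makes the
assignment **Good** (taxon = best profile); otherwise **Ambiguous**.  The
three categories partition every query set, a property under test.

Decisions that were genuinely open:

* The Bayes Factor is applied to bit scores *literally* (natural
  log-sum-exp of base-2 scores).  That is faithful to the rule as usually
  stated; the strictly Bayesian variant (convert bits to nats first) is a
  flag (`scale="nats"`).  With the default threshold the two differ only
  for margins within a factor ~1.44 of it.
* Only hits passing the E-value gate enter the competitor sum.  Including
  every profile would let noise-level scores drag clear winners into
  Ambiguous; with log-sum-exp the effect is tiny but the gated version is
  cleaner.
* The E-value gate defaults to 10.0 (the conventional per-hit reporting
  default); a stricter 0.01 inclusion-style preset is exposed.  On
  calibrated profiles, true coxI reads score hundreds of bits and either
  gate passes them; the gate matters only for junk reads.
* Best-hit ties break lexicographically by profile name; an exact tie has
  `ln(BF) = 0`, so the category (Ambiguous) never depends on the
  tie-break.
* Order-rank and species-rank profile collections are scanned
  independently, one assignment per rank, since a mixed collection would
  let a taxon's order profile compete against its own species profiles.

For reference-set curation from tabular homology hits, the package keeps
only hits sharing the best hit's taxonomic order per query (rows without
an order label are dropped with a warning; a query whose *best* hit is
unlabeled is dropped entirely).

## GC-content / diversity diagnostic

Per alignment column, read diversity and reference diversity are the
exponential Shannon entropy of the A/C/G/T frequencies (Hill number of
order 1): 1 for a monomorphic column, 4 for a uniform one.  Gaps and `N`
are excluded; all-gap columns are dropped from the model.  `GCref` is the
per-column G+C fraction among non-gap reference residues, averaged over a
centered 100-column window (truncated at the edges), in percent.  Reads
enter in reference coordinates — either aligned externally or placed by
the profile's Viterbi path (`place_in_alignment`).

Two regions are analyzed separately, matching the two strand-specific
read sets of a two-direction amplicon run: 5' = columns 1–400 and
3' = column 200 to the end (inclusive; a shorter alignment truncates with
a warning).

The model `Dreads ~ Dref + GCref` is fit by OLS (statsmodels) with a
sequential (Type I) ANOVA; F per term is its mean square over the
residual mean square, and explained variance is its share of the total
sum of squares.  Order dependence is reported, never hidden: both term
orders are available, swapping them changes term sums of squares but not
the residual (under test, including a cross-check against R's `anova(lm)`).

One subtlety matters for inference.  With `GCref` fitted *first* (the
order used for display tables), its sequential F is a *marginal* test: in
a finite sample `GCref` is never exactly orthogonal to `Dref`, so part of
the (large) biological signal leaks into `GCref`'s sequential sum of
squares and the test rejects far more than 5% under a true GC-null.  The
calibrated null test for "is there a GC effect beyond biology?" is
`GCref` conditioned on `Dref` (term order `Dref, GCref`).  The test suite
verifies the conditional test's type-I error is 5% ± 2% over 1000 null
replicates, and the null/power simulations use the conditional form.

A published decomposition of this kind contains one internal
inconsistency worth flagging: in the 3' block the three explained-variance
percentages do not sum to 100 (the residual share implied by the printed
sums of squares is 60.6%, not the printed 66.17% which belongs to the 5'
block).  The package reproduces the 5' percentages and the 3' F-values,
and recomputes 3' percentages from the sums of squares.

## Community evaluation

`detection_ratio` is the fraction of expected taxa with any Good-assigned
reads; `biomass_correlation` is Pearson's r between per-taxon counts and
biomass, computed only when at least two expected taxa were detected
(undefined otherwise, reported as missing); counts are raw, not relative.
`pair_ratio_report` gives a chosen species pair's count ratio per strand
and the arithmetic mean of the two — the statistic used to compare read
yield against biomass and qPCR ratios when assessing amplification bias.
The packaged expected-community fixture (`hsta/data/mpe5_community.tsv`)
describes a pitfall-trap litter community: 11 order/class-level taxa and
the 7 carabid beetle species with per-organism biomass.

## The synthetic community generator

The generator produces data with the statistical structure the validation
needs, not a sequence-realistic coxI simulator:

* **References.**  A random stop-free ancestor of 219 codons (657 nt, the
  classic barcode fragment length), then star trees: orders at 0.30
  expected substitutions/site from the ancestor, species at 0.05 from
  their order ancestor, and 3 individuals per species at 0.005 —
  divergence tiers typical of ordinal, congeneric and conspecific coxI
  variation.  Substitution rates are codon-position weighted (3rd position
  4x the 1st, 1st 2x the 2nd), and any codon mutated into a stop is
  redrawn, so references stay translatable.  Star trees are deliberate:
  they control divergence tiers directly without pretending to be a
  realistic phylogeny.
* **Reads.**  Per-taxon counts are multinomial with weights
  `biomass x bias_multiplier` (bias only, when the biomass-equalized
  design is selected — the equalized/natural pair of designs is a single
  boolean).  Each read is a uniform-start fragment of 250 nt with
  substitutions at `0.004 + 0.01 x (100-bp window GC fraction)` and a 1%
  per-homopolymer (length >= 3) single-base over/under-call rate — the
  signature pyrosequencing failure mode at study-era error magnitudes.
* **Truth.**  Read ids map one-to-one to a truth table (order, species,
  source reference, fragment start), which is the oracle for all
  end-to-end accuracy tests.

What passing these tests shows — and does not.  The simulator produces
equal-length, indel-free (except read errors) references, so profile
match states map 1:1 to alignment columns; real reference sets have
length variation and require the back-alignment stage the package also
tests separately.  Star-tree references make taxa compact and
well-separated; real orders are paraphyletic clouds with uneven sampling,
so the >=99% species-rank accuracy measured here is an upper bound, not a
field estimate.  Chimeras, primer artifacts and flowgram-level noise are
explicitly out of scope.

## Problem sizes and numerical choices

Test and acceptance runs use a 3-order / 7-species community with 150-codon
references, 100–250 reads, and 100-shuffle calibrations — sizes chosen so
the full validation, including a 1000-replicate type-I calibration of the
GC test, completes in a few minutes while keeping every statistical check
well-powered.  All randomness flows through explicit integer seeds;
`scripts/acceptance.py` derives every sub-seed from its single `--seed`.

Log-space arithmetic uses `logsumexp`-style max-factoring throughout;
transition pseudocounts must be positive so every allowed transition stays
reachable (enforced); E-value tails use `expm1`; ANOVA percentage
identities hold to 0.05 and sums of squares to 1e-6 relative.

## Known limitations

* Forward scores inflate logarithmically with background flank length
  (see above); single-number score thresholds should therefore be applied
  to reads of comparable length, as the classifier's E-value gate is.
* The Gumbel calibration shuffles the consensus, preserving composition
  but not higher-order structure; E-values are reproducible and monotone
  but approximate.
* The progressive aligner has no iterative refinement; for distant or
  length-heterogeneous reference sets an external protein MSA should be
  supplied.
* `hmm` profiles are JSON, not HMMER's `.hmm` format; interoperability
  with HMMER tooling is a non-goal.
* The GC diagnostic regresses diversity on smoothed GC; it identifies
  association, not mechanism, and does not correct reads.
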