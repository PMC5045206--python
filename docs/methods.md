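# Methods

## Model and procedure

The analysis takes a gapped multiple alignment of TF DNA-binding domains, a
fixed-width (or gapped) alignment of their binding sites, and a many-to-many
pairing table. After deduplicating identical (protein row, site row) string
pairs, the pipeline runs:

1. **Sequence weighting.** Identity distances (pairwise gap deletion: only
   columns ungapped in both rows are compared; rows with no comparable
   columns get distance 1) feed Saitou–Nei neighbor joining. Negative branch
   estimates are clamped to 0 and Q-criterion ties are broken by the lowest
   index pair, so trees are bit-reproducible for a given input order. The
   tree is rooted at the exact midpoint of the longest leaf–leaf path (ties:
   lexicographically smaller leaf pair) and Gerstein–Sonnhammer–Chothia
   weights are computed leaf-up: each leaf starts with its own branch
   length, each internal edge is divided among descendant leaves in
   proportion to their current weights (equal split when all are zero), and
   weights are normalized to sum to the leaf count so the weighted total N
   stays commensurate with the number of sequences — keeping the κN
   pseudocount mass on the scale of the data. Sites are weighted by the same
   chain by default (`--site-weights uniform` disables); pair weight is the
   product.
2. **Weighted counts and frequencies.** For each column pair, records gapped
   at either column are treated as missing (gaps are not a 21st symbol — the
   substitution model has no gap state). Pseudocounted frequencies follow

       f_i(a)    = [N_i(a)    + κ·Σ_b N_i(b) P(b→a)]       / (N(1+κ))
       f_ij(a,n) = [N_ij(a,n) + (κ/4)·Σ_b P(b→a) N_i(b)]   / (N(1+κ))

   the unique reading of the pseudocount algebra under which all
   distributions normalize to 1 and the joint marginalizes exactly to the
   positional frequencies. The nucleotide side always receives the uniform
   1/4 pseudocount; consequently an identity substitution matrix cancels the
   pseudocounts in the protein marginal only, not in the joint.
3. **Substitution model.** P(b→a) = q(a,b)/p(b) from a BLOSUM matrix.
   Biopython ships the matrices as rounded log-odds scores
   s = scale·log₂(q/(p·p)); the backgrounds are recovered by solving the
   linear system odds·p = 1 implied by marginal consistency, and rows are
   renormalized to absorb rounding. Default BLOSUM45 (the shipped matrix
   closest to the 30–40% identity range that suits cross-subfamily
   comparisons); BLOSUM50/62/80/90 and an exact identity model are
   selectable. A genuine quirk: on the low-identity matrices P(M→L)
   slightly exceeds P(M→M) — methionine is rare and highly interchangeable
   with the abundant leucine — so "self-substitution dominates" holds for
   19/20 residues on BLOSUM45 and for all 20 on BLOSUM62.
4. **Permutation null.** One seeded generator produces n_shuffles
   re-pairings (default 10,000; experiments below use less); every column
   pair is scored under every permutation (a single global permutation
   sequence, 20× cheaper than independent per-pair permutations and
   faithful to "re-connect the pairs k times"). Pair weights are recomputed
   as w(r)·w(s′) for the new partner.
5. **Trace correction.** Shared ancestry inflates observed MI across the
   board. The correction regresses observed I on the raw null mean over the
   bulk of pairs (top 5% of observed I excluded as candidate signal) and
   applies E′ = αE + β, σ′ = ασ with floors α ≥ 1, β ≥ 0: the correction can
   only widen the null, never manufacture significance, so every Z-score is
   monotonically non-increasing under it. With fewer than 10 assessable
   pairs the fit is skipped. The exact transformation used by the original
   web tool is not published; this regression form is this package's own
   documented construction, switchable off with `--no-trace-correction`.
6. **Z-scores and the Bernoulli cutoff.** Z = (I − E′)/σ′; pairs with σ′ = 0
   (constant columns, no ungapped records) are excluded from ranking as not
   assessable. B(k) = P(Binomial(M, p_k) ≥ k) with p_k the standard-normal
   upper tail at the k-th largest Z, evaluated entirely in log space
   (gammaln + logsumexp), so |log₁₀ p| of order 10⁴ is computed without
   underflow. k\* is the argmin of B(k) restricted to ranks with Z > 0 — a
   pair at or below its null expectation cannot be significant, and because
   MI ≥ 0 the Z distribution is bounded below, which would otherwise make
   B(k) for k near M spuriously tiny on any input. If even the best B(k)
   is ≥ 0.5, k\* = 0.

MI is computed in natural log; Z-scores are provably base-invariant (both
numerator and null scale by the same constant), which the suite asserts
numerically at 500 shuffles.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| κ | 0.5 | pseudocount mass as a fraction of N |
| BLOSUM | BLOSUM45 | substitution model for protein pseudocounts |
| n_shuffles | 10,000 | permutations for the null (≥ 200 for a stable σ) |
| site weights | gsc | sites weighted like TFs; `uniform` available |
| trace correction | on | affine null widening (α ≥ 1, β ≥ 0) |
| χ² cutoff | 50 | highlight threshold for contingency cells (arbitrary) |
| prune threshold | 0.02 | leaf distance below which near-identical sequences collapse (exposed as an operation; the pipeline relies on exact-duplicate removal) |

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` draws a star-of-clades family: 5 subfamilies × 40 records
(74 protein columns, 20 site columns). Each subfamily has ancestral protein
and site sequences; records are per-position redraws at
`within_subfamily_divergence` = 0.5 from 4-residue per-column pools
(`background_entropy`), so background columns carry a moderate clade signal
— the shared-ancestry confound the weighting and trace correction target —
while real subfamily members remain recognizably related. At each of 6
planted column pairs every record carries its subfamily's nucleotide–amino
acid combination except with probability `noise_rate` = 0.1, where both ends
are redrawn independently. Planted coordinates are column-disjoint by
design: under clade-level couplings any two clade-tracking columns
correlate, so pairs sharing columns would have statistically equivalent
cross-pairs and "recovery of the planted pair" would be ill-posed. An
optional dyad-symmetry mode complements site column 19−j from column j,
mimicking palindromic operators.

Consequences to keep in mind when reading test results:

- Cross-pairs of planted columns are *genuinely* correlated (association
  ≈ 0.81 vs 0.9 for planted), so the cutoff typically selects ≈ 30–40 pairs
  of which 6 are planted — recall is the meaningful recovery number, and
  precision against the planted list understates the method.
- The generator has no indels, no rate variation, no realistic substitution
  process, and clade sizes are equal; passing tests demonstrate calibration
  and power under this controlled confound, not performance on any real
  family.
- A fully independent null (`null_spec`: one clade, divergence 1.0, nothing
  planted) yields iid columns for type-I experiments.

## Numerical choices and degenerate inputs

- Ranking ties are broken by (−Z, j, i); results.json is byte-identical
  across reruns with the same config and seed.
- Weighted-count tensors are computed as one (Lp·20 × R)(R × Ls·4) matrix
  product per permutation; gap cells are all-zero one-hot rows, excluding
  gapped records from every count they touch.
- Empty pairing tables, ragged alignments, non-IUPAC characters ('U'
  included — DNA only), unknown ids and duplicate FASTA ids are hard errors.
- Constant columns and pairs with no ungapped records are flagged
  not-assessable rather than scored.
- PWM scores are plain additive log₂-odds; score thresholds from other
  tools' dialects are not comparable and the CLI treats the threshold as an
  arbitrary float. Site centers of even-length sites are fractional
  ((L−1)/2) and the promoter-distance comparison rounds half-up.

## Known limitations

- The Bernoulli cutoff assumes Gaussian Z-scores. The permutation MI null is
  χ²-like (for 4-letter column pools against 4 nucleotides, ≈ 9 degrees of
  freedom; measured Z skewness ≈ 0.9), so its right tail is heavier than
  Gaussian and fully independent data retains a handful of nominally
  significant pairs (median k\* ≈ 4 across null replicates, B-minima around
  10⁻¹…10⁻¹⁷) — orders of magnitude weaker than planted data (10⁻⁵⁰⁰⁰ and
  below), but not zero. The same behavior is visible in the original
  study's shuffled-input control, which retained ln p = −14.
- The trace correction is a single affine map for the whole matrix; it
  cannot absorb clade confounds that vary strongly between column pairs.
- Experiment sizes used by the validation suite: recovery 20 replicates at
  1000 shuffles; type-I 50 replicates at 400; scrambling 5 levels × 20
  replicates at 250; base-invariance 500. These sizes give stable medians
  and proportions while keeping the whole suite fast.
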