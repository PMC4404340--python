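# Methods

Formulas, conventions, and algorithmic choices implemented in mitopop. All
notation: n individuals, K haplotypes with absolute frequencies f_i and
relative frequencies p_i = f_i/n, L analysis sites.

## Analysis sites and haplotypes

Alignment columns containing a gap or IUPAC ambiguity code in *any* record
are excluded for *all* records (complete deletion). Haplotypes are classes
of individuals identical over the remaining sites, numbered H1..HK in order
of first appearance. A segregating site (S) has ≥ 2 observed bases; it is
parsimony-informative (PI) if ≥ 2 states each occur in ≥ 2 individuals
(frequency-weighted). A column with m states contributes m−1 substitutions,
each classified transition (A↔G, C↔T) or transversion against the
frequency-weighted majority state.

## Diversity and neutrality statistics

- Haplotype diversity: h = n(1 − Σ p_i²)/(n − 1).
- Nucleotide diversity: π = (n/(n−1)) Σ_{i<j} 2 p_i p_j d_ij with d_ij the
  per-site p-distance between haplotypes; this equals the direct mean of
  per-site differences over all C(n,2) individual pairs. k̄ = πL.
- Tajima's D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constants
  a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ of the original derivation.
- Fu's Fs = ln(S′/(1−S′)) where S′ = P(K ≥ K_obs) under the Ewens sampling
  distribution at θ = k̄. The probability uses unsigned Stirling numbers of
  the first kind, computed entirely in log space by the recurrence
  |s(m,k)| = |s(m−1,k−1)| + (m−1)|s(m−1,k)| with log-sum-exp, so samples
  with n in the hundreds remain stable. K_obs = 1 gives Fs = +∞; θ ≤ 0 and
  S = 0 cases are reported as NA, never 0. The implementation is pinned
  against an exact rational-arithmetic oracle in the test suite.

## Distances and trees

Kimura 2-parameter distance d = −½ln(1−2P−Q) − ¼ln(1−2Q) from transition
(P) and transversion (Q) proportions under *pairwise deletion* (each pair
uses the sites unambiguous in both sequences). Saturated pairs
(1−2P−Q ≤ 0 or 1−2Q ≤ 0) raise a dedicated error and surface as NA in
matrices. Neighbor-joining uses scikit-bio's implementation; negative
branch lengths are clamped to zero.

## AMOVA, ΦST, Mantel

Distance-based AMOVA decomposes sums of squared deviations computed from
the pairwise distance matrix: SSD(group) = Σ_{i<j in group} δ²_ij / n_group.
By default δ² is the distance itself (the Arlequin convention for
molecular distances); `square_distances=True` squares distances first.
Variance components use the standard unequal-sample-size coefficients; the
three-level design yields Φ_ST, Φ_CT, Φ_SC. Permutation schemes: Φ_ST
permutes individuals among populations; Φ_SC permutes individuals among
populations within groups; Φ_CT permutes whole populations among groups.
P-values are (b+1)/(B+1). Pairwise ΦST runs a two-population AMOVA per
pair; populations of size 1 give NA; negative estimates are preserved.

Geographic distances are great-circle (haversine, R = 6371.0088 km)
between population centroids (mean latitude/longitude). The Mantel test
correlates lower-triangle entries (Pearson r), with a two-sided test on
|r|; for ≤ 7 labels all permutations are enumerated exactly. The
fixture matrices reproduce the published regressions without any
transformation; optional FST/(1−FST) and log-distance transforms are
available as flags.

## ABGD

For each prior P on a log-spaced grid (default 10 steps over 0.001–0.1),
the ranked pairwise distances are scanned for the first gap g between
consecutive distances above P that exceeds X times both (a) the divergence
at which it occurs, max(d, P) — X is a relative gap width, so a jump no
wider than the divergence already accumulated below it never qualifies,
which also makes the scan robust to float jitter — and (b) the mean gap
among the smaller ranked distances. The partition takes connected
components of pairs closer than the gap midpoint, then recursion re-applies
the scan inside every group of ≥ 3 sequences until nothing splits. Group
counts are non-increasing in P (verified property), and planted clades with
inter-clade distance ≥ 0.05 and intra ≤ 0.008 are recovered at priors
≤ 0.008. The original server's sliding-window slope statistic is
approximated by this mean-gap baseline; behaviour is pinned by the
monotonicity and clade-recovery properties rather than bit-compatibility.

## Median-joining networks

Distances are weighted Hamming lengths with transversions counted 3×
(configurable) and optional per-site weights. The ε-relaxed minimum
spanning network keeps an edge iff its length is within ε of the Kruskal
cost level at which its endpoints first become connectable (ties merge
simultaneously). Median vectors are site-wise majority consensus sequences
of connected triplets; per iteration the candidate whose insertion most
reduces the minimum-spanning-tree cost over the node set is added
(lexicographic tie-break), to a fixed point. Maximum-parsimony
post-processing keeps only nodes and links on minimal-cost paths between
observed haplotypes, removes degree-≤1 medians, and smooths degree-2
medians into direct edges. On small instances the final cost equals an
exhaustive Steiner-tree optimum (verified in the test suite).

## Synthetic data

Two regimes, both infinite-sites with collision re-draw (S counting stays
exact) and transversion probability `tv_fraction` (default 0.1):

- **Star expansion**: per clade, a founder δ mutations from a shared
  random root; each individual adds Poisson(λ) private mutations. Produces
  singleton excess (negative D and Fs) and a clean inter-clade barcode gap.
- **Kingman coalescent**: exponential coalescence times with rate C(k,2);
  Poisson(θ/2 × branch length) mutations. Calibration: E[k̄] = θ and
  E[S] = θa₁ (verified).

For a planted two-clade ΦST, the expected within-population pairwise
distance is 2λ mutations and between-clade 2δ + 2λ, so distance-AMOVA
ΦST ≈ δ/(δ + λ). Setting δ = λ plants ΦST = 0.5. The empirical
calibration table (`docs/phist_calibration.tsv`, regenerated by
`scripts/calibrate_phist.py`) confirms the relation across a δ×λ grid.

## Reproducibility

Every stochastic routine takes an explicit seed; pipeline runs are
byte-identical given (config, seed). Undefined statistics are NA
throughout. The packaged fixtures are generated programmatically from
constants in `mitopop.fixtures` and round-trip through the TSV readers.
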