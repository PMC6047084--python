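# Methods

This note documents the models and procedures `hicforge` implements, the
defaults it ships, the numerical choices made where the design was open,
and what the synthetic generator does and does not emulate.

## 1. The redesign engine

### Constraint model

A window is a DNA string plus a feature annotation. Annotated elements
forbid substitution over their whole body, with two exceptions: CDS bodies
accept synonymous substitutions (their start and stop codons remain
forbidden), and retrotransposons are treated as fully mutable repeats.
Overlaps resolve as forbidden-wins. Codons are read on the feature strand;
a position covered by several CDS must be synonymous in *every* reading
frame, and a substitution in an incomplete terminal codon is rejected
outright (it cannot be verified). Coordinates are 0-based half-open
internally; reports are 1-based inclusive, and a printed interval's length
is `end − start`.

### Site edits

Deleting a site enumerates all single-base substitutions inside its
recognition window; creating a site uses the single substitution of a
putative (Hamming-distance-1) window. Every candidate must (a) sit on a
free position, (b) be synonymous in all covering CDS, and (c) create no new
site of *any* panel enzyme. The creation check rescans a neighborhood of
`site length − 1` on each side of the substitution for every panel enzyme —
sufficient because a single substitution can only complete a site that
overlaps it. Candidate ranking is fully deterministic: transitions (A↔G,
C↔T) before transversions, then leftmost position, then alphabetical
alternate base. When no candidate survives, the edit fails with a
per-candidate reason list.

### Chains and scores

For window *scoring*, candidates for an enzyme are its exact sites plus
putative sites whose substitution is free and synonymous. A greedy chain
starts at the leftmost candidate within one spacing of the window start;
each next member must lie within `spacing·(1 ± tol)` of the previous one
(default tol = 0.10 **of the spacing** — the window-size reading of the
tolerance would allow kilobase drift on a 400-bp grid, contradicting the
tight fragment-length distributions the design is for). Among qualifying
candidates the one closest to the ideal distance wins, ties to the smaller
position; when none qualifies a gap is recorded and the chain restarts at
the nearest candidate beyond the band. An interval's score is the median
absolute deviation of consecutive chain gaps plus `spacing` per failed
placement (the gap penalty makes scores comparable across enzymes; chains
with fewer than two members score +∞). A window's score minimizes the
summed interval scores over all assignments of distinct panel enzymes to
the spacing classes; putative candidates lost to forbidden-position
collisions are counted as conflicts and degrade the score through the gaps
they leave. Genome scans enumerate windows of 150 kb at 10-kb strides,
excluding telomere overlaps and 75 kb around centromeres (all
configurable).

### Redesign algorithm

Four passes, all deterministic:

0. *Dry run* — the placement of pass 2 is simulated on a scratch copy to
   learn which existing sites the chains will use.
1. *Prune* — every panel site not claimed by a dry-run chain is destroyed,
   left to right, enzymes in panel order. Deleting **before** placing is
   load-bearing: a placement whose footprint overlaps a not-yet-deleted
   site would otherwise protect that site's only synonymous escape
   positions, leaving it stranded.
2. *Place* — for each assigned enzyme (smallest spacing first, the most
   constrained ladder), sites are placed adaptively: the next ideal
   position is measured from the last *placed* site, so an off-grid
   placement shifts the downstream ladder instead of accumulating error.
   Within the admissible band an existing site beats any creation
   (minimal-mutation rule), then closest-to-ideal, then leftmost. This
   rule also makes the whole procedure idempotent: redesigning an
   already-redesigned window yields an empty ledger.
3. *Cleanup* — provisionally kept sites the adaptive chains did not use
   are pruned.

Verification then asserts: every CDS translation unchanged; no ledger
mutation on a forbidden position; scanning the output returns exactly the
placed sites (zero residuals, zero strays); and every out-of-tolerance gap
corresponds to a flagged failed placement. Any violation raises, carrying
the full mutation ledger.

A site lying wholly inside a forbidden feature is undeletable by
construction; real designs avoid this by *window choice* (the score
weights forbidden collisions), and the engine reports such sites as
residuals in non-strict mode rather than silently mutating protected
sequence.

### Ancillary predictions

Block splitting produces `ceil((L − overlap)/(block size − overlap))`
blocks of 3,000 bp with 200-bp overlaps by default (a 144,558-bp region
gives 52). PCRTags are tag-length windows (default 20 bp) where the two
homologs differ at ≥ 3 positions, preferred inside CDS, greedy and
non-overlapping; exact-match semantics only — no melting-temperature
model. Southern prediction digests both homologs, takes the fragment
containing the probe interval (error if the probe spans a cut), and forms
the two reciprocal crossover bands by pairing the left boundary of one
parent with the right boundary of the other; parental lengths always sum
to recombinant lengths.

## 2. Contact processing

Pairs are tab-separated with a `#columns:` header, 1-based positions on
disk, canonicalized so (chrom1, pos1) ≤ (chrom2, pos2). Matrix-mode
filtering drops intra-fragment events and convergent/divergent
same-chromosome pairs closer than 1.5 kb (undigested molecules and
self-circles); the distance-decay filter is stricter, keeping only tandem
pairs ≥ 1.5 kb — discarding all non-tandem pairs genome-wide would halve
valid data for maps, so the two modes differ deliberately. Fragment-level
events enter fixed bins by fragment midpoint (fragments never split across
bins). Outlier removal computes the 99.5th-percentile count over nonzero
fragment pairs and zeroes entries above 20× that threshold. SCN iterates
row-then-column division until all margins agree within 1e−6 (default);
each sweep is a pure diagonal scaling, so cross-ratios of all 2×2 minors
are exactly preserved and a symmetric input converges to a symmetric
balanced matrix (one final symmetrization absorbs roundoff — per-sweep
averaging would break exact cross-ratio invariance). Subsampling is a
seed-reproducible uniform without-replacement draw (events) or a
multivariate hypergeometric draw over the upper triangle (matrices).

*p(s)* log-bins intra-arm distances as `floor(log₁.₁ s)` and weights each
bin's count by the bin width `1.1^(1+bin)` and by the number of admissible
loci `L_arm − s` (representative s = the bin's geometric midpoint; this
makes uniformly drawn pairs exactly flat, which is the estimator's
calibration test). Ratio maps are element-wise log₂ with zeros masked, not
pseudocounted. Pile-ups average `window/bin`-sized sub-matrices (58 × 58
at the 145-kb/2.5-kb defaults) over anchor bins and ratio them against an
equal-count, seed-recorded draw of non-anchor bins (or fully random bins
on request); anchors within half a window of an edge are skipped and
reported. Trans-contact fraction is 100 × bridging pairs / pairs inside
the two homolog regions; the inter-homolog profile divides trans-pair
counts per offset bin by the number of admissible locus pairs at that
offset, so a uniform trans background is flat.

## 3. Distance strata and the resolution criterion

A stratum collects all pair counts at distance s ± Δs (default Δs =
350 bp). Fragments within `s_max + Δs` of the region end are excluded as
left pair members, which keeps stratum cardinality exactly constant across
the declared s range on a regular map (the finite-size correction).
Standard deviations use the unbiased (n−1) estimator. CV = σ/μ is the
inverse signal-to-noise of the map at that distance; rescaled collapse
divides each stratum by its mean and summarizes shape agreement as the
maximum pairwise two-sample KS distance (scale-invariant shapes collapse
in the heterogeneity-dominated regime, Poisson shapes do not).

Sequencing is random sampling of ligation events, so a homogeneous pair
population gives Poisson counts (Var = μ). Real pairs differ in
re-ligation propensity; modelling the count as N ~ Poisson(μλ) with a
unit-mean latent factor λ of CV c gives the distribution-agnostic
mixed-Poisson law **Var = μ + c²μ²**. The fit is linear least squares for
c² on (μ, σ²) strata, clipped at zero, with a delta-method standard error
propagating Var(σ̂²) ≈ 2σ⁴/(n−1); c below twice its SE is reported as
Poisson-compatible with μ* = ∞. The crossover mean μ* = 1/c² is where
heterogeneity variance equals Poisson variance — a graphical transition in
mean–variance space formalized here as the quadratic fit's intersection
point. The resolution at distance s is the smallest bin size whose mean
count per bin pair at s reaches μ*: mean count grows monotonically with
bin size and depth, so an ascending grid scan suffices, and μ* unreachable
at any bin ≤ s is reported as "unresolved at s".

## 4. The synthetic generator

The generator is a statistical twin, not a polymer model. Restriction maps
are regular (fixed d) or geometric (i.i.d. gaps, mean d — fragment-length
CV ≈ 1, the native-like regime). Pair weights are

    w_ij = len_i^β · len_j^β · max(s_ij, s₀)^(−α) · λ_ij

with midpoint distances s_ij, capture-bias exponent β = 1 (the simplest
monotone model of the empirical contacts-vs-fragment-size relation),
decay exponent α = 0.6 in the interphase presets, and λ_ij lognormal with
mean 1 and CV c drawn once per pair (per-pair, matching the re-ligation
framing; the fit that recovers c only uses means and variances, so the
lognormal choice is not load-bearing). The decay kernel is a pure power
law above the floor s₀ = 1 kb and flat below it; the floor sits under the
1.5-kb filter so it never influences filtered analyses, and above it the
log-log slope is exactly −α — the property the recovery tests check.
Reads are drawn multinomially from the pair model (≈ independent Poisson
in the small-probability regime the crossover analysis assumes), with
uniform positions inside fragments and random orientations; everything is
reproducible from a single seed.

Overlays: the meiotic loop array draws anchor spacings uniformly from
5–50 kb and multiplies adjacent-anchor pairs by κ₁ = 5, next-adjacent by
κ₂ = 2 and intra-domain pairs by δ = 2. The diploid generator substitutes
bases i.i.d. at 2% (the divergence regime of a designed region inside an
isogenic diploid), splits cis reads evenly between homologs, and makes a
fraction ρ (default 0.07) of pairs bridge homologs with a two-sided
exponential offset kernel of 10-kb scale centered at offset 0 — the
pairing width is a free parameter, the data constraining it only weakly.
An optional mappability flag relabels read ends whose 75-bp window covers
no substitution as "ambiguous" (resolvable fraction 1 − (1−q)^75 ≈ 0.78 at
q = 0.02).

What passing tests show — and don't. The generator reproduces the
*statistical* structure the analyses assume: regular vs geometric fragment
maps, power-law decay, latent overdispersion, planted anchors, diploid
trans contacts. It does not emulate mappability structure beyond the SNP
flag, chromosome-arm heterogeneity, duplicate reads, or any polymer
physics; tests passing on it validate the estimators' correctness and
calibration, not biological conclusions about real chromosomes.

### Problem sizes used in tests and the acceptance script

Test simulations use 150-kb regions (375 fragments at 400 bp) with 3×10⁵
to 10⁶ read pairs, 5,000 pairs per stratum over 30-point μ grids, and
≤ 400-bin matrices — sizes at which every stochastic check has comfortable
margin against its tolerance while the full suite stays fast. The
acceptance script's three computations (block count; crossover mean at
c = 0.316; decay slope from 10⁶ pairs) run in a few seconds total.

## 5. Known limitations

- Single-base edits only: a site needing two substitutions to create is
  not considered (the putative-site definition is Hamming distance 1).
- Placement is greedy/adaptive, not globally optimal; pathological
  candidate layouts can yield more flagged gaps than an exhaustive search
  would.
- Six-cutter ladders in dense coding sequence are putative-site-limited:
  at tol = 0.10 a 1.5-kb spacing has ~1 raw candidate per band before the
  synonymy filter, so flagged gaps are expected and reported rather than
  hidden.
- No primer thermodynamics, no indel-diverged homologs, no multi-chromosome
  balancing of the pile-up control draw beyond bin exclusion.
- The pairs dialect and TSV matrices are the only on-disk formats; no
  binary Hi-C ecosystem formats.
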