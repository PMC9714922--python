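# Methods

## Model and assumptions

The package treats a crystallographic B-factor as a per-chain relative
signal: only residues anomalously mobile *within their own chain* are
informative, so B-factors are standardised per chain,
b_i = (B_i − ⟨B⟩)/σ_B, using the population (divide-by-n) standard
deviation over the observed Cα B-factors.  Any fixed convention works —
only the thresholded ranks matter — but the choice is documented here and
kept stable.  The per-residue B is read from the Cα (C1′ for nucleotides);
a residue is *observed* iff that atom is present, so side-chain-only
residues count as missing.  σ_B = 0 (constant-B chains, plausible in tiny
synthetic fixtures) is not an error: the profile is flagged degenerate and
no residue can exceed a positive threshold.

Soft disorder unites two signals: b_i > 1 (strict) and residues missing
from at least one structure of a hierarchy node.  Missing-residue calls are
SEQRES-vs-ATOM differences, so the input files must carry SEQRES records to
distinguish "unresolved" from "not part of the construct"; without SEQRES
the observed residues are taken as the full sequence and a warning is
logged.  Positions missing in *every* structure of a DAG are treated as
intrinsic disorder: they never enter a test universe, because their
interface status is unknowable.  Positions missing at one level that order
upon further binding (disorder-to-order) do enter, which is the phenomenon
of interest.

Hierarchies are proxies for assembly order, not kinetics: a DAG edge only
asserts that a smaller complex's partners and ≥ 75 % of its interface recur
in a larger one.  Whether the deposited files are biological assemblies or
asymmetric units is not resolved here — files are analysed as given, and
crystal-packing contacts are not distinguished from biological ones.  Both
caveats carry over from the underlying analysis design.

## Parameters

| parameter | default | meaning |
|---|---|---|
| b threshold | 1 (dimensionless) | strict cut on the normalised b-factor; 0.5 and 3 are supported sensitivity settings |
| identity / length | 90 % / 90 % | inclusive cluster criteria; identity = matches / shorter-sequence length (see below) |
| node & edge overlap | 0.75 | strict ">": exactly 75 % fails, both for grouping structures into nodes and for parent→child interface retention |
| contact cutoff | 5.0 Å | inclusive Cα–Cα distance for protein–protein interfaces |
| probe radius | 1.4 Å | solvent probe for Shrake–Rupley accessibility |
| SASA points | 300/atom | quadrature resolution; doubling changes totals < 1 % on fixtures |
| surface RASA cutoff | 5 % | buried/exposed convention for the S universes; configurable, and the tests assert the monotone-superset property rather than the specific cutoff |
| bootstrap | 500 resamples, 90 % | percentile CI of the mean |

All of these are keys of `PipelineConfig` / the YAML config, so sensitivity
analyses are one-line changes.

## Numerical and design choices

**Sequence identity.**  Alignment uses Biopython's `PairwiseAligner` with
match = 1, mismatch = 0, gap = 0 (the modern equivalent of the classic
`globalxx` scheme).  Under this scoring an optimal alignment prefers a
gap–gap column pair over a mismatch column, so "matches / alignment length"
systematically deflates the identity of substituted same-length pairs
(10 % substitutions would read as 81.8 %, not 90 %).  Identity is therefore
defined as matches / length of the shorter sequence, which the length-ratio
rule keeps close to the longer one.  Member positions aligned to
representative gaps are dropped from all mapped residue sets.

**Clustering.**  Exhaustive greedy single-linkage over all chain pairs —
at desk scale this replaces a dedicated clustering engine while applying
identical criteria; an external cluster TSV can be ingested instead
(`clusters_tsv` hook).  A canonical pre-sort by structure id makes the
result order-invariant.  Representatives are chosen by best resolution,
then best R-value, then lexicographically (logged).

**Alternate locations.**  Per atom name the highest-occupancy conformer is
kept; ties go to the first encountered.

**SASA.**  Shrake–Rupley with a golden-spiral point lattice, element-typed
van der Waals radii and Tien-style theoretical maxima for RASA.  Residue
types without a tabulated maximum (nucleotides, coarse synthetic traces)
are normalised by their own isolated-atom area, an upper bound that keeps
RASA in [0, 100].  Nucleic-interface calls require a strictly positive SASA
decrease beyond 1e-6 Å², guarding quadrature noise.  The parent-complex
surface for the S universes is computed on the first structure listed in
the node.

**Node grouping.**  Members are grouped greedily in canonical id order;
rule (ii) is evaluated as the *joint* intersection across the whole group
(> 75 % of each member's interface, per interface type, members with empty
interfaces exempt) and re-verified post hoc.  Protein and nucleic
interfaces are tracked as separate types for grouping and edge retention,
but unioned into a single track for prediction scoring (a config flag on
`HierNode.ir()` callers can keep them apart).

**Edges.**  Candidates satisfy K-increase, multiset signature inclusion
and > 75 % interface retention (vacuous for unbound parents, so K = 0
roots can have children); a candidate (A, C) is discarded when some node B
has candidate edges (A, B) and (B, C).  The brute-force oracle in the test
suite re-derives this independently.  Strict K-increase guarantees
acyclicity.

**Universes and unknowable positions.**  For edge tests the excluded
"offspring-missing" set is positions unobserved in every structure of the
child node; for shell tests, positions unobserved in every structure of
the shell and never interface within it (the multi-descendant rule is not
uniquely determined by the source analysis; this reading is the
implemented one).  Undefined metrics (zero denominators) are flagged NaN
and dropped from aggregation rather than imputed; empty universes skip the
record with a warning.  The strict Sen > 1 − Spe comparison uses a 1e-9
guard so floating-point dust cannot promote exact diagonal ties.

## The synthetic generator

`softhier.synthetic` emulates the statistical structure the analysis
assumes: clusters of near-identical chains crystallised with 0, 1, 2, …
partners ("path" topology; "fork" gives one root with several K = 1
children), two structures per node, planted contiguous high-B and missing
segments plus member-specific missing residues (intermittent disorder),
and partner chains placed so that designated residues fall at 4.0 Å from a
partner Cα — inside the 5 Å cutoff while sequence neighbours (at
√(3.8² + 4²) ≈ 5.5 Å) stay outside, making planted contacts
single-residue exact.  Defaults: 60-residue chains, 12 % high-B fraction,
6 % missing fraction, 6 new interface residues per edge, baseline
B ~ N(30 Å², 3 Å²) with a 6-σ elevation on planted segments — large enough
that the b > 1 call recovers planted segments near-deterministically
(stray calls ≈ 0.2 % of background residues per chain), small enough to
keep the B column in PDB fixed-width range.

`overlap_f` is the probability that each new interface residue is drawn
from the parent's planted soft disorder.  The child's node-wide missing
segment is planned *before* the draw and excluded from the draw pool, so
the pool coincides with the edge-test universe and the measured mean
sensitivity converges to `overlap_f` without correction.  `uniform_ir`
replaces the biased draw by a uniform one — the exact realisation of
"overlap equal to the random rate" — and is compared against Sen_r on the
chain-minus-parent-interface universe, whose definition matches the pool.

What the generator does **not** emulate: realistic fold geometry, crystal
contacts, anisotropic or resolution-dependent B-factor noise, sequence
heterogeneity beyond point substitutions, conformational change between
nodes.  Passing tests therefore demonstrate correctness of the pipeline's
bookkeeping and statistics under the stated model, not biological
conclusions about real PDB data.

pLDDT profiles are emulated as 90 minus a 25-unit depression on the
planted union soft disorder, plus Gaussian noise; the low-confidence
region (LCR) operator flags residues strictly below their model's chain
mean and unions over models.

## Problem sizes

The shipped tests and the acceptance script run on synthetic studies of
70 clusters × 4 nodes × 2 members per overlap setting (210 edges each),
10⁴-residue chains for the Gaussian-tail check, 2·10⁴ random placements
for the expectation law, 400–1000 bootstrap repetitions, and exhaustive
subset enumeration up to universe size 8 (with a complete vectorised sweep
and a 2000-pair scalar sample at size 12).  These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances.

## Known limitations

* PDB format only (no mmCIF); no symmetry/BIOMT expansion, no hydrogens,
  no water handling.
* One interface track per prediction test (types unioned); atom-level
  interface typing and buried-surface energetics are out of scope.
* The unbound-node caveat — clusters whose alternative unbound crystals
  carry distinct soft disorder and may seed distinct branches — is not
  modelled.
* Statistical comparison of LCR against soft disorder at database scale is
  out of scope; the LCR operator and its synthetic calibration are
  provided as building blocks.
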