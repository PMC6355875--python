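# Methods

This note records the model, the defaults and the design choices behind
`ise_screen`, in the package's own terms.

## Filter model and balanced MCC

A filter is a conjunction of k closed intervals over named molecular
descriptors; boundary values pass (closed-interval convention, so a
molecule sitting exactly on a bound is inside). Filters are scored by
the class-balanced Matthews correlation coefficient: the inactive-class
confusion counts are rescaled by s = n_actives/n_inactives before the
standard MCC formula. This is exactly the standard MCC of the dataset in
which each active row is replicated n_inactives times and each inactive
row n_actives times; the test suite and the acceptance script verify
that identity against an exact-rational oracle on random confusion
tables. A zero factor in the denominator yields MCC = 0 (the usual
convention), and a filter that passes or fails everything therefore
scores 0.

On the published PPAR-δ validation table (395 actives / 10,000 presumed
inactives; six MBI borders) this recomputation reproduces the printed
MCC cells at +6.0 and +13.0 to three decimals. The −3.0/+3.0/+10.0 cells
print one unit low in the third decimal, and the printed enrichment at
+9.0/+10.0 (199/268) differs from the count-derived value (200/274);
`ise_screen.benchmarks` documents both quirks and flags which cells are
reproducible.

## The ISE loop

Tunable parameters (``ISEConfig``), with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `k` | 4 | clauses per filter; published models used 4 (occasionally 5) |
| `filters_per_iteration` | 1000 | random filters sampled per iteration; after sampling, any uncovered descriptor gets one extra targeted filter so elimination statistics exist for every pool member |
| `elimination_fraction` | 0.2 | fraction of the pool removed per iteration, lowest mean MCC first, ties broken by descriptor name |
| `exhaustive_threshold` | 100,000 | sampling stops once C(pool, k) is at most this many subsets |
| `band_fraction` | 0.20 | retain filters with MCC ≥ (1 − band) × top MCC ("about 20% less than the top"); exposed because published models imply bands near 0.22 |
| `dedup_overlap` | 0.99 | filters whose pass/fail vectors agree on more than this fraction of molecules are duplicates; the lower-MCC one is dropped |
| `quantile_grid` | 10 | candidate range bounds are the actives' deciles (11 grid points) |
| `seed` | 0 | one generator drives all randomness; the config snapshot is stored in the model file |

Range bounds are drawn from the *actives'* empirical quantiles: filters
must fit actives by design, and a finite grid bounds the search space. A
constant descriptor degenerates to a single-value clause. In the
exhaustive phase each k-subset receives its best-scoring range
assignment by deterministic coordinate ascent over the quantile grid,
starting from the widest ranges, with MCC ties resolved toward the least
restrictive clause; this keeps equivalent subsets byte-identical, which
the >99%-overlap deduplication then collapses reliably. Scoring is
bit-packed (eight molecules per byte, popcount-based confusion counts),
so the default exhaustive phase of ~10⁵ subsets on a few thousand
molecules completes in well under a minute.

Retention applies the MCC band before deduplication. The two orders
yield provably identical models (deduplication only ever discards the
lower-MCC member of an agreeing pair, and any filter that outranks an
in-band filter is itself in band), and band-first reduces the quadratic
deduplication to the in-band survivors. Raising the band fraction can
only widen the candidate set, so the model never shrinks — a property
the tests assert.

Degenerate inputs: a dataset with a single class, with NaN descriptors
(after `drop_incomplete`), or with fewer than k descriptors is rejected
up front; if the best exhaustive filter has MCC ≤ 0 the build aborts
with a "no discriminating filter" diagnostic rather than emitting a
meaningless model.

## MBI scoring

The weight of filter i is the rate ratio TPR_i/FPR_i rather than the raw
count ratio TP_i/FP_i: the published description ("TP/FP value") is
ambiguous, and rates make weights invariant to training class sizes. The
raw-count mode is available (`filter_weight(..., raw_counts=True)`).
When FP = 0 the FPR is floored at 1/(2·n_inactives) — half a count, the
standard continuity correction — so perfect filters get large finite
weights. Scores are sums, so flipping one filter from fail to pass moves
the MBI by exactly +2·w_i. An optional divide-by-filter-count
normalization (`normalize=True`) is provided because the published score
scaling is unstated; it changes nothing about ranking. Threshold
evaluation counts a molecule as positive when its score is ≥ the border
(closed at the border).

## Curation

Fingerprints are hashed linear-path fingerprints (paths of 1–7 bonds,
folded to 1024 bits, RDKit path enumeration). Bit-level compatibility
with any other toolkit's path fingerprint is *not* promised — thresholds,
not bit layouts, carry the scientific content — and every similarity in
the package is computed with its own fingerprints. Tanimoto similarity of
two empty bitsets is defined as 0. Diversity pruning is greedy in input
order (a molecule is dropped iff it is ≥ T similar to an already-kept
one); the published procedure does not state which member of a similar
pair was discarded, so first-come retention is a documented, reproducible
choice, and tests audit the output post hoc (no retained pair at or above
T). The applicability-domain box uses the sample standard deviation
(n − 1) and mean ± 2σ on the four Rule-of-Five descriptors; inactive
sampling is uniform without replacement among eligible candidates under
a fixed seed.

## Geometry

All distances are heavy-atom distances; hydrogens are ignored
(structure preparation with explicit hydrogens is out of scope, and the
donor–acceptor distance is defined between heavy atoms). "Distance to a
residue" is the minimum over all heavy-atom pairs of the whole residue —
backbone included — since the published criteria do not restrict the
atom set, and the same whole-residue rule applies to crucial residues.
Contact thresholds are ≤ 3.3 Å (H-bond, N/O–N/O) and ≤ 3.9 Å (van der
Waals) — "maximum distance" is inclusive — while the pose criteria use
strict < 3.5 Å / < 5.0 Å as written. Both published phrasings of
"important" are implemented: contacts with more than 3 ligands or an
H-bond with at least one (default), or contacts with ≥ 70% of ligands
(`important_rule="fraction"`). A pose set larger than 30 is truncated to
the 30 best energies with a warning; energy ties select the lower pose
index so verdicts are deterministic.

## Synthetic generators

The descriptor generator draws informative descriptors from
class-shifted unit normals (actives at mean = shift, default 3) and
noise descriptors from N(0, 1) in both classes. Defaults — 200 actives,
2000 inactives, 5 informative + 45 noise descriptors — stand in for a
curated training set of a few hundred actives diluted tenfold with
domain-matched inactives. Normality makes the best attainable filter
analytically computable (`expected_clause_mcc`). Not emulated: descriptor
correlations, integer-valued counts, multimodal chemical series, label
noise; passing tests on this generator demonstrate the correctness of
the search and scoring machinery, not performance on real chemistry.

The toy-complex generator realizes planned residue–ligand minimum
distances exactly: glycine-like residues (explicit N/O atoms, so H-bond
typing is exercised) sit 60 Å apart on a line, and each pose carries one
ligand atom per residue placed at the planned distance along a random
direction pointing away from the residue's other atoms. Plans with
distances outside 0.5–25 Å are rejected as infeasible. Randomized plans
avoid a ±0.06 Å window around the 3.5/5.0 Å decision boundaries so that
coordinate-format precision (PDB 3 decimals, SDF 4) cannot flip a
verdict. Verdict ground truth is computed from the plan by the counting
rule directly, independently of any coordinate arithmetic.

## Problem sizes used in the checks

The automated checks learn models on the 50-descriptor, 2200-molecule
synthetic preset (one elimination iteration, ~91,000 exhaustive subsets,
about 45 s on one CPU) and on a 12-descriptor, 360-molecule table for
the fast loop tests; the geometry filter is validated on 100 random toy
complexes with 9 residues and 3 poses each. These sizes exercise every
code path of the full-scale method; the algorithms scale to larger pools
simply by spending more elimination iterations.

## Known limitations

The learner assumes descriptors are numeric and complete; categorical
descriptors must be encoded upstream. Filters are axis-aligned boxes, so
correlated informative descriptors are covered by unions of filters
rather than oblique boundaries. On strongly overlapping classes the
retention band admits weakly informative filters (any filter within 20%
of the top MCC is kept by design, including ones using fewer truly
informative descriptors than the best filter). Consensus residue
derivation keys residues by (name, sequence number) and therefore
assumes consistent residue numbering across the reference complexes.
Docking itself — conformers, grids, energies — is consumed only as
files, never computed.
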