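# Methods

## Model

A binding site is modeled as a finite labeled point cloud: one point per
protein heavy atom within a cutoff (default 4.0 Å, atom center to atom
center, boundary inclusive) of any atom of a bound ligand, each carrying
one of six physico-chemical classes (ACC, DO, AD, ALI, PI, NONE).  Two
sites P (n atoms, the query) and Q (m atoms, n ≤ m) are compared by
searching for the rigid-body transform T_a that minimizes a dissimilarity
g(a); the transform is parameterized by a unit quaternion and a
translation, with the quaternion kept in the canonical half-space
(first nonzero component positive) so that the two antipodal encodings of
each rotation never coexist in an optimizer population.

Two inner objectives are implemented:

* **closest-point**: g(a) = mean squared distance from each transformed
  query atom to its nearest target atom.  Non-injective — many query atoms
  may share one target — which can make a bad pose look good.
* **matching distance** (the default): the mean squared residual of the
  minimum-cost *asymmetric assignment* of query atoms to distinct target
  atoms.  Computed with the rectangular Jonker–Volgenant algorithm
  (`scipy.optimize.linear_sum_assignment`); its exactness is verified in
  the test suite against brute-force enumeration over all injective maps.

In `same_property` mode only label-equal atom pairs are admissible edges,
inside the objective itself (not merely in post-hoc scoring).  NONE-labeled
atoms match nothing and are reported unmatched.  Feasibility is checked up
front: for the matching objective, compatibility is label equality, so the
graph is a union of complete bipartite blocks and Hall's condition reduces
to per-label count comparisons.  `relax` mode prices incompatible edges at
10× the squared joint bounding-box diagonal instead of forbidding them, so
batch runs over heterogeneous sites never abort; `all_pairs` ignores labels.

## Optimization

The outer problem min g(a) is non-smooth (the inner argmin switches
discretely), so the optimizer is a derivative-free controlled random
search:

1. Sample M transforms over Θ — quaternions uniform on the unit 3-sphere
   (normalized 4D Gaussians), translations uniform in an axis-aligned box
   centered on centroid(Q) − centroid(P) with per-axis half-width
   diam(P)/2 + diam(Q)/2, which contains every translation that can
   superpose the clouds.
2. Stop when g_max − g_min < ε over the population (absolute spread by
   default; a relative variant is available).
3. Otherwise draw N+1 = 7 members, form their weighted centroid a_c with
   weights w_i ∝ 1/(g_i − g_min + η), η = 10⁻³(g_max − g_min + 10⁻¹²)
   (better points pull harder; an unweighted variant is available), and
   reflect over the worst drawn point a†: ǎ = (1+α)a_c − αa†.  The first
   four components are then renormalized to a unit quaternion.
4. Accept the trial iff it improves on the population-wide worst value,
   replacing that worst member.

### Parameter choices

| parameter | default | rationale |
|---|---|---|
| M | 150 (= 25·N, N = 6) | standard population sizing for CRS in 6 dimensions |
| ε | 1e-4 Å² | population spread at which further contraction is numerically meaningless for Å-scale data |
| α₀ | 0.9 | see below |
| α schedule | α₀ · (spread ratio)^0.1 / (1 + k/(50M)) | see below |
| max_evals | 20 000 | typical convergence uses ~2 000–3 000 evaluations on 20–60-atom sites |

The reflection parameter α must start high and decay to zero as the
population clusters.  How fast it decays matters more than its exact form:
schedules that shrink α within a few hundred iterations turn every trial
into a near-centroid, and the population then collapses onto whichever
basin currently dominates — a premature-convergence failure we measured
directly (recovery of a planted transform on noise-free 20-point clones
dropped from 30/30 to 4/30 seeds under an aggressive schedule).  The
shipped schedule keeps α within a factor of ~2 of α₀ until the spread has
fallen several orders of magnitude (tenth-root dependence) and decays on an
iteration scale of 50·M; with α₀ = 0.9 it recovered the planted transform
on 100/100 seeds while converging in ~2 000 evaluations.

After the population converges, the returned minimizer is polished by
coordinate descent: alternate the exact inner mapping at the current
transform with the closed-form optimal transform for that mapping (Horn's
absolute-orientation quaternion method — the eigenvector of the 4×4
cross-covariance matrix with largest eigenvalue).  Both half-steps are
exact minimizations, so g never increases; with the closest-point mapping
this alternation *is* one ICP run, and with the assignment mapping it is
the natural analogue.  The polish matters because a population that has
collapsed to spread < ε still carries an O(√ε) transform error — about
0.01–0.03 Å of translation at ε = 1e-4 — which the closed-form step removes
at negligible cost.

The ICP baseline (`run_icp`) is the same alternation started from a fixed
pose with the closest-point mapping; its mean square error is monotonically
non-increasing and its fixed point depends on the start, which is exactly
why the global phase exists.  `make_symmetric_decoy_instance` constructs a
two-cluster site whose 180°-rotated pose is a deep ICP trap while the
global search reaches the exact superposition; the suite asserts both.

## Scoring

A total assignment pairs every query atom, so "aligned atoms" requires a
selection rule: the reporter counts assigned pairs within a
post-superposition distance cutoff (default 2.0 Å) and computes the RMSD
over exactly those pairs.  This is the main caveat when comparing against
published per-pair tables — any such table depends on its own (usually
unstated) counting rule, so agreement should be expected in ranking and
magnitude, not digit-for-digit.  Derived scores:

* SAS = RMSD × 100 / aligned atoms (lower is better; combines the two
  usual quality measures into one number),
* similarity = 2·aligned/(n+m) ∈ [0, 1], symmetric in the two sites and
  used for all-vs-all matrices,
* ROC retrieval: for each query site, all other sites are ranked by
  aligned-atom count (similarity as tie-break); an item is a true positive
  if it binds the same ligand group.  Curves and AUC come from
  scikit-learn; per-group curves average member queries' TPR on a common
  FPR grid.

The shipped `ATP_BENCHMARK` table holds published per-pair aligned-atom
counts and RMSDs for 18 reference comparisons of ATP-binding sites (two
methods side by side); it exists so the SAS formula and its column means
can be validated and reproduced without any network access.

## Atom typing

Labels come from a shipped TSV keyed by (residue name, atom name) — the
five classes follow pseudocenter-chemistry conventions (side-chain amines
and backbone N donate; carboxylate/carbonyl oxygens accept; hydroxyls and
imidazole nitrogens both; aromatic ring atoms of PHE/TYR/TRP/HIS are PI;
other carbons and sulfurs aliphatic) — with element-based fallbacks
(N → DO, O → ACC, C/S → ALI) for atoms outside the table and NONE
otherwise.  The table is data, not code, and can be edited or replaced
without touching the package.  It is a faithful implementation of the
class semantics, not a certified copy of any particular published table.

## Synthetic instances

`make_instance` emulates the geometry of the benchmark task while keeping
the answer known: a query cloud uniform in a 20 Å cube (the scale of a real
binding-site shell), a planted random rigid transform, isotropic Gaussian
coordinate noise (σ in Å), and decoy atoms sampled in the bounding box of
the true target atoms but kept ≥ 2σ + 1 Å from every true atom, so at
σ = 0 the planted assignment is the unique optimum at the ground-truth
transform.  Labels are drawn uniformly from the five classes and, in the
default `compatible` scheme, copied to the true correspondents so the
property filter never excludes a true pair.  Mock PDB files encode each
label as a representative (residue, atom) pair so extraction + typing
reproduce the instance exactly; the fake ligand is an offset copy of the
patch, guaranteeing the 4.0 Å shell recovers precisely the planted atoms.

What these fixtures do **not** emulate: covalent geometry and packing of
real side chains, correlated conformational change, crystallographic noise
structure, or realistic label frequencies.  Passing the recovery suite
shows the optimizer and objectives work as specified on well-posed
instances of realistic size; it does not by itself certify retrieval
accuracy on real, flexible binding sites.

Instance sizes in the test and acceptance experiments (20 atoms, 10 decoys,
σ ∈ {0–0.5} Å, 100 seeds) were chosen to match the scale of ligand-shell
patches while keeping a full 100-seed experiment around half a minute.

## Degenerate inputs and tie-breaking

* Nearest-neighbour ties and alternate assignment optima resolve to the
  lowest target index (deterministic argmin / solver ordering).
* All mapped points coincident → the closed-form solve returns identity
  rotation with centroid-aligning translation.
* Trial reflections with near-zero quaternion norm (< 1e-12) are discarded
  and the N+1 subset resampled.
* If |P| > |Q| the roles are swapped internally; reports are re-expressed
  in the caller's frame (transform inverted, pair table transposed).
* Multi-model PDB files use model 1; altlocs resolve to highest occupancy;
  waters and hydrogens are excluded from extraction by default; duplicate
  (chain, residue, insertion code, atom name) records are dropped.

## Known limitations

* Rigid-body only: no flexibility, scaling, or reflection; sites related by
  large conformational change will score poorly by construction.
* The aligned-atom cutoff (2.0 Å) is a convention; per-pair counts shift
  with it even when the underlying superposition is identical.
* CRS is stochastic; results are exactly reproducible only under a fixed
  seed and configuration (every CLI run writes both).
* The same-property filter is binary; chemically plausible near-matches
  (e.g. ACC vs AD) are either forbidden or fully allowed, never weighted.
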