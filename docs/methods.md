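# Methods

This note documents the models, numerical choices and limitations behind
`gatekin`, module by module.

## Trajectory handling

Coordinates are dense `(frames, atoms, 3)` arrays in Ångström with a flat
per-atom topology (name, 0-based residue index, residue name, backbone
and heavy-atom flags). Multi-model PDB is the canonical interchange
format; XYZ and DCD/XTC (with a PDB topology) go through the same
interface. Parsing and writing are delegated to MDAnalysis; residue
indices are remapped to a contiguous 0-based range on read, and reports
use 1-based numbering to match PDB convention. Hydrogens are recognized
by atom name (leading digits stripped, then an initial `H`), backbone
atoms by the names N/CA/C/O. Round-tripping through PDB preserves
coordinates to the format's 10⁻³ Å precision.

## Synthetic two-state trajectories

The generator emulates the one feature of a gated enzyme that the
analyses measure — two-state switching with condition-dependent
occupancies and designed contact changes — not force-field physics.

- **Latent gating.** A two-state Markov chain with transition
  probabilities p(closed→open) = s·(1−π) and p(open→closed) = s·π, so the
  stationary closed occupancy is exactly π (`occupancy_closed`) for any
  switching scale s (`switch_probability`, default 0.1/frame). The
  initial state is drawn from the stationary distribution.
- **Gate geometry.** The gate residue is translated rigidly along a fixed
  axis from the probe residue; the gate–probe CA distance equals the
  state-conditional Gaussian draw exactly (closed 5.0 ± 0.6 Å, open
  16.0 ± 0.8 Å by default, chosen so the 7/14 Å classification thresholds
  sit several standard deviations from either basin). Gate and probe are
  exempt from jitter, making the distance analysis exact by construction.
- **Scaffold.** All other residues sit on a 10 Å cubic lattice (four
  backbone atoms plus one hydrogen at fixed sub-Å offsets) with isotropic
  Gaussian jitter (0.15 Å default), so no undesigned residue pair ever
  approaches the 4.5 Å contact cutoff.
- **Designed contacts.** Each designed pair owns two satellite heavy
  atoms, one per residue, that meet 1.5 Å apart at a rendezvous site
  unique to the pair (≥ 20 Å from every residue site) in a
  Bernoulli(*p*c)-chosen subset of frames, and retract to their host
  residues otherwise. This realizes arbitrary per-pair contact
  probabilities with zero cross-talk between pairs — a deliberately
  unphysical construction that makes ground truth exact.
- **Presets.** The wild-type-like condition uses π = 0.5; the
  variant-like condition π = 0.8 (gate shifted toward closed) and forms
  three inter-domain contacts much more often (pc 0.2–0.3 → 0.8–0.9),
  one less often (0.7 → 0.2), one unchanged. Both share a rigid scaffold
  of two contact domains bridged by one edge, giving the consensus
  network a clean two-community structure.
- **Seeding.** One integer seed per spec; per-purpose substreams are
  spawned from it (`numpy.random.SeedSequence`), so state path, distance
  draws, contact draws and jitter are independently reproducible.

What the generator does *not* emulate: solvent, side-chain packing,
realistic fluctuation amplitudes, correlated inter-residue motion, or
any energetic coupling between gating and contacts. Passing tests on
synthetic data therefore validate the estimators (counting, binning,
superposition, eigendecomposition, graph algebra), not the physics of
any real trajectory.

## Conformational statistics

- **Superposition.** Least-squares (Kabsch, via
  `scipy.spatial.transform.Rotation.align_vectors`) onto the mean
  structure, iterated three times from the first frame; the mean-structure
  reference is the convention RMSF/PCA figures normally imply. RMSF is
  computed per atom on the selection (default: backbone) and averaged per
  residue. Both RMSF and PCA accept `align=False` for rigid setups.
- **Distances** are frame-internal (no alignment).
- **State classification** uses closed ≤ 7 Å, open ≥ 14 Å, intermediate
  between; intermediates are their own class and are excluded from any
  closed:open ratio.
- **Free-energy profile.** Raw histogram (default bin width 0.25 Å,
  fine enough to resolve the 7/14 Å thresholds) normalized to unit
  integral; *F* = −k*B*·*T*·ln *P* on occupied bins only (empty bins are
  NaN — undefined, not zero), offset so min *F* = 0 exactly.
  k*B* = 0.0019872041 kcal/(mol·K); the default 300 K gives
  k*B*·*T* = 0.596 kcal/mol. A histogram (not a KDE) keeps the density
  normalization and the basin-probability algebra exact.
- **PCA.** Frames of all input trajectories are pooled, superposed on
  the combined mean, and the covariance of the flattened Cartesian
  coordinates is eigendecomposed (`numpy.linalg.eigh`; eigenvalues
  clipped at 0 and sorted descending). Projections are returned per
  input trajectory so conditions can be overlaid. Sign convention:
  eigenvector signs are arbitrary, so PC1 can optionally be oriented by
  a per-frame scalar (`orient_by`, e.g. the gate distance — open frames
  then project positive); the fallback makes each component's
  largest-magnitude coefficient positive. Both rules are deterministic.

## Contact network analysis

- Contact: minimum heavy-atom distance < 4.5 Å (strict), evaluated with
  a per-frame k-d tree; sequence separation |i−j| ≥ 3 excludes trivially
  permanent neighbor contacts. Both values are parameters; the cutoff is
  the field's optimized convention and all heavy atoms are the most
  inclusive, testable atom set.
- Dynamic-contact interval is closed, [0.1, 0.9], and a pair qualifies
  if *either* condition is dynamic (the OR reading of "of each
  simulation"); the consensus threshold is inclusive (*p*c ≥ 0.9 in both).
- d*p*c is variant minus reference; net community differences sum d*p*c
  over masked (dynamic) pairs only, with intra-community sums reported
  under the diagonal. Summed over all community pairs including the
  diagonal, the nets equal the sum of all masked per-pair d*p*c — a
  conservation property the tests assert.
- **Community detection** is Girvan–Newman with exact edge-betweenness
  recomputation after each removal (betweenness and modularity from
  networkx; the removal loop, candidate collection and cut selection are
  implemented here). Ties in betweenness break toward the
  lexicographically smallest edge. Every partition along the dendrogram
  — starting from the connected components of the untouched graph — is
  scored with Newman–Girvan modularity on the original graph; the best
  cut wins (ties: fewer communities). This makes the stopping rule
  explicit where "Girvan–Newman plus modularity analysis" leaves it
  open, and is exact (verified against full partition enumeration on
  small graphs). Isolated residues remain as singleton communities.

## Kinetic fitting

All fits are unweighted nonlinear least squares (lmfit/Levenberg–
Marquardt); measurement scatter of the emulated instrument is ~5%
relative and near-homoscedastic on these scales, so weighting would add
parameters without information. Standard errors come from the estimated
covariance.

- **Transient:** A(t) = B·e^(−kobs·t) + C. Data-derived starting values
  (offset from the tail mean, amplitude from A(0) − C, rate from a
  log-linearized early segment) make convergence reliable from cold
  starts. A constant trace or a non-positive fitted kobs raises a
  model-mismatch error rather than returning a number.
- **Saturation:** kobs = kred·S/(Kd + S) + krev. Both nested models are
  fitted; the intercept krev is retained only when its 95% interval
  (±1.96 SE) excludes zero, implementing "not significantly different
  from zero" as a concrete rule. A Kd outside the sampled concentration
  range sets `Kd_reliable=False` instead of failing.
- **pH profiles** are fitted in log10 space — the slope +1/+2 language is
  log-linear, and log-space fitting weights the rising limb and the
  plateau comparably across the decade-scale range. One-pKa:
  y = C/(1 + 10^(pKa−pH)); two-pKa with both values constrained equal:
  y = C/(1 + 10^(pKa−pH) + 10^(2pKa−2pH)).
- **Michaelis–Menten:** kcat/Km and its error follow from the parameter
  covariance (first-order ratio propagation).
- Concentrations are molar internally; CSV readers convert mM/µM via an
  `S_unit` column or an explicit unit flag.

All fitters are exact (≤ 10⁻⁶ relative) on noise-free self-generated
data, invariant to row order, and agree with a refined grid-search
oracle within grid resolution.

## Mechanism inference

The derivation chain is pure algebra on the scheme relations (see
README): k5 from kcat and k3 (+ k4, default 0 since the measured
intercept is indistinguishable from zero), k1 from the reciprocal
difference of the two efficiencies, k2 from k1, k3 and kred/Kd. The
kred/Kd relation is the rapid-equilibrium form (Kd = k2/k1), the only
reading under which the full set closes on the measured inputs; the
steady-state form ((k2+k3)/k1) would make k2 negative for realistic
parameter sets with kred/Kd > kcat/Km. Feasibility (k3 > kcat,
kred/Kd > kcat/Km) is checked up front and violations raise named
errors.

Uncertainties propagate two ways: first-order delta method (central
finite differences of the closed forms) on the deterministic path, and
Monte Carlo (independent Gaussians truncated at zero, infeasible draws
discarded and counted, medians and central-68% half-widths reported).
Input errors are treated as independent — covariances between measured
parameters are generally unpublished — which likely understates the
derived uncertainties; this is a documented limitation. Reported values
round to 2 significant figures; raw values are retained in JSON.

Fold changes are reference/variant ratios of the raw derived constants,
with a 2-significant-figure rounding for reporting. Note that a ratio of
independently rounded constants can differ in its last digit from the
rounded ratio of raw constants; `MechanismComparison` keeps the raw
ratio so either convention can be recovered.

## Pipeline

The `run` subcommand executes simulate → conformational → dCNA →
kinetics → derive-rates from one YAML config. All method thresholds are
config defaults, never hard-coded in stages. Each run writes a manifest
with the seed, the full threshold echo, per-stage status and a SHA-256
checksum of every output; identical config + seed reproduces
byte-identical outputs (asserted in tests). Per-stage seeds are spawned
from the single config seed.

Default problem sizes (1000 frames per synthetic condition, 20,000
Monte-Carlo draws in the pipeline stage, 20 replicates in recovery
studies) were chosen so a full run completes in seconds while keeping
sampling errors a small fraction of the tolerances being tested.

## Known limitations

- The synthetic trajectory generator is a statistical mock (see above);
  it cannot validate superposition quality on realistically deforming
  structures, nor contact definitions against real side-chain packing.
- Girvan–Newman's dendrogram does not search all partitions; the
  modularity-maximum cut is exact only relative to that dendrogram
  (though it matches exhaustive enumeration on all tested graphs).
- pH-profile fitting assumes positive values (log space); profiles
  crossing zero require the linear-space variant, which is not exposed.
- The mechanism algebra assumes the oxidative half-reaction is fast and
  the reverse of flavin reduction negligible (k4 = 0 unless supplied);
  it does not fit the full two-substrate cycle differential equations.
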