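# Methods

This note records the models and conventions behind each analysis stage,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices a user may want to revisit.

## Structures and residue correspondence

All analyses operate on single-chain Cα traces (`StructureModel`): author
residue numbers, one-letter identities, coordinates in Å, optional
per-residue confidence read from the PDB B-factor column (pLDDT
convention). Only the first model/first chain of a file is read; alternate
locations resolve to the highest-occupancy conformer; non-standard residues
are kept with identity `X` so profiles stay index-complete.

Residue correspondence between models is never taken from raw numbering
(reference structures are often N-terminally truncated); it comes from a
global pairwise sequence alignment with BLOSUM62 and affine gap penalties
11/1. Percent identity is reported as matches over aligned (non-gap)
columns, to 0.1 — under this convention a pure truncation scores 100%.
These alignment settings are a declared convention: the proteins this
package compares are conformers or close homologs (≥ ~40% identity), where
the mapping is insensitive to the exact matrix and penalties.

## Per-residue Cα RMSD profiles

A profile is computed under **one global least-squares (Kabsch)
superposition** on all mapped Cα pairs, equal weights, followed by
per-residue Euclidean deviations in the mobile model's numbering. A
windowed or flexible fit would absorb exactly the rigid-segment motions
the profile is meant to expose. Unmapped residues are reported missing
(never zero). The superposition uses `scipy`'s `Rotation.align_vectors`
(proper rotation, det +1); the test suite checks it against a brute-force
rotation-grid oracle to < 1e-4 Å.

One consequence of a global equal-weight fit is load sharing: if a
fraction *f* of residues moves coherently, the fit assigns roughly *f* of
the motion to the static part. Profiles therefore show small nonzero
baselines on static segments whenever the mobile part is large; the
synthetic bundle keeps the mobile fraction at ~36% so that mobile and
static segments remain separated by the 2 Å threshold.

## Elastic similarity and cartography

The ensemble similarity score is a distance-matrix ("elastic") score over
the mapped residue pairs:

    S = Σ_{i<j} (θ − |d_ij^A − d_ij^B| / d*_ij) · exp(−(d*_ij / L)²),

with d the intramolecular Cα distances, d* their mean, θ = 0.2 (the
similarity threshold: pairs that differ by more than 20% of their mean
distance contribute negatively) and L = 20 Å (the envelope scale that
de-emphasises long-range pairs). Diagonal (i = j) terms contribute θ each.
Because all compared models are homologous conformers, the correspondence
comes from sequence alignment and no structural alignment search is
performed — this score variant is for *conformer* discrimination, not
remote-homolog detection.

Raw scores grow with the number of mapped residues, so the all-against-all
matrix is standardised Z-like, (S − m)/s, with the mean and spread fitted
on the input pool itself (optionally binned by aligned length when the
pool mixes sizes; a single bin is the default since conformer pools share
one sequence).

**Embedding.** The min-shifted similarity matrix is embedded by
correspondence analysis (SVD of the standardised residuals of the
row/column profiles); the first two principal coordinates are reported
with signs canonicalised (largest-magnitude coordinate positive per axis).
Classical (Torgerson) MDS on max−S is provided as an independent
cross-check and agrees in rank order (|Spearman| ≥ 0.95 in tests).

**State calls.** Each model's margin is
(s_OO − s_IO)/(s_OO + s_IO), computed after shifting similarities so that
the smallest entry of the two *anchor columns* is zero. Anchoring the
shift to the anchor columns (rather than the global matrix minimum) keeps
the margin calibrated when noisy conformer pairs dominate the matrix
minimum. The margin is ~affine in the transition coordinate (+1 at the OO
anchor, −1 at the IO anchor), so the default intermediate band of
δ = 1/3 makes the three calls coincide with the conventional thirds
partition of the transition; δ is configurable.

**Transition ordering** projects embeddings onto the OO→IO chord, ties
broken by similarity to the OO anchor.

## Residue-interaction networks

Nodes are residues; two residues at least 3 apart in sequence are in
contact when their Cα atoms are within 5 Å (configurable up to 8 Å). This
Cα proxy is a deliberate reduction: the package reads only Cα traces, so
heavy-atom contact definitions used by all-atom web services are out of
reach; cutoffs and strengths are therefore not numerically comparable
with those services, only structurally analogous. Interaction strength is
normalised per amino-acid type, I_ij = 100·n_ij/√(N_i·N_j), with N_x the
mean contact count of type x computed from the input pool itself (floored
at one contact so strengths stay in [0, 100]); edges below i_min = 3.0 are
pruned. Consensus networks keep edges present in ≥ 50% of an ensemble
(occupancy 1.0 degenerates to edge-set intersection). Communities are
connected components, with components above 30 nodes split by greedy
modularity maximisation — chosen for determinism over stochastic methods.
State comparison classifies edges OO-only / IO-only / shared and matches
communities across states by member-set Jaccard.

## Switch classification and epistasis

The switch readout is the **broad-scale deviation** (BSD): the fraction of
in-scope mapped residues (helix segments by default) whose deviation from
the native model exceeds τ = 2.0 Å. Verdicts: *switched* requires
BSD ≥ 0.25 **and** at least 4 signature segment-groups hit (a group is hit
when any member segment's mean deviation exceeds τ); *silent* requires
BSD < 0.05; anything else is *partial*. The default signature names the
carrier's co-moving blocks (h1b–h2N, h5–l5/6–h6a, l7/8–h8N, h9C–h10N,
h11C); for synthetic profiles the generator supplies its own signature
(its mobile helices). All thresholds are configurable and echoed in every
report; the numeric operationalisation of "broad-scale" and "partial" is
this package's convention — the underlying biology only distinguishes
qualitative classes.

Epistasis of a mutation pair is ε = bsd(A∪B) − bsd(A) − bsd(B), classified
cooperative (ε > 0.10), antagonistic (ε < −0.10) or additive. Suppressor
screens rank candidates by the drop in BSD they cause on an established
switched background.

The package does not run structure prediction. `emit_mutant_fasta` writes
mutant sequences plus a manifest whose predictor-settings column carries
the intended advanced-sampling configuration verbatim as metadata; mutant
models come back from the predictor (or, in tests, from the synthetic
response simulator).

### Mutation notation and the site registry

Tokens are `<wt><pos><mut>` (wild type validated against the template) or
`<pos><mut>` (wild type read from the template). Aliases expand
recursively through a registry-derived table; the bundled registry carries
the twelve synapomorphic sites of the Q5HQ64 carrier template with their
outgroup counterparts, from which the standard combination aliases (YN,
VY, VNT, VN, ANG, Ttg) are built. The six-site compound h3 alias
(GYGNGG = YN plus four h3 positions that are invariant glycines in the
orphan outgroup) requires the four G positions to be supplied by the
caller, since they are alignment-dependent; the defaults used in the
benchmarks (127, 133, 138, 141) are declared values bracketing the YN
pair, not literature-verified coordinates.

## Clade sequence analytics

**Patterns.** The PROSITE-like grammar supports literals, `[classes]` and
`x(m,n)` gaps. Matching is backtracking with gaps tried shortest-first, so
the reported first match is leftmost with minimal gap stretches. The test
suite proves behavioural equivalence with a regular-expression translation
on random patterns and on constructive expansions of the bundled MCg1
clade-diagnostic pattern.

**Rate shifts.** Per column (gap-majority columns skipped): type ii when
both groups are conserved at ≥ 0.9 (configurable) at different residues;
type i when exactly one group is conserved.

**Group-specific sites.** Two branches per column: a *harmony* branch —
1 minus the generalised Jensen–Shannon divergence (base 2, normalised by
log₂ k, pseudocount 0.5 per amino acid) between the k per-group residue
profiles — and a *relief* branch — nearest-hit/nearest-miss residue-match
weights, where each sampled sequence's nearest same-group and nearest
other-group neighbours (by whole-sequence mismatch count) vote on every
column, averaged over 100 seeded subsamples of half of each group. Both
observed scores are z-scored **per column against a group-label
permutation null** (100 random reassignments of sequences to groups;
relief nulls use 20 subsamples each for economy). A column whose residue
usage ignores the grouping scores like its own null (z ≈ 0); genuinely
group-distinct columns sit far outside it, which is what makes the
conventional dual selection thresholds (z-weight > 6, z-score < −10)
attainable and meaningful. Columns with > 50% gaps are never selected.

## Colocalization

The statistic is the mean over sites of the Cα distance to the nearest
other site. It was chosen over the all-pairs mean because evolutionarily
coupled site sets often form two or more tight clusters, which the
nearest-neighbour mean rewards and the all-pairs mean penalises; the
all-pairs mean is reported alongside. The null redraws same-size site sets
uniformly from the model's residues (without replacement within a draw;
draws identical to the observed set are rejected), and
p = (1 + #{null ≤ obs})/(n + 1). Calibration (uniform p under random site
sets) is verified by a KS test in the acceptance suite. No burial or
lipid-exposure weighting is applied.

## The synthetic rocking bundle

The generator emulates the *geometry of the readouts*, not carrier
physics. Eleven ideal α-helices (20 residues, 1.5 Å rise, 2.3 Å radius,
100°/residue) stand vertically at fixed xy positions; four of them — the
rocking bundle h1-h2-h6 plus the outer-gate helix h10, ~36% of residues —
form a rigid mobile arc that rotates 25° about the bundle axis and
translates 2 Å along it between the OO and IO anchors. Helix placement was
chosen so that (i) the residue-level contact differences between the
anchors are exactly the h1–h5 interface (OO-only) and the h10–h11
interface (IO-only), making the communities h1-h5-h8 and h6-h10-h11 each
fully connected in exactly one state, and (ii) after a global fit of one
anchor on the other, mean deviations are > 2 Å for every mobile helix and
< 2 Å for every static one. The generator verifies the planted contact
structure at build time and refuses to emit an ensemble that violates it.

Conformers at intermediate t are linear Cartesian interpolations of the
anchors plus optional isotropic Gaussian coordinate noise — adequate for
Cα-level statistics at 25° rotations, but not a physical trajectory
(torsion-space motion, loop remodelling and side chains are absent).
Ground-truth state labels follow the thirds convention (t < 0.33 OO,
t > 0.67 IO). Mutant "predictions" come from a response table mapping
label sets to target t values, with combination entries overriding
singles — this is what plants cooperative, antagonistic and suppressor
relationships; it contains no structural biology beyond that mapping.

Grouped MSAs: 3 groups of 11 sequences, 400 columns by default (the
realistic shape for within-clade representative sets of a transporter
family); background columns share one Dirichlet-drawn residue profile
across groups (concentration 0.5 over the 20 amino acids — moderately
conserved columns), planted type-ii and group-selective columns are
conserved at 0.95 within the relevant groups.

Because the generators plant exactly the signal each stage is built to
detect, passing tests demonstrates correctness of the computations and
recoverability of planted signal at the stated noise levels — not
performance on real predictor ensembles, where confidence varies along
the chain, loops move, and group structure is confounded by phylogeny.

## Known limitations

* Cα-only throughout: no side-chain contacts, no hydrogen-bond networks;
  interaction strengths are structural proxies.
* The elastic-score normalisation is pool-internal; scores are not
  comparable across pools and are not calibrated to any web service's
  Z-scores.
* Multiple flexible superposition is not implemented; multi-model figures
  are reproduced by superposing each model onto one designated reference.
* The group-specific-site scorer is a faithful-in-spirit reimplementation
  of the published harmony/relief approaches; exact numeric parity with
  the historical web servers is not promised (their subsample counts,
  pseudocounts and gap handling are unpublished).
* Remote database searches (pattern-seeded BLAST variants) are out of
  scope; the pattern matcher is local.
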