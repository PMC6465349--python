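# Methods

`ringdock` re-implements, as a reusable and testable pipeline, the
integrative-modelling procedure used to position a RING-domain E3 ubiquitin
ligase on the nucleosome surface from sparse experimental data: NMR
perturbation mapping of the binding footprint, a chemically observed
lysine-lysine crosslink, and mutagenesis-implicated basic residues on the
ligase. This note documents the models, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## Perturbation mapping

Chemical shift perturbations between a free and a bound titration point are
combined per residue as a weighted root sum of squares,

    CSP = sqrt( (w_H * d_H)^2 + (w_X * d_X)^2 ),

with w_H = 1 and w_X = 0.15 for the 15N dimension or 0.32 for the 13C
dimension, reflecting the relative chemical-shift dispersion of each
nucleus. Intensity ratios I_bound/I_free are optionally normalized by their
median so uniform dilution maps to 1. The combination rule is scale
covariant, so significance calls below are unaffected by the choice of
root-sum-of-squares versus an average of weighted magnitudes.

Significance is data driven: a background is estimated after one-sided
trimming of the `trim_fraction` (default 10%) most extreme values — the
high tail for CSPs, the low tail for intensity ratios, because each readout
moves in a known direction upon binding — and residues beyond one (two)
standard deviations from the trimmed mean are classed `one_sd` (`two_sd`).

One genuinely open choice is which set the SD is computed over. We default
to the full data (mean over the trimmed set, SD over all values): with a
half-normal background the trimmed-set SD yields thresholds near 1.1 and
1.5 background SDs and background false-positive rates of roughly 27% and
13% at the one- and two-SD levels, which would swamp any restraint set
derived from the calls. The full-data SD is inflated by the very effects
the classifier is meant to find, making it conservative; with the default
synthetic conditions it keeps two-SD false calls below 1% while retaining
>90% sensitivity. `SignificanceParams.trim_sd_on_trimmed=True` restores
the trimmed-set variant. Classification is exactly invariant under positive
rescaling of the data either way.

## Restraints

Active residues (significant perturbations on the receptor, mutagenesis
hits on the ligand) each define one ambiguous interaction restraint (AIR)
whose partner set is the actives plus passives of the other molecule.
Passives approximate the automatic convention of data-driven docking:
residues with fractional side-chain solvent accessibility >= 15% (atomic
areas by Shrake-Rupley with this package's united-atom radii, normalized by
the isolated-atom sphere area) and any heavy atom within 6.5 Å of an
active. The AIR acts on the r^-6-summed effective distance

    d_eff = ( sum_ij d_ij^-6 )^(-1/6)  <=  min_ij d_ij,

which is satisfied as soon as the active touches any allowed partner atom.
The effective-distance upper bound is 2.0 Å for all-atom structures; for
the coarse toy systems, whose residues are one or two pseudo-atoms and
whose closest clash-free approach is ~3 Å, the bound is set to the 5.0 Å
contact cutoff that also defines the true interface, so that a pose in
contact is a pose with zero restraint energy.

Restraint violations are penalized with a soft-square wall: flat to the
bound, quadratic (force constant 10 per Å², arbitrary units) for the next
2 Å, then linear with continuous value and slope. The linear tail caps the
force a far-from-satisfiable restraint can exert, so a ~10% admixture of
false-positive actives cannot drag the score minimum away from the basin
where the consistent majority is satisfied; with a pure quadratic the
minimum shifts by several Å under the same noise. The observed crosslink is
an unambiguous 28 Å Cα-Cα upper bound with the same wall. Random exclusion
of a fraction of AIRs is available behind a seeded flag and off by default.

## SASD

The solvent-accessible surface distance between two atoms is computed on a
voxel grid (default edge 1.0 Å, water probe 1.4 Å, 10 Å padding): a voxel
is blocked iff its center lies within atom radius + probe of any atom
center, and path lengths are found by uniform-cost search over the
26-connected accessible voxels with step costs {1, √2, √3}·voxel. Each
endpoint may enter solvent through any accessible voxel within 5 Å, paying
the straight entry segment; the reported SASD is the minimum of entry +
grid path + exit over all such voxel pairs (seeding only the single nearest
voxel can detour around the endpoint atom's own exclusion sphere and
overestimates unobstructed distances by up to twice the entry segment). An
endpoint with no accessible voxel within 5 Å is reported unreachable, not
an error. By the triangle inequality the measured SASD is never below the
Euclidean distance; grid discretization overestimates by at most ~8%
(26-connectivity) plus one voxel diagonal per endpoint. The radius table is
a coarse united-atom set (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20,
Zn 1.39 Å); SASD is grid-dominated, so refined radii change little.

Crosslinker arm length is never added: the standard compatibility bounds
for an amine-reactive bis-NHS ester crosslinker (30 Å prediction window,
35 Å rejection) apply to the Cα-Cα SASD directly.

## Docking

Rigid-body search: `n_trials` (default 500) placements of the ligand over
the centroid of the receptor actives at contact distance with random
orientation and in-plane jitter, each refined by a seeded stochastic
descent (`local_steps` moves of <= 2 Å / <= 10°, annealed, accepted on
score decrease), followed by a deterministic derivative-free (Powell)
polish of the top `polish_top` candidates that collapses each basin's
members onto its local minimum — without it, basin scatter of 2-5 Å leaves
the contact-based clustering with no coherent families. The score is

    total = w_air * E_AIR + w_xl * E_XL + w_clash * sum(overlap^2),

with overlap = r_i + r_j − 0.4 Å − d over inter-molecular heavy-atom pairs
and default weights (1, 1, 10): one Å of overlap costs one AIR force
constant unit, which is what actually prevents poses from threading into
the receptor; restraint bounds drive the geometry and absolute energies
only rank poses. All components depend only on interatomic distances and
are invariant under joint rigid motion.

Because the crosslink enters the score as a Euclidean bound while the
chemistry requires a surface path, candidates are walked from the top of
the ranking through a SASD filter (coarse 2.0 Å grid during the walk) and
rejected if any observed crosslink exceeds `sasd_reject` (35 Å;
unreachable counts as rejected), until `n_keep` (default 200) poses are
accepted; the best `final_sasd_top` poses are re-measured on a 1.0 Å grid.
Ranking is lexicographic in (total, E_AIR, trial index), and the whole
search is bitwise reproducible for a fixed seed.

## Clustering and the dominant cluster

Poses are compared by fraction of common contacts: the contact set is all
inter-molecular residue pairs with any heavy-atom distance <= 5.0 Å, and
FCC(A,B) = |A∩B| / min(|A|,|B|) — the min-normalization makes the measure
symmetric; the classical asymmetric form is available. Leader clustering at
FCC >= 0.75 with minimum cluster size 4; the representative of a cluster is
its best-scoring member. The *dominant* cluster is the one containing the
overall best-scoring solution (selection by size is available); on sparse
pseudo-atom contact sets the native family can split into subclusters while
a wrong family is internally tighter, so population alone is not a reliable
dominance criterion at this granularity.

## Validation read-outs

Hydrogen bonds: N/O(/S) donor-acceptor heavy-atom pairs across the
interface within 3.5 Å, with the D-H...A >= 120° criterion applied only
when explicit hydrogens are present; guanidinium and carboxylate groups are
treated atom-by-atom, so a bidentate arginine-glutamate pair reports each
contact. Catalytic geometry: Euclidean distance from the E2 catalytic
cysteine Sγ (residue 85 by default) to candidate target-lysine Nζ atoms,
per model with ensemble minimum and mean; a missing side chain (e.g. a
conformationally disordered tail lysine) falls back to Cα with a flag.
Crosslink compatibility: per-link SASD across a model ensemble plus the
complementary table of all predicted crosslinkable lysine pairs
(SASD < 30 Å). Conserved contacts: residue-pair contacts shared by at
least a conservation fraction (default 0.8) of an ensemble of homologous
complexes, mapped to a common numbering, emitted as residue-level pairwise
restraints; the threshold is a free parameter, and as it goes to 0 or 1 the
result approaches the union or intersection of the member contact sets.

Histone residue numbering differs between the fly, frog and human
conventions used across the experiments (e.g. fly H2B E110 is human E113,
fly H2A E60/D89/E91 are the human acidic-patch triad E61/D90/E92); the
structured cores align gap-free, so the maps are per-histone offsets with
explicit domains, and a residue outside the shared domain raises rather
than passing its number through.

## Synthetic study system

The toy complex stands in for the nucleosome-RING problem at desk scale: a
13x13x3 pseudo-atom slab (one CA-like atom per residue, 3.8 Å lattice,
0.2 Å jitter) with a three-column trench carved from the top layer whose
floor and walls are labelled glutamate (the acidic groove), and a 26-residue
ideal helix (CA + CB per residue) whose two groove-facing arginines are the
mutagenesis-analog actives. Two rim lysines near opposite trench ends and
two terminal helix lysines carry Nζ probes; the short-SASD pairs at the
planted pose (~15-25 Å) are crosslinkable, while the cross pairs (>40 Å)
violate the window. Placing the probes at the ends is deliberate: the
groove has an approximate end-to-end flip symmetry that footprint data
cannot break, and — exactly as in the real system — it is the crosslink,
through its SASD, that fixes the orientation. The planted pose is the
lowest clash-free drop of the helix into the trench, so it is clash-free by
construction; the true interface is the 5 Å contact set at that pose.

Synthetic observables: interface residues draw |N(mu, sigma)| with
mu = 0.10 ppm, background |N(0, sigma)| with sigma = 0.02 ppm (effect size
five noise SDs); a fraction rho of false-positive actives — expressed
relative to the size of the true footprint, so rho = 0.1 means one planted
false active per ten true ones — is swapped in from the background.
Titration series use the exact two-state binding quadratic for the bound
fraction under fast exchange. Every generator is a pure function of seed
and parameters and records a manifest sufficient for exact regeneration.

The headline experiment (`ringdock.experiments.run_recovery_trial`)
regenerates the toy, classifies a rho = 0.1 perturbation table, builds
AIRs, adds the one drawn crosslink, docks, clusters, and asks whether the
dominant-cluster representative lies within 5 Å ligand-RMSD of the planted
pose; the negative control scrambles the actives to a far surface patch
and replaces the crosslink with a window-violating decoy. The standard
experiment scale is 300 trials with 150 kept poses over five seeds (plus
three control seeds); a single run takes well under a minute on one CPU.
Note that the score landscape's minimum nearest the planted pose lies
~3.2 Å from it (polishing the planted pose itself relaxes there): with
one/two-atom residues, only two ligand actives and capped false-positive
drag, ~3 Å is the intrinsic resolution of the toy restraints, and recovery
should be read against the 5 Å criterion, not as sub-Å precision.

What the toy does not emulate: all-atom packing and side-chain chemistry,
flexible or solvent refinement of interfaces, realistic NMR observables
(line shapes, exchange broadening, assignment ambiguity), MS identification
noise, and the size and composition of a real nucleosome (DNA, four histone
types). Passing the synthetic tests therefore demonstrates the correctness
and identifiability of the pipeline's logic under its stated noise model,
not the accuracy of any particular biological model; analyses of deposited
integrative models (crosslink SASD statistics, catalytic-geometry
distances) require those external coordinate archives as inputs.

## Degenerate inputs and tie-breaks

Fewer than five values refuse threshold estimation; fewer than three or
collinear points refuse superposition. Alternate locations keep the
highest-occupancy conformer. Empty AIR partner sets are an error, an active
with no possible passive keeps a partner set of actives only. Leader-
clustering ties (equal neighbor counts) break toward the better-ranked
pose; pose-ranking ties break by (total, E_AIR, trial index). Zero or
negative free peak intensities mark the residue missing rather than
producing an infinite ratio. An empty docking ensemble (all poses
SASD-rejected) is returned with rejection statistics, not raised.
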