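# Methods

## The model

DNA is a bead–spring polymer: beads of diameter σ = 10 nm (29.4 bp at
0.34 nm/bp), FENE backbone springs (k = 30 k_BT/σ², R₀ = 1.5 σ) with the
purely repulsive WCA core folded into the bond potential, Kratky–Porod
bending energy κ(1 − cos θ) per bond angle, and WCA excluded volume between
all non-bonded particles. κ = 5.51 k_BT is fixed by the discrete-chain
relation l_P = −σ̄/ln⟨cos θ⟩ with ⟨cos θ⟩ = coth κ − 1/κ, which puts the
persistence length within 1% of the 50 nm of double-stranded DNA at the
measured mean bond length (0.97 σ).

DNA-binding proteins (cohesin-like bridges) are diffusing spheres of the
same diameter carrying up to `valence` simultaneous bonds to chain beads
(2, 3 or ~10). A bond is a harmonic spring (k = 30 k_BT/σ², rest length
1 σ) plus a binding energy −ε, default ε = 4 k_BT — the middle of the
3–5 k_BT range over which bridging-induced phase separation is predicted
to operate. Bonds are created and deleted by a Metropolis sweep every 20
integration steps: each (bridge, bead) pair — every existing bond plus
every unbonded bead within the capture radius r_b = 1.5 σ — is *toggled at
most once per sweep*, with acceptance min(1, e^(−ΔE)). The single-toggle
rule matters: attempting deletions and creations as separate passes lets a
bond be deleted and immediately re-created within one sweep, and the
resulting chain does not sample the Boltzmann measure (we verified the
implemented scheme against exact enumeration of the bond-set partition
function for a frozen configuration at ε = 0). The valence cap is enforced
as a hard constraint and asserted after every sweep. A bond stretched
beyond r_b can still be deleted (reversibility at the capture boundary is
only approximate; the harmonic energy at r_b is 3.75 k_BT, so such states
are rare).

Bridge number is fixed at 0.2 per chain bead and the periodic box is
scaled so the bridge concentration is constant across chain lengths,
2×10⁻⁴ σ⁻³ ≈ 0.33 µM — the physiological scale for cohesin.

## Integration

Overdamped (Brownian) Euler–Maruyama in reduced units (σ = 1, k_BT = 1,
friction γ = 1, so D = 1 and time is measured in bead diffusion times τ_B).
Two deliberate numerical choices:

- **Bounded uniform thermal kicks.** The noise increment is uniform on
  [−√(6Δt), +√(6Δt)] (variance 2DΔt), not Gaussian — standard practice in
  Brownian/Langevin integrators, since only the first two moments of the
  increment survive in the diffusion limit. Together with the cap of 0.1 σ
  per component on the deterministic displacement this makes FENE
  overstretch impossible by construction: near maximum extension the
  restoring displacement saturates the cap while the opposing kick is
  bounded below it.
- **Two timesteps.** The stiff part of the force field is the bonded
  WCA+FENE well (curvature ≈ 800 k_BT/σ²). Δt = 2×10⁻⁴ τ_B reproduces the
  two-bead bond distribution to ~6% in SD and the worm-like-chain
  ⟨R²⟩ to 2%; Δt = 5×10⁻⁴ τ_B inflates the bond SD ~50% and biases ⟨R²⟩ by
  −7%, a *length-independent* factor that cancels in log–log slopes.
  Precision statistics (persistence length, MSD, the phantom-chain
  control) use 2×10⁻⁴; cluster production runs use 5×10⁻⁴.

Pair interactions use a Verlet list (skin 0.7 σ, chosen after profiling:
dense condensate states are rebuild-dominated at smaller skins) over a
stamped linked-cell grid; cells are sized to cover both the pair-list
range and the capture radius so the binding sweep reuses them. Positions are kept wrapped with per-particle image counters inside
the compiled chunk and returned unwrapped. New configurations are
noise-free steepest-descent relaxed (displacement-clamped, FENE clamped)
to remove construction overlaps before dynamics.

## Cluster observable and the scaling experiment

A cluster is the connected component over *bridge-mediated* adjacency:
registered bonds and bridge–bridge proximity < r_c connect (default
r_c = 2.5 σ); an unbonded bead within r_c of a bridge joins as a member
but does not transmit connectivity. Bead–bead proximity never links (the
backbone would make the whole DNA one trivial component), and bead-transit
is excluded because it chains independently bound single bridges along a
stiff sub-critical rod into one spurious "cluster" — experimentally such
molecules are separate AFM grains. The observable is the radius of
gyration of the largest cluster (beads and bridges, equal weights).

Cluster formation is nucleation-limited: started from a random coil with
uniformly scattered bridges, desk-scale runs stay in the dispersed
metastable state for hundreds of τ_B. The production protocol therefore
measures the condensate *from the condensed side*: the chain is sampled
inside a sphere at 10% volume fraction (never tighter than the stiffness
allows) with bridges placed a few σ from the chain, and relaxed for
max(1.2×10⁵, 500·N) steps; the first half of each run is discarded and
the median largest-cluster R_G over the tail is recorded. A valence that
cannot sustain a condensate disperses from this start — that is a result,
not a failure of the protocol. Chain lengths are 14–453 beads
(0.4–13.3 kbp); the deep sub-critical lengths (14–34 beads, matching the
0.1–1 kbp molecules used experimentally for the constant regime) start
from the equilibrium coil instead — below l_C thermal looping is
impossible, and seeding a compact state there would manufacture the very
clusters whose absence is the prediction. The power law is fitted
(log₁₀–log₁₀ least squares) over lengths above the critical looping
length l_C = 2π²l_P ≈ 2903 bp ≈ 99 beads; 10 replicates per length;
medians over replicates.

At these parameters the valence-3 and valence-10 condensates are stable;
valence-2 clusters assemble and dissolve intermittently (largest-cluster
bead fraction fluctuating ~0.1–0.5) for ε anywhere in 4–6 k_BT and capture
radii 1.5–2.2 σ. The single-bond registry evidently lacks the effective
multi-bead attraction that patch potentials provide, so the bivalent
exponent is reported as measured rather than forced.

The phantom control (no excluded volume, no bridges) exploits the fact
that the initial-configuration sampler draws bond angles from the exact
Boltzmann distribution: each replicate starts in equilibrium, is
integrated briefly, and contributes one R_G sample; the ensemble mean per
length enters the fit. Over the chosen decade (150–1219 beads, 30–240
persistence lengths) the worm-like-chain finite-length correction to the
ideal-polymer slope 0.5 is ≈ +0.02.

## In-silico Hi-C

Contact maps are snapshot averages of the indicator d(i,j) ≤ r_c
(r_c = 2.5 σ, KD-tree with periodic boundary), first half of each
trajectory discarded. Compartment strength follows the standard Hi-C
recipe: observed/expected normalisation by the mean contact frequency at
each separation, Pearson correlation matrix, partition by the sign of the
leading eigenvector, score = mean within-block minus mean between-block
correlation, clipped to [0, 1]. Compartment experiments use a chain with
alternating sticky/neutral 20-bead blocks (only sticky beads bindable),
because checkerboards require binding heterogeneity.

## Fluorescence-trace procedures

- **Kymograph**: per frame, sum of 11 pixels perpendicular to the DNA
  line at each position, 2-D median-filtered background (21×21 default)
  subtracted, profile normalised by its frame maximum (zero-max frames
  guarded).
- **Cluster size in kbp**: (background-subtracted ROI / whole-molecule
  intensity) × 48.5 kbp; frames with non-positive totals are masked.
- **Compaction time**: Savitzky–Golay smoothing (window 250 points,
  polynomial order 2 — the lowest order that preserves ramp curvature;
  window shrunk to the trace length when needed), plateau = mean of the
  final 20%, baseline = mean of the first 5%, compaction time = first
  5%-crossing to first subsequent 95%-crossing. A trace whose tail still
  drifts by >10% of the amplitude is rejected.
- **Exponential fits**: single-exponential nonlinear least squares
  (trust-region, τ > 0), τ SD from the covariance; a warning if the trace
  spans less than one fitted τ.
- **Step finding**: exact dynamic-programming segmentation (minimum
  within-plateau SSE for each step count k), noise variance estimated
  robustly from the MAD of first differences, k chosen by the penalised
  cost SSE(k) + k·β with β = 3σ²(ln n + 2) (a Yao-type BIC with a safety
  factor for the optimised break positions), and the chosen staircase
  accepted only if a counter-fit with steps at plateau midpoints is worse
  by a χ² ratio > 1.5. On traces short enough for exhaustive enumeration
  the DP segmentation is bit-identical to brute force.

## AFM procedures

Polynomial background removal with iterative grain masking (pixels above
mean + 2 SD of the residual are excluded from the next fit). Grains are
8-connected regions above a height threshold (default 3× the robust field
noise SD; regions under 4 px discarded as speckle); volume = Σ height ×
pixel area. Single-molecule threshold = mean + k·SD of the single-complex
volume distribution (k = 7); stoichiometry = floor(cluster volume /
single-complex volume) — floored because a partial volume cannot be a
complex. Bridging classification: a protein centroid contacts every
contour segment within the contact radius; it bridges iff two contacted
arc positions are separated by more than 4× the contact radius.

Circularity 4πA/P² uses the marching-squares contour of a lightly smoothed
mask (Gaussian, 2 px): raw pixel-level contours overestimate a disk's
perimeter by ~5%, biasing circularity to ~0.89; with smoothing a 50-px disk
scores 0.999 and a 2:1 ellipse 0.840 against the elliptic-integral value
0.8412.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`), bit-reproducible, and
attach the full ground-truth parameter set. Noise is additive Gaussian
everywhere; EMCCD/Poisson statistics, optical drift and AFM tip
convolution are deliberately out of scope, so a green recovery test
establishes estimator correctness under the stated noise model, not
robustness to instrument systematics. The bleaching-staircase dwells are
exponential (memoryless photobleaching) truncated below at 10 frames at
the default sampling of 50 frames per mean dwell, so that every generated
event is resolvable — at 30%-of-step noise, two same-direction steps
closer than ~6 frames are information-theoretically ambiguous.

## Known limitations

- The bivalent-bridge condensate is marginal in the bond-registry model;
  its scaling exponent at desk scale does not reproduce the experimental
  0.45 (see the scaling section above).
- Production runs measure a relaxed condensed state, not a two-sided
  equilibrium bracketing; coarsening from dispersed starts is
  logarithmically slow and unreachable at desk scale.
- No hydrodynamics, no ATP-driven loop extrusion, no topological loading.
- The in-silico Hi-C block pattern (20-bead alternating) is an assumption;
  compartment scores depend on it quantitatively, though the
  valence ordering does not.
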