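# Methods

`conformosort` re-creates, at desk scale and against an exactly known ground
truth, the computational chain by which coexisting ATP-bound conformations of
a double-ring chaperonin (the GroEL system) can be resolved from side-view
single-particle cryo-EM images: simulation of a multi-conformer particle
stack, CTF handling and band-pass preprocessing, eigenimage-guided sorting
with competitive multi-reference alignment, C7-symmetric Fourier
reconstruction with split-half FSC, hinge-constrained multi-domain map
fitting, and quantification of domain rotations and salt-bridge switching.
This note records the models, the parameters that matter, the numerical
choices, and the known limitations.

## The phantom

The ground truth is a pseudo-atomic caricature of the chaperonin, not a
crystal structure. Each subunit is three point clouds (equatorial,
intermediate, apical domain; ~135 pseudo-atoms in total per subunit, unit
mass each) plus short helix-like runs (helices H, I, K/L, M, and the lateral
β-sheet edge) and one designated marker pseudo-atom per salt-bridge residue
(R197, E386, K80, E255, E257, K207, K242, K245, D83, K327, A109, R452, E461,
V464). Cloud lattice points carry a seeded sub-lattice jitter so the density
has internal texture at the resolution scale, as real protein does; a
perfectly homogeneous blob would make sub-pixel domain motions nearly
invisible in projection. Fourteen subunits form two staggered back-to-back
rings (C7, stagger 360/14°; the back-to-back flip is the proper rotation by
π about x, so chirality is preserved). Total height ≈ 134 Å, diameter
≈ 90 Å — GroEL-like proportions.

A conformational state is a set of rigid motions applied in a fixed order:

1. equatorial pivot about the inter-ring contact (tangential axis through
   the contact point at the ring interface) — equatorial domain only;
2. en-bloc tilt of the intermediate+apical block about hinge 1 (radial axis
   at the equatorial–intermediate boundary);
3. elevation of the apical domain about hinge 2 (tangential axis at the
   intermediate–apical boundary, carried along by the tilt);
4. outward radial shift of the apical domain along its current radial axis;
5. twist of the apical domain about that axis through its center of mass;
6. optional whole-ring rotation about the symmetry axis.

The canonical library pins the quantitatively stated motions: the T→Rs1
transition is a 35° en-bloc tilt; the apical domain elevates a further 20°
from Rs2 to the Rs-open state; Rs-open has completed 70% of the final
elevation; the last step to the GroES-accepting R-ES dome is a ~100° apical
twist. The end-state elevation is anchored at the crystallographically known
~60° upward swing of the apical domains, which together with the 70% and
20° constraints pins Rs-open at 42° and Rs2 at 22°. The double-ATP (Rd)
ladder uses smaller elevation/twist steps (10–12.5°, 0–27°) with a larger
equatorial pivot (22°), matching the observation that the double-ring states
move in smaller increments with an expanded equatorial ring.

Marker positions were solved numerically at design time (and then frozen as
constants) so the canonical states reproduce the contact bookkeeping used to
fingerprint states in density maps, with margin about the 8 Å cutoff:

* T: R197–E386 and E255–K207 formed, everything else open;
* Rs1/Rs2: K80–E386 and E255–K245 formed (the tilt swaps E386's partner
  from R197 to K80 and moves E255 from K207 to K245);
* Rd1 → Rd2/Rd3 → Rd4/Rd5: the click-stop ladder 255–245 →
  255/257–245 → 255/257–245/242, with K80–E386 never formed (the expanded
  equatorial ring);
* open states: all apical intersubunit contacts broken.

The equatorial pivot for the single-ATP states (9.094°) is calibrated so the
T→Rs1 transition lengthens the A109–A109 inter-ring contact by exactly
2.0 Å. The intrasubunit D83–K327 pair is placed so its separation runs
≈ 9.0 / 11.3 / 16.1 / 36.0 Å through T / Rs1 / Rs-open / R-ES,
approximating the printed Cα-separation trajectory (8 / 12.4 / 15.7 / 36 Å)
of the real molecule.

## Image formation

Maps are sums of isotropic Gaussians (one per pseudo-atom, integral = mass
weight) whose Fourier amplitude falls to 1/e at the nominal resolution;
every density used anywhere in the package — phantom volumes, matching
templates, the model density inside the fitting score — comes from this one
kernel, so a model scored against a map synthesized from itself is exactly
self-consistent. The desk-scale default is 64³ voxels at 4 Å/voxel and 9 Å
nominal resolution (the study's ATP maps are 8–9 Å); the paper-scale
geometry (192², 2.02 Å/px) remains available through the configuration.

Projections are line integrals along the viewing axis; Euler angles are
intrinsic ZYZ in degrees with the final Z as the in-plane rotation.
Simulated particles are side views (tilt uniform in 80–100°, azimuth and
in-plane uniform), shifted by ≤ 3 px, CTF-modulated (weak-phase model,
120 kV, 0.7–3.5 μm underfocus, 7% amplitude contrast), and carry white
Gaussian noise scaled so that signal variance / noise variance inside the
particle-radius mask equals the requested SNR. The particle radius is the
model circumradius plus the kernel reach (≈ 86 Å). All ground truth is
recorded per particle.

## Preprocessing and sorting

Particles are phase-flipped (sign of the CTF; no amplitude restoration),
band-pass filtered (175 Å – just above Nyquist, raised-cosine edges two
Fourier pixels wide), normalized to zero mean and unit background variance
outside a 0.4-box-radius mask, and centered by translation against the
stack mean.

Eigenimage analysis is plain PCA on pixels of the aligned stack.
Components whose power concentrates in the apical bands of a side view
(≥ 50% inside the mask) are treated as conformational; k-means (fixed seed)
on the selected coordinates partitions the stack. Because a top-bottom
pseudo-symmetric reference cannot distinguish a view from its flip, the
blind initialization does a two-level sort: a k = 2 split that separates
the two flip families (whose orientations are then made consistent by
comparing each subgroup reconstruction with the unliganded reference), then
the conformational split, over-partitioned two-fold with the most mutually
distinct subgroup maps kept as seeds.

Competitive alignment matches each particle against reprojections of every
reference over one azimuthal asymmetric unit (51.43°) of side views:
a low-passed coarse scan over the template bank (shift-tolerant), then a
per-reference local refinement on a fine grid (2.57° azimuth / 2.5° tilt /
3° in-plane) with full small-shift correlation and sub-pixel (parabolic)
peak interpolation, with template spectra weighted by the particle's |CTF|
envelope (matched filtering). Both tilt lobes of the flip ambiguity are
refined per reference, and a derived mirror test resolves the lobe. The
state decision is made at a common orientation — every reference scored at
the winner's (azimuth, tilt, in-plane) with its own sub-pixel shift
optimum — so noise overlapping the structure shared by all states cancels
in the score differences. Class references are then re-reconstructed and
the loop repeats until the moved fraction falls below the stability
tolerance (default 1%) or the iteration budget is reached. Rebuilt
references are damped (default: 70% previous reference, 30% new map,
scale-matched) and rebuilt from each class's highest-margin half, both of
which suppress the class-bleeding feedback in which blended references
attract each other's particles — the desk-scale incarnation of the drift
the original study caught by comparing asymmetric reconstructions at
different iteration numbers. The per-iteration movement history is always
returned so callers can detect it.

## Reconstruction, FSC, filtering

Reconstruction is direct Fourier inversion. What is gridded is the
transform of the centered object (a checkerboard phase on the image FFT),
which is smooth across Fourier voxels, deposited with a separable
Kaiser-Bessel-style kernel of width 3 alongside a weight volume; recorded
shifts are undone by phase ramps during insertion; C7 symmetry is imposed
by averaging the data and weight volumes over the seven rotations about the
polar axis before normalization; voxels never touched by a slice stay zero.
Resolution is the 0.5-crossing (linear interpolation between one-voxel
shells) of the FSC between soft-masked (0.45-box radius, 5-voxel cosine
edge) even/odd half-set reconstructions. The final amplitude filter
multiplies amplitudes at wavelengths beyond 20 Å by 0.1 and rolls off
beyond 8.5 Å, correcting the over-representation of low frequencies.

A note on symmetrization: a grid-sampled map cannot be exactly invariant
under a rotation by 360/7° (not a grid symmetry), so the C7-invariance and
idempotence properties hold only to interpolation accuracy (~a few percent
RMS on sharp maps), and the tests assert them at that level.

## Fitting

Flexible fitting is deterministic: the model is partitioned into named
rigid groups connected by hinges forming a tree rooted at the equatorial
domain (presets: two-body; three-domain; six-body with helix I, helices
K+L and the lateral sheet free; and the full state parameterization with
the equatorial pivot, both hinges, and the apical radial slide). Scoring
is the normalized real-space cross-correlation between the map and the
model's synthesized density over voxels within 6 Å of any atom, with the
posed subunit replicated C7 and the unliganded opposite ring included as
static context. Refinement is cyclic per-hinge line search (coarse scan,
then bounded local search), preceded when requested by a joint coarse grid
over the tilt/elevation pair — those two hinges share a mirror basin that
one-at-a-time scans jump between — and finished by a short simplex polish
over all angles; every update is accepted only if it improves the score,
so the correlation history is monotone and connectivity is exact. On
noise-free maps of canonical states the full parameterization recovers all
four state parameters to three decimal places (correlation 1.0000).

The C7 ring rebuild replicates a fitted subunit about the symmetry axis;
optionally the lateral β-sheet edge atoms are snapped back to their
reference geometry expressed in the neighboring subunit's fitted equatorial
frame, restoring the intersubunit contact exactly, and the minimum
intersubunit atom distance is reported as a steric check.

## Quantification

Domain motions are measured by least-squares (Kabsch) superposition of a
domain's pseudo-atoms between frame-aligned models, reported as axis/angle
plus the center-of-mass translation — exact for rigid motions, and
group-consistent under composition to 1e-6. Frames are aligned either by
superposing the nucleotide-free rings or by the closed-form Z-rotation that
best aligns per-subunit centers of mass. Contact tables hold the mean and
spread of each marker-pair distance over the seven subunit pairings
(intersubunit partner: the next subunit anticlockwise viewed from outside
the top ring; inter-ring pairings: nearest neighbor across the staggered
interface), with contacts beyond 8 Å counted broken, and the nearest
signature by Hamming distance assigns the state (ties — Rs1/Rs2, Rd2/Rd3,
Rd4/Rd5, which share signatures by construction — are returned as tied
sets, never guessed).

## The flagship benchmark and what it shows

The default end-to-end run sorts 500 particles per state of
{Rs1, Rs2, Rs-open over a T ring} at SNR 0.1 (64-px boxes, CTF applied,
seed-reproducible), with competitive alignment seeded from maps of the
configured state library; the blind two-level eigenimage initialization is
available as `reference_mode="msa"`. The run completes in under ten
minutes on one CPU and reports the confusion matrix, per-class FSC
resolutions, the recovered hinge angles against generator truth, and the
contact/state tables.

Its headline limitation is per-particle assignment accuracy at SNR 0.1.
With exact orientations the three states separate almost perfectly
(a matched-filter oracle at true angles and shifts reaches ≈ 96%), but at
desk scale (64-px images, ≈ 2 000 signal-bearing pixels) the per-particle
orientation estimate carries several degrees of noise-driven scatter, and
scoring states at an erroneous orientation attenuates exactly the
high-frequency density differences that distinguish them. Cross-correlation
classification — maximum-likelihood orientation marginalization is
deliberately out of scope — therefore plateaus near 75–80% one-shot
accuracy, and iterative reference rebuilding cannot exceed it. Passing
per-operation tests (alignment, eigenimage analysis, reconstruction,
fitting, quantification are all verified against oracles or exact ground
truth) therefore says the machinery is correct; the end-to-end accuracy
says how much information desk-scale images at this SNR actually carry
through this estimator, not what the method would achieve at the original
data's scale.

What the generator does not emulate: colored noise and ice/background
gradients, astigmatism, beam-induced motion, particle-picking errors, and
micrograph-level context; conclusions about those require real data.

## Problem sizes

Default test-suite and analysis sizes were chosen so the whole suite and
the acceptance script each complete comfortably on a single CPU: 48–64
voxel grids, 9 Å maps, stacks of tens to hundreds of particles for unit
and property tests, 1 500 particles for the flagship, 20 random
configurations for fitting parameter-recovery, and 6–8 bootstrap
replicates for the asymmetric-reconstruction null.
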