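# Methods

This note records the models, defaults and design choices behind
`petregu`, and what the synthetic setting does and does not establish.

## The phantom and what it emulates

All experiments run on a parametric digital head phantom (nested
ellipsoids; everything scales with the grid's physical extent so the same
anatomy renders at any resolution). Default PET grid: 64×64×48 voxels at
2 mm; the T1w-like image is rendered from the same geometry at half the
voxel size (1 mm) with additive Gaussian noise at 1% of the WM intensity.
The parcellation provides the nine analysis ROIs used throughout — three
cingulate patches (ACG/MCG/PCG), hippocampus (HPC), precuneus (PRC),
parietal (PRT) and temporal (TMP) patches, and cerebellar grey and white
matter (CRB GM / CRB WM) — spanning ~100 to ~2000 voxels, because
registration uncertainty is strongly ROI-size dependent.

Three anatomical features are deliberate:

* **Longitudinal fissure.** A midline CSF groove anchors in-plane
  rotation. Without it the smooth ellipsoidal cortex leaves the
  transaxial rotation almost unconstrained by NMI (1–3° residuals
  independent of count level), which drowns every count-level effect in a
  rotation-noise floor. Real brains have this anchor; the phantom needs
  it for the same reason.
* **Precuneus target patch**: a thick (8.5 mm) cortical patch bordered by
  skull/CSF on its outer face — it loses signal to cold neighbours when
  grey and white matter have equal activity.
* **Cerebellar reference shell**: a thin (4 mm) GM shell over cerebellar
  WM — it is suppressed by resolution when GM≫WM contrast exists, and
  protected (same-valued neighbours) when contrast is lost. The shell
  thickness was chosen by noiseless mapping of the partial-volume
  mechanism (3.5–5 mm all give the correct directions; 4 mm balances the
  margin against voxel-scale thinness at 2 mm).

Tissue activities per frame (arbitrary units, CSF fixed at 5% of WM):
early frames 1.8/1.0 (GM/WM, flow-like, identical for both amyloid
statuses); late negative 2.2/1.0 (high contrast); late positive 1.0/1.0
(contrast lost). Each frame is calibrated so its noiseless forward
projection totals the frame's expected counts (default 2×10⁶ late,
1×10⁶ early — desk-scale counts chosen so a 5% bootstrap is distinctly
noisy while a full suite stays within minutes). μ-values: soft tissue
0.0096/mm, bone 0.0151/mm at 511 keV.

## Simulation model

Parallel-beam, slice-stacked geometry (56 angles over 180°, radial bin
width = in-plane voxel size). The projector is built once as an explicit
sparse matrix, so forward and back projection are exact adjoints — the
matched-operator contract OSEM relies on, and the reason noiseless
reconstructions converge to the true regional means. An isotropic
Gaussian resolution kernel (default FWHM 2.0 mm) is applied in image
space inside the operator; with the kernel inside the matched pair, EM
also deconvolves it, so the default is kept small — a wide kernel makes
20-iteration regional recovery unattainably slow, and in this study the
dominant smoothness of the registration images comes from early-stopped
OSEM (1–3 iterations), not the detector. Scanner geometry beyond this
(cylindrical 3D sampling, gaps, dead time) is out of scope: the analysis
concerns how noise propagates through registration, not the scanner.

Expected prompts per bin are `a·(Ax) + s + r`: attenuation factors are
exact line integrals of the μ-map; scatter is a broad Gaussian blur
(FWHM 10 radial/axial bins) of the trues scaled to a fraction (default
0.15) of total prompts; randoms are uniform (default 0.15). Events are
Poisson draws expanded to a shuffled list-mode stream; the bootstrap
draws `round(f·N)` events with replacement — so a 100% "replicate" is
still a new realisation, matching the nonparametric bootstrap.

## Reconstruction

Standard OSEM with angle-interleaved subsets (default 14), uniform
positive initial image inside the inscribed-cylinder field of view, and
additive terms in the denominator of the multiplicative update. Modes:
NAC (no attenuation, no scatter), AC (attenuation only), QNT (attenuation
plus scatter); randoms are corrected in every mode. The data-driven
scatter estimate is a broad blur of the randoms-subtracted prompts scaled
by a fit on tail bins (attenuation factors ≥ 0.995, i.e. lines that
barely graze the object); the amplitude is fitted on the *unclipped*
residual because clipping first biases the tail sum upward under Poisson
noise. A 1 mm output voxel is produced by splitting each reconstructed
2 mm voxel into eight equal children, without interpolation.

The registration images use 1–3 iterations (the study grid); the fixed
quantitative PET used for SUVr uses QNT at 4 iterations with the
simulator's known scatter/randoms expectations scaled to the count level
— quantification is deliberately reconstructed more fully corrected and
further converged than the registration images.

## Registration

Rigid transforms are parameterised as three translations (mm) and three
intrinsic x-y-z rotations (degrees) about the fixed image's world centre
(rotating about the centre avoids conflating rotation with large
translations); matrices map moving world coordinates onto fixed world
coordinates. MR mispositioning draws each parameter from
Uniform(−10, +10) (mm or degrees) and pre-multiplies the image affine,
leaving voxel values intact.

The in-repo engine maximises NMI — (H(F)+H(M))/H(F,M) over a 64-bin
joint histogram restricted to voxels positive in both images — by
Powell's direction-set method over three resolution levels (decimation
4/2/1 with matched Gaussian pre-smoothing), trilinear interpolation,
ftol 10⁻⁴, at most 2000 evaluations per level. Millimetres and degrees
are treated as commensurate parameter units. The engine never returns a
pose worse than its initialisation (the best-seen pose is kept), and an
exhausted evaluation budget marks the result non-converged; non-converged
replicates are excluded from Dice distributions and counted, never
raised, since a failure is itself a finding. Any external tool exposing
`register(fixed, moving, init)` can replace the engine; none is required.

Label propagation is nearest-neighbour resampling of the MR-space
parcellation (the PET parcellation voxel-split to the 1 mm T1w grid).

## Uncertainty quantification

Per design cell, Dice is computed against the reference parcellation
propagated with the gold-standard registration — the full-count,
unperturbed AC reconstruction registered once per frame and engine. SDs
use the n−1 denominator throughout. Cell tables flag the per-frame
minimum-SD cell and the cells statistically indistinguishable from it by
Brown–Forsythe at α = 0.05 (pooled per-ROI-centred samples; median
centring is what distinguishes Brown–Forsythe from mean-centred Levene).
ROI averages are unweighted means over the nine ROIs.

SUVr propagation samples one fixed quantitative PET per frame with each
replicate's propagated ROIs, so the reported CoV isolates registration
imprecision from PET noise in the target image. PVC is iterative Yang
(default 5 iterations, relative-change stop 10⁻⁴, isotropic Gaussian PSF
default 4.5 mm): each iteration rebuilds a piecewise-constant synthetic
image from current regional means and multiplies the PET by
synthetic/smoothed-synthetic. The PVC *direction* property (target SUVr
down for the high-contrast late-negative frame, up for the contrast-less
late-positive frame) is assessed on the reconstruction of expected
(noise-free) 30%-level data: it is a resolution/contrast mechanism with
noiseless margins of −0.07 and +0.08, while a single Poisson realisation
at desk-scale counts adds a ±0.05 scatter to the shift — a one-draw
direction assertion would test the realisation, not the mechanism. The
CoV comparisons always use the noisy end-to-end pipeline.

## Orchestration, seeds, problem sizes

Every cell derives its seed as a 31-bit hash of (root seed, cell
identity); no global random state is used, so runs are deterministic,
order-independent and resumable (finished cells are reloaded from their
JSON records). The enumerators list design cells explicitly and reproduce
the full design's bookkeeping: 600/1800/1200/3000 images for the
reconstruction-parameter analysis and 800/2400 for the count-level
analysis.

The shipped reduced profile (`desk_design`) uses one late frame, AC mode,
2 iterations, levels {15%, 60%}, 3 bootstraps on a 48³ phantom — the
scale at which a determinism check (two cold runs, byte-identical CSVs)
is routine. The mechanism experiments in the test suite use one frame,
levels {5%, 60%} and 20 bootstraps on the default 64³ phantom; the
acceptance script uses 10 bootstraps at the same levels. These sizes were
chosen so a complete analysis runs in minutes per experiment on one CPU;
the full design grid is a configuration flag away but is cluster-scale
work.

## What passing tests do and do not show

The phantom establishes the *mechanisms*: Dice SD rises as counts fall;
more OSEM iterations raise voxel variance; PVC amplifies
registration-driven SUVr jitter and shifts SUVr in opposite directions
for the two late-frame contrasts; design bookkeeping is exact. The
phantom's piecewise-constant tissues, simplified 2-D-stacked geometry,
single anatomy, absence of head motion and of MR artefacts mean the
*numerical values* (Dice SDs, CoVs) are not predictions for any scanner
or cohort — on real data they depend on the scanner model, tracer
kinetics, registration software and population anatomy. Known further
limitations: one registration engine in-repo (external engines are an
adapter contract), randoms estimates are used unsmoothed, and the
scatter tail-fit underestimates broad scatter by ~30% (adequate for the
QNT-vs-AC contrast it serves).
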