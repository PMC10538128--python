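# Methods

This note documents the models, numerical choices and known limitations of
the toolkit. It is the companion to the API reference in the module
docstrings.

## Physical model

The sensor is a contactless ring of K = 32 area electrodes on the inner
wall of an insulating sleeve (relative permittivity 2), surrounded by a
grounded screen. All lengths are normalized to the electrode-ring radius
(1.0); defaults place the electrode band at radius 1.0–1.04, the sleeve out
to the screen at 1.15, and the simulation square at half-width 1.2. Each
electrode covers 80 % of its angular pitch; electrode 0 is centred at the
top of the image (the anterior chest wall of a supine patient).

The medium is described by the complex relative permittivity at the 100 MHz
excitation frequency,

    eps = eps' - j * sigma / (omega * eps0),

with tissue values taken from dielectric tables (lungs at inspiration /
expiration, pleural air and effusion fluid, heart/aorta, spine, fat,
electrode metal and sleeve plastic). The quasi-static potential solves
div(eps grad phi) = 0 with phi = 1 on the excited electrode and phi = 0 on
all other electrodes and the screen. Mutual capacitances follow from
Gauss' law: the flux of eps * E through the faces surrounding the sensing
electrode, divided by the potential difference. Both orderings of each
electrode pair are kept, giving M = K(K-1) = 992 measurements per frame.

## Discretization

The solver uses cell-centred finite volumes on a uniform Cartesian grid
(default 256 x 256 over the simulation square; a uniform grid replaces
adaptive mesh refinement, and grid convergence is verified by the coaxial
test below). Face conductances are harmonic means of the two adjacent
cells' permittivities; Dirichlet cells couple through half-cell faces so
the fixed potential sits on the cell boundary. One sparse LU factorization
(SuperLU in symmetric mode) per permittivity map serves all 32 excitations
as a single batched solve. Verified properties:

- relative residual of every solve <= 1e-10 (direct solve, ~1e-15 observed);
- reciprocity C(i,j) = C(j,i) to ~1e-15 relative;
- total charge over electrodes plus screen ~0 (<= 1e-8 relative);
- a two-ring coaxial capacitor (full-ring electrode via superposition of
  the two K=2 half-rings, plastic annulus) matches the analytic value
  2*pi*eps0*eps_r / ln(r_o/r_i) to 0.8 % at the 256 grid, with the error
  decreasing monotonically in grid refinement. The analytic inner radius is
  the outer face of the electrode band, where the discrete Dirichlet
  condition acts.

## Sensitivity matrix

The Jacobian of the M capacitances with respect to the N = 1856 in-FOV
pixel permittivities is computed with the discrete adjoint identity on the
finite-volume system: dC(i,j)/d eps_cell is the sum over the cell's faces
of the face-conductance derivative times the product of the two
unit-excitation fields' face differences. Because this is the exact
derivative of the discretized forward map, it matches finite-difference
perturbation entrywise (0.1 % observed, 1 % asserted) — unlike the
continuum formula integral(grad phi_i . grad phi_j), which only agrees to
O(h) near electrodes. The linearization point is the empty (air-filled)
sensor, matching the low calibration point.

## Field of view

Images are reconstructed on a 64 x 64 grid; only pixels inside a circular
field of view count, N = 1856 of them. No circle centred on the grid
centre (or on any pixel centre) yields exactly 1856 with the
pixel-centre-inside rule, so the calibrated default freezes radius 24.30 px
with the centre at (row 32.25, col 32.00): left-right symmetric, with a
quarter-pixel (0.4 % of the radius) vertical offset.

## Thorax phantom

Anatomy is parametric ellipses in FOV-radius units (thorax fat outline
0.95 x 0.78; lungs at (+-0.42, 0.02), 0.34 x 0.48, rotated -+15 deg; heart
0.22 x 0.26 at (0.10, -0.05); aorta r = 0.06; spine 0.13 x 0.10 at
(0, -0.60)). Randomization per organ: centre jitter +-0.05, rotation
jitter +-10 deg, independent per-axis scale U(0.9, 1.1); the respiration
phase is drawn uniformly per sample and sets the lung tissue values.

Diseases clip each lung with a shifted copy of the lung ellipse:
pneumothorax shifts it down and toward the midline so the uncovered part
(which becomes pleural air) lies anterior (image top); effusion shifts it
up so the fluid lies dorsal; hydropneumothorax shifts toward the midline
and splits the uncovered part at a horizontal fluid level drawn between
the 30th and 70th y-quantile of the diseased region. The shift distance is
found by bisection so the diseased fraction of the lung is U(0.1, 0.6).
The 17 classes are the 4 x 4 left/right lung states plus a random-ellipse
class (1–4 ellipses of random tissue inside the thorax outline).

Rasterization paints background air, then organs in order, then disease
partitions; a pixel belongs to the region covering its centre. The 64 x 64
image is the block average of the fine map.

## Measurement channel and calibration

Frames are calibrated against the empty sensor (low) and the sensor filled
with effusion fluid (high, the most conductive tissue). Two normalizations
exist:

- `normalize_frame`: the componentwise complex ratio
  (c - c_low) / (c_high - c_low);
- `normalize_channels`: each quadrature channel normalized separately.

The networks and algebraic methods consume the imaginary channel of
`normalize_channels`: it is 0 for the empty sensor, 1 for the
high-conductivity fill, and monotone in tissue conductivity in between.
(The imaginary part of the complex ratio vanishes at *both* calibration
points, which makes it non-monotonic in conductivity and unusable as a
scalar data channel.) Measurement noise is additive white Gaussian on this
channel with the SNR defined per vector.

All images are scored on a fixed display scale mapping conductivity
[0, 1.4] S/m (air to effusion fluid) onto [0, 255]; networks train on the
same scale divided by 255.

## Algebraic reconstruction

The working system folds the complex Jacobian and the calibration into a
real matrix J = d imag(c_n) / d (sigma/sigma_max), evaluated at the air
reference. Linear back projection is eps = eps_min + J_rownorm^T c_n with
rows scaled to unit maximum and eps_min = 0 (the calibration-low image).
The Tikhonov pseudoinverse solves (J^T J + alpha I) eps = J^T c_n with
alpha = 1e-9, via the equivalent dual form J^T (J J^T + alpha I)^{-1} c_n
(992 x 992, much better conditioned, identical solution).

Known limitation, reported honestly: thorax tissue at 100 MHz is far
outside the linear (Born) regime of the air-reference linearization — the
relative residual of the linear model on phantom data is ~40x. Back
projection survives this (it never inverts), reproducing the expected mean
SSIM of ~0.11. The pseudoinverse at alpha = 1e-9 amplifies the model error
through hundreds of weakly determined directions and collapses to noise
(SSIM ~0.00) for any scale convention of J we tested; an alpha sweep up to
1e-3 never exceeds SSIM 0.01. Its published quality level appears to
depend on a sensitivity-matrix scaling that is not recoverable from the
method description, so this toolkit reports the faithful computation
instead of matching the published number.

## Learned reconstruction

Both networks are implemented in a small NumPy layer library (`cceit.nn`)
with manual backpropagation, gradient-checked against finite differences;
training is bit-reproducible given a seed.

FCNN: input batch norm -> affine (992 -> 1856) -> batch norm -> ReLU ->
affine (-> 1856); MSE loss, Adam at 1e-3, batch 64. The hidden width
equals the output width — the minimal reading of a "shallow" one-hidden-
layer design.

cGAN: generator conditioned on the 32 x 32 measurement-matrix view
(rows = excitation, columns = sensing electrode, zero diagonal). The
default generator uses 4 x 4 stride-2 convolution encoder blocks (default
32-64-128-256 channels, leaky ReLU 0.2, batch norm), a **dense
bottleneck** (flatten, affine to 4096, reshaped to 8 x 8 tiles), and a
transposed-convolution decoder with dropout 0.5 in its two deepest blocks
(dropout replaces the latent vector) up to 64 x 64, ending in a sigmoid
3 x 3 output convolution masked to the FOV. The dense bottleneck is the
design choice that matters here: measurement space and image space are not
pixel-aligned, so the affine layer — not convolutional locality — is what
transports information between them, and it clearly outperformed the
fully convolutional U-Net with skip connections in our experiments (which
remains available via `bottleneck="conv"`). Discriminator: a strided
convolution head on the image, concatenated with the condition, two more
strided blocks, then affine -> sigmoid. Generator loss
BCE + 100 MSE + 100 L1 (means over FOV pixels); discriminator BCE; Adam at
2e-4, betas (0.5, 0.999), with linear learning-rate decay to zero over the
second half of training. With small training sets the discriminator
overfits and destabilizes the adversarial game, so the config exposes
discriminator pacing (`d_lr`, `d_every`); the scaled-down runs use a
discriminator learning rate of 1e-4 and one discriminator update per two
generator updates. Training aborts on mode collapse (discriminator loss
< 1e-4 for five consecutive epochs) or divergence.

## Metrics

RMSE, PSNR, global-statistics SSIM and Pearson correlation per image pair
on the display scale, with dataset summaries (mean, median, population
std, 64-bin histograms). PSNR is the standard 10 log10(MAX^2 / MSE) with
MAX the reference-image maximum, capped at 99 dB (the printed form of the
source's PSNR expression is dimensionally inconsistent; the standard form
is used). SSIM uses c1 = (0.01 * 255)^2, c2 = (0.03 * 255)^2 and
whole-FOV statistics with the conventional squared-mean denominator.

## Diagnostic value

A convolutional classifier (three stride-2 conv/batch-norm/ReLU blocks,
16-32-64 channels, affine head, softmax over the 17 classes) is trained on
ground-truth images with elementwise binary cross-entropy against one-hot
labels (a categorical-cross-entropy switch is provided), Adam, 75:25
learning/validation split. Applied to reconstructed test images, the
macro-averaged one-vs-rest ROC-AUC (per-class curves via scikit-learn,
macro curve on a 1001-point FPR grid) measures how much class information
each reconstruction method preserves.

## Problem sizes

The study-scale defaults are a 256-cell fine grid, 194,000 training
samples (9375 per lung-state class plus 44,000 random-ellipse samples) and
42,500 test samples. The test suite and the acceptance script run the
same pipeline at reduced sizes chosen as this package's desk-scale
conditions: the acceptance script generates 510 test samples (30 per
class) at the full 256 grid for the algebraic results; the end-to-end
tests use a 64-cell fine grid, 2,000 training and 306 test samples, a
half-width generator (16-32-64-128 channels), and correspondingly short
training schedules. What scaled-down runs demonstrate is the pipeline's
ordering and coarse quality levels, not the published full-scale values;
in particular the relative standing of the two networks at a few thousand
training samples need not match their standing at 194,000.

## What the synthetic data does not model

Everything is 2D and quasi-static: no out-of-plane currents, no
frequency-dependent tissue dispersion, no electrode contact effects (the
sensor is contactless by construction), no heart-cycle or breathing
dynamics within a frame, and no anatomical detail beyond ellipses.
Measurement noise is white Gaussian on the normalized channel; real
front-ends have correlated and signal-dependent noise. Conclusions about
real thorax data require real measurements.
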