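# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Pipeline model and assumptions

The pipeline assumes B-mode ultrasound of soft tissue containing one
(or more) roughly elliptical hypoechoic lesions whose interior is
*homogeneous* — the standard appearance of thyroid nodules — embedded
in brighter, more structured tissue, all degraded by multiplicative
speckle.  Every stage operates on a canonical [0, 1] intensity scale;
files are read by dividing by 2^depth − 1 and written as 8-bit.  Pixel
and block coordinates are (row, column) and 1-based in all user-facing
output; the linear index of block (r, c) in an n_r × n_c grid is
(r−1)·n_c + c, row-major, and the center of block (r, c) at block size
s (odd) is ((r−1)s + (s+1)/2, (c−1)s + (s+1)/2).

## Contrast enhancement

The S-function breakpoint estimator works on the 256-bin histogram of
the 5×5 mean-filtered image (the filter tightens the modes so tissue
classes appear as clear peaks).  Local maxima are taken on the **raw**
histogram (a bin strictly higher than both neighbors).  We deliberately
do not pre-smooth the histogram: smoothing turns isolated spikes into
plateaus with no strict maximum, and — more damagingly — by removing
the many small spurious maxima it inflates the mean peak height that
gates qualification, making the decision of whether a genuine secondary
peak "qualifies" a knife-edge.  The spurious maxima are harmless where
it matters: they dilute the mean height and never qualify themselves.

The tail limits B1/B2 each allow f1 = 1% of total pixels to be lost
beyond them (intensity below B1 is treated as background, above B2 as
noise).  With g_1/g_n the first/last of *all* local maxima and
g_min/g_max the first/last qualifying peaks, a = (1−f2)(g_1−g_min) +
g_min and c = f2(g_max−g_n) + g_n (f2 = 0.01), clamped into [·, B1] and
[·, B2].  Note a ≤ g_min always holds under this reading (g_1 ≤ g_min),
so the a-clamp is inert, while the c-clamp is usually active; c
consequently sits just inside the brightest qualifying peak, which is
what crushes bright background texture to 1 and leaves lesion texture
alive — the asymmetry the seed selector later feeds on.

b is found by exhaustive scan of integer b ∈ [a+1, c−1], maximizing
the mean binary Shannon entropy of the mapped image; ties go to the
smallest b.  When fewer than two peaks qualify (unimodal histogram)
the estimator falls back to the 1st/99th intensity percentiles for
(a, c), logged; a constant image passes through unchanged.

The neutrosophic truth/indeterminacy/falsity channels are computed
with full-range normalizations (T = (q̂−q̂_min)/(q̂_max−q̂_min),
I likewise on δ = |q−q̂|, F = 1−T) so both span [0, 1]; they are
diagnostics and do not feed the S-function path.  Intensification is
applied exactly once; unsharp masking uses a Gaussian of σ = 2 px and
amount 1.0.

## SRAD

The ICOV uses the average of squared forward and backward differences
for |∇I|², a 4-neighbor Laplacian, symmetric (zero-flux) boundaries,
and an ε = 1e−8 shift of I to keep divisions defined; a negative
radicand (possible at strong Laplacians) is clamped to 0.  Defaults
Δt = 0.05 and 100 iterations are conservative for the explicit scheme
(stability requires Δt ≤ 0.25); both are configurable.  The
homogeneous reference region for q0 is, by default, the 11×11 tile of
minimal intensity variance in the filter input, fixed once; q0 itself
is re-estimated there every iteration, since the speckle scale decays
as the filter progresses.  If the reference tile is degenerate
(q0 = 0, e.g. a saturated region after enhancement), the diffusion
coefficient degenerates to all-ones and the update reduces to mild
linear diffusion — logged, and harmless at these step sizes.

## Radon projections and bispectral entropies

Projections use pixel-driven linear splatting: each pixel center at
offset r = x cosθ + y sinθ contributes its value to the two nearest
integer offset bins with linear weights.  This conserves projection
mass *exactly* at every angle (the weights sum to 1), reduces to exact
column sums at θ = 0, and mirrors at θ = 180°; a rotate-and-resample
implementation can only conserve mass approximately.  The projection
length is ceil(s√2) rounded up to odd (17 for s = 11).

The projection mean is removed before the DFT; with the DC term
retained, |B| collapses toward a point mass at the origin and every
block looks alike.  The signal is zero-padded to N_fft = 32 (power of
two with headroom above the projection length) and the single-segment
bispectrum B(k1,k2) = R(k1)R(k2)R*(k1+k2) is evaluated on the lattice
Ω = {0 ≤ k2 ≤ k1, k1+k2 ≤ N_fft/2}, 81 points at N_fft = 32.  All four
entropies use natural logarithms (only the ranking across blocks
matters); the phase histogram uses 8 uniform bins on (−π, π].  An
all-zero bispectrum (exactly constant block) is assigned zero
entropies.  θ = 180° is retained as listed even though its magnitude
spectrum mirrors θ = 0°.

## Seed selection

E_v membership is inclusive at both ends (v ∈ [mean, max]), which
keeps the all-identical-blocks case well defined (every feature is at
once mean and max).  The SSIM tiebreak uses one uniform window
spanning the whole block — the comparison unit *is* the block — with
C1 = (0.01·L)², C2 = (0.03·L)², L = 1.  Missing neighbors at the grid
border contribute 0 to the sum, deliberately penalizing border blocks
(lesion centers are rarely at the image edge); a consequence is that
on a fully tied image the first *interior* block wins, not block 1.
Remaining ties go to the lowest linear index.

## Region growing

Classic seeded region growing: FIFO frontier, 8-connectivity, the
acceptance test |I(p) − μ| ≤ τ with μ initialized to the mean of the
11×11 window centered on the seed and updated as the running region
mean after every admission.  A frozen-mean mode (μ fixed at its
initial value) makes the algorithm an exact flood fill and is used for
oracle testing.  τ defaults to 0.12 on the [0, 1] scale — wide enough
to admit residual post-SRAD speckle fluctuation at typical lesion
contrast, narrow enough not to cross a 0.4 contrast step; it is the
one free parameter a user may need to touch on real data.  Interior
holes (speckle dropouts) are filled; no morphological smoothing is
applied, so the boundary is exactly where growth stopped.

## Evaluation metrics

TP and FP are both normalized by the automatic area |A|, making them
exactly complementary (TP + FP = 100).  SI is defined as the Jaccard
index — the standard "similarity index" distinct from Dice; note SI ≤
DC always.  The Hausdorff distance is the classical max-of-directed
distances between boundary pixel sets (pixels with a background
4-neighbor), Euclidean, in pixels; a mean-of-nearest-distances variant
(`hd_mode="mean"`) is provided because sub-pixel HD values reported in
the clinical literature usually correspond to averaged boundary error,
not the max.

## The phantom generator

Phantoms are piecewise-constant scenes — background level 0.65 with
elliptical lesions at level 0.25 by default (contrast 0.40, hypoechoic,
the mid-range of what B-mode nodules present) — multiplied by per-pixel
unit-mean Gamma noise of shape L (default L = 4 looks, i.e. point
SNR = √L = 2, typical of compounded B-mode), optionally plus additive
Gaussian noise, clipped to [0, 1].  A pixel belongs to a lesion iff its
center satisfies the ellipse inequality; overlapping lesions are
rejected so the ground truth stays unambiguous.  The default lesion
(semi-axes 28 and 40 px, rotated 20°) covers 18 full 11×11 blocks of a
256×256 image.

What the phantom does *not* emulate: point-spread-function correlation
of real speckle (pixels are independent), attenuation and shadowing,
scan-line geometry, and structured tissue texture around the nodule.
Real background tissue is more structured (lower entropy) than iid
speckle, which if anything *helps* the entropy contrast the seed
selector relies on; conversely, clutter such as vessels or calcifica-
tions, absent here, could distract it.  Passing phantom benchmarks
therefore demonstrates the machinery end-to-end under controlled
speckle statistics, not clinical performance.

## Benchmark scale and determinism

The end-to-end benchmark uses 20 phantoms at 256×256 — large enough
for a 23×23 block grid and a lesion spanning many blocks, small enough
that the whole benchmark runs in well under a minute on one core.  The
pipeline itself is fully deterministic; all randomness lives in the
phantom generator and is seeded.

## Known limitations

- The entropy criterion needs the lesion to be homogeneous *and* to
  occupy several full blocks; small nodules (≲ 2 blocks) or markedly
  heterogeneous ones will not reliably win the E_v vote.  On the
  default benchmark conditions the seed lands inside the lesion in
  ~90–95% of runs, not 100%: occasionally a background block edges out
  every lesion block by one marginal feature.
- Breakpoint estimation assumes a multimodal histogram; on
  near-unimodal images the percentile fallback gives a gentler, less
  selective mapping.
- TP/FP normalized by |A| reward under-segmentation; read them
  together with DC and SI.
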