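# Methods

`sinomar` implements sinogram-domain metal artifact reduction (MAR) for
parallel-beam CT: the entries of a sinogram whose rays pass through metal
(the *metal trace*) are treated as missing, deleted, and re-estimated by a
convolutional encoder–decoder before filtered back projection (FBP). This
note records the model, its assumptions, the numerical choices, and what the
synthetic benchmark does and does not show.

## Problem setting and model

A 2-D attenuation map `f(x, y)` scanned with parallel rays at angle θ yields
projections `g(θ, l)`, with `l` the signed detector offset. Metal implants
attenuate so strongly that the affected sinogram entries carry no usable
signal; reconstructing through them produces streak artifacts. The pipeline
is:

1. **Trace identification.** At simulation time the metal map is known
   exactly; at test time the scan is FBP-reconstructed, metal is segmented by
   a threshold (metal attenuation exceeds everything else by a margin, so
   a global threshold is well posed), and the binary metal map is reprojected.
   The reprojected shadow is binarized where the intersection path length
   exceeds half a detector bin and dilated along the detector axis
   (default 2 bins per side; the desk benchmark uses 1) to guarantee full
   coverage of the damaged band.
2. **Trace deletion.** Masked entries are set to zero; all other entries are
   left bit-exact. This is also how training pairs are made: the label is the
   complete sinogram, the input is the same sinogram with the trace zeroed.
3. **Completion.** A U-net-style network maps the zeroed sinogram to a
   completed one. The final output is always composited with the input —
   network values are kept only on the trace — so unaffected data are
   preserved bit-exactly no matter what the network does.
4. **Reconstruction.** Standard FBP (ramp filter, linear interpolation).

### Consistency conditions

For untruncated parallel-beam data the detector moments of the projections
are trigonometric polynomials of the image's geometric moments
(Helgason–Ludwig conditions):

    V_k(θ) = ∫ l^k g(θ, l) dl  =  Σ_{r=0}^{k} C(k,r) m_{r,k-r} cos^r θ sin^{k-r} θ,
    m_ij   = ∬ x^i y^j f(x, y) dx dy.

Order 0 says the per-angle projection mass is an angle-independent constant
(the total attenuation mass). Deleting a trace removes an angle-*dependent*
amount of mass, so the corrupted sinogram visibly violates the condition;
the completion should restore it. The `projection` module evaluates both
sides by direct quadrature and exposes per-angle residuals plus a
sinogram-only score (coefficient of variation of `V_0` across angles).

These identities hold exactly only for parallel-beam, untruncated data —
which is why the simulation enforces phantom support strictly inside the
inscribed disk of the detector span. Divergent-beam geometries are out of
scope.

### Network

Single-channel encoder–decoder with skip connections. Encoder blocks: two
3×3 stride-1 convolutions (leaky rectifier, negative slope 0.2) and a 3×3
stride-2 convolution replacing pooling. Channel schedule `base, 2·base,
4·base`, then `8·base` repeated; full scale is depth 5 / base 64, the desk
benchmark depth 4 / base 16. Decoder blocks mirror the encoder: stride-2
transposed convolution (implemented exactly as zero-stuffing + 3×3
convolution, computed at low resolution via its four output-parity classes),
skip concatenation, two 3×3 convolutions with plain rectifiers; a final
linear 3×3 convolution restores one channel. Output shape equals input
shape for sides divisible by `2^depth`.

No deep-learning framework is used: forward passes, analytic backward passes
(verified against central finite differences to ~1e-5 relative in float64)
and Adam are written directly in NumPy, float32, with convolutions evaluated
as nine shifted matrix products.

Sinograms are padded to network-divisible sizes: zero padding split evenly
on the detector axis (physically zero outside the detector span), circular
padding appended on the angle axis (a full-circle sinogram is periodic in
θ). The pad record inverts bit-exactly.

### Loss

With `f` the network output, `f̂` the label, and `M` the binary trace mask:

    L2loss   = Σ (M⊗f − M⊗f̂)²         — error on the trace only
    Amploss  = Σ (D_x f − D_x f̂)²      — detector-axis first differences
                                          (continuity at trace edges)
    Diffloss = Σ_θ (Σ_x f − Σ_x f̂)²    — per-angle mass (order-0 consistency)
    Loss     = L2loss + Amploss + Diffloss   (unit weights by default)

The two feature terms are deliberately unmasked: they constrain the whole
output toward sinograms that join continuously at trace boundaries and carry
angle-independent mass. Ablation switches disable the mask restriction
and/or the feature terms; weights are configurable.

Inputs and labels are normalized by the maximum label value of the training
set; the factor is stored with the weights and undone before compositing and
FBP.

## Synthetic data

Phantoms are additive ellipse composites: one large body ellipse
(attenuation 0.2–0.6 in arbitrary per-pixel units), a few internal ellipses
(0.2–1.0, summing where they overlap), and metal discs with attenuation
5.0–8.0 — at least 2.0 above any non-metal pixel, so threshold segmentation
(default threshold 4.0) is unambiguous. All sampling is seeded; placement
retries are bounded and failures raise. Rendering uses pixel-center
membership with no anti-aliasing, so a brute-force membership count is an
exact oracle.

What this emulates: the geometry of metal-damaged traces (sinusoidal bands
whose width tracks the implant size), untruncated parallel projections, and
the pairing of complete/incomplete sinograms. What it does not emulate:
anatomical texture, beam hardening, scatter, noise, polychromatic spectra,
and divergent-beam geometry. Metal damage is reduced to trace deletion, so
passing benchmarks here show that the completion machinery works — not that
it transfers to clinical scans.

## Numerical choices

- **Projector / FBP**: scikit-image `radon` / `iradon` (rotate-and-sum with
  linear interpolation; ramp filter). Everything shares one frame: pixel
  `(r, c)` of an `N×N` image sits at `x = c − N//2`, `y = N//2 − r`; the
  rotation axis projects to detector index `n_detectors//2`. This alignment
  was verified with impulse probes and is required for the higher-order
  moment identities to hold at the percent level.
- **Interpolating projectors and impulses**: rotate-and-sum does not
  conserve mass for single-pixel impulses (errors up to tens of percent at
  45°); it does for resolved objects. Point-like fixtures therefore use
  compact discs a few pixels wide.
- **FBP fidelity** is assessed on genuinely smooth (Gaussian-filtered,
  σ = 2 px) phantoms away from support edges, because ramp-filtered
  reconstruction cannot represent discontinuities without ringing; sharp
  ellipse composites measure edge response, not roundtrip fidelity.
- **Geometry defaults**: 512 detectors × 360 uniform angles over [0°, 360°);
  a [0°, 180°) mode exists since parallel data are redundant over a full
  circle. Detector spacing is 1 pixel; attenuation units are arbitrary.
- **Trace binarization** cutoff: 0.5 detector-bin path length, before
  dilation.
- Degenerate inputs: fully masked angle columns in the LI baseline are
  filled with zeros and flagged (no anchors exist); empty metal maps yield
  empty traces; single-angle FBP raises.

## Desk-scale benchmark

The reference experiment (`sinomar.experiments`) is sized for minutes on one
CPU core: 48-px phantoms with 1–2 metal discs, 64-detector × 64-angle
sinograms, trace dilation 1, depth-4 / base-16 network, Adam (learning rate
1e-3, batch 8), 200 steps over 100 training pairs, 10 held-out pairs. The
learning rate is the smallest round value at which training reliably
converges within this step budget; all values are exposed in `TrainConfig`.

With the full composite loss the trained network's held-out trace-region MAE
beats per-angle linear interpolation (LI-MAR) in at least 4 of 5 independent
seeds — the bar the acceptance suite asserts — e.g. seed 1: network 8.9 vs
LI 17.7, a ~50% reduction, with zero-fill at 32.0. The labels include the
metal's own projection, so LI — anchored on body values — cannot reproduce
the metal hump, while the network learns to.

**Ablation caveat.** On *trace-region MAE* at this scale the ablation grid
orders in reverse: unmasked plain L2 ≲ masked-L2-only < full composite loss
(seed 1: 6.7 / 7.0 / 8.9 — all still well below LI's 17.7). Two structural reasons: (1) compositing already
guarantees off-trace data preservation, so the mask's protective role —
the main argument for it on full-array metrics — cannot show up in a
trace-restricted metric; masking only reallocates gradient. (2) With unit
weights the order-0-consistency term dominates the composite gradient
(squared per-angle *sums* scale with the detector count), diluting trace
supervision in a short training budget. The acceptance suite asserts the
conventional ordering and therefore documents this reversal as a failing
test rather than hiding it; the ablation report itself is always produced.

## Known limitations

- Parallel-beam only; the consistency conditions used in the loss are exact
  only there.
- The NumPy training loop is single-threaded and desk-scale; the full-scale
  configuration (depth 5 / base 64 / 512×360) is expressible but slow.
- Trace-region MAE is the discriminative metric here; full-array sinogram
  MAE of composited outputs differs from label only on the trace, so both
  tell the same story at simulation scale.
- The printed full-scale block/channel counts of the original architecture
  are mutually inconsistent for a 512-px input (ten stride-2 reductions of
  512 is geometrically impossible); depth and channel schedule are therefore
  configurable, with defaults documented above.
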