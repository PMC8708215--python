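# sinomar

Sinogram-domain metal artifact reduction (MAR) for parallel-beam CT.

Metal implants block X-rays so completely that the affected sinogram entries
— the *metal trace*, a sinusoidal band across projection angles — carry no
usable signal, and reconstructing through them fills the image with streak
artifacts. `sinomar` treats those entries as missing data: it deletes the
trace, re-estimates it with a convolutional encoder–decoder trained on
paired (complete, trace-zeroed) sinograms, composites the estimate back so
every unaffected entry stays bit-exact, and reconstructs with filtered back
projection (FBP). A classical per-angle linear-interpolation baseline
(LI-MAR) and the standard evaluation metrics are included, along with a
seeded synthetic-data generator (ellipse phantoms with embedded metal
discs), so the whole pipeline is reproducible end to end on a laptop.

It is aimed at people studying CT artifact-reduction methods who want a
small, fully inspectable reference implementation with honest benchmarks.

## The method in brief

For an attenuation map `f(x, y)` with parallel-beam projections `g(θ, l)`,
the detector moments `V_k(θ) = ∫ l^k g(θ, l) dl` satisfy the
Helgason–Ludwig consistency conditions

    V_k(θ) = Σ_{r=0}^{k} C(k,r) m_{r,k−r} cos^r θ sin^{k−r} θ,
    m_ij = ∬ x^i y^j f dx dy;

in particular `V_0(θ) = m_00` is angle-independent. Zeroing a metal trace
removes an angle-dependent amount of mass and breaks this invariant. The
completion network (a U-net variant: stride-2 convolutions instead of
pooling, leaky rectifiers in the encoder, skip connections, single-channel
512×512-capable input) is trained with a three-term objective on output `f`
vs label `f̂`:

    Loss = Σ (M⊗f − M⊗f̂)²                       (masked L2: trace only)
         + Σ (D_x f − D_x f̂)²                    (continuity of detector-axis
                                                  differences at trace edges)
         + Σ_θ (Σ_x f(x,θ) − Σ_x f̂(x,θ))²       (per-angle mass: order-0
                                                  consistency)

with `M` the binary trace mask. At inference the network output is kept only
on the trace (`composite`), so mask-0 data are preserved bit-exactly.

Everything — including the network's forward/backward passes and Adam — is
plain NumPy; there is no deep-learning framework dependency.

## Worked example

```python
import sinomar as sm

# a random body phantom with one metal disc, and its paired sinograms
geom = sm.ScanGeometry.uniform(n_detectors=64, n_angles=64)
gen  = sm.GenerationConfig(image_size=48, metal_count_range=(1, 2),
                           metal_radius_range=(0.06, 0.15),
                           n_internal_range=(1, 3))
spec = sm.sample_random_phantom(7, gen)
pair = sm.make_pair(spec, geom, dilation_px=1)

# trace deletion breaks the order-0 consistency condition
print(f"V0 coefficient of variation, intact:    "
      f"{sm.v0_consistency(pair.label):.5f}")
print(f"V0 coefficient of variation, corrupted: "
      f"{sm.v0_consistency(pair.corrupted):.5f}")

# train the completion network at desk scale and compare against LI-MAR
from sinomar.experiments import run_learning_experiment
res = run_learning_experiment(seed=1)
print(f"held-out trace MAE  network:   {res.net_trace_mae:.2f}")
print(f"held-out trace MAE  LI-MAR:    {res.li_trace_mae:.2f}")
print(f"held-out trace MAE  zero-fill: {res.zero_fill_trace_mae:.2f}")
```

Output (about two minutes of single-core training):

```
V0 coefficient of variation, intact:    0.00170
V0 coefficient of variation, corrupted: 0.02909
held-out trace MAE  network:   8.92
held-out trace MAE  LI-MAR:    17.70
held-out trace MAE  zero-fill: 32.00
```

The intact sinogram's per-angle mass is constant to 0.17% (the consistency
condition holds); zeroing the trace inflates the spread ~17×. After 200
training steps the network's trace-region mean absolute error on held-out
phantoms is about half that of linear interpolation — LI anchors on body
values and cannot reproduce the metal's own projection hump, while the
network learns to — and far below leaving the trace at zero.

A command-line pipeline mirrors the library
(`sinomar simulate|train|complete|mar-li|reconstruct|evaluate|ablate`),
driven by a single YAML configuration; see `sinomar --help`.

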