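# Methods note

## Model

The phase of a microtubule tip is a continuous-time Markov chain on
{g, p, s} with generator entries `f_ij` (min⁻¹): catastrophe `f_gs`, rescue
`f_sg`, and the four pause-coupled rates `f_gp`, `f_pg`, `f_ps`, `f_sp`.
Conditional on the phase, length changes at +`v_g`, 0, or −`v_s` μm/min.
The simulator draws exact exponential dwell times (total exit rate per
state), picks successors proportionally to the individual exit rates,
integrates length piecewise-linearly, and reads the process out on a uniform
grid.  A shrinking tip that reaches zero length is truncated there and
restarted in growth (a *nucleation*; the count is recorded).  Gaussian
read-out noise is added to the sampled lengths and the result clipped at 0.

### Equilibrium quantities

With total exit rates `F_g`, `F_p`, `F_s`, the composite pairwise rates
follow the pattern `F_ab = f_ac·f_ba + f_ac·f_bc + f_ab·f_bc`.  These are the
spanning-tree weights of the chain, so the stationary phase distribution is
`π = (F_sp, F_sg, F_gp)/Ω` with `Ω = F_sp + F_pg + F_sg`, and

```
V = (v_g·F_sp − v_s·F_pg) / Ω
L = v_s·v_g / (v_s·F_gp/F_p − v_g·F_ps/F_p)
```

Under this pattern `F_pg ≡ F_gp` and `F_ps ≡ F_sp` identically, and **V
equals the stationary mean drift** `v_g·π_g − v_s·π_s` exactly — positive V
means growth dominates.  The package adopts this mathematically consistent
sign convention throughout, and the Monte-Carlo acceptance test checks the
long-run drift against **+V** for growth-dominated, shrink-dominated and
symmetric rate sets.  For the pinned study rates, V = 37.18 μm/min and
|L| = 5.2386 μm.

## Parameters, units, defaults

| quantity | default | rationale |
|---|---|---|
| rates `f_ij` | 0.11, 0.22, 8.54, 0.11, 0.22, 8.76 min⁻¹ | pinned study conditions |
| speeds `v_g`, `v_s` | 40.65, 45.17 μm/min | pinned study conditions |
| sampling `dt`, `N` | 3 s, 165 samples | pinned study conditions |
| read-out noise `σ` | 0.2 μm | the microscope's stated length resolution |
| initial length `x0` | 5 μm | the scale of the model's equilibrium length |
| initial phase | g | a freshly nucleated tip grows |
| resolution factor `d` | 3 | s = 55 kept samples, 0.33 subrate |
| patch window / threshold | w = 4, R > 0.90 | fusion convention |
| wavelet / levels / EPE | db2, 8 requested, 85% | transition detection convention |
| classification | Δ ≥ 0.2 μm; slope ≥ 0.15 (g) or ≤ −0.3 (s) μm/min | experimental thresholds |

A 165-sample record supports only 5 strict dyadic db2 levels; the requested
depth is capped with a warning.

### Generator realism and limits

The simulator is exact for the stated model.  It does not model GTP-cap
dynamics, length-dependent rates, measurement dropout or spatial blur; noise
is i.i.d. Gaussian truncated at zero.  At the pinned rates the chain is
strongly growth-dominated (π_g ≈ 0.94) and pause/shrink dwells last
~7 s ≈ 2 samples, which matters for estimator performance (below).

## Numerical choices

- **Kalman/EM.**  Standard forward recursions (innovations form) and RTS
  backward pass; the lag-one smoothed cross-covariance uses
  `Σ_{n,n−1|N} = Σ_{n|N} Σ_{n|n}⁻¹ Σ_{n,n−1|n}`, algebraically equal to the
  usual `Σ_{n|N} Aᵀ_{n−1}`.  H is held at 1 during EM (with scalar states
  `(H, F, Q, R)` is unidentifiable under similarity scaling).  Starting
  point: F = 1, Q = R = var(diff(y))/2, μ₀ = y₁, Σ₀ = var(y).  Variance
  floors of 1e−12 prevent degenerate collapse; a likelihood decrease beyond
  numerical slack raises.  A plain-float scalar fast path (~15× faster) is
  verified against the general matrix path and against brute-force joint
  Gaussian conditioning in the tests.
- **Boundary handling for the DWT.**  Default padding is linear
  extrapolation ("smooth"): trending length records under periodization
  acquire an artificial end-to-start jump — its finest-level coefficient
  dominates the record and starves the EPE budget (measured: ~1 detected
  peak per record, always at the boundary) — and reflection padding has the
  analogous slope-flip artifact.  db2's two vanishing moments annihilate a
  linear ramp, so smooth padding adds no spurious energy.  Periodization
  remains available and its energy conservation is tested.
- **Coefficient→sample map.**  The finest-level coefficient `k` responds to
  sample ≈ `2k` under smooth/symmetric padding and `min(2k+1, N−1)` under
  periodization (calibrated empirically on isolated kinks).
- **EPE selection.**  Coefficients sorted by energy (ties to the lower
  index); the shortest prefix reaching 85% of the total energy is retained —
  `[3, −2, 1]` keeps 2 coefficients, `[1, 1, 1, 1]` keeps all 4.
- **NL-I definition.**  The baseline is the average of the d+1 interpolated
  frames (the same averaging granted to MLK), not the base interpolant
  alone.
- **Tie-breaking.**  Patch fusion resolves equal qualifying pairs toward
  the lexicographically smallest; PCA signs are fixed so each component's
  largest-magnitude loading is positive; MI uses equal-width histograms
  with ⌈√N⌉ bins.
- **Seeding.**  Simulation and sample-loss use independent streams
  (`sampling_seed = seed + 101323` by default); identical configurations
  give byte-identical reports.

## Known limitations

- **Parameter recovery at the pinned conditions is resolution-limited.**
  Pause and shrinkage dwells (~2 samples) are at the scale of the sampling
  itself, and the 0.33-subrate reconstruction smears them further: the full
  pipeline recovers `v_g` within a few percent but misses pauses entirely
  and dilutes shrinkage slopes (recovered `v_s` ≈ 7–12 μm/min versus
  45.17), so the factor-of-2 recovery targets for the pause-coupled rates
  and the ±25% target for `v_s` are not met.  This is a property of the
  method at these conditions, not of the implementation; the acceptance
  test asserts the stated bands and reports the failures.
- **MLK ties NL-I.**  On piecewise-linear interpolated frames the EM
  likelihood is maximized as R → 0 (given the state the interpolant is
  locally noise-free), so the smoother converges to the identity and the
  MLK average differs from the NL-I average only through a tiny F̂ > 1
  bias.  Measured over 20 seeds: MLK − NL-I = −0.006 dB, the same sign on
  every seed, so the strict ordering MLK ≥ NL-I fails by a knife-edge
  margin while MLK-R ≥ MLK holds robustly (+0.57 dB, 20/20 seeds).
- **MLK-MI is high-variance.**  Keeping two principal components can
  discard genuine signal structure; its ensemble RMSE is occasionally far
  worse than the inputs' (the component-selection failure is exercised in
  the tests).
- **Drift sign convention.**  Alternative readings exist in which positive
  V is described as shrinkage-dominated; the package uses the convention
  forced by the algebra above (V = stationary drift, positive = growth).
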