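# Methods

## The growth-law model

A cortical condensate is described by two integrated fluorescence amounts,
WSP-1 `W` and F-actin `A` (IU), with volume tied linearly to content,
`V = v_A A + v_W W`.  The amounts evolve by mass-action growth laws:

```
dW/dt = k_r W − k_l A W / V
dA/dt = k_b A W / V − k_d A
```

Assumptions baked into this form:

- **Well-mixed interior.** Reaction rates depend on internal composition
  only; diffusion across the condensate is fast relative to reaction
  times.
- **Degree-1 homogeneity.** Scaling `(A, W)` by λ scales both rates by λ.
  Composition variables — stoichiometry `s = A/(A+W)`, effective F-actin
  volume fraction `φ = v_A A / V`, concentrations `c_A = A/V`,
  `c_W = W/V` — therefore evolve autonomously (*intensive dynamics*):

  ```
  dφ/dt = φ(1−φ) [ k_b(1−φ)/v_W − k_d − k_r + (k_l/v_A) φ ]
  ```

- **No condensate–condensate coupling.** No shared-pool depletion; in the
  unbounded regime growth would eventually be limited by effects outside
  the model.

Geometry of the system:

- Both nullclines are rays of constant stoichiometry through the origin:
  `s_W = k_r v_W / (k_r v_W + k_l − k_r v_A)` and
  `s_A = (k_b − k_d v_W) / (k_b − k_d v_W + k_d v_A)`.
- The origin is a fixed point with an unstable direction along the W axis
  (growth rate `k_r`) and a stable one along the A axis (decay `k_d`).
  With `s_W < s_A` trajectories are homoclinic loops: grow in W, then in
  A, lose W while still gaining A between the rays, then dissolve.
- The bracket in `dφ/dt` is linear in φ; its interior root
  `φ* = (k_b/v_W − k_d − k_r) / (k_b/v_W − k_l/v_A)` is stable and marks
  the *dominant composition* where dynamics are slowest.  Its
  stoichiometry image `s*` is where the ensemble spends most of its time,
  so the preferred concentration pair lies at the intersection of the
  constant-density line `v_A c_A + v_W c_W = 1` with the `s*` ray.
- The nullclines coincide when `v_A k_r / k_l + v_W k_d / k_b = 1`;
  solving for the F-actin loss rate gives the critical
  `k_d* = (k_b/v_W)(1 − v_A k_r/k_l)`.  Beyond it the rays switch order
  (`s_A < s_W`), the homoclinic loop disappears and growth is unbounded.
  `classify_regime` labels a parameter set within 1e-9 of the criterion
  value as "critical" (the closed form is exact; the tolerance only
  guards floating point).

## Canonical coefficients

The volume coefficients are measured quantities:
`v_A = 1.54e-7 (±1e-8)`, `v_W = 2.34e-7 (±2e-8)` µm³/IU, valid for
stoichiometries in [0.65, 0.93].  The four kinetic coefficients are
configuration, not measurement: the package's canonical set
`k_r = 0.1 /s, k_l = 1.9529e-8, k_b = 2.43e-7 µm³ IU⁻¹ s⁻¹, k_d = 0.15 /s`
is the minimal round choice that places the nullclines at stoichiometries
0.850 and 0.900 in a bounded regime (criterion value 0.933, critical
`k_d* ≈ 0.2196 /s`, dominant composition `φ* ≈ 0.8649`, `s* ≈ 0.9068`).

One timescale caveat follows from this choice and matters for interpreting
synthetic ensembles: with the nullclines only 0.05 apart in stoichiometry,
the relative decay rate at the dominant composition is
`(k_l/v_A) φ* − k_r ≈ 0.0097 /s`, so the deterministic life cycle from a
3 IU seed to dissolution below 1 IU lasts ≈ 430 s — the loop *shape*
matches the biology but the tail is slow, and at the default 120 s
observation horizon most synthetic tracks are censored mid-hover.
Analyses that need completed life cycles (lifetime distributions,
regime-separation checks) therefore choose their horizon from the
dynamics: the ODE dissolution time is computed first and the simulation
horizon set to a multiple of it.

## Synthetic track generation

The generator emulates the observation process behind condensate track
tables:

- **Nucleation**: Poisson in time (default 20 events/s per field of view),
  seeds drawn log-normal in W (median 3 IU, log-sd 0.5) with `A = 0.2` IU
  — WSP-1-first, above the WSP-1 nullcline so condensates can grow.
- **Dynamics**: per frame (0.5 s) the state advances in 10 substeps; the
  deterministic drift uses a classical RK4 step (the noise-free limit
  reproduces the integrated orbit to ~1e-8), and each of the four rate
  terms receives an independent multiplicative Gaussian kick of scale
  `intrinsic_noise_sd·r_i·√dt` (chemical-Langevin-like; preserves
  positivity after clipping at 0 and approximately preserves
  homogeneity).  Default `intrinsic_noise_sd = 0.1 /√s`; this produces
  stochastic rescue events (tracks re-crossing the WSP-1 nullcline) at
  the ~1% level.
- **Observation**: each latent amount, and the spherical-equivalent
  cross-sectional area derived from the relation volume, is multiplied by
  an independent log-normal factor (log-sd 0.05) per frame.
- **Detection**: a track ends at the first frame whose latent total drops
  below 1 IU; tracks shorter than 3 frames are discarded; tracks alive at
  the horizon are flagged censored.

What the generator does *not* emulate: segmentation and track-linking
errors, diffraction effects on small condensates, spatial interactions,
photobleaching, background drift.  Passing recovery tests therefore show
that the estimators invert the generating process faithfully under the
stated noise model — not that they are robust to every artifact of real
microscopy.

RNAi presets rescale the canonical coefficients by the measured knockdown
effects (mild: `k_r×0.83, k_l×1.01, k_d×1.7`; moderate:
`k_r×0.85, k_l×1.20, k_d×2.7`; `k_b` unchanged in both).  The strong
condition has no measurable dynamic condensates, so its preset pins `k_d`
at `1.2 k_d*`, just past the critical point, rather than extrapolating a
trend whose procedure is not available; the companion
`estimate_kd_lower_bound` performs the simpler severity-rank linear
extrapolation and returns its result explicitly as a lower bound.

## Estimators and numerical choices

- **Derivatives**: central differences `(x_{i+1} − x_{i−1})/2Δt`,
  endpoints dropped; exact for quadratics, O(Δt²) bias otherwise
  (measured ≈ 2e-3 relative at Δt = 0.5 s on noise-free orbits, falling
  fourfold at Δt = 0.25 s).  An optional 5-frame local-quadratic
  (Savitzky–Golay) derivative exists but is off by default because
  smoothing biases rates at the loop's turning points.  Central
  differences carry one caveat on stochastic data: within a
  quasi-stationary cloud (condensates hovering at `φ*`) they average
  forward and time-reversed drift and so underestimate the true drift
  across the cloud's width.  This is visible as attenuation of recovered
  `k_d` fold changes for strongly perturbed presets whose hover sits
  inside the fitting window.
- **Field binning**: geometric (log-spaced) bins, default 24 per axis,
  because amounts span about two orders of magnitude; per-bin mean, SEM
  and count; bins under 20 points are masked.
- **Empirical nullclines**: per A-column sign changes of the binned mean
  rate along W, where both flanking bins must differ from zero by ≥ 2 SEM
  (gaps of insignificant bins are allowed between the flanks — the rate
  genuinely approaches zero at the nullcline); at least 3 crossings are
  required before a ray is reported, otherwise a no-nullcline error is
  raised (the expected outcome for unbounded-regime data).  Crossings are
  summarised by a total-least-squares ray through the origin on
  unit-normalised points; uncertainty by bootstrap over crossings.
- **Volume fit**: zero-intercept least squares of spherical-equivalent
  measured volume on `(A, W)`, restricted to the stoichiometry window
  [0.65, 0.93]; points outside the window are excluded from the fit but
  kept downstream.  Uncertainties by bootstrap over condensates (points
  within a track are autocorrelated), default 200 resamples, seeded.
  Known limitation: with multiplicative measurement noise on the amounts
  this is an errors-in-variables regression; at 5% noise the recovered
  `v_W` is biased high by up to ~20% because WSP-1 contributes the
  smaller volume share over most of the window.  Noise-free recovery is
  exact to 1e-6.
- **Kinetic fit**: the growth laws imply
  `Ẇ/W = k_r − (k_l/v_A) φ` and `Ȧ/A = (k_b/v_W)(1−φ) − k_d`, so two
  weighted linear regressions of per-point relative rates on φ (weights ∝
  amount, stabilising multiplicative noise; amounts below 0.5 IU
  excluded) recover all four coefficients via
  `k_r = b_W, k_l = −m_W v_A, k_b = −m_A v_W, k_d = −m_A − b_A`.  The φ
  fitting window is the image of the stoichiometry window.  Bootstrap
  over condensates for errors; a nonnegative slope (which would make
  `k_l` or `k_b` nonpositive) is flagged, not clipped.  At the reference
  noise levels recovery of the canonical coefficients from 2,000 tracks
  is within 10% (the residual is dominated by the central-difference and
  errors-in-variables effects above, not sampling error).
- **Density estimation**: occupancy contours and the preferred
  concentration pair use a binned Gaussian KDE (2-D histogram smoothed
  with per-axis Silverman bandwidths on a 128² grid).  Highest-density
  regions take their threshold from the (1−level) quantile of the density
  at the points themselves, so enclosed mass is calibrated by
  construction to within histogram discreteness (±2%).
- **Orbit integration**: adaptive RK45, rtol 1e-8 / atol 1e-12 IU
  (orbits span decades, so relative control matters).  Integration stops
  once the total amount falls below 1e-9 of its initial value: the
  homoclinic orbit has returned to the fixed point, and continuing to
  integrate the exponentially vanishing state is numerically meaningless
  (the clipped vector field could otherwise re-inject growth through
  rounding at the unstable axis).

## Pipeline and reproducibility

`run_pipeline` executes simulate (or read) → volume fit → portrait →
kinetic fit → ensemble summary, writing TSV tables, key-value reports and
a JSON summary.  All randomness flows from a single seed (sub-seeds are
derived per stage), and a fixed seed yields bit-identical outputs.  The
demo configuration completes in a few seconds on one CPU.

## Known limitations

- The canonical kinetic coefficients reproduce the published nullcline
  geometry but not the ~10 s lifetime scale (see above); only a uniform
  rescaling of all four rates — which leaves every dimensionless
  conclusion unchanged — could match both.
- Fold-change recovery for strongly perturbed conditions is attenuated by
  the hover-cloud effect on central differences; direction of effect is
  robust, magnitudes are lower bounds in practice.
- The volume fit trusts the spherical shape assumption uniformly,
  including for condensates near the diffraction limit.
- The track reader accepts only the fixed TSV dialect documented in the
  README; adapters for other deposited schemas are future work.
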