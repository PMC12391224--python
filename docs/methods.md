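# Methods

## Signal model and processing chain

A cartridge run produces one power trace per well, sampled uniformly
(default 1 Hz) for ~48 h, in µW. Internally everything is seconds and
µW so time integrals are directly µJ; hours appear only at presentation.
The observed trace of a well is modelled as

    P(t) = spike(t) + drift_col(t) + metabolism(t) + background + noise

where the spike is the loading-friction transient shared by all wells,
the drift is a slow instrumental trend common to a column, and the
background is the media/gel's own signal, also common to a column's
cell-free references. The pipeline removes these nuisance terms in
four stages:

1. **Reference correction.** Subtract the pointwise mean of the same
   column's reference traces. Anything common to the column — spike,
   column drift, media background — cancels; what remains is the
   sample's metabolic signal plus residual well-specific drift and
   noise (noise variance grows by a factor 1 + 1/r for r references).
2. **Trimming.** Drop `trim_start_s` (default 1800 s, the instrument's
   ~30 min equilibration) and optionally a tail. Gaps in sampling are
   hard errors, never interpolated: silent interpolation would bias the
   integral.
3. **Baseline correction.** In `per_column_linear` mode a straight line
   is least-squares fit to the pooled, moving-average-smoothed
   same-column signals over a quiescent window (default 5–10 h: after
   the spike has dissipated, before metabolic onset at 12–15 h) and
   subtracted; then a constant shift pins the minimum of the smoothed
   trace at exactly zero. `per_well_constant` applies only the shift.
   Smoothing (default half-width 300 s) prevents a single noise
   excursion from defining the baseline. Raw values still below zero
   after the shift — noise dips below the smoothed minimum — are
   clipped to zero so the positivity contract holds pointwise.
4. **Integration.** Trapezoidal rule at native sampling (dense uniform
   sampling makes higher-order quadrature pointless); totals divided by
   the well's cell count give µJ/cell. Wells with no cells keep raw
   totals; per-cell heat is undefined (`None`) there.

### The baseline-offset area (a known, deliberate bias)

Pinning the smoothed minimum at zero and clipping negative noise makes
every integral slightly positive even for a metabolically silent well:
over a quiescent span of length T the clip contributes roughly
E[max(0, ε)]·T ≈ σ_eff·φ(0)·T, plus the shift (≈ the depth of the
smoothed-noise minimum) times the full window. At the default 0.2 µW
noise this "baseline offset area" is ~2·10⁴ µJ per well, a few percent
of a fed well's ~4·10⁵ µJ — and it is exactly what real no-cell control
wells report as small nonzero totals. The alternative (allowing signed
integrals) would violate the positivity contract the processing is
defined by, so the bias is accepted and documented rather than removed;
recovery tests bound the median absolute relative error (≤5% at default
noise) and a directional regression test asserts the bias is positive,
monotone in noise level, and bounded. Subtracting the no-cell-control
offset over-corrects (controls clip over the whole run, metabolic wells
only outside their active phase) and is therefore not applied.

## Heteroscedastic inference

Group variances of per-cell heat differ by an order of magnitude
(0.063–0.674 µJ²/cell² in the packaged dataset), so the one-way model
assumes a separate variance per group. The saturated mean model makes
the GLS means equal the sample means regardless of weights, so the
omnibus test is the closed-form Wald F with plug-in weights
w_g = n_g/s_g² on (k−1, N−k) df — verified in tests to coincide with an
iteratively reweighted GLS fit and with R `nlme::gls` +
`varIdent(form = ~1|group)`. Unbiased (n−1) variances are used
throughout; groups with fewer than two observations, or zero variance,
are refused rather than regularized.

With n = 8 per group the plug-in F is mildly anticonservative: under a
simulated null with the fixture's variance pattern its empirical size
at nominal 0.05 is ≈0.09. The test suite guards the band [0.03, 0.12]
as a regression check, not a claim of exactness.

Pairwise comparisons are Games–Howell: Welch standard error
√(s_i²/n_i + s_j²/n_j), Satterthwaite df per pair, and p-values from
the studentized-range distribution for k groups at q = |t|·√2 (the
in-suite cross-check is pingouin's independent implementation). The
compact letter display uses the insert-and-absorb algorithm, which
guarantees two groups share a letter iff their comparison is
non-significant; letters are assigned by descending group mean so the
largest mean reads "a".

## Tissue extrapolation and electron balance

Per-cell heat scales to tissue heat density multiplicatively:
µJ/cell × cells/mm² / 1000 → mJ/mm²; × thickness (mm) → mJ/mm. The
packaged healthy/osteoarthritic parameters are 4363 vs 1622 cells/mm²
(superficial-zone density) and 3.9 vs 3.68 mm (central medial
femorotibial thickness). The glucose-group mean (2.7925 µJ/cell) is the
per-cell heat used for these projections.

The capsule electron balance counts donor electrons as
Σ concentration × dilution × liquid volume × degree of reduction
(glucose 24, pyruvate 10, glutamine 18 e⁻/mol — nitrogen taken to
ammonia level; standard bioenergetic convention) against acceptor
electrons from headspace O₂ at 4 e⁻/mol. Defaults encode the capsule
geometry (656 µL total = 150 µL gel + 186 µL media + 320 µL headspace),
a 1:3 media:PBS dilution, and an elevation-corrected O₂ concentration
of 6.84 mmol/L. The liquid volume carrying donors is taken as gel +
media at suspension-media concentrations; serum and other trace carbon
are excluded (composition unknown). Under this convention the
glucose-media ratio computes to ≈5.9 (oxygen-limited) and the
glutamine-media ratio to ≈0.5 (oxygen-replete); only the glucose value
is asserted against its nominal ~5.5 band, since the volume convention
behind the published glutamine figure is not recoverable.

## Synthetic plates

The generator emulates the stated experimental world: 48 wells
(6 rows × 8 columns, 16 references in rows A/F), 1 Hz, 48 h, additive
i.i.d. Gaussian noise (default 0.2 µW), linear column drift (default
0.05 µW/h), and a loading spike (50 µW, τ = 600 s — magnitudes are not
published; chosen to dissipate within the observed 0–5 h window and
identical across wells so reference correction cancels it, as the
sample/reference traces of the real instrument do).

Metabolic kinetics are phenomenological: zero during a lag
(acclimatisation, default 13 h, the middle of the observed 12–15 h
onset band), then a saturating exponential rise toward
`peak_pW_per_cell × cell_count`, optionally followed by exponential
decay after fuel exhaustion. The default group profiles encode the
reported phenomenology — cells-only peaking at ~48 pW/cell and
exhausting at ~32 h (decay constant 4 h, a parameter the reports do not
quantify); fed groups plateauing near 38 h and holding, with peaks
(28 / 19 pW/cell, inside the 4–50 pW/cell envelope) chosen so 48 h
per-cell integrals land near the observed ~2.8 / ~1.9 µJ/cell group
means. `profiles_for_per_cell_heat` rescales peaks exactly to target
per-cell integrals (the integral is linear in the peak), which the
closed-loop tests use to match the published group means.

The closed-form integral of the kinetic curve is the recovery oracle;
it is independent of the trapezoidal pipeline route and checked against
1 s quadrature. A single integer seed drives everything through
deterministic per-well substreams `(seed, row, column)`, so equal seeds
give byte-identical plates.

What the generator does **not** model: autocorrelated instrument noise,
well-to-well kinetic variability within a group (within-group variance
in simulated plates comes from noise and processing alone, and is much
smaller than the biological variance in real data), thermal physics of
the capsule, or any enthalpy bookkeeping linking media composition to
total heat. A green closed-loop test therefore establishes that the
pipeline recovers programmed heat under the stated noise/drift model —
not that real biological variance structures are reproduced.

## Numerical choices

- Tolerances: positivity enforced with a 1e-9 µW slack; integration
  oracle asserted to 1e-9 relative; noiseless end-to-end recovery to
  0.1% (observed ~1e-5; the residual is the open trapezoid end vs the
  analytic integral to the full duration).
- Heavy property tests (100-plate closed loop, noise-bias sweep) run at
  0.1 Hz sampling; the headline recovery test runs at the full
  1 Hz × 48 h × 48 wells scale.
- Table ordering is column-major (B1, C1, …, E1, B2, …), matching how
  the cartridge is read.
- No-cell wells: the published table reports them in µJ/cell; the
  packaged fixture reproduces those numbers verbatim, and closed-loop
  tests tabulate control wells per nominal 150,000 cells to mirror that
  convention. The pipeline itself reports `None` per-cell heat for
  0-cell wells.
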