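# Methods

## System model

A system is a list of named *sites* — the atoms the analyses actually use —
grouped into molecules of a species. The built-in vocabulary covers the
drug scaffold variants DBD1–DBD5 (amine hydrogens H2/H4, sulfonyl oxygens
O11/O12), the phospholipids DOPC and DOPS (phosphate P, head oxygens
O13/O14, phosphodiester oxygens O11/O12, tail carbonyl/ester oxygens
O22/O32), cholesterol (hydroxyl O and H), water and ions. The vocabulary is
data-driven: a site-map JSON can declare new species without code changes.

Coordinates are angstrom, times nanoseconds, everywhere. Boxes are
orthorhombic only; triclinic input is rejected rather than silently
mis-wrapped, since every distance in the package is a minimum-image
distance computed by per-component wrapping. Bilayer molecules carry a
leaflet label; when absent it is assigned from the sign of each molecule's
phosphorus z relative to the median phosphorus z of the first frame, which
is exact for any pre-built symmetric bilayer.

File surfaces: single frames read/write as PDB (Å) and GRO (nm, converted
on ingest) through MDAnalysis; multi-frame series use a deliberately plain
text format (header `t Lx Ly Lz`, then one `x y z` line per atom per
frame) so fixtures stay human-readable and diffable.

## Radial distribution functions

`g_AB(r) = V <n_B(r)> / (4 N_B pi r^2 dr)`, averaged over frames and A
sites. Numerical choices, all covered by the brute-force equivalence test:

- **Binning** is half-open `[r, r+dr)`; a distance exactly at `r_max` is
  discarded. Default `dr = 0.05 Å`, `r_max = 12 Å` — fine enough to resolve
  the 1.6–2.1 Å hydrogen-bond band, and `r_max` is validated against half
  the smallest box edge (minimum-image validity).
- **Shell volume** uses the bin-centre `r²` rather than the exact
  `((r+dr)³−r³)` form; at `dr = 0.05` the difference is below 1%, and the
  oracle tests use the same convention so the comparison is exact.
- **V** is the trajectory-averaged box volume. Constant-pressure boxes
  fluctuate and a per-frame V would weight frames unevenly; the choice is
  configurable in effect because the curve retains its normalization
  metadata.
- **Pooling** of equivalent sites (O13/O14, O22/O32, O11/O12) happens at
  the selection level: the pooled population becomes species B with
  `N_B` the pooled count. Averaging two single-site RDFs of equal `N_B`
  gives the same curve, so the two readings of "averaged given their
  equivalence" coincide under this normalization.

## Potentials of mean force and barriers

`W(r) = −ln g(r)` in kBT units. Bins with `g = 0` are *undefined* (NaN) —
not zero, not capped — because the reversible-work relation simply carries
no information where no samples exist. Barrier extraction scans each
contiguous defined run inside a search window (default 1.0–6.0 Å, spanning
the hydrogen-bond first shell and the 4–5 Å second shell) for the first
interior local minimum followed by the first interior local maximum, using
`scipy.signal.find_peaks` with a prominence threshold (default 0.05 kBT)
to reject sampling wiggles; flat extrema resolve to their smallest-r edge.
No smoothing is applied by default; an odd-window moving average is
available. "No barrier" is a distinct outcome (None), not `dW = 0`.

Conversion to kcal/mol multiplies by an explicit factor, default 0.596.
Note a deliberate quirk: 0.596 kcal/mol corresponds to kB·T at ≈300 K,
while the emulated system is at 310.15 K (kB·310.15 K ≈ 0.616 kcal/mol).
The package follows the 0.596 reporting convention as the default and
never recomputes the factor from temperature behind the caller's back.

## Membrane metrics

`A = Lx·Ly / n_leaflet` with cholesterol included in the leaflet count (a
flag excludes it for lipid-only conventions); `dz` = mean upper-leaflet
phosphorus z minus mean lower-leaflet phosphorus z. Per-frame series are
emitted raw (no smoothing window), with population mean/sd and the sd/mean
fluctuation ratio.

## Hydrogen-bond kinetics

Bond criterion: donor–partner minimum-image distance ≤ cutoff, default
2.5 Å — wide enough to enclose the observed 1.6–2.1 Å bond-length band
with margin. No angular criterion is imposed (the site maps carry no
bond-vector information); the boundary case `d == cutoff` counts as bound.

Lifetimes: maximal bound runs of the frame-sampled state sequence, merged
across unbound gaps of duration ≤ tolerance (default 2 ns, always recorded
in output headers), `tau` = mean merged-run duration with duration = frame
count × dt. Gap frames inside a merged run count toward the duration.
Intervals truncated by the trajectory ends are included by default —
excluding them discards most data when `tau` is comparable to the
trajectory length, but including them biases `tau` downward in that
regime; the flag `include_edges=False` flips the trade. A never-bound pair
reports `tau = NaN` with zero intervals, distinct from a zero lifetime.

For pooled partners the per-frame bond partner is the *nearest* pooled
site, so a swap between the two equivalent oxygens of one phosphate group
does not register as a break.

Bridges: a frame is a bridging event when two distinct drug sites are
simultaneously bound to sites of two distinct partner molecules; two sites
on the same lipid do not bridge. Events carry the full contact list so
lipid+cholesterol triples can be reconstructed.

## Synthetic generator

The generator emulates the statistical structure the estimators assume,
not the physics that produces it:

- Two leaflets of 100 molecules each (56 DOPC : 14 DOPS : 30 CHOL) on
  jittered lattices, phosphate planes at ±21.5 Å (thickness 43.0 Å),
  default box 78.1 × 78.1 × 95.7 Å³, one drug molecule at the upper
  interface. Head oxygens sit ~1 Å inward of the phosphate plane,
  phosphodiester oxygens ~3 Å, tail oxygens ~8 Å.
- Each binding channel (donor site, partner species, pooled partner sites)
  is an independent two-state continuous-time Markov chain: exponential
  unbound dwells of mean 1/k_on and bound dwells of mean 1/k_off,
  simulated on the continuous clock and *sampled on the frame grid* — an
  excursion shorter than dt can be missed, exactly as in any real
  frame-sampled trajectory. The continuous-clock ground truth is returned,
  so estimator discretization bias is directly measurable.
- Bound distances are |N(mean, sd)| with per-donor defaults 1.7 Å (H2) and
  2.05 Å (H4), sd 0.1 Å — Gaussian is an assumption of this generator, not
  a property of any real system. The default channel battery pairs H2 with
  DOPC/DOPS head oxygens and H4 with DOPC phosphodiester oxygens and the
  cholesterol hydroxyl, with 1/k_off of 63.2, 27.0, 61.5 and 4.4 ns —
  spanning the few-ns to tens-of-ns lifetime regime — over 600 ns at
  dt = 0.1 ns.
- Non-bound partner oxygens are kept ≥ 4 Å from each donor so that RDF
  first shells are attributable to the configured channel. This carves a
  depleted zone between the bond shell and ~4.5 Å: the synthetic PMF well
  is one-sided (g = 0 beyond the flank), so barriers extracted from
  synthetic data are flank/noise extrema within the 0–10 kBT plausibility
  band rather than literature-scale barriers. That is a property of the
  generator, not of the extractor, and is why barrier correctness is
  established on analytic oracles (quartic double well) instead.
- Lateral box area fluctuates with a 5% sd by default (matching a
  constant-pressure bilayer's area fluctuation scale); all-atom thermal
  jitter is 0.3 Å per frame.

What passing tests on this generator do **not** show: real force-field
energetics, correlated binding between channels, angular hydrogen-bond
geometry, water competition, or lipid diffusion. They do show that every
estimator recovers the statistics it claims to measure, at the tolerances
its sampling permits.

## Problem sizes and tolerances in the test suite

Stochastic recovery tests use 3-standard-error bands with fixed seeds:
dwell-time recovery uses ≥ 2000 events from the bare chain (cheap), the
full detection-pipeline recovery uses a 9-molecule-per-leaflet patch over
20 000 frames (~300 events at 1/k_off = 3 ns). The uniform-gas RDF check
uses 150 tagged sites against 4000 background sites over 200 frames, which
puts every bin beyond 2 Å within 5% of unity with comfortable margin.
Brute-force equivalence checks (pair counting, bond thresholding, bridge
triples) run on ≤ 50-atom systems and assert bit-identical results.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- The RDF normalization assumes an isotropic reference; for sites confined
  to the interfacial slab the large-r plateau is below 1, which affects
  absolute W offsets but not barrier differences.
- No hydrogen-bond autocorrelation formalism (intermittent/continuous
  correlation functions) — lifetimes are mean continuous intervals only.
- The DCD/XTC adapter seam is declared but not implemented; the text
  trajectory format and PDB/GRO single frames are the supported inputs.
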