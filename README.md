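# memdrug

Trajectory analysis for small-molecule / lipid-bilayer systems: how a drug
sitting at a membrane interface binds lipid and cholesterol sites, how
strongly, and for how long.

The package targets the standard analysis battery for a drug–membrane MD
trajectory — here a benzothiadiazine-class solute at a DOPC/DOPS/cholesterol
bilayer in the liquid-crystal phase — and ships a synthetic-trajectory
generator with exact ground truth so every estimator can be validated end
to end without running any molecular dynamics.

## What it computes

**Site–site radial distribution functions.** For tagged site species A and B,

```
g_AB(r) = V <n_B(r)> / (4 N_B pi r^2 dr)
```

with `n_B(r)` the B-site count in the spherical shell `[r, r+dr)` around an
A site (minimum-image distances), `N_B` the total B count and `V` the mean
box volume, so `g -> 1` at large r in a uniform system. Equivalent sites
(e.g. the phosphate oxygens O13/O14) can be pooled into one population.

**Potentials of mean force and binding barriers.** The reversible-work
approximation `W_AB(r) = -kBT ln g_AB(r)`; the binding barrier `dW` is the
difference between the first local maximum and the preceding first local
minimum of W(r), reported in kBT and converted to kcal/mol with an explicit
factor (default 1 kBT = 0.596 kcal/mol).

**Membrane structural metrics.** Area per lipid `A = Lx*Ly / n_leaflet`
(lipids + cholesterol in one leaflet) and bilayer thickness `dz` = difference
of the mean phosphorus z between the two leaflets, per frame and averaged.

**Hydrogen-bond kinetics.** Distance-criterion bond detection (default
cutoff 2.5 Å), mean continuous bond lifetimes `tau` with transient breaks
shorter than a tolerance merged (default 2 ns), and detection of bridging
frames where two drug sites simultaneously bind two distinct membrane
molecules.

**Synthetic trajectories.** A two-leaflet 56:14:30 DOPC/DOPS/CHOL pseudo-
bilayer with one drug molecule whose donor sites (H2, H4) bind partner
oxygens as two-state Markov chains — exponential on/off kinetics, Gaussian
bond-length fluctuations around 1.7 Å (H2) / 2.05 Å (H4) — with the exact
state history returned alongside the coordinates.

## Worked example

```python
from memdrug import (
    SyntheticConfig, BindingPairSpec, HBPairSpec,
    build_system, simulate_binding, select_sites,
    compute_rdf, rdf_to_pmf, extract_barrier,
    membrane_series, pair_lifetime_table,
)

cfg = SyntheticConfig(
    seed=42,
    n_lipid_per_leaflet=25,
    box=(45.0, 45.0, 95.7),
    n_frames=2001,          # 200 ns at dt = 0.1 ns
    pairs=[BindingPairSpec("H2", "DOPC", ("O13", "O14"), k_on=0.5, k_off=0.1)],
)
system, _ = build_system(cfg)
traj, truth = simulate_binding(system, cfg)

series = membrane_series(traj)
print(f"A  = {series.mean_A:.2f} +/- {series.sd_A:.2f} A^2")
print(f"dz = {series.mean_dz:.2f} +/- {series.sd_dz:.2f} A")

h2 = select_sites(system, "DBD3", "H2")
rdf = compute_rdf(traj, h2, select_sites(system, "DOPC", {"O13", "O14"}))
print(f"g(r) peak at r = {rdf.r_peak:.2f} A")

table = pair_lifetime_table(traj, [HBPairSpec("DBD3", "H2", "DOPC", ("O13", "O14"))])
s = table[0]
print(f"{s.pair_label}: d = {s.mean_distance_bound:.2f} A, "
      f"tau = {s.tau:.1f} ns over {s.n_intervals} intervals")
```

prints

```
A  = 80.97 +/- 4.03 A^2
dz = 43.00 +/- 0.10 A
g(r) peak at r = 1.68 A
H2 / O13-O14 DOPC: d = 1.70 A, tau = 16.5 ns over 10 intervals
```

The RDF peak sits in the bin containing the configured 1.7 Å bond length
and the mean bound distance recovers it to two decimals. The lifetime
estimate (16.5 ns from 10 intervals, ground truth 1/k_off = 10 ns) shows
the sampling spread inherent to tens-of-ns bonds in a 200 ns window — the
same spread a real trajectory of that length has. The thickness matches the
constructed phosphate planes at ±21.5 Å; the area per lipid here reflects
the small 45 Å demo box, not a physical bilayer.

A YAML-driven pipeline runs the whole battery and writes CSV tables plus a
run manifest (`memdrug run --config run.yaml`); `memdrug synth`, `memdrug
rdf`, `memdrug membrane` and `memdrug hbonds` expose the individual stages.

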