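"""Synthetic bilayer trajectories with prescribed drug-binding statistics.

Every downstream estimator in this package (RDF, PMF, membrane metrics,
hydrogen-bond lifetimes) needs trajectories whose ground truth is known.
This module builds a two-leaflet pseudo-bilayer patch — per-leaflet
composition 56 DOPC : 14 DOPS : 30 CHOL on jittered lattices at
z = ±`leaflet_z_offset` — with one drug molecule at the upper interface
whose donor sites bind partner oxygens as independent two-state
continuous-time Markov chains:

* unbound dwell ~ Exponential(mean 1/k_on), bound dwell ~ Exponential(mean
  1/k_off), simulated on the continuous clock and sampled on the frame grid
  (an excursion shorter than dt can be missed — exactly what any
  frame-sampled trajectory analysis sees);
* while bound, the donor-partner distance is drawn as |N(mean, sd)| with a
  per-donor default of 1.7 Å (H2) and 2.05 Å (H4), the characteristic
  hydrogen-bond lengths of the emulated drug-membrane system;
* while unbound, the drug performs a uniform-step random walk with
  reflecting walls inside the upper interfacial slab.

There is no physics here — no forces, no thermostat — only the statistical
shapes the estimators assume, plus the exact ground truth needed to
measure their bias.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    DEFAULT_VOCABULARY,
    Frame,
    SiteRef,
    SystemMap,
    Trajectory,
    select_sites,
)

__all__ = [
    "BindingPairSpec",
    "SyntheticConfig",
    "GroundTruthBinding",
    "default_binding_battery",
    "build_system",
    "simulate_binding",
    "ideal_gas_frame",
    "sample_two_state_chain",
    "states_on_grid",
    "write_ground_truth_csv",
]

# Site z-placement inside a leaflet, in Å inward from the phosphate plane.
_HEAD_SITES = {"P": 0.0, "O13": 1.0, "O14": 1.0, "O11": 3.0, "O12": 3.0}
_TAIL_SITES = {"O22": 8.0, "O32": 8.0}
_LIPID_SITE_DEPTH = {**_HEAD_SITES, **_TAIL_SITES}
_CHOL_SITE_DEPTH = {"OH-O": 0.5, "OH-H": 0.5}


@dataclass(frozen=True)
class BindingPairSpec:
    """One donor-partner binding channel with its own on/off kinetics.

    Rates are in ns^-1; ``bound_distance_mean`` (Å) falls back to the
    per-donor default in :class:`SyntheticConfig` when None.
    """

    donor_site: str
    partner_species: str
    partner_sites: tuple[str, ...]
    k_on: float
    k_off: float
    bound_distance_mean: float | None = None

    @property
    def label(self) -> str:
        return f"{self.donor_site}/{'-'.join(self.partner_sites)} {self.partner_species}"


def default_binding_battery() -> list[BindingPairSpec]:
    """Default binding channels: head- and tail-group oxygens of the two
    phospholipids plus the cholesterol hydroxyl, with mean bound lifetimes
    (1/k_off) spanning the few-ns to tens-of-ns regime typical of
    drug-membrane hydrogen bonds."""
    return [
        BindingPairSpec("H2", "DOPC", ("O13", "O14"), k_on=0.10, k_off=1 / 63.2),
        BindingPairSpec("H2", "DOPS", ("O13", "O14"), k_on=0.05, k_off=1 / 27.0),
        BindingPairSpec("H4", "DOPC", ("O11", "O12"), k_on=0.10, k_off=1 / 61.5),
        BindingPairSpec("H4", "CHOL", ("OH-O",), k_on=0.02, k_off=1 / 4.4),
    ]


@dataclass
class SyntheticConfig:
    """Generator settings.  Defaults emulate the reference study system:
    100 lipid+cholesterol molecules per leaflet in a 78.1 x 78.1 x 95.7 Å
    box, phosphate planes at ±21.5 Å (thickness 43.0 Å), one drug molecule,
    600 ns sampled every 0.1 ns."""

    seed: int = 0
    n_lipid_per_leaflet: int = 100
    box: tuple[float, float, float] = (78.1, 78.1, 95.7)
    dt: float = 0.1
    n_frames: int = 6001
    bound_distance_mean: dict[str, float] = field(
        default_factory=lambda: {"H2": 1.7, "H4": 2.05, "O11": 2.1, "O12": 2.1}
    )
    bound_distance_sd: float = 0.1
    leaflet_z_offset: float = 21.5
    pairs: list[BindingPairSpec] = field(default_factory=default_binding_battery)
    drug_species: str = "DBD3"
    box_jitter_frac: float = 0.05  # sd of the lateral-area factor
    position_jitter_sd: float = 0.3  # Å, per-frame thermal jitter
    exclusion_radius: float = 4.0  # Å, non-bound partner oxygens kept out
    partner_swap_prob: float = 0.02  # per-frame swap between equivalent sites
    min_spacing: float = 4.0  # Å, minimal lattice spacing before error
    n_water: int = 0  # optional uniform background species

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.bound_distance_sd <= 0:
            raise ValueError("bound_distance_sd must be > 0")
        for p in self.pairs:
            if p.k_on < 0 or p.k_off < 0:
                raise ValueError(f"negative rate in pair {p.label}")


@dataclass
class GroundTruthBinding:
    """Exact state history of one binding channel.

    ``intervals`` lives on the continuous clock as (bound, t_start, t_end)
    triples covering [0, duration]; ``bound`` is the state sampled on the
    frame grid; ``partner_molecule`` is the designated partner.
    """

    pair: BindingPairSpec
    intervals: list[tuple[bool, float, float]]
    bound: np.ndarray
    partner_molecule: int

    def mean_bound_interval(self) -> float:
        durs = [t1 - t0 for s, t0, t1 in self.intervals if s]
        return float(np.mean(durs)) if durs else math.nan


# ---------------------------------------------------------------------------
# Two-state chain on the continuous clock
# ---------------------------------------------------------------------------

def sample_two_state_chain(
    k_on: float,
    k_off: float,
    duration: float,
    rng: np.random.Generator,
    start_bound: bool | None = None,
) -> list[tuple[bool, float, float]]:
    """Alternating exponential dwell intervals covering [0, duration].

    The initial state defaults to the stationary distribution
    (P(bound) = k_on / (k_on + k_off)); an absorbing state (zero escape
    rate) is entered immediately so that e.g. k_off = 0 yields a single
    bound interval of the full duration.
    """
    if k_on + k_off <= 0:
        raise ValueError("k_on + k_off must be > 0")
    if start_bound is None:
        if k_off == 0:
            state = True
        elif k_on == 0:
            state = False
        else:
            state = bool(rng.random() < k_on / (k_on + k_off))
    else:
        state = start_bound
    out: list[tuple[bool, float, float]] = []
    t = 0.0
    while t < duration:
        rate = k_off if state else k_on
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        t1 = min(t + dwell, duration)
        out.append((state, t, t1))
        t = t1
        state = not state
    return out


def states_on_grid(
    intervals: list[tuple[bool, float, float]], times: np.ndarray
) -> np.ndarray:
    """Sample the interval sequence at the given times (half-open on the
    right: a frame at an interval boundary takes the newer state)."""
    starts = np.array([t0 for _, t0, _ in intervals])
    states = np.array([s for s, _, _ in intervals], dtype=bool)
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(states) - 1)
    return states[idx]


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def _leaflet_composition(n: int) -> list[str]:
    n_dopc = round(0.56 * n)
    n_dops = round(0.14 * n)
    n_chol = n - n_dopc - n_dops
    if min(n_dopc, n_dops, n_chol) < 0:
        raise ValueError(f"cannot realize 56:14:30 composition with n={n}")
    return ["DOPC"] * n_dopc + ["DOPS"] * n_dops + ["CHOL"] * n_chol


def build_system(config: SyntheticConfig) -> tuple[SystemMap, Frame]:
    """Place the bilayer on jittered per-leaflet lattices and the drug at
    the upper interface; returns the system map and the initial frame."""
    lx, ly, lz = config.box
    n = config.n_lipid_per_leaflet
    m = math.ceil(math.sqrt(n))
    spacing = min(lx, ly) / m
    if spacing < config.min_spacing:
        raise ValueError(
            f"box {lx:.1f}x{ly:.1f} too small for {n} molecules per leaflet "
            f"(lattice spacing {spacing:.2f} Å < {config.min_spacing} Å)"
        )
    rng = np.random.default_rng(config.seed)
    atoms: list[SiteRef] = []
    positions: list[np.ndarray] = []
    leaflet: dict[int, str] = {}
    mol_id = 0
    off = config.leaflet_z_offset

    for label, sign in (("upper", +1.0), ("lower", -1.0)):
        species = _leaflet_composition(n)
        rng.shuffle(species)
        cells = [(i, j) for i in range(m) for j in range(m)][:n]
        for (ci, cj), sp in zip(cells, species):
            x0 = (ci + 0.5) * lx / m + rng.uniform(-0.15, 0.15) * spacing
            y0 = (cj + 0.5) * ly / m + rng.uniform(-0.15, 0.15) * spacing
            depth = _LIPID_SITE_DEPTH if sp in ("DOPC", "DOPS") else _CHOL_SITE_DEPTH
            for site, d in depth.items():
                lat = rng.uniform(-1.2, 1.2, size=2)
                atoms.append(SiteRef(mol_id, sp, site))
                positions.append(
                    np.array([x0 + lat[0], y0 + lat[1], sign * (off - d)])
                )
            leaflet[mol_id] = label
            mol_id += 1

    # one drug molecule at the upper interface, sites clustered within ~2 Å
    cx, cy = lx / 2.0, ly / 2.0
    drug_z = off + 2.0
    drug_offsets = {
        "H2": np.array([0.0, 0.0, -1.0]),
        "H4": np.array([1.8, 0.0, -1.0]),
        "O11": np.array([0.0, 1.5, 0.0]),
        "O12": np.array([1.8, 1.5, 0.0]),
    }
    for site, d in drug_offsets.items():
        atoms.append(SiteRef(mol_id, config.drug_species, site))
        positions.append(np.array([cx, cy, drug_z]) + d)
    mol_id += 1

    for _ in range(config.n_water):
        atoms.append(SiteRef(mol_id, "WATER", "O"))
        positions.append(rng.uniform(0, 1, size=3) * np.array([lx, ly, lz]))
        mol_id += 1

    system = SystemMap(atoms=atoms, leaflet=leaflet)
    frame = Frame(time=0.0, positions=np.array(positions), box=config.box)
    return system, frame


# ---------------------------------------------------------------------------
# Binding simulation
# ---------------------------------------------------------------------------

def _designated_partner(
    system: SystemMap, frame0: Frame, pair: BindingPairSpec, donor_pos: np.ndarray
) -> tuple[int, np.ndarray]:
    """Pick the upper-leaflet partner molecule nearest the drug start."""
    pool = select_sites(system, pair.partner_species, set(pair.partner_sites))
    if pool.size == 0:
        raise ValueError(f"no partner sites for pair {pair.label}")
    upper = {
        m for m, l in system.leaflet.items() if l == "upper"
    }
    cand = [i for i in pool if system.atoms[i].molecule_id in upper] or list(pool)
    d2 = np.sum((frame0.positions[cand] - donor_pos) ** 2, axis=1)
    best_mol = system.atoms[cand[int(np.argmin(d2))]].molecule_id
    own = np.array(
        [i for i in pool if system.atoms[i].molecule_id == best_mol], dtype=np.intp
    )
    return best_mol, own


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_binding(
    system: SystemMap, config: SyntheticConfig, frame0: Frame | None = None
) -> tuple[Trajectory, dict[str, GroundTruthBinding]]:
    """Simulate the frame sequence and return it with exact ground truth.

    Fully reproducible from (seed, config): all randomness flows from one
    `numpy` Generator seeded with ``config.seed``.
    """
    if not any(p.k_on + p.k_off > 0 for p in config.pairs):
        raise ValueError("at least one pair must have k_on + k_off > 0")
    rng = np.random.default_rng(config.seed + 1)
    if frame0 is None:
        # build_system is deterministic in config.seed, so the rebuilt
        # frame matches any system built from the same config
        _, frame0 = build_system(config)
    nf = config.n_frames
    times = np.arange(nf) * config.dt
    duration = times[-1]
    home = frame0.positions.copy()
    lx, ly, lz = config.box
    off = config.leaflet_z_offset

    # per-frame boxes: lateral area factor ~ N(1, box_jitter_frac)
    area = np.clip(rng.normal(1.0, config.box_jitter_frac, size=nf), 0.5, None)
    boxes = np.empty((nf, 3))
    boxes[:, 0] = lx * np.sqrt(area)
    boxes[:, 1] = ly * np.sqrt(area)
    boxes[:, 2] = lz

    # drug centre: uniform-step random walk, reflecting in the upper slab
    drug_idx = np.array(
        [i for i, a in enumerate(system.atoms) if a.species == config.drug_species],
        dtype=np.intp,
    )
    drug_home = home[drug_idx].copy()
    centre0 = drug_home.mean(axis=0)
    steps = rng.uniform(-0.5, 0.5, size=(nf, 3))
    steps[0] = 0.0
    centre = centre0 + np.cumsum(steps, axis=0)
    z_lo, z_hi = off - 2.0, off + 6.0
    span = z_hi - z_lo
    z = np.mod(centre[:, 2] - z_lo, 2 * span)
    centre[:, 2] = z_lo + np.where(z > span, 2 * span - z, z)  # reflect
    centre[:, 0] = np.mod(centre[:, 0], lx)
    centre[:, 1] = np.mod(centre[:, 1], ly)

    # all-atom thermal jitter around home positions
    pos = home[None, :, :] + rng.normal(
        0.0, config.position_jitter_sd, size=(nf, system.n_atoms, 3)
    )
    pos[:, drug_idx, :] = centre[:, None, :] + (drug_home - centre0)[None, :, :]

    donor_index = {
        a.site_name: i
        for i, a in zip(drug_idx, (system.atoms[i] for i in drug_idx))
    }

    truth: dict[str, GroundTruthBinding] = {}
    bound_atom_of_frame: dict[int, np.ndarray] = {}  # pair order -> atom idx per frame
    for k, pair in enumerate(config.pairs):
        if pair.donor_site not in donor_index:
            raise ValueError(f"drug has no site {pair.donor_site!r}")
        di = donor_index[pair.donor_site]
        if pair.k_on + pair.k_off == 0:
            intervals = [(False, 0.0, float(duration))]
        else:
            intervals = sample_two_state_chain(
                pair.k_on, pair.k_off, float(duration), rng
            )
        bound = states_on_grid(intervals, times)
        mol, own_atoms = _designated_partner(system, frame0, pair, home[di])
        # choose which equivalent site carries the bond, swapping rarely
        choice = np.zeros(nf, dtype=np.intp)
        if len(own_atoms) > 1:
            swaps = rng.random(nf) < config.partner_swap_prob
            choice = np.mod(np.cumsum(swaps), len(own_atoms)).astype(np.intp)
        chosen = own_atoms[choice]
        nb = int(bound.sum())
        if nb:
            r = np.abs(
                rng.normal(
                    pair.bound_distance_mean
                    if pair.bound_distance_mean is not None
                    else config.bound_distance_mean[pair.donor_site],
                    config.bound_distance_sd,
                    size=nb,
                )
            )
            u = _random_unit_vectors(rng, nb)
            pos[bound, chosen[bound], :] = pos[bound, di, :] + r[:, None] * u
        bound_atom_of_frame[k] = np.where(bound, chosen, -1)
        truth[pair.label] = GroundTruthBinding(
            pair=pair, intervals=intervals, bound=bound, partner_molecule=mol
        )

    # keep non-bound partner oxygens out of the donor's first shell
    for donor_site in {p.donor_site for p in config.pairs}:
        di = donor_index[donor_site]
        pool = np.unique(
            np.concatenate(
                [
                    select_sites(system, p.partner_species, set(p.partner_sites))
                    for p in config.pairs
                    if p.donor_site == donor_site
                ]
            )
        )
        carries_bond = np.zeros((nf, pool.size), dtype=bool)
        for k, p in enumerate(config.pairs):
            if p.donor_site == donor_site:
                carries_bond |= pool[None, :] == bound_atom_of_frame[k][:, None]
        d = pos[:, pool, :] - pos[:, di, None, :]
        d -= boxes[:, None, :] * np.round(d / boxes[:, None, :])
        dist = np.linalg.norm(d, axis=2)
        too_close = (dist < config.exclusion_radius) & ~carries_bond
        if np.any(too_close):
            f_ix, p_ix = np.nonzero(too_close)
            vec = d[f_ix, p_ix, :]
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            pushed = pos[f_ix, di, :] + vec / norm * (config.exclusion_radius + 0.5)
            pos[f_ix, pool[p_ix], :] = pushed

    frames = [
        Frame(time=float(times[i]), positions=pos[i], box=boxes[i]) for i in range(nf)
    ]
    return Trajectory(system=system, frames=frames, dt=config.dt), truth


# ---------------------------------------------------------------------------
# Ideal-gas oracle frames
# ---------------------------------------------------------------------------

def ideal_gas_frame(
    n_A: int, n_B: int, box, seed: int = 0
) -> tuple[SystemMap, Frame]:
    """Uniform i.i.d. positions for two inert species — the closed-form
    reference for RDF normalization (g must tend to 1 everywhere)."""
    if n_A < 1 or n_B < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    vocab = {"GAS_A": ("X",), "GAS_B": ("X",)}
    atoms = [SiteRef(i, "GAS_A", "X") for i in range(n_A)]
    atoms += [SiteRef(n_A + i, "GAS_B", "X") for i in range(n_B)]
    b = np.asarray(box, dtype=float)
    pos = rng.uniform(0.0, 1.0, size=(n_A + n_B, 3)) * b
    system = SystemMap(atoms=atoms, vocabulary=vocab)
    return system, Frame(time=0.0, positions=pos, box=b)


def write_ground_truth_csv(truth: dict[str, GroundTruthBinding], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["pair", "state", "t_start", "t_end"])
        for label, gt in truth.items():
            for state, t0, t1 in gt.intervals:
                w.writerow([label, "bound" if state else "unbound", f"{t0:.6f}", f"{t1:.6f}"])
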