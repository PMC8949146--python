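"""Hydrogen-bond detection, lifetime estimation, and bridge detection.

A hydrogen bond is declared by a pure distance criterion: donor site and
partner heavy atom within a cutoff (default 2.5 Å, enclosing the
characteristic 1.6-2.1 Å hydrogen-bond band with margin; no angular
criterion is imposed).  A distance exactly at the cutoff counts as bound.

The mean continuous lifetime tau of a bond is the mean duration of its
maximal bound runs, after merging runs separated by unbound gaps no longer
than a reformation tolerance — short-lived breaking and reformation of a
bond is not counted as two events.  Intervals truncated by the trajectory
ends are included by default (toggleable), which biases tau downward when
lifetimes are comparable to the trajectory length.

A bridging configuration is one drug molecule simultaneously bound through
two of its sites to two distinct partner molecules (lipid and/or
cholesterol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

import numpy as np

from .core import SiteRef, SystemMap, Trajectory, pair_distances, select_sites

__all__ = [
    "DEFAULT_CUTOFF",
    "DEFAULT_TOLERANCE",
    "BondTimeline",
    "LifetimeSummary",
    "BridgeEvent",
    "HBPairSpec",
    "detect_bonds",
    "lifetimes",
    "pair_lifetime_table",
    "detect_bridges",
]

DEFAULT_CUTOFF = 2.5  # Å
DEFAULT_TOLERANCE = 2.0  # ns, reformation tolerance for merging breaks


@dataclass
class BondTimeline:
    """Per-frame bound/unbound state and distance for one donor-partner pair."""

    donor: SiteRef
    acceptor_label: str
    states: np.ndarray  # bool per frame
    distances: np.ndarray  # Å per frame (recorded regardless of state)
    cutoff: float


@dataclass
class LifetimeSummary:
    """Mean continuous bound lifetime of one pair (tau, ns)."""

    pair_label: str
    mean_distance_bound: float
    tau: float
    n_intervals: int
    tolerance_used: float


@dataclass
class BridgeEvent:
    """One frame in which the drug bridges two distinct partner molecules."""

    frame_index: int
    drug_sites: list[str]
    partner_molecules: list[int]
    partner_sites: list[str]
    contacts: list[tuple[str, int, str, str]] = field(default_factory=list)
    # contacts: (drug_site, partner_molecule_id, partner_species, partner_site)


@dataclass(frozen=True)
class HBPairSpec:
    """A (drug site, pooled partner) pairing for the lifetime table."""

    donor_species: str
    donor_site: str
    partner_species: str
    partner_sites: tuple[str, ...]

    @property
    def label(self) -> str:
        return (
            f"{self.donor_site} / "
            f"{'-'.join(self.partner_sites)} {self.partner_species}"
        )


def detect_bonds(
    traj: Trajectory,
    donor_sel: np.ndarray,
    acceptor_sel: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[BondTimeline]:
    """One timeline per (donor, acceptor) atom pair.

    Bound iff the minimum-image distance is <= cutoff (boundary counts as
    bound); the distance is recorded at every frame regardless of state.
    """
    donor_sel = np.asarray(donor_sel, dtype=np.intp)
    acceptor_sel = np.asarray(acceptor_sel, dtype=np.intp)
    if donor_sel.size == 0 or acceptor_sel.size == 0:
        raise ValueError("empty selection")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    nf = traj.n_frames
    dist = np.empty((nf, donor_sel.size, acceptor_sel.size))
    for i, frame in enumerate(traj.frames):
        dist[i] = pair_distances(
            frame.positions[donor_sel], frame.positions[acceptor_sel], frame.box
        )
    out = []
    for a, da in enumerate(donor_sel):
        for b, ab in enumerate(acceptor_sel):
            acc = traj.system.atoms[ab]
            out.append(
                BondTimeline(
                    donor=traj.system.atoms[da],
                    acceptor_label=f"{acc.site_name} {acc.species}#{acc.molecule_id}",
                    states=dist[:, a, b] <= cutoff,
                    distances=dist[:, a, b].copy(),
                    cutoff=cutoff,
                )
            )
    return out


def _bound_runs(states: np.ndarray) -> list[tuple[int, int]]:
    """Maximal bound runs as (first, last) frame indices, inclusive."""
    s = np.asarray(states, dtype=bool)
    if s.size == 0:
        return []
    d = np.diff(s.astype(np.int8))
    starts = (np.nonzero(d == 1)[0] + 1).tolist()
    ends = np.nonzero(d == -1)[0].tolist()
    if s[0]:
        starts = [0] + starts
    if s[-1]:
        ends = ends + [s.size - 1]
    return list(zip(starts, ends))


def merged_intervals(
    states: np.ndarray, dt: float, tolerance: float
) -> list[tuple[int, int]]:
    """Bound runs merged across unbound gaps of duration <= tolerance."""
    runs = _bound_runs(states)
    if not runs:
        return []
    merged = [runs[0]]
    for start, end in runs[1:]:
        gap_frames = start - merged[-1][1] - 1
        if gap_frames * dt <= tolerance:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def lifetimes(
    timeline: BondTimeline,
    dt: float,
    tolerance: float = DEFAULT_TOLERANCE,
    include_edges: bool = True,
    pair_label: str | None = None,
) -> LifetimeSummary:
    """Mean continuous bound interval (tau) of one timeline.

    An interval's duration is its frame count times dt (gap frames inside a
    merged interval count toward the duration).  A never-bound timeline
    yields n_intervals = 0 and tau = NaN — undefined, not zero.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ivals = merged_intervals(timeline.states, dt, tolerance)
    if not include_edges:
        last = timeline.states.size - 1
        ivals = [(a, b) for a, b in ivals if a != 0 and b != last]
    durs = [(b - a + 1) * dt for a, b in ivals]
    bound = timeline.states
    return LifetimeSummary(
        pair_label=pair_label
        or f"{timeline.donor.site_name} / {timeline.acceptor_label}",
        mean_distance_bound=float(np.mean(timeline.distances[bound]))
        if bound.any()
        else nan,
        tau=float(np.mean(durs)) if durs else nan,
        n_intervals=len(durs),
        tolerance_used=tolerance,
    )


def pooled_timeline(
    traj: Trajectory, spec: HBPairSpec, cutoff: float = DEFAULT_CUTOFF
) -> BondTimeline:
    """Timeline of one drug site against the nearest pooled partner site.

    The per-frame bond partner is the nearest site in the pooled selection,
    so a swap between equivalent oxygens does not register as a break.
    """
    donor_sel = select_sites(traj.system, spec.donor_species, spec.donor_site)
    if donor_sel.size != 1:
        raise ValueError(
            f"expected one donor atom for {spec.donor_species}:{spec.donor_site}, "
            f"got {donor_sel.size}"
        )
    pool = select_sites(traj.system, spec.partner_species, set(spec.partner_sites))
    if pool.size == 0:
        raise ValueError(f"empty partner pool for {spec.label}")
    nf = traj.n_frames
    dmin = np.empty(nf)
    for i, frame in enumerate(traj.frames):
        d = pair_distances(
            frame.positions[donor_sel], frame.positions[pool], frame.box
        )
        dmin[i] = d.min()
    return BondTimeline(
        donor=traj.system.atoms[donor_sel[0]],
        acceptor_label=f"{'-'.join(spec.partner_sites)} {spec.partner_species}",
        states=dmin <= cutoff,
        distances=dmin,
        cutoff=cutoff,
    )


def pair_lifetime_table(
    traj: Trajectory,
    pair_specs: list[HBPairSpec],
    cutoff: float = DEFAULT_CUTOFF,
    tolerance: float = DEFAULT_TOLERANCE,
    include_edges: bool = True,
) -> list[LifetimeSummary]:
    """One lifetime summary per (drug site, pooled partner) pairing."""
    return [
        lifetimes(
            pooled_timeline(traj, spec, cutoff),
            traj.dt,
            tolerance,
            include_edges=include_edges,
            pair_label=spec.label,
        )
        for spec in pair_specs
    ]


def detect_bridges(
    traj: Trajectory,
    drug_sel: np.ndarray,
    partner_sel: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[BridgeEvent]:
    """Frames where >=2 distinct drug sites bind two distinct partners.

    ``drug_sel`` holds the candidate drug sites (>= 2 required) and
    ``partner_sel`` the candidate partner sites of any species.  An event
    requires two bound contacts that differ in both the drug site and the
    partner molecule; two sites bound to the same molecule do not bridge.
    """
    drug_sel = np.asarray(drug_sel, dtype=np.intp)
    partner_sel = np.asarray(partner_sel, dtype=np.intp)
    if drug_sel.size < 2:
        raise ValueError("need >= 2 drug sites to detect bridges")
    atoms = traj.system.atoms
    events: list[BridgeEvent] = []
    for fi, frame in enumerate(traj.frames):
        d = pair_distances(
            frame.positions[drug_sel], frame.positions[partner_sel], frame.box
        )
        si, pi = np.nonzero(d <= cutoff)
        if si.size < 2:
            continue
        contacts = [
            (
                atoms[drug_sel[a]].site_name,
                atoms[partner_sel[b]].molecule_id,
                atoms[partner_sel[b]].species,
                atoms[partner_sel[b]].site_name,
            )
            for a, b in zip(si, pi)
        ]
        is_bridge = any(
            c1[0] != c2[0] and c1[1] != c2[1]
            for i, c1 in enumerate(contacts)
            for c2 in contacts[i + 1 :]
        )
        if is_bridge:
            events.append(
                BridgeEvent(
                    frame_index=fi,
                    drug_sites=sorted({c[0] for c in contacts}),
                    partner_molecules=sorted({c[1] for c in contacts}),
                    partner_sites=sorted({c[3] for c in contacts}),
                    contacts=contacts,
                )
            )
    return events
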