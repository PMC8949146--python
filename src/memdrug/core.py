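"""Domain types and periodic-boundary geometry shared by all analysis stages.

The objects here describe a simulation system at the granularity the
analyses need: *sites* (named atoms such as a drug's H2 hydrogen or a
lipid's phosphorus) grouped into molecules of a given species, plus
time-stamped coordinate frames with an orthorhombic periodic box.

Coordinates are stored in angstrom (Å) and times in nanoseconds (ns)
throughout the package; file readers convert on ingest (GRO files store
nm).  Only orthorhombic boxes are supported — triclinic input is rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_VOCABULARY",
    "MEMBRANE_SPECIES",
    "SiteRef",
    "SystemMap",
    "Frame",
    "Trajectory",
    "minimum_image_distance",
    "pair_distances",
    "select_sites",
    "assign_leaflets",
    "read_sitemap_json",
    "write_sitemap_json",
    "read_trajectory_text",
    "write_trajectory_text",
    "read_frame",
    "write_frame",
]

#: Built-in site vocabulary.  Drug species expose the two amine hydrogens
#: (H2, H4) and the two sulfonyl oxygens (O11, O12); phospholipids expose
#: the phosphate group (P, O13, O14), the phosphodiester oxygens (O11, O12)
#: and the two carbonyl/ester tail oxygens (O22, O32); cholesterol exposes
#: its hydroxyl oxygen and hydrogen.  The vocabulary is data-driven: a
#: site-map JSON may declare additional species without code changes.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    **{f"DBD{i}": ("H2", "H4", "O11", "O12") for i in range(1, 6)},
    "DOPC": ("P", "O11", "O12", "O13", "O14", "O22", "O32"),
    "DOPS": ("P", "O11", "O12", "O13", "O14", "O22", "O32"),
    "CHOL": ("OH-O", "OH-H"),
    "WATER": ("O", "H1", "H2"),
    "ION": ("ION",),
}

#: Species that belong to the bilayer and therefore carry a leaflet label.
MEMBRANE_SPECIES = frozenset({"DOPC", "DOPS", "CHOL"})


@dataclass(frozen=True)
class SiteRef:
    """One named atom: which molecule it belongs to, and what it is."""

    molecule_id: int
    species: str
    site_name: str


@dataclass
class SystemMap:
    """Atoms grouped into molecules, with leaflet assignment and vocabulary.

    Parameters
    ----------
    atoms
        Ordered atom list; position ``i`` in every :class:`Frame` refers to
        ``atoms[i]``.
    leaflet
        ``molecule_id -> "upper" | "lower"`` for bilayer molecules
        (DOPC/DOPS/CHOL); drug, water and ion molecules carry no label.
    vocabulary
        ``species -> allowed site names``.  Defaults to
        :data:`DEFAULT_VOCABULARY`.
    membrane_species
        Species that must (and alone may) carry a leaflet label.
    """

    atoms: list[SiteRef]
    leaflet: dict[int, str] = field(default_factory=dict)
    vocabulary: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )
    membrane_species: frozenset[str] = MEMBRANE_SPECIES

    def __post_init__(self) -> None:
        for a in self.atoms:
            sites = self.vocabulary.get(a.species)
            if sites is None:
                raise ValueError(f"unknown species {a.species!r}")
            if a.site_name not in sites:
                raise ValueError(
                    f"site {a.site_name!r} not in vocabulary of {a.species!r}"
                )
        species_of = self.molecule_species
        for mol_id, label in self.leaflet.items():
            if label not in ("upper", "lower"):
                raise ValueError(f"bad leaflet label {label!r}")
            if species_of[mol_id] not in self.membrane_species:
                raise ValueError(
                    f"leaflet label on non-membrane molecule {mol_id}"
                )
        for mol_id, sp in species_of.items():
            if sp in self.membrane_species and mol_id not in self.leaflet:
                raise ValueError(f"membrane molecule {mol_id} has no leaflet")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def molecule_species(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for a in self.atoms:
            prev = out.setdefault(a.molecule_id, a.species)
            if prev != a.species:
                raise ValueError(
                    f"molecule {a.molecule_id} has conflicting species"
                )
        return out

    def leaflet_molecules(self, label: str) -> list[int]:
        return sorted(m for m, l in self.leaflet.items() if l == label)

    @property
    def per_leaflet_count(self) -> int:
        """Lipid + cholesterol molecules in one leaflet.

        Raises if the two leaflets are asymmetric, in which case the caller
        must choose a count explicitly.
        """
        n_up = len(self.leaflet_molecules("upper"))
        n_lo = len(self.leaflet_molecules("lower"))
        if n_up != n_lo:
            raise ValueError(
                f"asymmetric leaflets ({n_up} upper vs {n_lo} lower); "
                "pass per_leaflet_count explicitly"
            )
        return n_up


def _as_box(box) -> np.ndarray:
    b = np.asarray(box, dtype=float).reshape(3)
    if not np.all(np.isfinite(b)) or np.any(b <= 0):
        raise ValueError(f"box components must be finite and > 0, got {b}")
    return b


@dataclass
class Frame:
    """One time point: positions in Å plus the orthorhombic box (Lx,Ly,Lz)."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.box = _as_box(self.box)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))


@dataclass
class Trajectory:
    """A time-ordered frame sequence over one :class:`SystemMap`."""

    system: SystemMap
    frames: list[Frame]
    dt: float

    def __post_init__(self) -> None:
        n = self.system.n_atoms
        for f in self.frames:
            if len(f.positions) != n:
                raise ValueError(
                    f"frame has {len(f.positions)} atoms, system has {n}"
                )
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Span covered by the sampled frames, (n_frames - 1) * dt."""
        return (self.n_frames - 1) * self.dt


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image_distance(p1, p2, box) -> float:
    """Minimum-image distance between two points in an orthorhombic box.

    Returns the smallest ``|p1 - p2 + n * box|`` over integer translation
    vectors ``n``; for an orthorhombic box this is obtained by wrapping each
    Cartesian component into ``[-L/2, L/2)``.
    """
    b = _as_box(box)
    d = np.asarray(p1, dtype=float) - np.asarray(p2, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinates")
    d -= b * np.round(d / b)
    return float(np.linalg.norm(d))


def pair_distances(pos_a: np.ndarray, pos_b: np.ndarray, box) -> np.ndarray:
    """Minimum-image distance matrix, shape ``(len(pos_a), len(pos_b))``."""
    b = _as_box(box)
    d = np.asarray(pos_a, float)[:, None, :] - np.asarray(pos_b, float)[None, :, :]
    d -= b * np.round(d / b)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _as_labels(x) -> tuple[str, ...]:
    if isinstance(x, str):
        return (x,)
    return tuple(x)


def select_sites(system: SystemMap, species, site_name) -> np.ndarray:
    """Atom indices matching the given species and site name(s).

    ``species`` and ``site_name`` each accept a single label or a set of
    labels; a site-name set pools equivalent sites (e.g. ``{"O13","O14"}``)
    into one population whose size is the total pooled count.
    """
    species_set = _as_labels(species)
    site_set = _as_labels(site_name)
    for sp in species_set:
        if sp not in system.vocabulary:
            raise KeyError(f"unknown species {sp!r}")
    for s in site_set:
        if not any(s in system.vocabulary[sp] for sp in species_set):
            raise KeyError(
                f"site {s!r} not defined for species {sorted(species_set)}"
            )
    idx = [
        i
        for i, a in enumerate(system.atoms)
        if a.species in species_set and a.site_name in site_set
    ]
    return np.array(idx, dtype=np.intp)


def assign_leaflets(system: SystemMap, frame: Frame) -> dict[int, str]:
    """Leaflet labels from the sign of (z_P - median z over all P atoms).

    Molecules without a phosphorus site (cholesterol) are assigned by the
    sign of their mean site z relative to the same median.  Returns a new
    ``molecule_id -> label`` mapping; the system is not modified.
    """
    z = frame.positions[:, 2]
    p_idx = [i for i, a in enumerate(system.atoms) if a.site_name == "P"]
    if not p_idx:
        raise ValueError("no phosphorus sites; cannot assign leaflets")
    z_mid = float(np.median(z[p_idx]))
    out: dict[int, str] = {}
    species_of = system.molecule_species
    for mol_id, sp in species_of.items():
        if sp not in system.membrane_species:
            continue
        own = [i for i, a in enumerate(system.atoms) if a.molecule_id == mol_id]
        own_p = [i for i in own if system.atoms[i].site_name == "P"]
        ref = np.mean(z[own_p]) if own_p else np.mean(z[own])
        out[mol_id] = "upper" if ref >= z_mid else "lower"
    return out


# ---------------------------------------------------------------------------
# Site-map JSON
# ---------------------------------------------------------------------------

def write_sitemap_json(system: SystemMap, path) -> None:
    """Serialize a SystemMap (molecules, sites, leaflets, vocabulary)."""
    mols: dict[int, dict] = {}
    for i, a in enumerate(system.atoms):
        m = mols.setdefault(
            a.molecule_id,
            {
                "id": a.molecule_id,
                "species": a.species,
                "leaflet": system.leaflet.get(a.molecule_id),
                "sites": {},
            },
        )
        m["sites"].setdefault(a.site_name, []).append(i)
    doc = {
        "vocabulary": {k: list(v) for k, v in system.vocabulary.items()},
        "molecules": [mols[k] for k in sorted(mols)],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_sitemap_json(path) -> SystemMap:
    with open(path) as fh:
        doc = json.load(fh)
    vocab = {k: tuple(v) for k, v in doc["vocabulary"].items()}
    indexed: dict[int, SiteRef] = {}
    leaflet: dict[int, str] = {}
    for mol in doc["molecules"]:
        if mol.get("leaflet"):
            leaflet[mol["id"]] = mol["leaflet"]
        for site, idxs in mol["sites"].items():
            for i in idxs:
                indexed[i] = SiteRef(mol["id"], mol["species"], site)
    if sorted(indexed) != list(range(len(indexed))):
        raise ValueError("site map atom indices are not contiguous from 0")
    atoms = [indexed[i] for i in range(len(indexed))]
    return SystemMap(atoms=atoms, leaflet=leaflet, vocabulary=vocab)


# ---------------------------------------------------------------------------
# Canonical plain-text trajectory format
# ---------------------------------------------------------------------------
# One block per frame: a header line "t Lx Ly Lz" (ns, Å) followed by one
# "x y z" line (Å) per atom, in SystemMap atom order.

def write_trajectory_text(traj: Trajectory, path) -> None:
    n = traj.system.n_atoms
    with open(path, "w") as fh:
        for f in traj.frames:
            fh.write(
                f"{f.time:.6f} {f.box[0]:.6f} {f.box[1]:.6f} {f.box[2]:.6f}\n"
            )
            np.savetxt(fh, f.positions.reshape(n, 3), fmt="%.6f")


def read_trajectory_text(path, system: SystemMap, dt: float | None = None) -> Trajectory:
    n = system.n_atoms
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        t, lx, ly, lz = map(float, lines[i].split())
        block = lines[i + 1 : i + 1 + n]
        pos = np.array([list(map(float, ln.split())) for ln in block])
        frames.append(Frame(time=t, positions=pos, box=(lx, ly, lz)))
        i += 1 + n
    if dt is None:
        dt = frames[1].time - frames[0].time if len(frames) > 1 else 1.0
    return Trajectory(system=system, frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# Single-frame PDB / GRO I/O (MDAnalysis backend)
# ---------------------------------------------------------------------------

def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None:
        raise ValueError("file carries no box information")
    dims = np.asarray(dimensions, dtype=float)
    if not np.allclose(dims[3:], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {dims[3:]}) not supported; "
            "only orthorhombic boxes are handled"
        )
    return _as_box(dims[:3])


def read_frame(path, time: float = 0.0) -> Frame:
    """Read a single PDB or GRO frame.  Positions returned in Å.

    MDAnalysis converts GRO nm coordinates to Å on ingest; PDB files are
    already in Å (box from the CRYST1 record).
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    box = _check_orthorhombic(u.dimensions)
    return Frame(time=time, positions=u.atoms.positions.astype(float), box=box)


def write_frame(frame: Frame, system: SystemMap, path) -> None:
    """Write one frame as PDB or GRO (chosen by file extension)."""
    import warnings

    import MDAnalysis as mda

    n = system.n_atoms
    mol_ids = [a.molecule_id for a in system.atoms]
    uniq = sorted(set(mol_ids))
    resindex = [uniq.index(m) for m in mol_ids]
    u = mda.Universe.empty(
        n, n_residues=len(uniq), atom_resindex=resindex, trajectory=True
    )
    # Site names like "OH-O" exceed PDB/GRO name fields; strip the dash.
    u.add_TopologyAttr("names", [a.site_name.replace("-", "")[:4] for a in system.atoms])
    u.add_TopologyAttr(
        "resnames",
        [system.molecule_species[m][:4] for m in uniq],
    )
    u.add_TopologyAttr("resids", [m + 1 for m in uniq])
    u.atoms.positions = frame.positions
    u.dimensions = [*frame.box, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
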