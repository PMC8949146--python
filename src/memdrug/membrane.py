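"""Bilayer structural metrics: area per lipid and thickness.

Area per lipid A is the lateral box area Lx*Ly divided by the number of
lipid + cholesterol molecules in one leaflet (cholesterol counts by
default; a flag excludes it for comparison with lipid-only conventions).
Bilayer thickness dz is the difference between the mean phosphorus
z-coordinates of the two leaflets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, SystemMap, Trajectory

__all__ = [
    "MembraneSeries",
    "area_per_lipid",
    "bilayer_thickness",
    "membrane_series",
]


@dataclass
class MembraneSeries:
    """Per-frame A (Å²) and dz (Å) with their trajectory statistics."""

    times: np.ndarray
    area_per_lipid: np.ndarray
    thickness: np.ndarray
    mean_A: float
    mean_dz: float
    sd_A: float
    sd_dz: float

    @property
    def fluctuation_A(self) -> float:
        """sd/mean of the area series (dimensionless)."""
        return self.sd_A / self.mean_A

    @property
    def fluctuation_dz(self) -> float:
        return self.sd_dz / self.mean_dz

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# mean_A={self.mean_A:.6f} sd_A={self.sd_A:.6f} "
                f"mean_dz={self.mean_dz:.6f} sd_dz={self.sd_dz:.6f}\n"
            )
            fh.write("t,A,dz\n")
            for t, a, d in zip(self.times, self.area_per_lipid, self.thickness):
                fh.write(f"{t:.6f},{a:.8g},{d:.8g}\n")


def area_per_lipid(frame: Frame, per_leaflet_count: int) -> float:
    """A = Lx * Ly / per_leaflet_count, in Å²."""
    if per_leaflet_count < 1:
        raise ValueError("per_leaflet_count must be >= 1")
    return float(frame.box[0] * frame.box[1]) / per_leaflet_count


def _leaflet_p_indices(system: SystemMap, label: str) -> list[int]:
    mols = set(system.leaflet_molecules(label))
    return [
        i
        for i, a in enumerate(system.atoms)
        if a.site_name == "P" and a.molecule_id in mols
    ]


def bilayer_thickness(frame: Frame, system: SystemMap) -> float:
    """dz = mean z(upper-leaflet P) - mean z(lower-leaflet P), in Å."""
    out = {}
    for label in ("upper", "lower"):
        idx = _leaflet_p_indices(system, label)
        if not idx:
            raise ValueError(f"{label} leaflet has no phosphorus sites")
        out[label] = float(np.mean(frame.positions[idx, 2]))
    return out["upper"] - out["lower"]


def membrane_series(
    traj: Trajectory,
    per_leaflet_count: int | None = None,
    include_cholesterol: bool = True,
) -> MembraneSeries:
    """Per-frame A and dz plus mean and standard deviation (population sd).

    ``per_leaflet_count`` defaults to the system's leaflet census; set
    ``include_cholesterol=False`` to divide by phospholipids only.
    """
    system = traj.system
    if per_leaflet_count is None:
        if include_cholesterol:
            per_leaflet_count = system.per_leaflet_count
        else:
            species_of = system.molecule_species
            counts = {
                lab: sum(
                    1
                    for m in system.leaflet_molecules(lab)
                    if species_of[m] != "CHOL"
                )
                for lab in ("upper", "lower")
            }
            if counts["upper"] != counts["lower"]:
                raise ValueError("asymmetric leaflets; pass per_leaflet_count")
            per_leaflet_count = counts["upper"]
    a = np.array([area_per_lipid(f, per_leaflet_count) for f in traj.frames])
    dz = np.array([bilayer_thickness(f, system) for f in traj.frames])
    return MembraneSeries(
        times=traj.times,
        area_per_lipid=a,
        thickness=dz,
        mean_A=float(a.mean()),
        mean_dz=float(dz.mean()),
        sd_A=float(a.std()),
        sd_dz=float(dz.std()),
    )
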