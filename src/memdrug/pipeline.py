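"""Config-driven orchestration of the full analysis battery.

One :class:`RunConfig` — loaded from a strict YAML schema (unknown keys
are errors) — drives trajectory acquisition (file or synthetic), membrane
metrics, RDFs, PMFs with barrier extraction, hydrogen-bond lifetimes and
bridge detection, and writes one CSV per product plus a run manifest
(parameters, package version, seed, config hash).  Re-running with the
same config and seed reproduces byte-identical CSVs; wall-clock
timestamps live only in the manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import __version__
from .core import Trajectory, read_sitemap_json, read_trajectory_text, select_sites
from .energetics import (
    DEFAULT_PROMINENCE,
    DEFAULT_WINDOW,
    KBT_TO_KCAL,
    extract_barrier,
    rdf_to_pmf,
)
from .hbonds import (
    DEFAULT_CUTOFF,
    DEFAULT_TOLERANCE,
    HBPairSpec,
    detect_bridges,
    pair_lifetime_table,
)
from .membrane import membrane_series
from .structure import DEFAULT_DELTA_R, DEFAULT_R_MAX, compute_rdf, pooled_rdf
from .synthetic import SyntheticConfig, BindingPairSpec, simulate_binding, write_ground_truth_csv

__all__ = ["RunConfig", "PipelineError", "run_all"]

log = logging.getLogger("memdrug")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending pair label."""

    def __init__(self, stage: str, label: str | None, cause: Exception):
        self.stage, self.label = stage, label
        where = f"stage {stage!r}" + (f", pair {label!r}" if label else "")
        super().__init__(f"{where}: {cause}")


def _parse_site_spec(text: str) -> tuple[str, tuple[str, ...]]:
    """Parse 'SPECIES:SITE1,SITE2' into (species, site tuple)."""
    try:
        species, sites = text.split(":")
        names = tuple(s.strip() for s in sites.split(",") if s.strip())
        if not species or not names:
            raise ValueError
    except ValueError:
        raise ValueError(
            f"bad site spec {text!r}; expected 'SPECIES:SITE[,SITE...]'"
        ) from None
    return species.strip(), names


@dataclass
class RDFPairSpec:
    a: str  # e.g. "DBD3:H2"
    b: str  # e.g. "DOPC:O13,O14"

    @property
    def label(self) -> str:
        return f"{self.a} vs {self.b}"


@dataclass
class RunConfig:
    """Validated run settings; see :func:`RunConfig.from_yaml`."""

    output_dir: str
    seed: int = 0
    temperature: float = 310.15
    synthetic: SyntheticConfig | None = None
    trajectory: str | None = None
    sitemap: str | None = None
    rdf_pairs: list[RDFPairSpec] = field(default_factory=list)
    r_max: float = DEFAULT_R_MAX
    delta_r: float = DEFAULT_DELTA_R
    pmf_window: tuple[float, float] = DEFAULT_WINDOW
    prominence: float = DEFAULT_PROMINENCE
    smooth_window: int = 1
    conversion_factor: float = KBT_TO_KCAL
    hb_pairs: list[HBPairSpec] = field(default_factory=list)
    cutoff: float = DEFAULT_CUTOFF
    tolerance: float = DEFAULT_TOLERANCE
    bridge_drug_sites: str | None = None  # e.g. "DBD3:H2,H4"
    bridge_partners: list[str] = field(default_factory=list)

    _SCHEMA = {
        "output_dir",
        "seed",
        "temperature",
        "synthetic",
        "trajectory",
        "sitemap",
        "rdf",
        "hbonds",
        "bridges",
    }
    _RDF_KEYS = {"pairs", "r_max", "delta_r", "window", "prominence",
                 "smooth_window", "conversion_factor"}
    _HB_KEYS = {"pairs", "cutoff", "tolerance"}
    _BRIDGE_KEYS = {"drug_sites", "partners"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        unknown = set(doc) - cls._SCHEMA
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in doc:
            raise ValueError("config requires 'output_dir'")
        kw: dict = {
            "output_dir": doc["output_dir"],
            "seed": int(doc.get("seed", 0)),
            "temperature": float(doc.get("temperature", 310.15)),
            "trajectory": doc.get("trajectory"),
            "sitemap": doc.get("sitemap"),
        }
        if "synthetic" in doc and doc["synthetic"] is not None:
            syn = dict(doc["synthetic"])
            pairs = syn.pop("pairs", None)
            syn_kw = {}
            allowed = set(SyntheticConfig.__dataclass_fields__)
            bad = set(syn) - allowed
            if bad:
                raise ValueError(f"unknown synthetic keys: {sorted(bad)}")
            for k, v in syn.items():
                syn_kw[k] = tuple(v) if k == "box" else v
            if pairs is not None:
                syn_kw["pairs"] = [
                    BindingPairSpec(
                        donor_site=p["donor_site"],
                        partner_species=p["partner_species"],
                        partner_sites=tuple(p["partner_sites"]),
                        k_on=float(p["k_on"]),
                        k_off=float(p["k_off"]),
                        bound_distance_mean=p.get("bound_distance_mean"),
                    )
                    for p in pairs
                ]
            kw["synthetic"] = SyntheticConfig(**syn_kw)
        rdf = doc.get("rdf") or {}
        bad = set(rdf) - cls._RDF_KEYS
        if bad:
            raise ValueError(f"unknown rdf keys: {sorted(bad)}")
        kw["rdf_pairs"] = [
            RDFPairSpec(a=p["a"], b=p["b"]) for p in rdf.get("pairs", [])
        ]
        kw["r_max"] = float(rdf.get("r_max", DEFAULT_R_MAX))
        kw["delta_r"] = float(rdf.get("delta_r", DEFAULT_DELTA_R))
        kw["pmf_window"] = tuple(rdf.get("window", DEFAULT_WINDOW))
        kw["prominence"] = float(rdf.get("prominence", DEFAULT_PROMINENCE))
        kw["smooth_window"] = int(rdf.get("smooth_window", 1))
        kw["conversion_factor"] = float(rdf.get("conversion_factor", KBT_TO_KCAL))
        hb = doc.get("hbonds") or {}
        bad = set(hb) - cls._HB_KEYS
        if bad:
            raise ValueError(f"unknown hbonds keys: {sorted(bad)}")
        hb_pairs = []
        for p in hb.get("pairs", []):
            dsp, dsites = _parse_site_spec(p["donor"])
            psp, psites = _parse_site_spec(p["partner"])
            if len(dsites) != 1:
                raise ValueError(f"hbond donor must be one site: {p['donor']!r}")
            hb_pairs.append(HBPairSpec(dsp, dsites[0], psp, psites))
        kw["hb_pairs"] = hb_pairs
        kw["cutoff"] = float(hb.get("cutoff", DEFAULT_CUTOFF))
        kw["tolerance"] = float(hb.get("tolerance", DEFAULT_TOLERANCE))
        br = doc.get("bridges") or {}
        bad = set(br) - cls._BRIDGE_KEYS
        if bad:
            raise ValueError(f"unknown bridges keys: {sorted(bad)}")
        kw["bridge_drug_sites"] = br.get("drug_sites")
        kw["bridge_partners"] = list(br.get("partners", []))
        cfg = cls(**kw)
        if cfg.synthetic is None and (cfg.trajectory is None or cfg.sitemap is None):
            raise ValueError(
                "config must give either 'synthetic' or both 'trajectory' and 'sitemap'"
            )
        return cfg

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def _default_specs(cfg: RunConfig) -> RunConfig:
    """Derive RDF/HB/bridge specs from the synthetic binding battery when
    the config leaves them empty."""
    syn = cfg.synthetic
    if syn is None:
        return cfg
    updates = {}
    if not cfg.rdf_pairs:
        updates["rdf_pairs"] = [
            RDFPairSpec(
                a=f"{syn.drug_species}:{p.donor_site}",
                b=f"{p.partner_species}:{','.join(p.partner_sites)}",
            )
            for p in syn.pairs
        ]
    if not cfg.hb_pairs:
        updates["hb_pairs"] = [
            HBPairSpec(
                syn.drug_species, p.donor_site, p.partner_species,
                tuple(p.partner_sites),
            )
            for p in syn.pairs
        ]
    if cfg.bridge_drug_sites is None:
        donors = sorted({p.donor_site for p in syn.pairs})
        updates["bridge_drug_sites"] = f"{syn.drug_species}:{','.join(donors)}"
    if not cfg.bridge_partners:
        updates["bridge_partners"] = sorted(
            {
                f"{p.partner_species}:{','.join(p.partner_sites)}"
                for p in syn.pairs
            }
        )
    return replace(cfg, **updates)


def _selection(system, spec_text: str):
    species, sites = _parse_site_spec(spec_text)
    return select_sites(system, species, set(sites))


def _safe(label: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in label).strip("_")


def _acquire_trajectory(cfg: RunConfig, out: Path):
    if cfg.synthetic is not None:
        syn = replace(cfg.synthetic, seed=cfg.seed)
        from .synthetic import build_system

        system, _ = build_system(syn)
        traj, truth = simulate_binding(system, syn)
        write_ground_truth_csv(truth, out / "ground_truth.csv")
        return traj, truth
    system = read_sitemap_json(cfg.sitemap)
    traj = read_trajectory_text(cfg.trajectory, system)
    return traj, None


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns a manifest dict (also written to disk)."""
    cfg = _default_specs(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def stage(name: str, label: str | None = None):
        log.info("stage %s%s", name, f" [{label}]" if label else "")

    try:
        stage("trajectory")
        traj, _truth = _acquire_trajectory(cfg, out)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("trajectory", None, e) from e
    stages.append({"stage": "trajectory", "n_frames": traj.n_frames,
                   "n_atoms": traj.system.n_atoms})

    try:
        stage("membrane")
        series = membrane_series(traj)
        series.to_csv(out / "membrane_timeseries.csv")
        with open(out / "membrane_summary.json", "w") as fh:
            json.dump(
                {
                    "mean_area_per_lipid_A2": series.mean_A,
                    "sd_area_per_lipid_A2": series.sd_A,
                    "mean_thickness_A": series.mean_dz,
                    "sd_thickness_A": series.sd_dz,
                    "fluctuation_A": series.fluctuation_A,
                    "fluctuation_dz": series.fluctuation_dz,
                },
                fh,
                indent=1,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("membrane", None, e) from e
    stages.append({"stage": "membrane", "n_frames": traj.n_frames})

    barrier_rows = []
    for i, pair in enumerate(cfg.rdf_pairs):
        try:
            stage("rdf/pmf", pair.label)
            sel_a = _selection(traj.system, pair.a)
            sel_b = _selection(traj.system, pair.b)
            rdf = compute_rdf(traj, sel_a, sel_b, r_max=cfg.r_max, delta_r=cfg.delta_r)
            rdf.to_csv(out / f"rdf_{i}_{_safe(pair.label)}.csv")
            pmf = rdf_to_pmf(rdf, temperature=cfg.temperature)
            pmf.to_csv(out / f"pmf_{i}_{_safe(pair.label)}.csv")
            res = extract_barrier(
                pmf,
                search_window=cfg.pmf_window,
                prominence=cfg.prominence,
                smooth_window=cfg.smooth_window,
                conversion_factor=cfg.conversion_factor,
            )
            row = {"pair": pair.label, "r_peak": rdf.r_peak}
            if res is None:
                row.update(
                    r_min="", W_min="", r_max="", W_max="",
                    dW_kBT="", dW_kcal="", barrier="none",
                )
            else:
                row.update(
                    r_min=f"{res.r_min:.6g}", W_min=f"{res.W_min:.6g}",
                    r_max=f"{res.r_max:.6g}", W_max=f"{res.W_max:.6g}",
                    dW_kBT=f"{res.delta_W:.6g}", dW_kcal=f"{res.delta_W_kcal:.6g}",
                    barrier="found",
                )
            barrier_rows.append(row)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("rdf/pmf", pair.label, e) from e
    stages.append({"stage": "rdf/pmf", "n_pairs": len(cfg.rdf_pairs)})
    with open(out / "barriers.csv", "w", newline="") as fh:
        fh.write(f"# conversion_factor_kcal_per_kBT={cfg.conversion_factor}\n")
        w = csv.DictWriter(
            fh,
            fieldnames=["pair", "r_peak", "r_min", "W_min", "r_max", "W_max",
                        "dW_kBT", "dW_kcal", "barrier"],
        )
        w.writeheader()
        w.writerows(barrier_rows)

    try:
        stage("hbonds")
        table = pair_lifetime_table(
            traj, cfg.hb_pairs, cutoff=cfg.cutoff, tolerance=cfg.tolerance
        )
        with open(out / "lifetimes.csv", "w", newline="") as fh:
            fh.write(
                f"# cutoff_A={cfg.cutoff} tolerance_ns={cfg.tolerance}\n"
            )
            w = csv.writer(fh)
            w.writerow(["pair", "distance", "tau", "n_intervals"])
            for s in table:
                w.writerow(
                    [s.pair_label, f"{s.mean_distance_bound:.6g}",
                     f"{s.tau:.6g}", s.n_intervals]
                )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("hbonds", None, e) from e
    stages.append({"stage": "hbonds", "n_pairs": len(cfg.hb_pairs)})

    try:
        stage("bridges")
        events = []
        if cfg.bridge_drug_sites and cfg.bridge_partners:
            import numpy as np

            drug_sel = _selection(traj.system, cfg.bridge_drug_sites)
            partner_sel = np.unique(
                np.concatenate(
                    [_selection(traj.system, p) for p in cfg.bridge_partners]
                )
            )
            events = detect_bridges(traj, drug_sel, partner_sel, cutoff=cfg.cutoff)
        with open(out / "bridges.csv", "w", newline="") as fh:
            fh.write(f"# cutoff_A={cfg.cutoff}\n")
            w = csv.writer(fh)
            w.writerow(["frame", "drug_sites", "partner_molecules", "partner_sites"])
            for ev in events:
                w.writerow(
                    [
                        ev.frame_index,
                        "+".join(ev.drug_sites),
                        "+".join(map(str, ev.partner_molecules)),
                        "+".join(ev.partner_sites),
                    ]
                )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("bridges", None, e) from e
    stages.append({"stage": "bridges", "n_events": len(events)})

    cfg_doc = cfg.canonical_dict()
    cfg_json = json.dumps(cfg_doc, sort_keys=True, default=str)
    manifest = {
        "package": "memdrug",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_doc,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stages": stages,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
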