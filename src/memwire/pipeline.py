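"""Pipeline orchestration, reference-table bookkeeping, and reports.

``run_pipeline`` executes the enabled stages in order (generate/io -> wires
-> binding -> enrichment -> potential) on a synthetic system or on input
files, writing per-stage CSV/JSON outputs plus a machine-readable run report
stamped with a hash of the effective configuration.

``consistency_checks`` audits published run metadata and composition tables:
saved frames x save interval must reproduce the stated simulation time,
non-protein charges must balance the protein net charge, and the restrained
NPT equilibration schedule must sum to its stated total.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding as _binding
from . import enrichment as _enrichment
from . import synthetic as _synthetic
from . import wires as _wires
from .electrostatics import PotentialConfig, wire_potential_profile
from .model import SpeciesTag

__all__ = [
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "consistency_checks",
    "load_reference_table",
]

log = logging.getLogger("memwire")


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

_TABLES = {
    "run_metadata": "run_metadata.csv",
    "system_composition": "system_composition.csv",
    "deep_binding_counts": "deep_binding_counts.csv",
    "equilibration_schedule": "equilibration_schedule.csv",
}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load one of the packaged published-metadata tables by short name."""
    if name not in _TABLES:
        raise KeyError(f"unknown table {name!r}; available: {sorted(_TABLES)}")
    with resources.files("memwire.data").joinpath(_TABLES[name]).open() as fh:
        return pd.read_csv(fh)


def consistency_checks(
    metadata: pd.DataFrame | None = None,
    composition: pd.DataFrame | None = None,
    equilibration: pd.DataFrame | None = None,
) -> dict:
    """Arithmetic audit of run metadata, composition, and equilibration tables.

    Empty/None tables produce an empty check section.  Returns a report dict
    with ``ok`` False if any row is inconsistent.
    """
    report: dict = {"ok": True, "checks": []}

    if metadata is not None and len(metadata):
        bad = []
        times = {}
        for _, row in metadata.iterrows():
            expected_us = row["saved_frames"] * row["save_interval_ps"] / 1e6
            # the stated time is printed to 4 decimals; compare at that precision
            if abs(expected_us - row["time_us"]) > 5e-5 + 1e-12:
                bad.append(f"{row['protein']} run {row['run']}: "
                           f"{row['saved_frames']} x {row['save_interval_ps']} ps = "
                           f"{expected_us:.4f} us != stated {row['time_us']}")
            times.setdefault(row["protein"], []).append(expected_us)
        report["run_time_totals_us"] = {p: float(np.sum(v)) for p, v in times.items()}
        report["total_time_us"] = float(sum(sum(v) for v in times.values()))
        report["mean_run_time_us"] = float(np.mean([t for v in times.values() for t in v]))
        report["checks"].append({"name": "frames_x_interval", "discrepancies": bad})
        if bad:
            report["ok"] = False

    if composition is not None and len(composition):
        charges = {}
        for col in [c for c in composition.columns if c.startswith("count_")]:
            label = col[len("count_"):]
            nonprot = composition[composition["molecule"] != "protein"]
            total = float((nonprot["charge_e"].astype(float) * nonprot[col]).sum())
            charges[label] = -total  # electroneutrality: protein charge balances the rest
        report["protein_net_charge"] = charges
        report["checks"].append({"name": "electroneutrality", "discrepancies": []})

    if equilibration is not None and len(equilibration):
        eq = equilibration.dropna(subset=["length_ns"])
        restrained_npt = eq[
            (eq["barostat"].notna())
            & (eq["barostat"].astype(str).str.len() > 0)
            & (eq[["backbone_restraint", "sidechain_restraint", "other_restraint"]].sum(axis=1) > 0)
        ]
        unrestrained = eq[
            eq[["backbone_restraint", "sidechain_restraint", "other_restraint"]].sum(axis=1) == 0
        ]
        report["npt_restrained_total_ns"] = float(restrained_npt["length_ns"].sum())
        report["unrestrained_total_ns"] = float(unrestrained["length_ns"].sum())
        report["checks"].append({"name": "equilibration_sums", "discrepancies": []})

    return report


# ---------------------------------------------------------------------------
# run configuration and report
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    ``synthetic`` holds :class:`~memwire.synthetic.SyntheticSpec` overrides
    plus optional ``plant_wire`` (p, gaps, helix_pair), ``plant_events`` and
    ``plant_enrichment`` blocks; stage sections override analysis defaults.
    """

    seed: int = 0
    output_dir: str = "memwire_out"
    stages: dict = field(default_factory=lambda: {
        "generate": True, "wires": True, "binding": True,
        "enrichment": True, "potential": False,
    })
    input_structure: str | None = None
    input_trajectory: str | None = None
    synthetic: dict = field(default_factory=dict)
    wires: dict = field(default_factory=dict)
    binding: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    potential: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (the output location is excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    wire_summary: dict | None = None
    binding_events: list[dict] | None = None
    binding_site_counts: dict | None = None
    enrichment_ratios: dict | None = None
    potential_summary: dict | None = None
    ground_truth: dict | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_np_default)


def _np_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _build_trajectory(config: RunConfig):
    if config.input_trajectory:
        from .io import read_trajectory

        traj = read_trajectory(config.input_trajectory)
        return traj, None
    spec_kwargs = dict(config.synthetic)
    plant_wire = spec_kwargs.pop("plant_wire", None)
    plant_events = spec_kwargs.pop("plant_events", [])
    plant_enrich = spec_kwargs.pop("plant_enrichment", None)
    spec = _synthetic.SyntheticSpec(seed=config.seed, **spec_kwargs)
    sysd = _synthetic.generate_system(spec)
    if plant_wire:
        sched = _synthetic.PlantedWireSchedule.bernoulli(
            spec.n_frames,
            plant_wire.get("p", 0.3),
            seed=config.seed + 1,
            gap_when_present=plant_wire.get("gap_when_present", 0.30),
            gap_when_absent=plant_wire.get("gap_when_absent", 0.50),
        )
        pair = tuple(plant_wire.get("helix_pair", ("TM4", "TM5")))
        _synthetic.plant_wire_schedule(sysd, sched, pair)
    if plant_enrich:
        _synthetic.plant_enrichment(
            sysd,
            fold=plant_enrich.get("fold", 3.0),
            ring=tuple(plant_enrich.get("ring", (0.0, 1.0))),
            leaflet=plant_enrich.get("leaflet", "C"),
        )
    # events last: an event AA overrides its enrichment placement
    for ev in plant_events:
        _synthetic.plant_binding_event(sysd, _synthetic.PlantedBindingEvent(**ev))
    return sysd.trajectory, sysd


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages and write all outputs to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "effective_config.yaml").write_text(config.to_yaml())
    report = RunReport(config_hash=config.config_hash, seed=config.seed)

    if not any(config.stages.values()):
        (out / "report.json").write_text(report.to_json())
        return report

    traj, sysd = _build_trajectory(config)
    system = traj.system
    if sysd is not None:
        report.ground_truth = sysd.ground_truth
        _synthetic.write_ground_truth(sysd, out / "ground_truth.json")

    if config.stages.get("wires"):
        log.info("stage wires: %d frames", traj.n_frames)
        wcfg = _wires.WireSearchConfig(**config.wires)
        stats, wire_list = _wires.classify_and_summarize(traj, wcfg, return_wires=True)
        pd.DataFrame(
            {
                "frame": np.arange(len(stats.max_gaps)),
                "time_ps": stats.times,
                "max_gap_nm": stats.max_gaps,
                "formed": stats.formed,
                "unit": stats.units,
            }
        ).to_csv(out / "wire_series.csv", index=False)
        report.wire_summary = stats.summary()
        (out / "wire_summary.json").write_text(json.dumps(report.wire_summary, indent=2))
    else:
        wire_list = None

    if config.stages.get("binding"):
        log.info("stage binding")
        bcfg = _binding.BindingConfig(**config.binding)
        sites = _binding.default_sites(system, traj.frames[0])
        probes = _binding.probes_from_system(system)
        states = _binding.classify_trajectory(traj, sites, probes, bcfg)
        events = _binding.extract_events(
            states, traj.frame_interval, bcfg.gap_tolerance_frames, traj.n_frames
        )
        pd.DataFrame([dataclasses.asdict(ev) for ev in events]).to_csv(
            out / "binding_events.csv", index=False
        )
        site_counts: dict[str, int] = {}
        for ev in events:
            site_counts[ev.site] = site_counts.get(ev.site, 0) + 1
        report.binding_events = [dataclasses.asdict(ev) for ev in events]
        report.binding_site_counts = site_counts

    if config.stages.get("enrichment"):
        log.info("stage enrichment")
        ratios = {}
        for leaflet in ("C", "M"):
            try:
                prof = _enrichment.radial_mole_fraction(traj, leaflet, **config.enrichment)
                ratios[leaflet] = _enrichment.enrichment_ratio(prof)
                pd.DataFrame(
                    {
                        "bin_lo_nm": prof.bin_edges[:-1],
                        "bin_hi_nm": prof.bin_edges[1:],
                        "mole_fraction": prof.mole_fraction,
                        "n_AA": prof.n_aa,
                        "n_total": prof.n_total,
                    }
                ).to_csv(out / f"enrichment_{leaflet}.csv", index=False)
            except ValueError as exc:
                ratios[leaflet] = None
                log.warning("enrichment %s leaflet skipped: %s", leaflet, exc)
        report.enrichment_ratios = ratios
        (out / "enrichment_ratios.json").write_text(json.dumps(ratios, indent=2))

    if config.stages.get("potential"):
        log.info("stage potential")
        if wire_list is None:
            wcfg = _wires.WireSearchConfig(**config.wires)
            _, wire_list = _wires.classify_and_summarize(traj, wcfg, return_wires=True)
        pcfg = PotentialConfig(**config.potential)
        formed = [w for w in wire_list if w.formed and w.max_gap <= 0.33]
        profile = wire_potential_profile(traj, formed, pcfg)
        pd.DataFrame(
            {
                "z_nm": profile.z_centers,
                "mean_kT_e": profile.mean_kT_e,
                "mean_V": profile.mean_volts,
                "n_samples": profile.n_samples,
            }
        ).to_csv(out / "potential_profile.csv", index=False)
        report.potential_summary = {
            "maxima_mean_kT_e": profile.maxima_mean,
            "maxima_sd_kT_e": profile.maxima_sd,
            "n_wires": int(len(profile.per_wire_maxima)),
        }

    (out / "report.json").write_text(report.to_json())
    return report
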