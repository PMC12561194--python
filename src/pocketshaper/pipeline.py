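"""End-to-end workflow: ensemble → coordinates → free-energy landscape →
basins → per-basin interaction fingerprints → hotspots → pre-reaction-state
statistics → tunnel metrics → machine-readable report.

The workflow is driven by a single YAML config (all defaults are printed
back into the resolved config for provenance), executes its stages in a
fixed order with fail-fast semantics, and is deterministic: the same
config and seed produce byte-identical artifacts, so the report carries a
content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .core import ConformationEnsemble, read_multimodel_pdb, resolve_selection
from .interactions import ContactConfig, fingerprint, select_hotspots
from .landscape import compute_fel, find_minima, representative_frame, rg_series, rmsd_series
from .prs import PRSConfig, prs_population
from .channels import tunnel_metrics

logger = logging.getLogger("pocketshaper")

__all__ = ["WorkflowConfig", "WorkflowReport", "load_config", "run_workflow"]

_DEFAULTS = {
    "seed": 0,
    "selections": {
        "ligand": synthetic.LIGAND_SEL,
        "acceptor_o": synthetic.ACCEPTOR_O8_SEL,
        "anomeric_c": synthetic.ANOMERIC_C_SEL,
        "catalytic_n": synthetic.CATALYTIC_N_SEL,
        "coordinate_atoms": "name CA",
    },
    "fel": {"bins": [32, 32], "temperature_K": 300.0, "min_separation_bins": 3},
    "contacts": {},
    "prs": {"threshold": 3.5},
    "hotspots": {"min_frequency": 0.5, "require_all_basins": True},
    "tunnel": None,
    "output_dir": "pocketshaper_out",
}


class ConfigError(ValueError):
    """Raised before any stage runs, naming the offending field."""


@dataclass(frozen=True)
class WorkflowConfig:
    raw: dict

    @property
    def resolved(self) -> dict:
        return self.raw


@dataclass
class WorkflowReport:
    config_hash: str
    content_hash: str
    stages: dict
    hotspot_table: list
    prs_summary: dict
    output_dir: str


def _merge_defaults(user: dict, defaults: dict) -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict) and isinstance(user.get(k), dict):
            out[k] = _merge_defaults(user[k], v)
        elif k in user:
            out[k] = user[k]
        else:
            out[k] = v
    for k in user:
        if k not in out:
            out[k] = user[k]
    return out


def _validate(cfg: dict) -> None:
    if "ensemble" not in cfg or not isinstance(cfg["ensemble"], dict):
        raise ConfigError("missing required section 'ensemble'")
    ens = cfg["ensemble"]
    if ("path" in ens) == ("synthetic" in ens):
        raise ConfigError("'ensemble' needs exactly one of 'path' or 'synthetic'")
    sels = cfg.get("selections", {})
    for fld in ("ligand", "acceptor_o", "anomeric_c", "catalytic_n", "coordinate_atoms"):
        if not isinstance(sels.get(fld), str) or not sels[fld].strip():
            raise ConfigError(f"missing or empty selection field 'selections.{fld}'")
    bins = cfg["fel"]["bins"]
    if len(bins) != 2 or any(int(b) < 2 for b in bins):
        raise ConfigError("'fel.bins' must be two integers ≥ 2")
    if float(cfg["fel"]["temperature_K"]) <= 0:
        raise ConfigError("'fel.temperature_K' must be > 0")
    if float(cfg["prs"]["threshold"]) <= 0:
        raise ConfigError("'prs.threshold' must be > 0")


def load_config(path) -> WorkflowConfig:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge_defaults(user, _DEFAULTS)
    _validate(cfg)
    return WorkflowConfig(raw=cfg)


def _build_ensemble(cfg: dict, seed: int) -> tuple[ConformationEnsemble, object]:
    ens_cfg = cfg["ensemble"]
    if "path" in ens_cfg:
        return read_multimodel_pdb(ens_cfg["path"]), None
    syn = dict(ens_cfg["synthetic"])
    contacts = tuple(
        synthetic.PlantedContact(
            residue_key=(c["chain"], int(c["resnum"])),
            interaction_type=c["type"],
            basin_id=int(c["basin"]),
            frequency=float(c["frequency"]),
        )
        for c in syn.get("planted_contacts", [])
    )
    prs_spec = syn.get("planted_prs")
    planted_prs = (int(prs_spec["basin"]), float(prs_spec["rate"])) if prs_spec else None
    spec = synthetic.default_two_basin_spec(
        n_frames=int(syn.get("n_frames", 2000)),
        occupancies=tuple(float(p) for p in syn.get("basin_occupancies", (0.75, 0.25))),
        jitter_sigma=float(syn.get("jitter_sigma", 0.12)),
        planted_contacts=contacts,
        planted_prs=planted_prs,
        seed=seed,
    )
    return synthetic.generate_two_basin_ensemble(spec)


def run_workflow(config: WorkflowConfig, output_dir: str | Path | None = None) -> WorkflowReport:
    """Execute every stage on the configured ensemble and write artifacts.

    Stage order: ensemble → RMSD/Rg series → FEL → basins → per-basin
    fingerprints → hotspot table → PRS report → (optional) tunnel metrics
    → manifest.  Any stage failure propagates immediately (fail-fast); no
    later artifacts are written.
    """
    cfg = config.resolved
    seed = int(cfg["seed"])
    out = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(cfg, sort_keys=True, default=str)
    config_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    logger.info("workflow start (config hash %s)", config_hash)
    stages: dict = {}

    ensemble, truth = _build_ensemble(cfg, seed)
    topo = ensemble.topology
    sels = cfg["selections"]
    # resolve every selection before any stage runs (pre-run validation)
    resolved = {}
    for fld in ("ligand", "acceptor_o", "anomeric_c", "catalytic_n", "coordinate_atoms"):
        sel = resolve_selection(topo, sels[fld])
        if sel.is_empty:
            raise ConfigError(f"selection 'selections.{fld}' matches no atoms")
        resolved[fld] = sel
    stages["ensemble"] = {"n_frames": ensemble.n_frames, "n_atoms": topo.n_atoms}
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
        stages["ensemble"]["ground_truth"] = str(out / "ground_truth.json")

    coord_sel = resolved["coordinate_atoms"]
    x = rmsd_series(ensemble, coord_sel, ensemble.frames[0])
    y = rg_series(ensemble, coord_sel)
    logger.info("reaction coordinates done")

    fel_cfg = cfg["fel"]
    surface = compute_fel(
        x,
        y,
        bins=tuple(int(b) for b in fel_cfg["bins"]),
        temperature_K=float(fel_cfg["temperature_K"]),
    )
    surface.to_tsv(out / "fel.tsv")
    basins = find_minima(
        surface, min_separation_bins=int(fel_cfg["min_separation_bins"]), x=x, y=y
    )
    basin_report = [
        {
            "bin": list(b.bin_index),
            "delta_g_kcal_mol": b.delta_g,
            "kind": b.kind,
            "n_members": len(b.member_frames),
            "representative_frame": (
                representative_frame(b, surface, x, y) if b.member_frames else None
            ),
        }
        for b in basins
    ]
    (out / "basins.json").write_text(json.dumps(basin_report, indent=1))
    stages["fel"] = {"path": str(out / "fel.tsv"), "n_basins": len(basins)}
    logger.info("FEL done: %d basins", len(basins))

    contact_cfg = ContactConfig(**cfg["contacts"])
    fps = {}
    for k, b in enumerate(basins):
        if not b.member_frames:
            continue
        fps[k] = fingerprint(
            ensemble,
            resolved["ligand"],
            contact_cfg,
            frame_indices=b.member_frames,
            scope=f"basin-{k}",
        )
    if not fps:
        fps[0] = fingerprint(ensemble, resolved["ligand"], contact_cfg)
    hot_cfg = cfg["hotspots"]
    hotspots = select_hotspots(
        fps,
        min_frequency=float(hot_cfg["min_frequency"]),
        require_all_basins=bool(hot_cfg["require_all_basins"]),
    )
    hotspot_table = [
        {
            "chain": rk[0],
            "resnum": rk[1],
            "types": list(types),
            "per_basin_frequency": {str(b): f for b, f in per_basin.items()},
        }
        for rk, types, per_basin in hotspots
    ]
    (out / "hotspots.json").write_text(json.dumps(hotspot_table, indent=1))
    stages["hotspots"] = {"path": str(out / "hotspots.json"), "n": len(hotspots)}
    logger.info("hotspots done: %d residues", len(hotspots))

    prs_cfg = PRSConfig(
        acceptor_O=resolved["acceptor_o"],
        anomeric_C=resolved["anomeric_c"],
        catalytic_N=resolved["catalytic_n"],
        threshold=float(cfg["prs"]["threshold"]),
    )
    report = prs_population(ensemble, prs_cfg)
    prs_summary = report.to_dict()
    (out / "prs.json").write_text(json.dumps(prs_summary, indent=1))
    stages["prs"] = {"path": str(out / "prs.json")}
    logger.info("PRS done: fraction %.4f", report.prs_fraction)

    if cfg.get("tunnel"):
        tun_cfg = cfg["tunnel"]
        spec = synthetic.ToyTunnelSpec(
            centerline=tuple(tun_cfg["centerline"]),
            radius_profile=tuple(float(r) for r in tun_cfg["radius_profile"]),
            sphere_spacing=float(tun_cfg.get("sphere_spacing", 1.0)),
        )
        profile = synthetic.generate_toy_tunnel(spec)
        tm = tunnel_metrics(profile, cost_scale=float(tun_cfg.get("cost_scale", 1.0)))
        tun_out = {
            "length_A": tm.length,
            "curvature": tm.curvature,
            "bottleneck_radius_A": tm.bottleneck_radius,
            "throughput": tm.throughput,
            "cost": tm.cost,
        }
        (out / "tunnel.json").write_text(json.dumps(tun_out, indent=1))
        stages["tunnel"] = tun_out

    artifact_names = sorted(
        p.name for p in out.iterdir() if p.suffix in (".json", ".tsv")
    )
    hasher = hashlib.sha256()
    for name in artifact_names:
        hasher.update(name.encode())
        hasher.update((out / name).read_bytes())
    content_hash = hasher.hexdigest()[:16]

    manifest = {
        "config": cfg,
        "config_hash": config_hash,
        "content_hash": content_hash,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    logger.info("workflow complete (content hash %s)", content_hash)
    return WorkflowReport(
        config_hash=config_hash,
        content_hash=content_hash,
        stages=stages,
        hotspot_table=hotspot_table,
        prs_summary=prs_summary,
        output_dir=str(out),
    )
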