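"""Two-system comparison workflow: align -> RMSF/COM/contacts -> PCA -> FEL
-> events, aggregated into one machine-readable report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np

from . import __version__
from .contacts import (ContactSpec, compare_contact_maps, contact_map,
                       interface_contact_count)
from .core import (MolecularSystem, NucleosomeAnnotation, TrajectorySegment,
                   annotate_nucleosome, read_structure, read_trajectory,
                   select_sites)
from .events import (event_coincidence, segment_detachment_series,
                     residue_site_distance_series, threshold_events)
from .fluctuations import basepair_rmsf, compare_rmsf, site_rmsf
from .geometry import com_distance_series, converged_average, dimer_atoms
from .pca_fel import (find_basins, fit_pca, free_energy_landscape,
                      project_frames)

log = logging.getLogger("nucdyn")

ALL_STAGES = ("rmsf", "com", "contacts", "pca", "fel", "events")

# report precision: Angstrom 3 decimals, kT 2 decimals, fractions 3 decimals
def _a(x):  # noqa: E302
    return None if x is None else round(float(x), 3)


def _kt(x):
    return None if x is None else round(float(x), 2)


def _fr(x):
    return None if x is None else round(float(x), 3)


@dataclass
class SystemBundle:
    """A loaded, annotated, core-aligned system ready for analysis."""

    name: str
    system: MolecularSystem
    traj: TrajectorySegment
    annotation: NucleosomeAnnotation
    config: dict

    @property
    def protein_ca(self):
        groups, labels = [], []
        for role in self.annotation.protein_roles():
            sel = select_sites(self.system, self.annotation, role=role,
                               atom_class="CA")
            groups.extend(sel.groups)
            labels.extend(sel.site_labels)
        from .core import SiteSelection
        return SiteSelection(label="protein CA", groups=groups,
                             site_labels=labels, grouping="residue")


def load_system(config: dict, name: str) -> SystemBundle:
    """Read structure + trajectory, annotate, and align on the protein core.

    Config keys: ``structure``, ``trajectory``, ``chain_roles``, optional
    ``regions``, ``dyad_bp_offset``, ``window_fraction``, ``dt_ns``.
    """
    system = read_structure(config["structure"])
    traj = read_trajectory(system, config["trajectory"],
                           window_fraction=config.get("window_fraction"),
                           dt_ns=config.get("dt_ns", 1.0))
    annotation = annotate_nucleosome(system, config)
    bundle = SystemBundle(name=name, system=system, traj=traj,
                          annotation=annotation, config=config)
    ca = bundle.protein_ca.atom_indices
    aligned, _avg = converged_average(traj, ca, n_iter=2)
    bundle.traj = aligned
    return bundle


def _role_rmsf(bundle: SystemBundle, role: str):
    sel = select_sites(bundle.system, bundle.annotation, role=role,
                       atom_class="CA")
    return sel, site_rmsf(bundle.traj, sel,
                          thirds=bundle.traj.n_window_frames >= 9)


def _stage_rmsf(a: SystemBundle, b: SystemBundle) -> dict:
    out: dict = {"roles": {}}
    shared = [r for r in a.annotation.protein_roles()
              if r in b.annotation.protein_roles()]
    for role in shared:
        sel_a, prof_a = _role_rmsf(a, role)
        sel_b, prof_b = _role_rmsf(b, role)
        # pair sites by residue number (labels are "chain:resnum")
        res_a = {s.split(":")[1]: s for s in prof_a.sites}
        res_b = {s.split(":")[1]: s for s in prof_b.sites}
        site_map = [(res_a[r], res_b[r]) for r in res_a if r in res_b]
        regions = {}
        for name, (rrole, (lo, hi)) in a.annotation.named_regions.items():
            if rrole == role:
                regions[name] = [res_a[str(r)] for r in range(lo, hi + 1)
                                 if str(r) in res_a]
        cmp = compare_rmsf(prof_a, prof_b, site_map=site_map, regions=regions)
        out["roles"][role] = {
            "n_sites": len(cmp.sites),
            "threshold_A": _a(cmp.threshold),
            "max_abs_delta_A": _a(np.max(np.abs(cmp.delta)) if len(cmp.delta) else None),
            "n_significant": int(np.sum(cmp.significant)),
            "significant_sites": [s for s, f in zip(cmp.sites, cmp.significant) if f],
            "region_extrema": {k: [s, _a(d)] for k, (s, d) in cmp.extrema.items()},
            "unmapped_a": cmp.unmapped_a,
            "unmapped_b": cmp.unmapped_b,
        }
    if a.annotation.has_dna and b.annotation.has_dna:
        pa = basepair_rmsf(a.traj, a.system, a.annotation,
                           thirds=a.traj.n_window_frames >= 9)
        pb = basepair_rmsf(b.traj, b.system, b.annotation,
                           thirds=b.traj.n_window_frames >= 9)
        cmp = compare_rmsf(pa, pb)
        out["basepair"] = {
            "n_sites": len(cmp.sites),
            "threshold_A": _a(cmp.threshold),
            "max_abs_delta_A": _a(np.max(np.abs(cmp.delta)) if len(cmp.delta) else None),
            "n_significant": int(np.sum(cmp.significant)),
        }
    return out


_PAIRINGS = (("homotetramer", "homodimer-1", "homodimer-2"),
             ("heterotetramer-1", "homodimer-1", "hetdimer-1"),
             ("heterotetramer-2", "homodimer-2", "hetdimer-2"))


def _stage_com(a: SystemBundle, b: SystemBundle) -> dict:
    out: dict = {}
    for label, d1, d2 in _PAIRINGS:
        row = {}
        for bundle in (a, b):
            if d1 not in bundle.annotation.dimers or d2 not in bundle.annotation.dimers:
                continue
            g1 = dimer_atoms(bundle.system, bundle.annotation, d1)
            g2 = dimer_atoms(bundle.system, bundle.annotation, d2)
            series = com_distance_series(bundle.traj, bundle.system, g1, g2,
                                         label=f"{label} ({bundle.name})")
            row[bundle.name] = {"mean_A": _a(series.mean), "sd_A": _a(series.sd),
                                "n_frames": len(series.values)}
        if row:
            names = list(row)
            if len(names) == 2:
                row["delta_mean_A"] = _a(row[names[1]]["mean_A"]
                                         - row[names[0]]["mean_A"])
            out[label] = row
    return out


def _interface_residues(bundle: SystemBundle, role: str):
    chain = bundle.annotation.role_chain(role)
    return [(chain, r) for r in bundle.system.chain_residues(chain)]


def _stage_contacts(a: SystemBundle, b: SystemBundle,
                    cutoff: float = 3.6) -> dict:
    spec = ContactSpec(cutoff=cutoff)
    maps = {}
    counts = {}
    for bundle in (a, b):
        ra = _interface_residues(bundle, "H3-like")
        rb = _interface_residues(bundle, "H3-like'")
        maps[bundle.name] = contact_map(bundle.traj, bundle.system, ra, rb, spec)
        cc = interface_contact_count(bundle.traj, bundle.system, ra, rb, spec)
        counts[bundle.name] = {"mean": _fr(cc.mean),
                               "histogram": {str(k): int(v)
                                             for k, v in cc.histogram.items()}}
    rows = compare_contact_maps(maps[a.name], maps[b.name])
    status_counts = {}
    for r in rows:
        status_counts[r["status"]] = status_counts.get(r["status"], 0) + 1
    return {
        "cutoff_A": cutoff,
        "interface": "H3-like : H3-like'",
        "n_pairs": {a.name: len(maps[a.name].pairs),
                    b.name: len(maps[b.name].pairs)},
        "counts": counts,
        "status_counts": status_counts,
        "pairs": [{"pair": [list(p) for p in r["pair"]],
                   "fraction_a": _fr(r["fraction_a"]),
                   "fraction_b": _fr(r["fraction_b"]),
                   "status": r["status"]} for r in rows],
    }


def _stage_pca_fel(a: SystemBundle, b: SystemBundle, do_fel: bool,
                   bins: int = 32, min_depth: float = 1.0) -> dict:
    out: dict = {}
    for bundle in (a, b):
        sel = bundle.protein_ca
        model = fit_pca(bundle.traj, sel)
        top = model.eigenvalues[:10]
        entry: dict = {
            "n_sites": model.n_sites,
            "top_eigenvalues_A2": [_a(v) for v in top],
            "total_variance_A2": _a(model.total_variance),
        }
        if do_fel:
            proj = project_frames(bundle.traj, model, k=2)
            fel = free_energy_landscape(proj, bins=bins)
            # short trajectories cannot afford the default bin-count floor
            min_count = max(2, min(10, bundle.traj.n_window_frames // 200))
            basins = find_basins(fel, min_depth=min_depth, min_count=min_count)
            entry["fel"] = {
                "bins": bins,
                "n_basins": basins.n_basins,
                "occupied_area_A2": _a(basins.occupied_area),
                "basin_min_F_kT": [_kt(bb.min_f) for bb in basins.basins],
                "barriers_kT": {f"{i}-{j}": _kt(v)
                                for (i, j), v in basins.barriers.items()},
            }
        out[bundle.name] = entry
    return out


def _stage_events(bundle: SystemBundle) -> dict | None:
    cfg = bundle.config.get("events")
    if not cfg or not bundle.annotation.has_dna:
        return None
    b0, b1 = cfg["bp_range"]
    series, dist = segment_detachment_series(
        bundle.traj, bundle.system, bundle.annotation, (b0, b1),
        threshold=cfg.get("threshold", 8.0),
        min_duration=cfg.get("min_duration"),
        hysteresis=cfg.get("hysteresis", 1.0))
    out = {
        "detachment": {
            "definition": series.definition,
            "n_episodes": series.n_episodes,
            "episodes": [list(ep) for ep in series.episodes],
            "min_distance_mean_A": _a(dist.mean),
        }
    }
    if "swing_residue" in cfg:
        chain, resnum = cfg["swing_residue"]
        swing_dist = residue_site_distance_series(
            bundle.traj, bundle.system, bundle.annotation, (chain, int(resnum)),
            target_bp=cfg["swing_target_bp"])
        swing = threshold_events(swing_dist, "swing engagement",
                                 cutoff=cfg.get("swing_cutoff", 3.6))
        rep = event_coincidence(series, swing, window=cfg.get("window"))
        out["swing"] = {"n_episodes": swing.n_episodes,
                        "episodes": [list(ep) for ep in swing.episodes]}
        out["coincidence"] = rep.to_dict()
    return out


def run_compare(config_a: dict, config_b: dict,
                stages: tuple[str, ...] | None = None,
                seed: int = 0, fel_bins: int = 32,
                out_dir: str | None = None) -> dict:
    """Run the two-system comparison and return the report dict.

    ``stages`` defaults to all of ``rmsf, com, contacts, pca, fel, events``;
    ``fel`` implies ``pca``. Stage failures are recorded in the report and
    re-raised as ``StageError`` after all stages ran.
    """
    stages = tuple(stages) if stages else ALL_STAGES
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    a = load_system(config_a, config_a.get("name", "A"))
    b = load_system(config_b, config_b.get("name", "B"))
    log.info("loaded %s (%d atoms) and %s (%d atoms)",
             a.name, a.system.n_atoms, b.name, b.system.n_atoms)

    report: dict = {
        "systems": {a.name: {"structure": str(config_a["structure"]),
                             "n_atoms": a.system.n_atoms,
                             "n_frames": a.traj.n_frames,
                             "window": list(a.traj.window)},
                    b.name: {"structure": str(config_b["structure"]),
                             "n_atoms": b.system.n_atoms,
                             "n_frames": b.traj.n_frames,
                             "window": list(b.traj.window)}},
        "stages": {},
        "provenance": {
            "version": __version__,
            "seed": seed,
            "config_hash": hashlib.sha256(
                json.dumps([config_a, config_b], sort_keys=True,
                           default=str).encode()).hexdigest(),
        },
    }
    failed = []
    runners = {
        "rmsf": lambda: _stage_rmsf(a, b),
        "com": lambda: _stage_com(a, b),
        "contacts": lambda: _stage_contacts(a, b),
        "pca": lambda: _stage_pca_fel(a, b, do_fel=False),
        "fel": lambda: _stage_pca_fel(a, b, do_fel=True, bins=fel_bins),
        "events": lambda: {n: _stage_events(s)
                           for n, s in ((a.name, a), (b.name, b))},
    }
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        if stage == "pca" and "fel" in stages:
            continue  # fel output includes the PCA summary
        log.info("running stage %s", stage)
        try:
            report["stages"][stage] = runners[stage]()
        except Exception as exc:  # noqa: BLE001 - stage isolation
            log.error("stage %s failed: %s", stage, exc)
            report["stages"][stage] = {"failed": str(exc)}
            failed.append(stage)
    report["failed_stages"] = failed
    if out_dir is not None:
        write_report(report, out_dir)
    return report


class StageError(RuntimeError):
    pass


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_markdown(report: dict) -> str:
    lines = ["# Comparison report", ""]
    names = list(report["systems"])
    lines.append(f"Systems: {' vs '.join(names)}")
    lines.append(f"Seed: {report['provenance']['seed']}; "
                 f"config hash {report['provenance']['config_hash'][:12]}")
    lines.append("")
    for stage, payload in report["stages"].items():
        lines.append(f"## {stage}")
        if isinstance(payload, dict) and "failed" in payload:
            lines.append(f"FAILED: {payload['failed']}")
        else:
            lines.append("```json")
            lines.append(json.dumps(payload, indent=2, sort_keys=True))
            lines.append("```")
        lines.append("")
    if report.get("failed_stages"):
        lines.append(f"Failed stages: {', '.join(report['failed_stages'])}")
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir: str) -> list[str]:
    import os
    os.makedirs(out_dir, exist_ok=True)
    files = []
    for fname, text in (("report.json", report_json(report)),
                        ("report.md", report_markdown(report))):
        path = os.path.join(out_dir, fname)
        with open(path, "w") as fh:
            fh.write(text)
        files.append(path)
    manifest = os.path.join(out_dir, "manifest.json")
    with open(manifest, "w") as fh:
        json.dump({"files": [os.path.basename(f) for f in files],
                   "config_hash": report["provenance"]["config_hash"]},
                  fh, indent=2, sort_keys=True)
    files.append(manifest)
    return files
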