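"""End-to-end orchestration: contacts -> energetics -> entry -> FES ->
pathways -> kinetics, driven by one structured config.

The pipeline runs either on user-supplied files (topology + annotations +
trajectories + parameter table + rate tables) or on the built-in
synthetic demo case, writes every stage's table next to a JSON run
report, and echoes the fully resolved configuration so a run can be
reproduced exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import contacts as _contacts
from . import energetics as _energetics
from . import entry as _entry
from . import fes as _fes
from . import kinetics as _kinetics
from . import pathways as _pathways
from . import synthcase as _synth
from .model_io import AnalysisConfig

log = logging.getLogger("entryscope")

__all__ = ["RunReport", "run_all", "default_config"]

_STAGES = ("contacts", "energetics", "entry", "fes", "pathways", "kinetics")


@dataclass
class RunReport:
    """Per-stage status and headline numbers of one pipeline run."""

    stages: dict[str, str]
    config_hash: str
    parameters: dict[str, Any]
    outputs: dict[str, str]
    headline: dict[str, Any]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, set):
        return sorted(v)
    raise TypeError(f"not JSON-serializable: {type(v)}")


def default_config() -> dict:
    """The demo configuration: synthetic case, all stages enabled."""
    return {
        "seed": 1,
        "analysis": {},
        "synthetic": {
            "n_residues": 40,
            "n_polymer_units": 5,
            "n_frames": 120,
            "noise": 0.3,
            "events_per_corridor": 4,
        },
        "kinetics": {
            "K_m_conv": 0.3, "V_max_conv": 1.0,
            "K_m_inv": 0.5, "V_max_inv": 2.0,
            "noise_fraction": 0.05, "n_points": 8,
            "conversion": 1.66,          # g/L -> uM attack sites
            "substrate_load": 25.0,      # uM attack sites at fixed load
        },
        "stages": {s: True for s in _STAGES},
    }


def _validate(cfg: Mapping) -> dict:
    merged = default_config()
    for k, v in cfg.items():
        if k not in merged:
            raise ValueError(f"unknown config section: {k!r}")
        if isinstance(merged[k], dict):
            unknown = set(v) - (set(merged[k]) | set(
                f.name for f in dataclasses.fields(AnalysisConfig)))
            if k != "analysis" and set(v) - set(merged[k]):
                raise ValueError(f"unknown keys in section {k!r}: "
                                 f"{sorted(set(v) - set(merged[k]))}")
            if k == "analysis" and unknown:
                raise ValueError(f"unknown analysis keys: {sorted(unknown)}")
            merged[k].update(v)
        else:
            merged[k] = v
    AnalysisConfig(**merged["analysis"])   # bounds check
    return merged


def run_all(config: str | Path | Mapping, out_dir: str | Path,
            force: bool = False) -> RunReport:
    """Execute the pipeline per the config and write outputs + report.

    ``config`` is a YAML path or an in-memory mapping; unknown keys and
    out-of-bounds parameters fail before any stage runs.  Existing output
    directories are refused unless ``force`` is set.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)
    cfg = _validate(cfg)
    out = Path(out_dir)
    report_path = out / "report.json"
    if report_path.exists() and not force:
        raise FileExistsError(f"{report_path} exists; use force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    (out / "resolved_config.yaml").write_text(cfg_text)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]

    seed = int(cfg["seed"])
    acfg = AnalysisConfig(**{**cfg["analysis"], "seed": seed})
    stages_on = cfg["stages"]
    statuses: dict[str, str] = {}
    outputs: dict[str, str] = {}
    headline: dict[str, Any] = {}

    # ---- synthetic inputs ------------------------------------------------
    s = cfg["synthetic"]
    spec = _synth.FixtureSpec(seed=seed, n_residues=s["n_residues"],
                              n_polymer_units=s["n_polymer_units"],
                              n_frames=s["n_frames"], noise=s["noise"])
    system, ref = _synth.make_toy_system(spec)
    trajs, truths, corridors = [], [], []
    k = 0
    for corridor in (1, 2, 3):
        for _ in range(int(s["events_per_corridor"])):
            t, truth, c = _synth.simulate_entry(system, ref, spec, corridor,
                                                seed=seed * 1000 + k)
            trajs.append(t)
            truths.append(truth)
            corridors.append(c)
            k += 1
    log.info("generated %d synthetic entry trajectories (%d frames each)",
             len(trajs), spec.n_frames)

    def run_stage(name, fn):
        if not stages_on.get(name, True):
            statuses[name] = "skipped"
            return
        try:
            fn()
            statuses[name] = "ok"
        except Exception as exc:   # mark and continue: partial runs keep outputs
            log.error("stage %s failed: %s", name, exc)
            statuses[name] = f"failed: {exc}"

    # ---- contacts --------------------------------------------------------
    def do_contacts():
        planted = {int(r): 0.9 for r in
                   np.asarray(system.enzyme_residues())[4:7]}
        ctraj, _ = _synth.simulate_contacts(system, ref, spec.n_frames,
                                            planted, seed=seed + 7)
        cmap, persistent, labels = _contacts.analyze(ctraj, system, acfg)
        df = _contacts.contact_table(cmap, system, out / "contacts.tsv")
        outputs["contacts"] = str(out / "contacts.tsv")
        headline["persistent_contact_count"] = len(persistent)
        headline["proximal_residues"] = sorted(
            r for r, l in labels.items() if l == "proximal")
    run_stage("contacts", do_contacts)

    # ---- energetics ------------------------------------------------------
    series0 = {}

    def do_energetics():
        nonlocal series0
        series0 = _energetics.residue_energy_series(trajs[0], system, acfg)
        in_contact = [r for r, es in series0.items()
                      if np.any(np.abs(es.total) > 1e-12)]
        prof = _energetics.class_profile(series0, in_contact, system)
        with open(out / "class_profile.tsv", "w") as fh:
            fh.write("class\tscaled_energy_kcal_mol\tn_contacting\n")
            for c, e in sorted(prof.class_energy.items()):
                fh.write(f"{c}\t{e:.6g}\t{prof.class_counts[c]}\n")
        outputs["energetics"] = str(out / "class_profile.tsv")
        headline["class_profile"] = {c: round(e, 4)
                                     for c, e in prof.class_energy.items()}
    run_stage("energetics", do_energetics)

    # ---- entry -----------------------------------------------------------
    all_series, all_events = [], []

    def do_entry():
        for t in trajs:
            es = _entry.entry_series(t, system, acfg)
            all_series.append(es)
            all_events.append(_entry.segment_entries(es, acfg))
        tally = _entry.tally_entries(all_events, all_series)
        headline["entry_tally"] = dataclasses.asdict(tally)
        with open(out / "entry_events.json", "w") as fh:
            json.dump([[dataclasses.asdict(e) for e in evs]
                       for evs in all_events], fh, indent=2, default=_jsonable)
        outputs["entry"] = str(out / "entry_events.json")
    run_stage("entry", do_entry)

    # ---- FES over (SER-C, E_int) ----------------------------------------
    def do_fes():
        poly = np.where(system.polymer_mask)[0]
        enz = np.where(system.enzyme_mask)[0]
        xs, ys = [], []
        for t, es in zip(trajs, all_series):
            for f in range(t.n_frames):
                c, l = _energetics.pair_energy(t.coordinates[f], enz, poly,
                                               system, acfg, t.frame_box(f))
                ys.append(c + l)
            xs.append(es.ser_c)
        x = np.concatenate(xs)
        grid = _fes.fes2d(x, np.asarray(ys), bins=40,
                          temperature=acfg.temperature,
                          axis_names=("SER-C / A", "E_int / kcal mol-1"))
        grid.to_tsv(out / "fes_serc_eint.tsv")
        feats = _fes.fes_features(grid, boundary=acfg.productive_cutoff)
        feats.to_json(out / "fes_features.json")
        outputs["fes"] = str(out / "fes_serc_eint.tsv")
        headline["fes_productive_minima"] = len(feats.productive_minima)
        headline["fes_barrier_kj_mol"] = (None if np.isnan(feats.barrier)
                                          else round(feats.barrier, 3))
    run_stage("fes", do_fes)

    # ---- pathways --------------------------------------------------------
    def do_pathways():
        matrix, residues, event_id, weights = _pathways.entry_feature_matrix(
            all_events, trajs, system, radius=acfg.pca_radius)
        model = _pathways.pca_fit(matrix, weights, residues)
        model.to_json(out / "pc_model.json")
        proj = _pathways.project(model, matrix)
        labels = _pathways.assign_pathways(proj, event_id, k=3, seed=seed)
        with open(out / "pathways.json", "w") as fh:
            json.dump({str(e): l for e, l in labels.items()}, fh, indent=2)
        outputs["pathways"] = str(out / "pathways.json")
        headline["pathway_counts"] = {
            p: sum(1 for l in labels.values() if l == p) for p in (1, 2, 3)}
        headline["pc1_explained_fraction"] = round(
            float(model.explained_fraction[0]), 4)
    run_stage("pathways", do_pathways)

    # ---- kinetics --------------------------------------------------------
    def do_kinetics():
        kc = cfg["kinetics"]
        conv = _synth.make_kinetic_data(kc["K_m_conv"], kc["V_max_conv"], "conv",
                                        kc["n_points"], kc["noise_fraction"],
                                        seed=seed + 11)
        inv = _synth.make_kinetic_data(kc["K_m_inv"], kc["V_max_inv"], "inv",
                                       kc["n_points"], kc["noise_fraction"],
                                       seed=seed + 13)
        fc = _kinetics.fit_mm(conv)
        fi = _kinetics.fit_mm(inv)
        sec = _kinetics.secondary_params(fc, fi, kc["conversion"],
                                         substrate_load=kc["substrate_load"])
        table = {
            "conv_K_m": _kinetics.round_report(fc.K_m),
            "conv_V_max": _kinetics.round_report(fc.V_max),
            "inv_K_m": _kinetics.round_report(fi.K_m),
            "inv_V_max": _kinetics.round_report(fi.V_max),
            "k_cat": _kinetics.round_report(sec.k_cat),
            "molar_K_m": _kinetics.round_report(sec.molar_K_m),
            "molar_eta": _kinetics.round_report(sec.molar_eta),
        }
        with open(out / "kinetics.json", "w") as fh:
            json.dump(table, fh, indent=2)
        outputs["kinetics"] = str(out / "kinetics.json")
        headline["kinetic_table"] = table
    run_stage("kinetics", do_kinetics)

    report = RunReport(stages=statuses, config_hash=cfg_hash,
                       parameters=cfg, outputs=outputs, headline=headline)
    report.to_json(report_path)
    return report
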