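"""Analysis orchestration: run configured stages and emit a report bundle.

A run is driven by a single config mapping (YAML on disk). Each enabled
stage writes its artifact into the output directory and contributes headline
numbers to ``summary.json``. All randomness flows from the seeds recorded in
the config, so re-running an identical config gives a byte-identical summary.

Stages operate either on user-supplied coordinate files (``structure``,
``structure_b`` paths with chain-role selections) or, by default, on the
package's synthetic fixtures, which carry exact ground truth and make the
pipeline runnable end-to-end with no downloads.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import binding, interface, membrane, superpose, synth
from .structio import Selection, parse_selection, read_structure, write_structure

__all__ = ["DEFAULT_CONFIG", "RunConfig", "run", "load_config"]

logger = logging.getLogger("rascal.pipeline")

DEFAULT_CONFIG: dict = {
    "out_dir": "rascal_out",
    "seed": 0,
    "log_level": "INFO",
    "stages": [],                # subset of: interface, motion, membrane, binding
    "interface": {
        "structure": None,       # path; synthetic planted complex when null
        "partner_a": "A",        # selection strings, "chain:ranges/atom"
        "partner_b": "B",
        "n_hbonds": 3, "n_saltbridges": 1, "n_nonbonded": 5,
        "find_zinc": True,
    },
    "motion": {
        "structure": None,       # reference; synthetic complex when null
        "structure_b": None,     # perturbed/second structure
        "anchor": "A",
        "domain": "B",
        "chain_map": {},
        # synthetic-truth parameters (used when structure is null)
        "angle_deg": 25.0, "screw_A": 2.0, "axis": [0.0, 0.0, 1.0],
    },
    "membrane": {
        "slab": {"x_extent": 120.0, "y_extent": 120.0, "spacing": 2.0,
                 "headgroup_z": 2.0, "thickness": 4.0},
        "pose": {"tilt": 90.0, "rotation": -15.0, "dgz": 15.0},
        "clash_cutoff_A": 1.0,
        "ensemble": {"n": 200, "tilt": [90.0, 8.0], "rotation": [-15.0, 8.0],
                     "dgz_mean": 30.0, "dgz_sd": 0.5, "bin_halfwidth": 5.0},
        "write_pdb": True,
    },
    "binding": {
        "isotherms": None,       # CSV path (concentration_M, response_RU, replicate)
        "panel": [{"name": "RBDCRD", "kd_nM": 152.0},
                  {"name": "RBD", "kd_nM": 356.0}],
        "rmax_RU": 100.0,
        "noise_frac": 0.02,
        "concentrations_nM": [10, 30, 100, 300, 1000, 3000, 10000, 20000],
        "reference": "RBDCRD",
    },
}


@dataclasses.dataclass
class RunConfig:
    raw: dict

    @property
    def out_dir(self) -> Path:
        return Path(self.raw["out_dir"])

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def stages(self) -> list[str]:
        return list(self.raw.get("stages") or [])

    def section(self, name: str) -> dict:
        return self.raw.get(name, {})


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None,
                ) -> RunConfig:
    """Load a YAML config merged over the embedded defaults."""
    raw = DEFAULT_CONFIG
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        raw = _merge(raw, yaml.safe_load(path.read_text()) or {})
    if overrides:
        raw = _merge(raw, overrides)
    return RunConfig(raw=raw)


def _sel(text_or_none: str | None, default: str) -> Selection:
    return parse_selection(text_or_none if text_or_none else default)


def _require_file(path_str: str, what: str) -> Path:
    path = Path(path_str)
    if not path.exists():
        raise FileNotFoundError(f"{what}: {path}")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_interface(cfg: RunConfig, out: Path) -> dict:
    params = cfg.section("interface")
    if params.get("structure"):
        model = read_structure(_require_file(params["structure"], "interface structure"))
        truth = None
    else:
        model, truth = synth.make_planted_complex(
            int(params["n_hbonds"]), int(params["n_saltbridges"]),
            int(params["n_nonbonded"]), seed=cfg.seed)
    sel_a = _sel(params.get("partner_a"), "A")
    sel_b = _sel(params.get("partner_b"), "B")
    report = interface.interface_report(model, sel_a, sel_b)
    report.contacts_table().to_csv(out / "contacts.tsv", sep="\t", index=False)
    result = report.to_dict()
    if truth is not None:
        result["planted_counts"] = list(truth.counts())
    if params.get("find_zinc", True):
        sites = interface.find_zinc_sites(model)
        result["zinc_sites"] = [
            {"zinc": list(s.zinc), "residues": [list(r) for r in s.residues]}
            for s in sites]
    return result


def _stage_motion(cfg: RunConfig, out: Path) -> dict:
    params = cfg.section("motion")
    anchor = _sel(params.get("anchor"), "A")
    domain = _sel(params.get("domain"), "B")
    chain_map = dict(params.get("chain_map") or {})
    result: dict = {}
    if params.get("structure"):
        model_a = read_structure(_require_file(params["structure"], "motion structure"))
        model_b = read_structure(_require_file(params["structure_b"], "motion structure_b"))
    else:
        model_a = synth.make_complex_like()
        model_b, truth = synth.make_perturbed_copy(
            model_a, domain, axis=np.asarray(params["axis"], float),
            angle_deg=float(params["angle_deg"]), screw_disp=float(params["screw_A"]),
            seed=cfg.seed)
        result["planted"] = {"angle_deg": truth.rotation_angle,
                             "screw_A": truth.screw_displacement}
    motion = superpose.domain_motion(model_a, model_b, anchor, domain, chain_map)
    result.update(motion.to_dict())
    (out / "motion.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    return result


def _stage_membrane(cfg: RunConfig, out: Path) -> dict:
    params = cfg.section("membrane")
    frame = synth.make_lipid_slab(**params["slab"])
    pose = params["pose"]
    complex_model = synth.make_complex_like()
    reference = synth.make_kras_like()
    posed_ref = membrane.construct_pose(reference, frame, float(pose["tilt"]),
                                        float(pose["rotation"]), float(pose["dgz"]))
    fit_sel = Selection(chains=("A",), residue_ranges=membrane.KRAS_FIT_RANGES,
                        atom_names=("CA",))
    posed_complex, fit_rmsd = membrane.align_complex_to_posed_reference(
        complex_model, posed_ref, fit_sel)
    occ = membrane.count_clashes(posed_complex, frame,
                                 cutoff=float(params["clash_cutoff_A"]),
                                 gdomain_sel=Selection(chains=("A",)))
    loops = membrane.loop_insertion(posed_complex, frame, raf_chain="B")
    angles = membrane.pose_angles(posed_complex, frame, chain="A")
    ens = params["ensemble"]
    poses, truth = synth.make_pose_ensemble(
        int(ens["n"]), tuple(ens["tilt"]), tuple(ens["rotation"]),
        synth.DgzBinModel(default_mean=float(ens["dgz_mean"]),
                          noise_sd=float(ens["dgz_sd"]),
                          bin_halfwidth=float(ens["bin_halfwidth"])),
        seed=cfg.seed, frame=frame, reference=reference, with_models=False)
    summary = membrane.ensemble_summary(
        [(p.angles, p.d_gz) for p in poses],
        bin_halfwidth=float(ens["bin_halfwidth"]))
    summary.table().to_csv(out / "ensemble_bins.tsv", sep="\t", index=False)
    loops.to_csv(out / "loop_insertion.tsv", sep="\t", index=False)
    if params.get("write_pdb", True):
        write_structure(posed_complex, out / "posed_complex.pdb", format="pdb")
    (out / "membrane_frame.json").write_text(
        json.dumps(frame.to_dict(), indent=1, sort_keys=True))
    inserted = loops[loops["inserted"]]
    return {
        "pose": {"tilt_deg": angles.tilt, "rotation_deg": angles.rotation,
                 "dgz_A": occ.d_gz, "fit_rmsd_A": fit_rmsd},
        "n_res_clash": occ.n_res_clash,
        "n_inserted_loop_residues": int(inserted.shape[0]),
        "inserted_loops": sorted(set(int(v) for v in inserted["loop"])),
        "ensemble": {"n_poses": summary.n_poses, "n_bins": len(summary.bins)},
    }


def _stage_binding(cfg: RunConfig, out: Path) -> dict:
    params = cfg.section("binding")
    isotherms: list[binding.IsothermData] = []
    if params.get("isotherms"):
        import pandas as pd
        path = _require_file(params["isotherms"], "binding isotherms")
        df = pd.read_csv(path)
        for name, grp in df.groupby(df.get("replicate", "all")):
            isotherms.append(binding.IsothermData(
                grp["concentration_M"].to_numpy(),
                grp["response_RU"].to_numpy(), replicate=name))
    else:
        conc = np.asarray(params["concentrations_nM"], float) * 1e-9
        rmax = float(params["rmax_RU"])
        noise = float(params["noise_frac"]) * rmax
        for i, entry in enumerate(params["panel"]):
            isotherms.append(synth.make_isotherm(
                float(entry["kd_nM"]) * 1e-9, rmax, conc, noise,
                seed=cfg.seed + i, replicate=entry["name"]))
    table = binding.fit_panel(isotherms)
    table.to_csv(out / "kd_table.tsv", sep="\t", index=False)
    result = {"kd_table": table.to_dict(orient="records")}
    reference = params.get("reference")
    kds = {row["variant"]: row["kd_mean_M"] for row in result["kd_table"]}
    if reference in kds:
        result["fold_change_vs_" + reference] = {
            name: binding.fold_change(kd, kds[reference])
            for name, kd in kds.items() if name != reference}
    return result


_STAGES = {
    "interface": _stage_interface,
    "motion": _stage_motion,
    "membrane": _stage_membrane,
    "binding": _stage_binding,
}


def run(config: RunConfig) -> dict:
    """Execute every enabled stage; return (and write) the summary.

    A stage failure is recorded in the summary and the remaining stages still
    run; the summary's ``ok`` flag is true iff all enabled stages succeeded.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    level = getattr(logging, str(config.raw.get("log_level", "INFO")).upper(), logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("rascal")
    root.setLevel(level)
    root.addHandler(handler)
    summary: dict = {"seed": config.seed, "stages": {}, "config": config.raw, "ok": True}
    try:
        for name in config.stages:
            if name == "all":
                continue
            stage = _STAGES.get(name)
            if stage is None:
                raise ValueError(f"unknown stage {name!r}")
            logger.info("running stage %s", name)
            try:
                summary["stages"][name] = {"ok": True, "result": stage(config, out)}
            except FileNotFoundError:
                raise  # missing inputs fail the whole run, fast
            except Exception as exc:
                logger.exception("stage %s failed", name)
                summary["stages"][name] = {"ok": False, "error": f"{type(exc).__name__}: {exc}"}
                summary["ok"] = False
    finally:
        root.removeHandler(handler)
        handler.close()
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=str) + "\n")
    return summary
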