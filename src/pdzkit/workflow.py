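"""Config validation and the one-command simulate -> analyse -> report pipeline."""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PdzkitError
from .csp import RegionMap, perturbation_profile, region_summary
from .itc import (
    InjectionSchedule,
    Isotherm,
    OneSiteParams,
    ThermoTable,
    fit_one_site,
)
from .saltbridge import (
    ContactCriterion,
    distance_series,
    helix_undocked_fraction,
    occupancy_table,
)
from .structure import default_scheme, parse_trajectory, write_trajectory
from .synth import (
    ITCSpec,
    TitrationSpec,
    gen_contact_trajectory,
    gen_itc_experiment,
    gen_titration_peaklists,
    wt_like_spec,
)

log = logging.getLogger("pdzkit")

STAGES = (
    "simulate_traj",
    "saltbridge",
    "helixstate",
    "simulate_itc",
    "itc_fit",
    "simulate_peaks",
    "csp",
)

DEFAULTS: dict = {
    "seed": 0,
    "out_dir": "pdzkit_run",
    "log_level": "INFO",
    "temperature": 298.15,
    "stages": list(STAGES),
    "criterion": {"mode": "anchor_carbon", "cutoff": 5.0},
    "trajectory": {
        "n_frames": 300,
        "frame_interval": 2.0,
        "mean_dwell": 50.0,
        "jitter_sd": 0.05,
        "distance_pair": [["A", 334], ["B", -5]],
    },
    "itc": {
        "n": 0.99,
        "Kd_uM": 1.5,
        "dH": -9.8,
        "n_injections": 19,
        "injection_volume_uL": 2.0,
        "syringe_conc_uM": 900.0,
        "cell_conc_uM": 70.0,
        "cell_volume_uL": 200.0,
        "noise_sd_ucal": 0.1,
        "dilution_heat_ucal": -0.3,
    },
    "titration": {
        "Kd_uM": 1.5,
        "protein_conc_uM": 100.0,
        "ligand_concs_uM": [0.0, 50.0, 100.0, 200.0, 500.0, 2000.0],
        "noise_sd_ppm": 0.0,
    },
    "regions": [
        ["beta2", 323, 328],
        ["beta2-beta3-loop", 329, 334],
        ["beta3", 335, 340],
        ["alpha2", 370, 378],
        ["alpha3", 394, 403],
    ],
    "aggregate_pairs": [
        "Lys(-5)-Glu331",
        "Lys(-5)-Glu334",
        "Lys(-4)-Glu331",
        "Lys(-5)-Glu401",
        "Lys(-4)-Glu373",
    ],
}


@dataclass
class RunConfig:
    settings: dict

    def __getitem__(self, key):
        return self.settings[key]

    @property
    def seed(self) -> int:
        return int(self.settings["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.settings["out_dir"])

    @property
    def criterion(self) -> ContactCriterion:
        c = self.settings["criterion"]
        return ContactCriterion(c["mode"], float(c["cutoff"]))

    @property
    def regions(self) -> RegionMap:
        return RegionMap(tuple((n, int(a), int(b)) for n, a, b in self.settings["regions"]))


def _merge(defaults: dict, user: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (user or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def validate_config(text: str) -> tuple[RunConfig | None, list[str]]:
    """Parse + validate a YAML run config.

    Returns ``(config, [])`` on success or ``(None, violations)`` with the
    complete list of violations, never just the first one.
    """
    errors: list[str] = []
    try:
        user = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        return None, [f"not valid YAML: {exc}"]
    if not isinstance(user, dict):
        return None, ["top-level config must be a mapping"]

    known = set(DEFAULTS)
    for key in set(user) - known:
        errors.append(f"unknown config key {key!r}")
    settings = _merge(DEFAULTS, {k: v for k, v in user.items() if k in known})

    for stage in settings["stages"]:
        if stage not in STAGES:
            errors.append(f"stages: unknown stage {stage!r}")
    if not isinstance(settings["seed"], int):
        errors.append("seed: must be an integer")
    if not float(settings["temperature"]) > 0:
        errors.append("temperature: must be > 0")
    crit = settings["criterion"]
    if crit.get("mode") not in ("anchor_carbon", "charged_center"):
        errors.append(f"criterion.mode: unknown mode {crit.get('mode')!r}")
    if not float(crit.get("cutoff", 0)) > 0:
        errors.append("criterion.cutoff: must be > 0")
    traj = settings["trajectory"]
    if int(traj["n_frames"]) < 1:
        errors.append("trajectory.n_frames: must be >= 1")
    if float(traj["frame_interval"]) <= 0:
        errors.append("trajectory.frame_interval: must be > 0")
    if float(traj["jitter_sd"]) < 0:
        errors.append("trajectory.jitter_sd: must be >= 0")
    itc = settings["itc"]
    for key in ("Kd_uM", "syringe_conc_uM", "cell_conc_uM", "cell_volume_uL",
                "injection_volume_uL", "n"):
        if not float(itc[key]) > 0:
            errors.append(f"itc.{key}: must be > 0")
    if int(itc["n_injections"]) < 1:
        errors.append("itc.n_injections: must be >= 1")
    if float(itc["noise_sd_ucal"]) < 0:
        errors.append("itc.noise_sd_ucal: must be >= 0")
    tit = settings["titration"]
    if not float(tit["Kd_uM"]) > 0:
        errors.append("titration.Kd_uM: must be > 0")
    if not float(tit["protein_conc_uM"]) > 0:
        errors.append("titration.protein_conc_uM: must be > 0")
    if any(float(c) < 0 for c in tit["ligand_concs_uM"]):
        errors.append("titration.ligand_concs_uM: must be >= 0")
    for region in settings["regions"]:
        if len(region) != 3 or int(region[1]) > int(region[2]):
            errors.append(f"regions: bad region entry {region!r}")

    if errors:
        return None, errors
    return RunConfig(settings), []


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    status: str = "ok"

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status,
                "stages": self.stages,
                "versions": self.versions,
                "wall_time_s": self.wall_time_s,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(out_dir: Path, files: list[Path]) -> list[dict]:
    return [
        {
            "path": str(f.relative_to(out_dir)),
            "sha256": _sha256(f),
            "bytes": f.stat().st_size,
        }
        for f in files
    ]


def run_pipeline(config: RunConfig) -> RunReport:
    """Run the selected stages in dependency order, writing one output tree.

    Identical config + seed produce byte-identical analysis tables; the run
    report (which includes wall time) is written alongside as report.json.
    """
    t0 = time.monotonic()
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    scheme = default_scheme()
    report = RunReport(config=config.settings, versions=_versions())
    selected = [s for s in STAGES if s in config["stages"]]

    try:
        for stage in selected:
            log.info("running stage %s", stage)
            files = _STAGE_FUNCS[stage](config, out, scheme)
            report.stages[stage] = {"files": _manifest(out, files)}
    except Exception as exc:
        report.status = f"failed at stage {stage}: {exc}"
        report.wall_time_s = time.monotonic() - t0
        (out / "report.json").write_text(report.to_json())
        raise PdzkitError(f"stage {stage!r} failed: {exc}") from exc

    report.wall_time_s = time.monotonic() - t0
    (out / "report.json").write_text(report.to_json())
    return report


def _versions() -> dict:
    import scipy

    return {
        "pdzkit": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


# --------------------------------------------------------------------------
# stage implementations (simulate stages write inputs; analysis stages read
# them back from disk so the full I/O path is exercised)
# --------------------------------------------------------------------------

def _stage_simulate_traj(config: RunConfig, out: Path, scheme) -> list[Path]:
    t = config["trajectory"]
    spec = wt_like_spec(
        n_frames=int(t["n_frames"]),
        seed=config.seed,
        mean_dwell=float(t["mean_dwell"]),
    )
    spec.jitter_sd = float(t["jitter_sd"])
    spec.frame_interval = float(t["frame_interval"])
    traj, truth = gen_contact_trajectory(spec, scheme)
    traj_path = out / "trajectory.pdb"
    truth_path = out / "trajectory_truth.tsv"
    traj_path.write_text(write_trajectory(traj))
    truth_path.write_text(truth.to_tsv())
    return [traj_path, truth_path]


def _load_traj(config: RunConfig, out: Path):
    path = out / "trajectory.pdb"
    if not path.exists():
        raise PdzkitError("trajectory.pdb not found; run simulate_traj first")
    return parse_trajectory(
        path.read_text(), frame_interval=float(config["trajectory"]["frame_interval"])
    )


def _stage_saltbridge(config: RunConfig, out: Path, scheme) -> list[Path]:
    traj = _load_traj(config, out)
    spec = wt_like_spec()
    pairs = [t.pair for t in spec.pairs]
    aggregates = {"PDZ3-Lys(-4)(-5)": list(config["aggregate_pairs"])}
    table = occupancy_table(traj, pairs, aggregates, config.criterion, scheme)
    table_path = out / "occupancy.tsv"
    table_path.write_text(table.to_tsv())
    (a, b) = config["trajectory"]["distance_pair"]
    dist = distance_series(
        traj, (a[0], int(a[1])), (b[0], int(b[1])), scheme, metric="anchor_min"
    )
    dist_path = out / "distance_series.tsv"
    dist_path.write_text(dist.to_csv(sep="\t", index=False, float_format="%.3f"))
    return [table_path, dist_path]


def _stage_helixstate(config: RunConfig, out: Path, scheme) -> list[Path]:
    traj = _load_traj(config, out)
    undocked = helix_undocked_fraction(traj, config.criterion, scheme)
    path = out / "helix_state.tsv"
    path.write_text(
        "quantity\tvalue\n"
        f"undocked_fraction\t{undocked:.6f}\n"
        f"undocked_percent\t{100 * undocked:.1f}%\n"
    )
    return [path]


def _itc_schedule(config: RunConfig) -> InjectionSchedule:
    c = config["itc"]
    return InjectionSchedule.uniform(
        n_injections=int(c["n_injections"]),
        injection_volume=float(c["injection_volume_uL"]),
        syringe_conc=float(c["syringe_conc_uM"]) * 1e-6,
        cell_conc_initial=float(c["cell_conc_uM"]) * 1e-6,
        cell_volume=float(c["cell_volume_uL"]),
        temperature=float(config["temperature"]),
    )


def _stage_simulate_itc(config: RunConfig, out: Path, scheme) -> list[Path]:
    c = config["itc"]
    spec = ITCSpec(
        true_params=OneSiteParams(
            n=float(c["n"]), Kd=float(c["Kd_uM"]) * 1e-6, dH=float(c["dH"])
        ),
        schedule=_itc_schedule(config),
        noise_sd=float(c["noise_sd_ucal"]),
        dilution_heat=float(c["dilution_heat_ucal"]),
        seed=config.seed,
    )
    iso, truth = gen_itc_experiment(spec)
    files = []
    for name, heats in (("isotherm.tsv", iso.heats), ("blank.tsv", iso.blank_heats)):
        df = pd.DataFrame(
            {
                "injection": np.arange(1, len(heats) + 1),
                "volume_uL": spec.schedule.injection_volumes,
                "heat_ucal": heats,
            }
        )
        path = out / name
        path.write_text(df.to_csv(sep="\t", index=False, float_format="%.6f"))
        files.append(path)
    truth_path = out / "itc_truth.tsv"
    truth_path.write_text(
        "n\tKd_M\tdH_kcal_mol\n"
        f"{truth.params.n:.6g}\t{truth.params.Kd:.6g}\t{truth.params.dH:.6g}\n"
    )
    files.append(truth_path)
    return files


def read_isotherm_tsv(text: str, schedule: InjectionSchedule, blank_text: str | None = None) -> Isotherm:
    heats = pd.read_csv(pd.io.common.StringIO(text), sep="\t")["heat_ucal"].to_numpy()
    blank = None
    if blank_text is not None:
        blank = pd.read_csv(pd.io.common.StringIO(blank_text), sep="\t")[
            "heat_ucal"
        ].to_numpy()
    return Isotherm(heats=heats, schedule=schedule, blank_heats=blank)


def _stage_itc_fit(config: RunConfig, out: Path, scheme) -> list[Path]:
    iso_path = out / "isotherm.tsv"
    if not iso_path.exists():
        raise PdzkitError("isotherm.tsv not found; run simulate_itc first")
    blank_path = out / "blank.tsv"
    iso = read_isotherm_tsv(
        iso_path.read_text(),
        _itc_schedule(config),
        blank_path.read_text() if blank_path.exists() else None,
    )
    params, diag = fit_one_site(iso)
    row = ThermoTable.from_fit(params, T=float(config["temperature"]), label="fit")
    path = out / "thermo.tsv"
    path.write_text(
        "n\tKd_uM\tdH_kcal_mol\tminus_TdS_kcal_mol\tdG_kcal_mol\tresidual_norm\n"
        f"{params.n:.4f}\t{row.Kd_uM:.3g}\t{row.dH:.2f}\t{row.minus_TdS:.2f}"
        f"\t{row.dG:.2f}\t{diag.residual_norm:.4g}\n"
    )
    return [path]


def _stage_simulate_peaks(config: RunConfig, out: Path, scheme) -> list[Path]:
    t = config["titration"]
    # perturbation localized in the loop and helix regions, as in a titration
    ddmax = {("A", i): (0.0, 0.0) for i in range(302, 404)}
    for i in range(329, 335):
        ddmax[("A", i)] = (0.55, 1.8)
    for i in range(394, 404):
        ddmax[("A", i)] = (0.25, 0.9)
    for i in range(370, 379):
        ddmax[("A", i)] = (0.12, 0.5)
    spec = TitrationSpec(
        Kd=float(t["Kd_uM"]) * 1e-6,
        ddmax=ddmax,
        protein_conc=float(t["protein_conc_uM"]) * 1e-6,
        ligand_concs=tuple(float(c) * 1e-6 for c in t["ligand_concs_uM"]),
        noise_sd=float(t["noise_sd_ppm"]),
        seed=config.seed,
    )
    lists, truth = gen_titration_peaklists(spec)
    files = []
    for i, plist in enumerate(lists):
        path = out / f"peaks_{i:02d}.tsv"
        path.write_text(plist.to_tsv())
        files.append(path)
    truth_path = out / "titration_truth.tsv"
    truth_path.write_text(
        "ligand_conc_M\tfraction_bound\n"
        + "".join(f"{c:.6g}\t{fb:.8f}\n" for c, fb in truth.fractions_bound.items())
    )
    files.append(truth_path)
    return files


def _stage_csp(config: RunConfig, out: Path, scheme) -> list[Path]:
    peak_files = sorted(out.glob("peaks_*.tsv"))
    if len(peak_files) < 2:
        raise PdzkitError("need simulated peak lists; run simulate_peaks first")
    from .csp import PeakList

    free = PeakList.from_tsv(peak_files[0].read_text(), label="free")
    bound = PeakList.from_tsv(peak_files[-1].read_text(), label="bound")
    profile = perturbation_profile(free, bound)
    prof_path = out / "csp_profile.tsv"
    prof_path.write_text(
        profile.to_frame().to_csv(sep="\t", index=False, float_format="%.4f")
    )
    summary = region_summary(profile, config.regions)
    sum_path = out / "csp_regions.tsv"
    sum_path.write_text(summary.to_csv(sep="\t", index=False, float_format="%.4f"))
    return [prof_path, sum_path]


_STAGE_FUNCS = {
    "simulate_traj": _stage_simulate_traj,
    "saltbridge": _stage_saltbridge,
    "helixstate": _stage_helixstate,
    "simulate_itc": _stage_simulate_itc,
    "itc_fit": _stage_itc_fit,
    "simulate_peaks": _stage_simulate_peaks,
    "csp": _stage_csp,
}
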