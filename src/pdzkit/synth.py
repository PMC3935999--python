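"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, each emitting a machine-readable truth record:

* :func:`gen_contact_trajectory` — multi-frame coordinates whose salt-bridge
  states follow two-state Markov chains (prescribed stationary occupancy and
  mean dwell) with optional per-frame competition between bridges sharing a
  partner.
* :func:`gen_itc_experiment` — noisy single-site titration heats plus a blank
  dilution run.
* :func:`gen_titration_peaklists` — fast-exchange HSQC titration peak lists.

Trajectory geometry is scaffolding, not physics.  Negatively charged
residues act as static hubs; each positively charged residue is mobile and
docks onto at most one hub per frame, which makes bridges sharing a mobile
residue geometrically exclusive by construction.  Anchor-carbon distances
are placed at the formed/broken target distances plus clipped Gaussian
jitter, with margins validated so that no jittered distance can ever cross
either detection cutoff: detector output therefore equals the truth record
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .itc import InjectionSchedule, Isotherm, OneSiteParams, model_heats
from .csp import Peak, PeakList
from .saltbridge import PairSpec
from .structure import (
    Atom,
    ChargedGroupScheme,
    Residue,
    Structure,
    Trajectory,
    default_scheme,
)

__all__ = [
    "PairTarget",
    "TrajectorySpec",
    "TrajectoryTruth",
    "ITCSpec",
    "TitrationSpec",
    "gen_contact_trajectory",
    "gen_itc_experiment",
    "gen_titration_peaklists",
    "fraction_bound",
    "default_residue_codes",
    "wt_like_spec",
]

#: Detection cutoffs the geometry must never let jitter cross.
_ANCHOR_CUTOFF = 5.0
_CENTER_CUTOFF = 4.0
#: Offset of a charged-group mass center from its anchor tip (Å): mobile
#: charge points 0.5 Å toward the hub, so center-center = anchor-min - 0.5.
_CHARGE_OFFSET = 0.5


@dataclass(frozen=True)
class PairTarget:
    """One bridge to simulate: spec, stationary occupancy and mean dwell."""

    pair: PairSpec
    occupancy: float
    mean_dwell: float = 50.0  # frames; placeholder default, configurable

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError(
                f"{self.pair.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.mean_dwell < 1.0:
            raise ValidationError(f"{self.pair.name}: mean dwell must be >= 1 frame")


@dataclass
class TrajectorySpec:
    pairs: list[PairTarget]
    residue_codes: dict[tuple[str, int], str]
    n_frames: int = 1000
    frame_interval: float = 2.0  # ps
    competition_groups: list[list[str]] = field(default_factory=list)
    formed_distance: float = 4.0  # Å (anchor-carbon minimum when formed)
    broken_distance: float = 7.0  # Å (single-hub mobiles when broken)
    jitter_sd: float = 0.05  # Å; clipped at 4 sigma
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        labels = [t.pair.name for t in self.pairs]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate pair labels in trajectory spec")
        for t in self.pairs:
            for key in (t.pair.residue_a, t.pair.residue_b):
                if key not in self.residue_codes:
                    raise ValidationError(f"no residue code given for {key}")
        for group in self.competition_groups:
            unknown = set(group) - set(labels)
            if unknown:
                raise ValidationError(
                    f"competition group references unknown pairs {sorted(unknown)}"
                )
        # Jitter must not be able to push any distance across a cutoff.
        margin = min(
            _ANCHOR_CUTOFF - self.formed_distance,
            self.broken_distance - _ANCHOR_CUTOFF,
            _CENTER_CUTOFF - (self.formed_distance - _CHARGE_OFFSET),
            (self.broken_distance - _CHARGE_OFFSET) - _CENTER_CUTOFF,
        )
        if margin <= 0:
            raise ValidationError(
                "formed/broken distances must bracket both detection cutoffs"
            )
        if 4.0 * self.jitter_sd >= margin:
            raise ValidationError(
                f"jitter sd {self.jitter_sd} can cross a detection cutoff "
                f"(4*sd must stay below {margin:.3f} Å)"
            )


@dataclass
class TrajectoryTruth:
    """Exact per-frame bridge states plus the configured targets."""

    states: dict[str, np.ndarray]  # label -> bool per frame
    targets: dict[str, PairTarget]

    def occupancy(self, label: str) -> float:
        return float(np.mean(self.states[label]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {label: s.astype(int) for label, s in self.states.items()}
        )

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index_label="frame")


# ---------------------------------------------------------------------------
# state sampling
# ---------------------------------------------------------------------------

def _sample_markov(rng, pi: float, dwell: float, n: int) -> np.ndarray:
    """Two-state chain with stationary P(formed)=pi and mean formed dwell."""
    if pi == 0.0:
        return np.zeros(n, dtype=bool)
    if pi == 1.0:
        return np.ones(n, dtype=bool)
    p_leave = 1.0 / dwell  # formed -> broken
    p_enter = pi * p_leave / (1.0 - pi)  # broken -> formed, from stationarity
    if p_enter > 1.0:
        raise ValidationError(
            f"occupancy {pi} unreachable with mean dwell {dwell} "
            "(entering probability exceeds 1)"
        )
    u = rng.random(n)
    states = np.empty(n, dtype=bool)
    states[0] = u[0] < pi  # start from the stationary distribution
    for t in range(1, n):
        if states[t - 1]:
            states[t] = u[t] >= p_leave
        else:
            states[t] = u[t] < p_enter
    return states


def _sample_group(rng, pis: list[float], n: int) -> np.ndarray:
    """Per-frame categorical draw over group members + 'none'.

    Returns an integer array with -1 for 'none'; marginal fidelity is
    preferred over dwell fidelity within groups (documented limitation).
    """
    probs = np.array(pis + [1.0 - sum(pis)])
    choices = rng.choice(len(probs), size=n, p=probs)
    choices[choices == len(pis)] = -1
    return choices


def _merge_groups(spec: TrajectorySpec, mobile_of: dict[str, tuple[str, int]]):
    """Union-find over pairs: same mobile residue, or declared competition."""
    labels = [t.pair.name for t in spec.pairs]
    parent = {lab: lab for lab in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    by_mobile: dict[tuple[str, int], str] = {}
    for lab in labels:
        m = mobile_of[lab]
        if m in by_mobile:
            union(lab, by_mobile[m])
        else:
            by_mobile[m] = lab
    for group in spec.competition_groups:
        for lab in group[1:]:
            union(group[0], lab)

    merged: dict[str, list[str]] = {}
    for lab in labels:
        merged.setdefault(find(lab), []).append(lab)
    return list(merged.values())


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _orthobasis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _charged_offsets(n_atoms: int, u: np.ndarray) -> list[np.ndarray]:
    """Mass-balanced placements around the group center, perpendicular to u."""
    if n_atoms == 1:
        return [np.zeros(3)]
    e1, e2 = _orthobasis(u)
    r = 0.55
    return [
        r * (np.cos(2 * np.pi * k / n_atoms) * e1 + np.sin(2 * np.pi * k / n_atoms) * e2)
        for k in range(n_atoms)
    ]


def _residue_sign(code_key, spec: TrajectorySpec, scheme: ChargedGroupScheme, terminus):
    res = Residue(spec.residue_codes[code_key], code_key[1], code_key[0])
    return scheme.group_for(res, terminus)


def gen_contact_trajectory(
    spec: TrajectorySpec, scheme: ChargedGroupScheme | None = None
) -> tuple[Trajectory, TrajectoryTruth]:
    """Simulate a trajectory whose bridge states follow the spec exactly.

    Returns the trajectory and a truth record with the exact per-frame
    states; by construction the anchor-carbon (5 Å) and charged-center (4 Å)
    detectors both reproduce the truth record frame for frame.
    """
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    # Orient every pair: the positively charged residue is the mobile one.
    groups_by_res: dict[tuple[str, int], object] = {}
    mobile_of: dict[str, tuple[str, int]] = {}
    hub_of: dict[str, tuple[str, int]] = {}
    for t in spec.pairs:
        p = t.pair
        ga = _residue_sign(p.residue_a, spec, scheme, p.terminus_a)
        gb = _residue_sign(p.residue_b, spec, scheme, p.terminus_b)
        if ga.sign * gb.sign != -1:
            raise ValidationError(f"{p.name}: residues must carry opposite charges")
        (mob, hub) = (p.residue_a, p.residue_b) if ga.sign > 0 else (p.residue_b, p.residue_a)
        mobile_of[p.name] = mob
        hub_of[p.name] = hub
        groups_by_res[p.residue_a] = (ga, p.terminus_a)
        groups_by_res[p.residue_b] = (gb, p.terminus_b)

    merged = _merge_groups(spec, mobile_of)
    targets = {t.pair.name: t for t in spec.pairs}
    for group in merged:
        total = sum(targets[lab].occupancy for lab in group)
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"occupancies in exclusive group {sorted(group)} sum to "
                f"{total:.3f} > 1"
            )

    # --- sample truth states -----------------------------------------------
    states: dict[str, np.ndarray] = {}
    for group in merged:
        if len(group) == 1:
            lab = group[0]
            states[lab] = _sample_markov(
                rng, targets[lab].occupancy, targets[lab].mean_dwell, n
            )
        else:
            choice = _sample_group(rng, [targets[lab].occupancy for lab in group], n)
            for k, lab in enumerate(group):
                states[lab] = choice == k

    # --- lay out hubs ------------------------------------------------------
    hubs = sorted({hub_of[lab] for lab in targets}, key=str)
    hub_pos = {
        h: np.array([15.0 * i, 0.0, 0.0]) for i, h in enumerate(hubs)
    }
    mobiles = sorted({mobile_of[lab] for lab in targets}, key=str)
    free_pos = {
        m: np.array([15.0 * i, 0.0, 40.0]) for i, m in enumerate(mobiles)
    }
    # docking direction per (mobile, hub): fan out in the xy/xz half-space
    dock_dirs: dict[tuple, np.ndarray] = {}
    for h in hubs:
        partners = sorted({mobile_of[lab] for lab in targets if hub_of[lab] == h}, key=str)
        for j, m in enumerate(partners):
            angle = np.pi / 2 + (j - (len(partners) - 1) / 2) * (np.pi / 4)
            dock_dirs[(m, h)] = np.array([np.cos(angle), np.sin(angle), 0.0])

    # --- topology ----------------------------------------------------------
    residues: list[Residue] = []
    for key in sorted(set(hubs) | set(mobiles), key=str):
        group, _term = groups_by_res[key]
        res = Residue(spec.residue_codes[key], key[1], key[0])
        for name in group.anchor_carbons:
            res.add_atom(Atom(name, "C", np.zeros(3)))
        for name in group.charged_atoms:
            element = "O" if name.startswith("O") else "N"
            res.add_atom(Atom(name, element, np.zeros(3)))
        residues.append(res)
    topology = Structure(residues, title="synthetic contact trajectory")
    atom_keys = topology.atom_keys()
    col = {k: i for i, k in enumerate(atom_keys)}
    coords = np.zeros((n, len(atom_keys), 3))

    # --- static hub atoms --------------------------------------------------
    down = np.array([0.0, 0.0, -1.0])
    for h in hubs:
        group, _ = groups_by_res[h]
        tip = hub_pos[h]
        a1, a2 = group.anchor_carbons
        coords[:, col[(h[0], h[1], a1)], :] = tip + 1.5 * down
        coords[:, col[(h[0], h[1], a2)], :] = tip
        for name, off in zip(
            group.charged_atoms, _charged_offsets(len(group.charged_atoms), down)
        ):
            coords[:, col[(h[0], h[1], name)], :] = tip + off

    # --- mobile atoms: per-frame docking -----------------------------------
    jitter = np.clip(
        rng.normal(0.0, spec.jitter_sd, size=n), -4 * spec.jitter_sd, 4 * spec.jitter_sd
    ) if spec.jitter_sd > 0 else np.zeros(n)

    for m in mobiles:
        group, _ = groups_by_res[m]
        my_pairs = [lab for lab in targets if mobile_of[lab] == m]
        # dock index per frame: position in my_pairs, or -1 for undocked
        dock = np.full(n, -1, dtype=int)
        for k, lab in enumerate(my_pairs):
            dock[states[lab]] = k
        options = []  # (mask, anchor_point, direction, distance_per_frame)
        for k, lab in enumerate(my_pairs):
            h = hub_of[lab]
            options.append(
                (dock == k, hub_pos[h], dock_dirs[(m, h)], spec.formed_distance + jitter)
            )
        undocked = dock == -1
        if len(my_pairs) == 1:
            # single-hub mobiles sit at the broken distance on the same ray
            h = hub_of[my_pairs[0]]
            options.append(
                (undocked, hub_pos[h], dock_dirs[(m, h)], spec.broken_distance + jitter)
            )
        else:
            options.append(
                (undocked, free_pos[m], np.array([1.0, 0.0, 0.0]), np.zeros(n))
            )
        a1, a2 = group.anchor_carbons
        for mask, base, u, dist in options:
            if not np.any(mask):
                continue
            d = dist[mask][:, None]
            tip = base + d * u
            coords[mask, col[(m[0], m[1], a2)], :] = tip
            coords[mask, col[(m[0], m[1], a1)], :] = tip + 1.5 * u
            q = tip - _CHARGE_OFFSET * u
            for name, off in zip(
                group.charged_atoms, _charged_offsets(len(group.charged_atoms), u)
            ):
                coords[mask, col[(m[0], m[1], name)], :] = q + off

    # template topology carries frame-0 coordinates
    for res in topology.residues:
        for name in res.atoms:
            res.atoms[name] = Atom(
                name, res.atoms[name].element, coords[0, col[(res.chain, res.index, name)]]
            )
    traj = Trajectory(topology, coords, frame_interval=spec.frame_interval)
    return traj, TrajectoryTruth(states=states, targets=targets)


def default_residue_codes() -> dict[tuple[str, int], str]:
    """Residue types of the charged residues in the reference system."""
    return {
        ("A", 331): "GLU",
        ("A", 332): "ASP",
        ("A", 334): "GLU",
        ("A", 355): "LYS",
        ("A", 373): "GLU",
        ("A", 399): "ARG",
        ("A", 401): "GLU",
        ("A", 403): "LYS",
        ("B", -5): "LYS",
        ("B", -4): "LYS",
        ("B", -3): "GLU",
    }


def wt_like_spec(n_frames: int = 1000, seed: int = 0, mean_dwell: float = 50.0) -> TrajectorySpec:
    """A trajectory spec with the wild-type-like occupancy targets.

    Bridges sharing the 334 carboxylate are declared an explicit competition
    group; bridges sharing a mobile Lys/Arg are exclusive by construction.
    """

    def target(a, b, category, occ, label=None):
        return PairTarget(
            PairSpec(a, b, category=category, label=label), occupancy=occ,
            mean_dwell=mean_dwell,
        )

    pairs = [
        target(("B", -5), ("A", 331), "ligand-b2b3-loop", 0.200, "Lys(-5)-Glu331"),
        target(("B", -5), ("A", 334), "ligand-b2b3-loop", 0.362, "Lys(-5)-Glu334"),
        target(("B", -4), ("A", 331), "ligand-b2b3-loop", 0.372, "Lys(-4)-Glu331"),
        target(("B", -5), ("A", 401), "ligand-alpha3-helix", 0.019, "Lys(-5)-Glu401"),
        target(("B", -3), ("A", 403), "ligand-alpha3-helix", 0.001, "Glu(-3)-Lys403"),
        target(("B", -4), ("A", 373), "ligand-other", 0.198, "Lys(-4)-Glu373"),
        target(("A", 403), ("A", 331), "alpha3-b2b3-loop", 0.027, "Lys403-Glu331"),
        target(("A", 403), ("A", 332), "alpha3-b2b3-loop", 0.007, "Lys403-Asp332"),
        target(("A", 403), ("A", 334), "alpha3-b2b3-loop", 0.000, "Lys403-Glu334"),
        target(("A", 334), ("A", 399), "alpha3-domain", 0.397, "Glu334-Arg399"),
        target(("A", 355), ("A", 401), "alpha3-domain", 0.443, "Lys355-Glu401"),
    ]
    return TrajectorySpec(
        pairs=pairs,
        residue_codes=default_residue_codes(),
        n_frames=n_frames,
        competition_groups=[["Lys(-5)-Glu334", "Glu334-Arg399"]],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass
class ITCSpec:
    true_params: OneSiteParams
    schedule: InjectionSchedule
    noise_sd: float = 0.0  # µcal
    dilution_heat: float = 0.0  # µcal per injection
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class ITCTruth:
    params: OneSiteParams
    clean_heats: np.ndarray  # model heats without dilution or noise


def gen_itc_experiment(spec: ITCSpec) -> tuple[Isotherm, ITCTruth]:
    """Noisy titration heats plus an independently noisy blank run."""
    rng = np.random.default_rng(spec.seed)
    clean = model_heats(spec.true_params, spec.schedule)
    n = len(clean)
    heats = clean + spec.dilution_heat + rng.normal(0.0, spec.noise_sd, n) * (
        1 if spec.noise_sd > 0 else 0
    )
    blank = spec.dilution_heat + rng.normal(0.0, spec.noise_sd, n) * (
        1 if spec.noise_sd > 0 else 0
    )
    iso = Isotherm(heats=heats, schedule=spec.schedule, blank_heats=np.asarray(blank))
    return iso, ITCTruth(params=spec.true_params, clean_heats=clean)


# ---------------------------------------------------------------------------
# NMR titration
# ---------------------------------------------------------------------------

def fraction_bound(protein_conc: float, ligand_conc: float, Kd: float) -> float:
    """Bound protein fraction from the exact single-site quadratic."""
    if ligand_conc == 0.0:
        return 0.0
    s = protein_conc + ligand_conc + Kd
    complex_conc = 0.5 * (s - np.sqrt(s * s - 4 * protein_conc * ligand_conc))
    return float(complex_conc / protein_conc)


@dataclass
class TitrationSpec:
    Kd: float  # molarity
    ddmax: dict[tuple[str, int], tuple[float, float]]  # residue -> (ΔδH, ΔδN) ppm
    protein_conc: float = 100e-6
    ligand_concs: tuple[float, ...] = (0.0, 50e-6, 100e-6, 200e-6, 500e-6, 2000e-6)
    noise_sd: float = 0.0  # ppm, applied to both dimensions
    free_shifts: dict[tuple[str, int], tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.Kd > 0 or not self.protein_conc > 0:
            raise ValidationError("Kd and protein_conc must be > 0")
        if any(c < 0 for c in self.ligand_concs):
            raise ValidationError("ligand concentrations must be >= 0")
        if self.free_shifts is None:
            # deterministic synthetic free-state shifts
            self.free_shifts = {
                res: (8.0 + 0.003 * i, 112.0 + 0.11 * i)
                for res, i in zip(sorted(self.ddmax), range(len(self.ddmax)))
            }


@dataclass
class TitrationTruth:
    Kd: float
    fractions_bound: dict[float, float]  # ligand conc -> fraction bound
    ddmax: dict[tuple[str, int], tuple[float, float]]


def gen_titration_peaklists(spec: TitrationSpec) -> tuple[list[PeakList], TitrationTruth]:
    """Fast-exchange peak lists: observed shift = free + f_bound · Δδ_max + noise."""
    rng = np.random.default_rng(spec.seed)
    lists = []
    fractions = {}
    for conc in spec.ligand_concs:
        fb = fraction_bound(spec.protein_conc, conc, spec.Kd)
        fractions[conc] = fb
        peaks = []
        for res in sorted(spec.ddmax):
            h0, n0 = spec.free_shifts[res]
            dh_max, dn_max = spec.ddmax[res]
            noise = rng.normal(0.0, spec.noise_sd, 2) if spec.noise_sd > 0 else (0.0, 0.0)
            peaks.append(
                Peak(res, h0 + fb * dh_max + noise[0], n0 + fb * dn_max + noise[1])
            )
        label = "free" if conc == 0 else f"titration-point:{conc:g}"
        lists.append(PeakList(peaks, label=label, ligand_conc=conc))
    return lists, TitrationTruth(spec.Kd, fractions, dict(spec.ddmax))
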