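"""Per-frame salt-bridge detection, occupancy statistics and distance series.

Two geometric criteria are supported:

* ``anchor_carbon`` — a bridge is formed in a frame iff the *minimum* distance
  over the 2x2 cross pairs of anchor carbons is strictly below the cutoff
  (default 5.0 Å).  Strict inequality: a distance exactly at the cutoff does
  not count.
* ``charged_center`` — formed iff the distance between the mass-weighted
  centers of the two charged groups is strictly below the cutoff (default
  4.0 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .structure import (
    ChargedGroupScheme,
    Structure,
    Trajectory,
    charged_group_center,
)

__all__ = [
    "ContactCriterion",
    "PairSpec",
    "StateSeries",
    "OccupancyTable",
    "CriterionComparison",
    "contact_state",
    "state_series",
    "occupancy",
    "any_of_occupancy",
    "helix_undocked_fraction",
    "HELIX_ANCHOR_BRIDGES",
    "criterion_agreement",
    "distance_series",
    "occupancy_table",
]

#: Row-category labels mirroring the occupancy-table section headers.
CATEGORIES = (
    "ligand-b2b3-loop",
    "ligand-alpha3-helix",
    "ligand-other",
    "alpha3-b2b3-loop",
    "alpha3-domain",
)


@dataclass(frozen=True)
class ContactCriterion:
    mode: str = "anchor_carbon"
    cutoff: float = 5.0

    def __post_init__(self):
        if self.mode not in ("anchor_carbon", "charged_center"):
            raise ValidationError(f"unknown criterion mode {self.mode!r}")
        if not self.cutoff > 0:
            raise ValidationError("cutoff must be > 0")

    @classmethod
    def anchor_carbon(cls, cutoff: float = 5.0) -> "ContactCriterion":
        return cls("anchor_carbon", cutoff)

    @classmethod
    def charged_center(cls, cutoff: float = 4.0) -> "ContactCriterion":
        return cls("charged_center", cutoff)


@dataclass(frozen=True)
class PairSpec:
    """A candidate salt bridge between two oppositely charged residues."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    category: str = "ligand-other"
    terminus_a: str | None = None  # "N"/"C" to select a terminal group
    terminus_b: str | None = None
    label: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"category {self.category!r} not one of {CATEGORIES}"
            )

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        (ca, ia), (cb, ib) = self.residue_a, self.residue_b
        return f"{ca}{ia}-{cb}{ib}"


@dataclass
class StateSeries:
    """Boolean formed/broken state of one pair, one entry per frame."""

    pair: PairSpec
    states: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 1:
            raise ValidationError("states must be a 1-D boolean array")

    def __len__(self) -> int:
        return len(self.states)


def _check_opposite_signs(res_a, res_b, pair: PairSpec, scheme: ChargedGroupScheme):
    sa = scheme.sign(res_a, pair.terminus_a)
    sb = scheme.sign(res_b, pair.terminus_b)
    if sa * sb != -1:
        raise ValidationError(
            f"pair {pair.name}: residues do not carry opposite charges"
        )


def contact_state(
    frame: Structure,
    pair: PairSpec,
    criterion: ContactCriterion,
    scheme: ChargedGroupScheme,
) -> bool:
    """Is the salt bridge formed in this frame?  Scalar (per-frame) route."""
    res_a = frame.residue(*pair.residue_a)
    res_b = frame.residue(*pair.residue_b)
    _check_opposite_signs(res_a, res_b, pair, scheme)
    if criterion.mode == "anchor_carbon":
        group_a = scheme.group_for(res_a, pair.terminus_a)
        group_b = scheme.group_for(res_b, pair.terminus_b)
        dmin = min(
            float(np.linalg.norm(res_a.atom(na).position - res_b.atom(nb).position))
            for na in group_a.anchor_carbons
            for nb in group_b.anchor_carbons
        )
        return dmin < criterion.cutoff
    center_a = charged_group_center(res_a, scheme, pair.terminus_a)
    center_b = charged_group_center(res_b, scheme, pair.terminus_b)
    return float(np.linalg.norm(center_a - center_b)) < criterion.cutoff


def _anchor_columns(traj: Trajectory, pair: PairSpec, scheme: ChargedGroupScheme):
    res_a = traj.topology.residue(*pair.residue_a)
    res_b = traj.topology.residue(*pair.residue_b)
    _check_opposite_signs(res_a, res_b, pair, scheme)
    group_a = scheme.group_for(res_a, pair.terminus_a)
    group_b = scheme.group_for(res_b, pair.terminus_b)
    cols_a = [traj.atom_column(*pair.residue_a, n) for n in group_a.anchor_carbons]
    cols_b = [traj.atom_column(*pair.residue_b, n) for n in group_b.anchor_carbons]
    return cols_a, cols_b


def _center_track(traj: Trajectory, key: tuple[str, int], terminus, scheme):
    res = traj.topology.residue(*key)
    group = scheme.group_for(res, terminus)
    cols = [traj.atom_column(*key, n) for n in group.charged_atoms]
    weights = np.array([res.atom(n).mass for n in group.charged_atoms])
    pts = traj.coords[:, cols, :]  # (n_frames, n_charged, 3)
    return np.average(pts, axis=1, weights=weights)


def _pair_distances(
    traj: Trajectory,
    pair: PairSpec,
    scheme: ChargedGroupScheme,
    metric: str,
) -> np.ndarray:
    if metric == "anchor_min":
        cols_a, cols_b = _anchor_columns(traj, pair, scheme)
        pa = traj.coords[:, cols_a, :]  # (n, 2, 3)
        pb = traj.coords[:, cols_b, :]
        diff = pa[:, :, None, :] - pb[:, None, :, :]  # (n, 2, 2, 3)
        return np.linalg.norm(diff, axis=-1).min(axis=(1, 2))
    if metric == "center":
        ca = _center_track(traj, pair.residue_a, pair.terminus_a, scheme)
        cb = _center_track(traj, pair.residue_b, pair.terminus_b, scheme)
        return np.linalg.norm(ca - cb, axis=-1)
    raise ValidationError(f"unknown distance metric {metric!r}")


def state_series(
    traj: Trajectory,
    pair: PairSpec,
    criterion: ContactCriterion,
    scheme: ChargedGroupScheme,
) -> StateSeries:
    """Per-frame contact states over a whole trajectory (vectorised route).

    Equivalent to applying :func:`contact_state` frame by frame, in order.
    """
    metric = "anchor_min" if criterion.mode == "anchor_carbon" else "center"
    dist = _pair_distances(traj, pair, scheme, metric)
    return StateSeries(pair, dist < criterion.cutoff)


def occupancy(series: StateSeries) -> float:
    """Fraction of frames in which the bridge is formed."""
    if len(series) == 0:
        raise ValidationError("cannot compute occupancy of an empty series")
    return float(np.mean(series.states))


def any_of_occupancy(series_set: list[StateSeries]) -> float:
    """Fraction of frames in which at least one member bridge is formed."""
    if not series_set:
        raise ValidationError("need at least one series")
    lengths = {len(s) for s in series_set}
    if len(lengths) != 1:
        raise ValidationError(f"series length mismatch: {sorted(lengths)}")
    if 0 in lengths:
        raise ValidationError("cannot compute occupancy of empty series")
    stacked = np.stack([s.states for s in series_set])
    return float(np.mean(np.any(stacked, axis=0)))


#: The two bridges anchoring the C-terminal helix to the domain core
#: (protein-chain residue indices in full-length numbering).
HELIX_ANCHOR_BRIDGES = ((334, 399), (355, 401))


def helix_anchor_pairs(protein_chain: str = "A") -> list[PairSpec]:
    return [
        PairSpec((protein_chain, i), (protein_chain, j), category="alpha3-domain")
        for i, j in HELIX_ANCHOR_BRIDGES
    ]


def helix_undocked_fraction(
    traj: Trajectory,
    criterion: ContactCriterion,
    scheme: ChargedGroupScheme,
    protein_chain: str = "A",
) -> float:
    """Fraction of frames in which neither helix-anchoring bridge is formed.

    Frames with at least one of the 334-399 / 355-401 bridges formed count as
    helix-docked; this returns 1 minus the any-of occupancy of the two.
    """
    series = [
        state_series(traj, p, criterion, scheme)
        for p in helix_anchor_pairs(protein_chain)
    ]
    return 1.0 - any_of_occupancy(series)


@dataclass
class CriterionComparison:
    agreement: float
    occupancy_anchor: float
    occupancy_center: float


def criterion_agreement(
    traj: Trajectory,
    pair: PairSpec,
    scheme: ChargedGroupScheme,
    anchor: ContactCriterion | None = None,
    center: ContactCriterion | None = None,
) -> CriterionComparison:
    """Frame-wise agreement between the two contact criteria for one pair."""
    anchor = anchor or ContactCriterion.anchor_carbon()
    center = center or ContactCriterion.charged_center()
    sa = state_series(traj, pair, anchor, scheme)
    sc = state_series(traj, pair, center, scheme)
    agreement = float(np.mean(sa.states == sc.states))
    return CriterionComparison(agreement, occupancy(sa), occupancy(sc))


def distance_series(
    traj: Trajectory,
    residue_a: tuple[str, int],
    residue_b: tuple[str, int],
    scheme: ChargedGroupScheme,
    metric: str = "anchor_min",
    terminus_a: str | None = None,
    terminus_b: str | None = None,
) -> pd.DataFrame:
    """Per-frame distance between two charged groups.

    Returns a two-column frame (time_ps, distance_A), ready for TSV export.
    """
    pair = PairSpec(residue_a, residue_b, terminus_a=terminus_a, terminus_b=terminus_b)
    dist = _pair_distances(traj, pair, scheme, metric)
    return pd.DataFrame({"time_ps": traj.times, "distance_A": dist})


@dataclass
class OccupancyTable:
    """Per-pair and aggregate bridge frequencies (fractions in [0, 1])."""

    rows: pd.DataFrame  # columns: label, category, frequency
    n_frames: int
    criterion: ContactCriterion
    series: dict[str, StateSeries] = field(default_factory=dict)

    def frequency(self, label: str) -> float:
        match = self.rows.loc[self.rows["label"] == label, "frequency"]
        if match.empty:
            raise KeyError(label)
        return float(match.iloc[0])

    def to_tsv(self) -> str:
        out = self.rows.copy()
        out["percent"] = (100.0 * out["frequency"]).map(lambda v: f"{v:.1f}%")
        header = (
            f"# n_frames={self.n_frames}\tcriterion={self.criterion.mode}"
            f"\tcutoff={self.criterion.cutoff:g}\n"
        )
        return header + out[["category", "label", "percent"]].to_csv(
            sep="\t", index=False
        )


def occupancy_table(
    traj: Trajectory,
    pairs: list[PairSpec],
    aggregates: dict[str, list[str]] | None = None,
    criterion: ContactCriterion | None = None,
    scheme: ChargedGroupScheme | None = None,
) -> OccupancyTable:
    """Occupancy of each pair plus named any-of aggregates over pair labels."""
    from .structure import default_scheme

    criterion = criterion or ContactCriterion.anchor_carbon()
    scheme = scheme or default_scheme()
    series: dict[str, StateSeries] = {}
    records = []
    for pair in pairs:
        s = state_series(traj, pair, criterion, scheme)
        if pair.name in series:
            raise ValidationError(f"duplicate pair label {pair.name!r}")
        series[pair.name] = s
        records.append(
            {"category": pair.category, "label": pair.name, "frequency": occupancy(s)}
        )
    for agg_name, member_labels in (aggregates or {}).items():
        members = []
        for label in member_labels:
            if label not in series:
                raise ValidationError(
                    f"aggregate {agg_name!r} references unknown pair {label!r}"
                )
            members.append(series[label])
        records.append(
            {
                "category": "aggregate",
                "label": agg_name,
                "frequency": any_of_occupancy(members),
            }
        )
    rows = pd.DataFrame(records, columns=["category", "label", "frequency"])
    return OccupancyTable(rows, traj.n_frames, criterion, series)
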