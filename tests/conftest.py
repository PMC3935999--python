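import numpy as np
import pytest

from pdzkit.saltbridge import PairSpec
from pdzkit.structure import (
    Atom,
    Residue,
    Structure,
    Trajectory,
    default_scheme,
)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


def make_residue(code, index, chain, atoms):
    """atoms: dict name -> (element, position)."""
    res = Residue(code, index, chain)
    for name, (element, pos) in atoms.items():
        res.add_atom(Atom(name, element, np.asarray(pos, dtype=float)))
    return res


def lys_residue(index=355, chain="A", tip=(0.0, 0.0, 0.0), u=(1.0, 0.0, 0.0)):
    """A Lys side-chain group: CE at tip, CD 1.5 Å behind, NZ 0.5 Å ahead."""
    tip = np.asarray(tip, float)
    u = np.asarray(u, float)
    return make_residue(
        "LYS",
        index,
        chain,
        {
            "CD": ("C", tip - 1.5 * u),
            "CE": ("C", tip),
            "NZ": ("N", tip + 0.5 * u),
        },
    )


def glu_residue(index=334, chain="A", tip=(0.0, 0.0, 0.0), u=(1.0, 0.0, 0.0)):
    """A Glu carboxylate: CD at tip, CG behind, OE1/OE2 center 0.5 Å ahead."""
    tip = np.asarray(tip, float)
    u = np.asarray(u, float)
    perp = np.array([-u[1], u[0], 0.0])
    if not perp.any():
        perp = np.array([1.0, 0.0, 0.0])
    q = tip + 0.5 * u
    return make_residue(
        "GLU",
        index,
        chain,
        {
            "CG": ("C", tip - 1.5 * u),
            "CD": ("C", tip),
            "OE1": ("O", q + 0.55 * perp),
            "OE2": ("O", q - 0.55 * perp),
        },
    )


def pair_frame(distance):
    """Glu A334 tip at origin pointing +x, Lys B-5 tip at (distance, 0, 0)
    pointing -x.  Minimum anchor cross-distance is exactly `distance`;
    charged centers are 1 Å closer (distance - 1.0)."""
    glu = glu_residue(334, "A", tip=(0, 0, 0), u=(1, 0, 0))
    lys = lys_residue(-5, "B", tip=(distance, 0.0, 0.0), u=(-1.0, 0.0, 0.0))
    return Structure([glu, lys])


def pair_trajectory(distances, frame_interval=2.0):
    """Trajectory of pair_frame geometries at the given per-frame distances."""
    frames = [pair_frame(d) for d in distances]
    return Trajectory.from_structures(frames, frame_interval=frame_interval)


GLU_LYS_PAIR = PairSpec(("A", 334), ("B", -5), category="ligand-b2b3-loop")


def markov_effective_sigma(pi, dwell, n):
    """Binomial sigma corrected for two-state-chain autocorrelation.

    The chain's non-unit eigenvalue is lam = 1 - p10 - p01 with p10 = 1/dwell
    and p01 = pi/(dwell (1-pi)); the variance of the occupancy estimate is
    inflated by (1+lam)/(1-lam).
    """
    p10 = 1.0 / dwell
    p01 = pi * p10 / (1.0 - pi)
    lam = 1.0 - p10 - p01
    n_eff = n * (1.0 - lam) / (1.0 + lam)
    return np.sqrt(pi * (1.0 - pi) / n_eff)
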