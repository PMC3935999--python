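"""Structures, trajectories and charged-group chemistry.

Coordinates are in Å throughout.  Residue numbering is taken verbatim from
the input: by convention the protein chain spans indices 302-403 (full-length
PSD-95 numbering) and the hexapeptide ligand chain spans -5..0, with 0 the
C-terminal residue.  Nothing is ever re-indexed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data.IUPACData import atom_weights
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .errors import (
    IncompleteResidueError,
    NotApplicableError,
    PDBParseError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "ChargedGroup",
    "ChargedGroupScheme",
    "default_scheme",
    "parse_structure",
    "parse_trajectory",
    "write_structure",
    "write_trajectory",
    "anchor_atoms",
    "charged_group_center",
    "mass_delta_cyclization",
    "validate_numbering",
]

# Monoisotopic masses (Da); average masses come from Bio.Data.IUPACData.
_MONOISOTOPIC = {"H": 1.0078250319, "O": 15.9949146221}

#: Default chain tags: "A" = protein, "B" = ligand (overridable in config).
PROTEIN_CHAIN = "A"
LIGAND_CHAIN = "B"

PROTEIN_INDEX_RANGE = (302, 403)
LIGAND_INDEX_RANGE = (-5, 0)


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        if not self.name:
            raise ValidationError("atom name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValidationError(f"atom {self.name}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValidationError(f"atom {self.name}: non-finite coordinates")
        object.__setattr__(self, "position", pos)

    @property
    def mass(self) -> float:
        return atom_weights[self.element.capitalize()]


@dataclass
class Residue:
    """One residue; ``atoms`` is keyed by atom name (unique within a residue)."""

    code: str
    index: int
    chain: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    modification: str | None = None  # None | "phospho-Tyr" | "succinimide"

    def add_atom(self, atom: Atom) -> None:
        if atom.name in self.atoms:
            raise ValidationError(
                f"duplicate atom {atom.name!r} in residue ({self.chain}, {self.index})"
            )
        self.atoms[atom.name] = atom

    def atom(self, name: str) -> Atom:
        try:
            return self.atoms[name]
        except KeyError:
            raise IncompleteResidueError(self.chain, self.index, name) from None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.index)


class Structure:
    """An ordered collection of residues with unique (chain, index) keys."""

    def __init__(self, residues: list[Residue], title: str = ""):
        self.residues = list(residues)
        self.title = title
        self._by_key: dict[tuple[str, int], Residue] = {}
        for res in self.residues:
            if res.key in self._by_key:
                raise ValidationError(f"duplicate residue key {res.key}")
            self._by_key[res.key] = res

    def residue(self, chain: str, index: int) -> Residue:
        try:
            return self._by_key[(chain, index)]
        except KeyError:
            raise ValidationError(
                f"no residue ({chain}, {index}) in structure"
            ) from None

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self.residues)

    def atom_keys(self) -> list[tuple[str, int, str]]:
        """Flat (chain, residue index, atom name) keys in deterministic order."""
        return [
            (res.chain, res.index, name)
            for res in self.residues
            for name in res.atoms
        ]

    def coordinates(self) -> np.ndarray:
        return np.array(
            [a.position for res in self.residues for a in res.atoms.values()]
        )


class Trajectory:
    """Ordered frames over a fixed topology.

    Stored as a template :class:`Structure` plus an (n_frames, n_atoms, 3)
    coordinate array, so very long synthetic trajectories stay cheap; frames
    are materialised as Structures on demand.
    """

    def __init__(self, topology: Structure, coords: np.ndarray, frame_interval: float = 2.0):
        coords = np.asarray(coords, dtype=float)
        n_atoms = len(topology.atom_keys())
        if coords.ndim != 3 or coords.shape[1:] != (n_atoms, 3):
            raise TopologyError(
                f"coordinate array {coords.shape} does not match topology "
                f"({n_atoms} atoms)"
            )
        if coords.shape[0] < 1:
            raise ValidationError("trajectory needs at least one frame")
        if not frame_interval > 0:
            raise ValidationError("frame_interval must be > 0")
        self.topology = topology
        self.coords = coords
        self.frame_interval = float(frame_interval)
        self._atom_index = {k: i for i, k in enumerate(topology.atom_keys())}

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def atom_column(self, chain: str, index: int, name: str) -> int:
        try:
            return self._atom_index[(chain, index, name)]
        except KeyError:
            raise IncompleteResidueError(chain, index, name) from None

    def frame(self, i: int) -> Structure:
        xyz = self.coords[i]
        residues = []
        k = 0
        for res in self.topology.residues:
            new = Residue(res.code, res.index, res.chain, {}, res.modification)
            for name, atom in res.atoms.items():
                new.atoms[name] = replace(atom, position=xyz[k])
                k += 1
            residues.append(new)
        return Structure(residues, title=f"frame {i}")

    def frames(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_structures(cls, frames: list[Structure], frame_interval: float = 2.0) -> "Trajectory":
        if not frames:
            raise ValidationError("trajectory needs at least one frame")
        ref_keys = frames[0].atom_keys()
        coords = np.empty((len(frames), len(ref_keys), 3))
        for i, frame in enumerate(frames):
            if frame.atom_keys() != ref_keys:
                missing = set(ref_keys) ^ set(frame.atom_keys())
                raise TopologyError(
                    f"frame {i} topology differs from frame 0 "
                    f"(mismatched keys: {sorted(missing)[:5]})"
                )
            coords[i] = frame.coordinates()
        return cls(frames[0], coords, frame_interval)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _infer_modification(resname: str) -> tuple[str, str | None]:
    # Modified residues keep a standard 3-letter code plus a tag so that
    # wild-type tooling still reads the files; PTR/SNN aliases are accepted.
    if resname == "PTR":
        return "TYR", "phospho-Tyr"
    if resname == "SNN":
        return "ASP", "succinimide"
    return resname, None


def _biopdb_models(text: str):
    parser = PDBParser(PERMISSIVE=False, QUIET=False)
    handle = io.StringIO(text)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure("pdzkit", handle)
    except PDBConstructionException as exc:
        msg = str(exc)
        if "defined twice" in msg:
            raise ValidationError(msg) from exc
        raise PDBParseError(msg) from exc
    return list(structure.get_models())


def _model_to_structure(model, title: str = "") -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            code, modification = _infer_modification(res.get_resname().strip())
            out = Residue(code, res.get_id()[1], chain.get_id(), {}, modification)
            for atom in res:
                element = atom.element if atom.element else atom.get_name()[0]
                out.add_atom(Atom(atom.get_name(), element, atom.get_coord()))
            residues.append(out)
    return Structure(residues, title=title)


def parse_structure(text: str) -> Structure:
    """Parse a single-model PDB document into a :class:`Structure`."""
    models = _biopdb_models(text)
    if not models:
        raise PDBParseError("no ATOM/HETATM records found")
    return _model_to_structure(models[0])


def parse_trajectory(text: str, frame_interval: float = 2.0) -> Trajectory:
    """Parse a multi-model PDB into a :class:`Trajectory` (frames in file order).

    All MODEL blocks must share the topology of the first; a missing or extra
    atom raises :class:`TopologyError`.
    """
    models = _biopdb_models(text)
    if not models:
        raise PDBParseError("no MODEL blocks or ATOM records found")
    frames = [_model_to_structure(m) for m in models]
    return Trajectory.from_structures(frames, frame_interval=frame_interval)


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    if len(name) < 4:
        # Standard PDB convention: columns 13-16, 1-letter elements indented.
        name = f" {name}" if len(atom.element) == 1 else name
    x, y, z = atom.position
    resname = {"phospho-Tyr": "PTR", "succinimide": "SNN"}.get(
        res.modification, res.code
    )
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {res.chain:1s}"
        f"{res.index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {atom.element.upper():>2s}"
    )


def write_structure(structure: Structure) -> str:
    lines = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    serial = 0
    for res in structure.residues:
        for atom in res.atoms.values():
            serial += 1
            lines.append(_format_atom_line(serial, atom, res))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_trajectory(traj: Trajectory) -> str:
    lines = []
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        lines.append(f"MODEL     {i + 1:4d}")
        serial = 0
        for res in frame.residues:
            for atom in res.atoms.values():
                serial += 1
                lines.append(_format_atom_line(serial, atom, res))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def validate_numbering(
    structure: Structure,
    protein_chain: str = PROTEIN_CHAIN,
    ligand_chain: str = LIGAND_CHAIN,
) -> None:
    """Enforce the domain numbering conventions (protein 302-403, ligand -5..0)."""
    errors = []
    for res in structure.residues:
        if res.chain == protein_chain:
            lo, hi = PROTEIN_INDEX_RANGE
        elif res.chain == ligand_chain:
            lo, hi = LIGAND_INDEX_RANGE
        else:
            continue
        if not lo <= res.index <= hi:
            errors.append(
                f"residue ({res.chain}, {res.index}) outside [{lo}, {hi}]"
            )
    if errors:
        raise ValidationError("; ".join(errors))


# ---------------------------------------------------------------------------
# Charged-group chemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargedGroup:
    """A formally charged group plus its two chain-terminal anchor carbons."""

    sign: int  # +1 or -1
    charged_atoms: tuple[str, ...]
    anchor_carbons: tuple[str, str]

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValidationError("charged-group sign must be +1 or -1")
        if len(self.anchor_carbons) != 2:
            raise ValidationError("exactly two anchor carbons are required")
        if not self.charged_atoms:
            raise ValidationError("charged_atoms must be non-empty")


class ChargedGroupScheme:
    """Lookup from residue chemistry to its charged group.

    Keys are residue codes ("LYS"), modification tags ("phospho-Tyr") or
    terminal group labels ("N-terminus", "N-terminus:GLY", "C-terminus").
    Modification tags take precedence over the residue code; a succinimide
    tag removes the Asp side-chain charge entirely.
    """

    def __init__(self, groups: dict[str, ChargedGroup]):
        self.groups = dict(groups)

    def group_for(self, residue: Residue, terminus: str | None = None) -> ChargedGroup:
        if terminus == "N":
            key = f"N-terminus:{residue.code}"
            group = self.groups.get(key) or self.groups.get("N-terminus")
            if group is None:
                raise NotApplicableError("no N-terminal group in scheme")
            return group
        if terminus == "C":
            group = self.groups.get("C-terminus")
            if group is None:
                raise NotApplicableError("no C-terminal group in scheme")
            return group
        if residue.modification == "succinimide":
            raise NotApplicableError(
                f"succinimide residue ({residue.chain}, {residue.index}) "
                "carries no side-chain charge"
            )
        if residue.modification and residue.modification in self.groups:
            return self.groups[residue.modification]
        if residue.code in self.groups:
            return self.groups[residue.code]
        raise NotApplicableError(
            f"residue type {residue.code} carries no charged side chain"
        )

    def sign(self, residue: Residue, terminus: str | None = None) -> int:
        return self.group_for(residue, terminus).sign


def default_scheme() -> ChargedGroupScheme:
    """The default anchor-carbon table.

    Anchors are "the two last carbons before the charged atoms", walked back
    along the covalent chain of each side chain or terminus.  The phospho-Tyr
    entry is a documented configurable choice (ring carbons flanking CZ).
    """
    return ChargedGroupScheme(
        {
            "LYS": ChargedGroup(+1, ("NZ",), ("CD", "CE")),
            "ARG": ChargedGroup(+1, ("NE", "NH1", "NH2"), ("CD", "CZ")),
            "GLU": ChargedGroup(-1, ("OE1", "OE2"), ("CG", "CD")),
            "ASP": ChargedGroup(-1, ("OD1", "OD2"), ("CB", "CG")),
            "HIS": ChargedGroup(+1, ("ND1", "NE2"), ("CB", "CG")),
            "N-terminus": ChargedGroup(+1, ("N",), ("CA", "CB")),
            "N-terminus:GLY": ChargedGroup(+1, ("N",), ("CA", "C")),
            "C-terminus": ChargedGroup(-1, ("O", "OXT"), ("CA", "C")),
            "phospho-Tyr": ChargedGroup(-1, ("O1P", "O2P", "O3P"), ("CE1", "CE2")),
        }
    )


def anchor_atoms(
    residue: Residue,
    scheme: ChargedGroupScheme,
    terminus: str | None = None,
) -> frozenset[str]:
    """The two anchor-carbon names for the residue's charged group."""
    return frozenset(scheme.group_for(residue, terminus).anchor_carbons)


def charged_group_center(
    residue: Residue,
    scheme: ChargedGroupScheme,
    terminus: str | None = None,
) -> np.ndarray:
    """Mass-weighted center of the charged atoms of the residue's group."""
    group = scheme.group_for(residue, terminus)
    masses = []
    positions = []
    for name in group.charged_atoms:
        atom = residue.atom(name)  # raises IncompleteResidueError if missing
        masses.append(atom.mass)
        positions.append(atom.position)
    masses = np.asarray(masses)
    return np.average(np.asarray(positions), axis=0, weights=masses)


def mass_delta_cyclization(mass_scale: str = "average") -> float:
    """Mass of one water molecule, lost upon Asp -> succinimide condensation."""
    if mass_scale == "average":
        return 2 * atom_weights["H"] + atom_weights["O"]
    if mass_scale == "monoisotopic":
        return 2 * _MONOISOTOPIC["H"] + _MONOISOTOPIC["O"]
    raise ValueError(f"unknown mass scale {mass_scale!r}")
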