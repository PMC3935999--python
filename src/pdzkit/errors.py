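"""Exception hierarchy shared by all pdzkit modules."""


class PdzkitError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(PdzkitError):
    """A structure/trajectory document could not be parsed."""


class TopologyError(PdzkitError):
    """Trajectory frames do not share an identical residue/atom topology."""


class ValidationError(PdzkitError):
    """A domain object violates one of its invariants."""


class IncompleteResidueError(PdzkitError):
    """A residue lacks an atom required by the requested computation."""

    def __init__(self, chain: str, index: int, atom: str):
        self.chain = chain
        self.index = index
        self.atom = atom
        super().__init__(
            f"residue ({chain}, {index}) is missing required atom {atom!r}"
        )


class NotApplicableError(PdzkitError):
    """The requested charged-group operation does not apply to this residue."""


class FitConvergenceError(PdzkitError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        self.last_iterate = last_iterate
        super().__init__(message)


class ConfigError(PdzkitError):
    """A run configuration failed validation; carries all violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
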