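"""Exception hierarchy shared across the package."""


class SiteAlignError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SiteAlignError, ValueError):
    """An input violates a documented precondition."""


class ParseError(SiteAlignError):
    """A structure file could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class LigandNotFoundError(SiteAlignError):
    """The requested ligand residue is absent; lists available HETATM names."""

    def __init__(self, selector: str, available: list[str]):
        self.selector = selector
        self.available = available
        super().__init__(
            f"ligand {selector!r} not found; available HETATM residues: "
            + (", ".join(available) if available else "(none)")
        )


class InfeasibleGraphError(SiteAlignError):
    """Some query atom has no compatible target atom under the label filter."""

    def __init__(self, p_index: int, label: str):
        self.p_index = p_index
        self.label = label
        super().__init__(
            f"query atom {p_index} (label {label}) has no compatible target atom; "
            "use all-pairs or relaxed compatibility mode"
        )


class InfeasibleAssignmentError(SiteAlignError):
    """No injective assignment exists on the given cost graph."""


class DegenerateCandidateError(SiteAlignError):
    """A trial 7-vector has a (near-)zero quaternion part and cannot be normalized."""


class UndefinedScoreError(SiteAlignError):
    """A score (RMSD, SAS, AUC) is undefined for the given input."""
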