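"""Exception hierarchy for solvcontact."""


class SolvContactError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedElementError(SolvContactError):
    """A structure contains an element outside the supported set."""

    def __init__(self, element: str, context: str = ""):
        self.element = element
        msg = f"unsupported element {element!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class AtomTypingError(SolvContactError):
    """An atom matched no typing rule in the active scheme."""

    def __init__(self, atom_index: int, environment: str, scheme: str):
        self.atom_index = atom_index
        self.environment = environment
        self.scheme = scheme
        super().__init__(
            f"atom {atom_index}: environment {environment!r} has no type "
            f"code in scheme {scheme!r}"
        )


class ParameterCoverageError(SolvContactError):
    """A required atom-type code is missing from a parameter table."""

    def __init__(self, code: str, scheme: str):
        self.code = code
        super().__init__(f"type code {code!r} not present in table {scheme!r}")


class TableValidationError(SolvContactError):
    """A bundled or user parameter table failed schema validation."""


class ConsistencyError(SolvContactError):
    """Cross-object bookkeeping mismatch (misaligned volumes, foreign contacts...)."""
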