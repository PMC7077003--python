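"""Exception hierarchy shared across the package."""


class DmsBenchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DmsBenchError):
    """A run or method configuration is inconsistent or incomplete."""


class ValidationError(DmsBenchError):
    """Input data violates an invariant (bad alphabet, conflicting rows, out-of-range score)."""


class FormatError(DmsBenchError):
    """A file does not conform to its expected dialect."""


class SequenceMismatchError(ValidationError):
    """Variant wild-type residues disagree with the reference sequence beyond tolerance."""

    def __init__(self, message: str, positions: list[int]):
        super().__init__(message)
        self.positions = positions


class RefusalError(DmsBenchError):
    """A computation declined to produce a result (too little data, empty
    intersection, single-class labels, undefined statistic)."""
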