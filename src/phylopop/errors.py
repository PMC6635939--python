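"""Exception hierarchy shared across the package."""


class PhylopopError(Exception):
    """Base class for all package-specific errors."""


class InputError(PhylopopError):
    """Malformed or invalid user input (files, tables, parameters)."""


class AlignmentError(InputError):
    """Sequences violate alignment invariants (ragged lengths, bad symbols)."""


class ConsistencyError(PhylopopError):
    """Two inputs that must agree (alignment vs. population map) do not."""


class EstimationError(PhylopopError):
    """A statistic is undefined for the given data (e.g. S=0, HT=0)."""
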