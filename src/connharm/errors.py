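"""Exception hierarchy for connharm."""


class ConnharmError(Exception):
    """Base class for all connharm errors."""


class InvalidInputError(ConnharmError, ValueError):
    """An input violates a documented precondition."""


class InvalidFixtureError(InvalidInputError):
    """A synthetic-fixture request is infeasible."""


class DegenerateMapError(InvalidInputError):
    """A per-vertex map is degenerate (e.g. constant) for the requested operation."""


class NumericalError(ConnharmError, RuntimeError):
    """A numerical routine failed to converge or diverged."""


class ParseError(ConnharmError, ValueError):
    """An on-disk artifact could not be parsed."""
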