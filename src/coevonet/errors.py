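"""Exception hierarchy used across the package."""


class CoevonetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CoevonetError):
    """Invalid user-supplied configuration (bad column index, empty grid, ...)."""


class FormatError(CoevonetError):
    """Malformed input file (ragged alignment, unparseable record, ...)."""


class DegenerateInputError(CoevonetError):
    """Input is structurally valid but the requested quantity is undefined
    (all columns trimmed away, zero-edge graph for modularity, <2 nodes for
    path length, ...)."""


class GenerationError(CoevonetError):
    """The synthetic-data generator could not realize the requested geometry."""
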