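"""Exception hierarchy for rinmd."""


class RinmdError(Exception):
    """Base class for all rinmd errors."""


class FormatError(RinmdError):
    """A structure/topology/trajectory/parameter file could not be parsed."""


class UnsupportedDialectError(FormatError):
    """A file dialect or feature (e.g. DCD fixed-atom blocks) is not supported."""


class EmptySystemError(RinmdError):
    """An operation produced or received a system with no residues."""


class TopologyInconsistencyError(RinmdError):
    """Topology and coordinates (or two graphs) disagree on atoms/nodes."""


class ConfigurationError(RinmdError):
    """A required parameter, charge or LJ assignment is missing or invalid."""


class GenerationError(RinmdError):
    """A synthetic fixture request is unsatisfiable."""
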