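"""Exception hierarchy for cyclobind."""


class CyclobindError(Exception):
    """Base class for all cyclobind errors."""


class StructureParseError(CyclobindError):
    """A structure file could not be parsed."""


class TrajectoryError(CyclobindError):
    """Inconsistent multi-model trajectory input."""


class TopologyError(CyclobindError):
    """Cyclodextrin topology could not be identified."""


class GeometryError(CyclobindError):
    """Degenerate geometry prevents a descriptor from being computed."""


class ParameterError(CyclobindError):
    """Invalid or inconsistent numerical parameters."""
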