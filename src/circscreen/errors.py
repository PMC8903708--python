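"""Exception hierarchy shared across the pipeline stages."""


class CircscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(CircscreenError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(CircscreenError, ValueError):
    """An input file is malformed; message carries the offending location."""


class AnalysisError(CircscreenError, ValueError):
    """An analysis stage received data it cannot meaningfully process."""


class GenerationError(CircscreenError, RuntimeError):
    """A synthetic-data spec is infeasible (e.g. colliding codon constraints)."""


class ContractError(CircscreenError, ValueError):
    """A function received input violating its documented contract."""
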