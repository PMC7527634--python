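"""Exception hierarchy shared by all recspot modules."""


class RecspotError(Exception):
    """Base class for all recspot errors."""


class ValidationError(RecspotError):
    """A sequence or record violates an invariant (alphabet, duplicate id, ...)."""


class FastaParseError(RecspotError):
    """The input file is not FASTA-formatted; message names the offending line."""


class ParameterError(RecspotError):
    """A parameter is outside its documented domain."""


class SequenceTooShortError(RecspotError):
    """A sequence is too short for the requested feature extraction."""


class AlignmentError(RecspotError):
    """Feature blocks do not cover the same samples in the same order."""


class ShapeError(RecspotError):
    """An array has an incompatible shape for the network or matrix operation."""


class DivergenceError(RecspotError):
    """Training produced a non-finite loss; message names the iteration."""


class DegenerateMetricError(RecspotError):
    """A metric denominator is identically zero (e.g. a class is absent)."""
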