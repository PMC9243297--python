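"""Exception hierarchy shared across the toolkit."""


class SelexError(Exception):
    """Base class for all selexkit errors."""


class ParseError(SelexError):
    """A sequence or metadata file could not be parsed."""


class ValidationError(SelexError):
    """An input violated a documented invariant."""


class PCRError(SelexError):
    """In-silico PCR failed (no annealing site, ambiguity, or orientation)."""


class KmerLimitError(SelexError):
    """Requested k exceeds the supported k-mer length (k <= 10)."""


class SimulationError(SelexError):
    """The SELEX simulator reached an unrecoverable state."""


class CoverageError(SelexError):
    """Sub-sampling / rank-concordance analysis received invalid input."""
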