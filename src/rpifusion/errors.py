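"""Exception hierarchy for the rpifusion pipeline.

Every stage raises a named error; the CLI maps each class to a distinct
exit code so shell callers can branch on the failure kind.
"""


class RpifusionError(Exception):
    """Base class for all package errors."""


# --- input parsing / validation -----------------------------------------

class MalformedFasta(RpifusionError):
    """FASTA file could not be parsed into records."""


class AlphabetError(RpifusionError):
    """A sequence contains characters outside its declared alphabet."""


class DuplicatePair(RpifusionError):
    """The same (rna_id, protein_id) row appears more than once."""


class UnknownId(RpifusionError):
    """An interaction pair references an id with no loaded sequence."""


class ScoreRangeError(RpifusionError):
    """A PPI edge score falls outside [0, 1]."""


class SymbolError(RpifusionError):
    """A structure string contains an unknown symbol."""


# --- encoding ------------------------------------------------------------

class DimensionError(RpifusionError):
    """A feature vector has the wrong length for the requested operation."""


class EmptySeries(RpifusionError):
    """The cosine transform received a zero-length series."""


class SequenceTooShort(RpifusionError):
    """Sequence shorter than the minimum the encoder requires."""


class DegenerateProperty(RpifusionError):
    """A physicochemical property is constant across its units."""


# --- selection / training -----------------------------------------------

class SingleClassError(RpifusionError):
    """Labels contain fewer than two classes."""


class FractionRangeError(RpifusionError):
    """Retain fraction outside (0, 1]."""


class ConfigError(RpifusionError):
    """Invalid model or simulation configuration."""


class StrategyError(RpifusionError):
    """Unknown feature-fusion strategy name."""


class TooFewSamples(RpifusionError):
    """Not enough samples per class for the requested CV split."""


class ExhaustedSpace(RpifusionError):
    """Negative sampling cannot find enough non-positive pairs."""


#: CLI exit codes, one per error family (0 = success, 1 = unexpected).
EXIT_CODES = {
    MalformedFasta: 10,
    AlphabetError: 11,
    DuplicatePair: 12,
    UnknownId: 13,
    ScoreRangeError: 14,
    SymbolError: 15,
    DimensionError: 20,
    EmptySeries: 21,
    SequenceTooShort: 22,
    DegenerateProperty: 23,
    SingleClassError: 30,
    FractionRangeError: 31,
    ConfigError: 32,
    StrategyError: 33,
    TooFewSamples: 34,
    ExhaustedSpace: 35,
}
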