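"""Exception types shared across the package."""


class MirseedError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(MirseedError, ValueError):
    """A sequence contains a character outside {A,C,G,T,U,N}."""


class FastqParseError(MirseedError, ValueError):
    """A FASTQ file is structurally malformed (truncated or mislabelled record)."""


class ReferenceError_(MirseedError, ValueError):
    """A reference sequence violates a precondition (too short, duplicate id)."""


class ConfigurationError(MirseedError, ValueError):
    """Inconsistent run configuration (unknown sample, missing file, bad option)."""


class DegenerateLibraryError(MirseedError, ValueError):
    """A library has zero matched reads and cannot be normalized."""


class NormalizationError(MirseedError, ValueError):
    """Ct normalization is impossible (no reference-gene measurements)."""


class InsufficientReplicatesError(MirseedError, ValueError):
    """A statistical test was requested with fewer than two replicates per group."""


class UndefinedFoldChangeError(MirseedError, ZeroDivisionError):
    """Fold change requested against a zero control mean."""


class SpanError(MirseedError, ValueError):
    """A scan query is longer than its target."""


class IntegrityError(MirseedError, ValueError):
    """An internal record violates its structural invariant."""
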