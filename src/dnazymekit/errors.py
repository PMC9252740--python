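"""Exception hierarchy for dnazymekit.

Every error a user can trigger through bad input derives from
:class:`DnazymekitError`, so callers (and the CLI) can catch one type.
"""


class DnazymekitError(Exception):
    """Base class for all dnazymekit errors."""


class FormatError(DnazymekitError):
    """The input could not be parsed in the detected or requested format."""


class MultiRecordError(FormatError):
    """More than one sequence record was found; exactly one substrate per run."""

    def __init__(self, count: int):
        self.count = count
        super().__init__(
            f"input contains {count} sequence records; exactly one substrate "
            f"is accepted per run"
        )


class EmptySubstrateError(DnazymekitError):
    """Sanitization removed every character; no substrate remains."""


class SubstrateLengthError(DnazymekitError):
    """Substrate exceeds the 2000-nt maximum."""

    def __init__(self, length: int, limit: int = 2000):
        self.length = length
        self.limit = limit
        super().__init__(
            f"substrate is {length} nt after sanitization; the maximum "
            f"accepted length is {limit} nucleotides"
        )


class AlphabetConflictError(DnazymekitError):
    """A residue contradicts the declared substrate type (e.g. U in DNA)."""


class UnsupportedConversionError(DnazymekitError):
    """DNA<->RNA conversion requested for a chimeric substrate."""


class KnowledgeBaseError(DnazymekitError):
    """Knowledge-base file violates the documented schema."""


class ConfigurationError(DnazymekitError):
    """A mapping/config file is incomplete or contradictory."""


class DesignInfeasibleError(DnazymekitError):
    """No valid binding arms can be built for this site."""


class FilterSpecificationError(DnazymekitError):
    """A filter specification is self-contradictory (e.g. tm_min > tm_max)."""
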