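"""Exception hierarchy shared across the toolkit.

Exit-code mapping at the CLI: ``InputFormatError`` and ``ConfigError`` -> 2,
``ConsistencyError`` -> 3.
"""


class FinishkitError(Exception):
    """Base class for all toolkit errors."""


class InputFormatError(FinishkitError):
    """Malformed or unparseable input (bad character, bad record, ...)."""


class ConsistencyError(FinishkitError):
    """Inputs that parse but contradict each other (e.g. VCF REF vs FASTA)."""


class ConfigError(FinishkitError):
    """Infeasible or invalid configuration for a simulation or run."""


class AdjudicationError(FinishkitError):
    """A repeat-region read whose interior is not an integral tandem array."""
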