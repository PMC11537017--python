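"""Exception hierarchy for mrmediate.

Three failure classes are distinguished so that callers (and the CLI) can
map them onto distinct exit behaviour: configuration problems are user
errors in how a run was set up, input errors are problems with the data
supplied, and estimation errors arise when a statistical procedure cannot
produce a usable answer.
"""


class MRMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRMediateError):
    """A run was configured incorrectly (bad dialect, missing column, bad threshold)."""


class InputError(MRMediateError):
    """The supplied data cannot be analysed (empty intersection, too few SNPs)."""


class EstimationError(MRMediateError):
    """An estimator could not converge or produce a valid result."""
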