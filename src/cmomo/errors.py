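"""Exception hierarchy shared across the package."""


class CmomoError(Exception):
    """Base class for all package errors."""


class InvalidSmiles(CmomoError):
    """A SMILES string could not be parsed into a molecule."""


class EvaluationError(CmomoError):
    """An objective or constraint evaluator failed on a molecule."""


class BadAlertPattern(CmomoError):
    """A structural-alert SMARTS pattern failed to compile."""


class UnknownMolecule(CmomoError):
    """A table codec was asked to encode a molecule it does not contain."""


class CodecError(CmomoError):
    """A plug-in encoder/decoder failed."""


class DimensionMismatch(CmomoError):
    """Latent vectors (or objective vectors) of incompatible lengths."""


class BadParams(CmomoError):
    """Operation parameters violate a precondition."""


class EmptyPopulation(CmomoError):
    """An operation requiring a non-empty molecule set received none."""


class EmptyDatabase(CmomoError):
    """The candidate database for bank screening is empty."""


class NoSurvivors(CmomoError):
    """Bank screening eliminated every database molecule."""


class InitializationFailed(CmomoError):
    """Population initialization could not produce a single usable molecule."""


class ConfigError(CmomoError):
    """A run configuration is invalid; message names the offending field."""


class EmptyInput(CmomoError):
    """A metric was called with no result sets."""
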