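"""Exception hierarchy for the qebss package."""


class QEBSSError(Exception):
    """Base class for all qebss errors."""


class FormatError(QEBSSError):
    """A file could not be parsed in the expected format."""


class EmptyTrajectoryError(QEBSSError):
    """No frames remain after applying the equilibration skip."""


class MissingAmideHydrogenError(QEBSSError):
    """A requested residue has no backbone amide hydrogen."""


class GridMismatchError(QEBSSError):
    """Profiles or correlation functions live on incompatible grids."""


class EmptySelectionError(QEBSSError):
    """No simulation passed the comparison-number threshold."""


class ConfigError(QEBSSError):
    """Pipeline configuration is invalid or inconsistent."""
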