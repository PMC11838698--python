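"""Exception hierarchy.

``ConfigError`` marks bad configuration (wrong widths, invalid parameters);
``DataError`` marks bad inputs (unparsable SMILES, empty sequences, label
violations).  CLI maps both to a nonzero exit distinct from usage errors.
"""


class CoscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(CoscreenError):
    """Invalid configuration: widths, parameter ranges, duplicate names."""


class DataError(CoscreenError):
    """Invalid data: unparsable records, empty inputs, contract violations."""


class IntegrityError(CoscreenError):
    """Corrupt or incompatible persisted artifact (model file, index)."""
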