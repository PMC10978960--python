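"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (usage 1, parse 2, network 3,
internal 4).
"""


class SahhkitError(Exception):
    """Base class for all package errors."""


class InputError(SahhkitError):
    """Invalid or missing input data (empty sequence, absent ligand, ...)."""


class FormatError(SahhkitError):
    """Unparseable file content (coordinates, FASTA, peak tables)."""


class ConfigurationError(SahhkitError):
    """Invalid configuration: unknown keys, missing annotation, bad thresholds."""


class GeometryError(SahhkitError):
    """Degenerate or incomplete geometry (collinear points, missing atoms)."""


class MeasurementError(SahhkitError):
    """Assay tables that cannot be scored (e.g. all peak areas zero)."""


class GenerationError(SahhkitError):
    """Synthetic-fixture generation failed (infeasible geometry, bad spec)."""


class MappingError(SahhkitError):
    """No structure chain could be mapped onto the reference annotation."""


class NetworkError(SahhkitError):
    """A remote fetch failed or the network is unavailable."""


class MergeError(SahhkitError):
    """Conflicting identifiers while merging reports."""
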