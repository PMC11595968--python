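"""Exception hierarchy.

Every error raised by cleftus derives from :class:`CleftusError` so callers
can catch the package's failures with a single except clause while still
discriminating schema problems from data-integrity problems.
"""


class CleftusError(Exception):
    """Base class for all cleftus errors."""


class SchemaError(CleftusError):
    """A manifest or config file does not match the documented schema."""


class ReferentialError(CleftusError):
    """A cross-reference inside a manifest does not resolve."""


class IntegrityError(CleftusError):
    """On-disk data contradicts its declared metadata (frame counts, sizes)."""


class FormatError(CleftusError):
    """A file payload cannot be decoded as the expected format."""


class AlignmentError(CleftusError):
    """Temporal alignment between modalities failed for a chunk."""


class SamplingError(CleftusError):
    """Pair sampling constraints cannot be satisfied."""


class TrainingError(CleftusError):
    """Training diverged or was asked to run on unusable inputs."""


class DependencyError(CleftusError):
    """An optional runtime dependency (e.g. pretrained weights) is missing."""
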