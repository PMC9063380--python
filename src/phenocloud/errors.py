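"""Exception hierarchy."""


class PhenoCloudError(Exception):
    """Base class for all phenocloud errors."""


class LoadError(PhenoCloudError):
    """A point-cloud file could not be read or failed validation."""


class MeasurementError(PhenoCloudError):
    """An organ is too degenerate to measure (e.g. a leaf with < 5 points)."""
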