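"""Exception hierarchy shared across fluoroquant modules."""


class FluoroQuantError(Exception):
    """Base class for all fluoroquant errors."""


class ParameterizationError(FluoroQuantError, ValueError):
    """A generator or analysis parameter is outside its admissible range."""


class SaturationError(ParameterizationError):
    """Requested intensity would exceed the sensor bit depth."""


class DegenerateImageError(FluoroQuantError, ValueError):
    """Image has no contrast to segment (all pixels equal)."""


class EmptyPlantError(FluoroQuantError, ValueError):
    """No valid foreground pixels to summarize."""


class ConfigurationError(FluoroQuantError, ValueError):
    """Invalid analysis configuration (unknown colormap, bad bin width, ...)."""


class FormatError(FluoroQuantError, ValueError):
    """Malformed on-disk data (axes, shapes, negative intensities, ...)."""


class InsufficientReplicationError(FluoroQuantError, ValueError):
    """Too few replicates for the requested statistical procedure."""


class InsufficientDataError(FluoroQuantError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(FluoroQuantError, ValueError):
    """Statistic undefined on this data (e.g. zero within-group variance with equal means)."""


class ZeroVarianceError(DegenerateDataError):
    """Correlation undefined because one variable has zero variance."""


class ReconciliationError(FluoroQuantError, ValueError):
    """Image files and the metadata table cannot be reconciled."""
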