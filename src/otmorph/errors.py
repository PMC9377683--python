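"""Exception and warning types shared across the package."""


class OTMorphError(Exception):
    """Base class for all package errors."""


class MapFormatError(OTMorphError):
    """A volume file could not be parsed as MRC2014/CCP4."""


class MapDataError(OTMorphError):
    """A volume parsed but its voxel data is unusable (e.g. non-finite)."""


class DegenerateInputError(OTMorphError):
    """An input map carries no usable mass (all-zero / all-negative)."""


class GridMismatchError(OTMorphError):
    """Two maps expected on a common grid have different shapes."""


class NumericalError(OTMorphError):
    """Scaling iterations produced non-finite values (regularization too small)."""


class IllConditionedKernelWarning(UserWarning):
    """The heat-kernel width is below ~0.3 voxel; the operator is near-singular."""


class AnisotropicVoxelWarning(UserWarning):
    """Voxel edges differ between axes; the mean edge is used for physical units."""
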