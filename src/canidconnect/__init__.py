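"""Habitat-suitability and landscape-connectivity modelling for canids.

The pipeline: ensemble habitat-suitability modelling -> negative-exponential
resistance transform -> cumulative resistant kernels and factorial
least-cost-path densities -> core-habitat prioritization, fragmentation
metrics, and spatial-randomization validation against road-crossing data.
"""

from importlib import resources

from . import connectivity, cores, io, metrics, sdm, synth, validation  # noqa: F401
from .raster import (  # noqa: F401
    AlignmentError,
    PredictorStack,
    RasterGrid,
    ResistanceSurface,
    SuitabilitySurface,
)
from .vector import OccurrenceSet, ProtectedAreas, RoadKillTable, RoadNetwork  # noqa: F401

__version__ = "0.1.0"


def markazi_roadkill_path():
    """Path to the bundled Markazi Province 2013-2018 road-mortality table."""
    return resources.files("canidconnect.data") / "markazi_roadkill_2013_2018.csv"
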