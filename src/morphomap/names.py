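"""Parsing of CellProfiler-convention feature names.

A feature name is a sequence of underscore-separated tokens:

    [mad_]<compartment>_<measurement type>_..._<metric and channel tokens>

* An optional ``mad`` prefix marks a within-well dispersion (median
  absolute deviation) summary rather than a within-well median.
* The compartment is one of ``Cells``, ``Cytoplasm`` or ``Nuclei``.
* The measurement type is one of ``Intensity``, ``Texture``,
  ``RadialDistribution``, ``AreaShape``, ``Correlation_Correlation``,
  ``Granularity`` or ``Neighbors`` (``Correlation_Correlation`` spans two
  tokens and names the cross-channel pixel correlation measurement).
* Channel tokens name the stain channels the measurement involves; they
  are omitted for ``AreaShape`` and ``Neighbors``, which are geometric.
* The remaining tokens form the metric name, which is treated as opaque
  because the metric vocabulary is open-ended.

Examples
--------
>>> parse_feature_name("mad_Cytoplasm_Intensity_MeanIntensity_AGP")
FeatureDescriptor(raw_name='mad_Cytoplasm_Intensity_MeanIntensity_AGP', ...)
>>> parse_feature_name("Nuclei_AreaShape_Eccentricity").channels
()
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import FeatureNameError

#: The five Cell Painting channels: DNA (Hoechst), endoplasmic reticulum,
#: RNA/nucleoli, actin+Golgi+plasma membrane, and mitochondria.
DEFAULT_CHANNELS: tuple[str, ...] = ("DNA", "ER", "RNA", "AGP", "Mito")

COMPARTMENTS: frozenset[str] = frozenset({"Cells", "Cytoplasm", "Nuclei"})

MEASUREMENT_TYPES: frozenset[str] = frozenset(
    {
        "Intensity",
        "Texture",
        "RadialDistribution",
        "AreaShape",
        "Correlation_Correlation",
        "Granularity",
        "Neighbors",
    }
)

#: Measurement types that are purely geometric and carry no channel token.
CHANNEL_FREE_TYPES: frozenset[str] = frozenset({"AreaShape", "Neighbors"})

#: Name of the cell-count component appended to every well profile; it is
#: not a CellProfiler measurement and is exempt from name parsing.
CELL_COUNT = "cell_count"

#: Prefix marking a dispersion (MAD) profile component.
MAD_PREFIX = "mad"


@dataclass(frozen=True)
class FeatureDescriptor:
    """Structured form of a CellProfiler-convention feature name."""

    raw_name: str
    dispersion_prefix: str  # "none" or "mad"
    compartment: str
    measurement_type: str
    channels: tuple[str, ...] = field(default=())
    metric_name: str = ""

    def __post_init__(self) -> None:
        if (self.measurement_type in CHANNEL_FREE_TYPES) != (not self.channels):
            raise FeatureNameError(
                f"{self.raw_name!r}: channels must be empty exactly for "
                f"{sorted(CHANNEL_FREE_TYPES)} measurements"
            )

    def format(self) -> str:
        """Return the feature name; inverse of :func:`parse_feature_name`."""
        if self.raw_name:
            return self.raw_name
        return canonical_name(
            self.dispersion_prefix,
            self.compartment,
            self.measurement_type,
            self.metric_name,
            self.channels,
        )


def canonical_name(
    dispersion_prefix: str,
    compartment: str,
    measurement_type: str,
    metric_name: str,
    channels: Sequence[str] = (),
) -> str:
    """Assemble a feature name in canonical token order.

    Channel tokens are placed last (matching e.g. intensity features such
    as ``Cytoplasm_Intensity_MeanIntensity_AGP``), except for
    ``Correlation_Correlation`` where the channel pair follows the
    measurement type directly and the metric token is implicit.
    """
    tokens: list[str] = []
    if dispersion_prefix == MAD_PREFIX:
        tokens.append(MAD_PREFIX)
    tokens.append(compartment)
    tokens.extend(measurement_type.split("_"))
    if measurement_type == "Correlation_Correlation":
        tokens.extend(channels)
        if metric_name and metric_name != "Correlation":
            tokens.append(metric_name)
    elif measurement_type in CHANNEL_FREE_TYPES:
        if metric_name:
            tokens.append(metric_name)
    else:
        if metric_name:
            tokens.append(metric_name)
        tokens.extend(channels)
    return "_".join(tokens)


def parse_feature_name(
    name: str, channels: Sequence[str] = DEFAULT_CHANNELS
) -> FeatureDescriptor:
    """Parse ``name`` into a :class:`FeatureDescriptor`.

    Parameters
    ----------
    name
        Underscore-tokenized feature name.
    channels
        Channel vocabulary used to distinguish channel tokens from metric
        tokens; defaults to the five Cell Painting channels.

    Raises
    ------
    FeatureNameError
        If the name cannot be parsed; the message names the offending
        token.
    """
    if not isinstance(name, str) or not name:
        raise FeatureNameError(f"empty or non-string feature name: {name!r}")
    tokens = name.split("_")
    i = 0
    dispersion = "none"
    if tokens[0] == MAD_PREFIX:
        dispersion = MAD_PREFIX
        i = 1
    if i >= len(tokens):
        raise FeatureNameError(f"{name!r}: nothing follows the 'mad' prefix")
    compartment = tokens[i]
    if compartment not in COMPARTMENTS:
        raise FeatureNameError(
            f"{name!r}: unknown compartment token {compartment!r} "
            f"(expected one of {sorted(COMPARTMENTS)})"
        )
    i += 1
    if i >= len(tokens):
        raise FeatureNameError(f"{name!r}: missing measurement-type token")
    if tokens[i : i + 2] == ["Correlation", "Correlation"]:
        mtype = "Correlation_Correlation"
        i += 2
    elif tokens[i] in MEASUREMENT_TYPES:
        mtype = tokens[i]
        i += 1
    else:
        raise FeatureNameError(
            f"{name!r}: unknown measurement-type token {tokens[i]!r}"
        )

    rest = tokens[i:]
    channel_vocab = set(channels)
    if mtype in CHANNEL_FREE_TYPES:
        found_channels: tuple[str, ...] = ()
        metric_tokens = rest
    else:
        found = [t for t in rest if t in channel_vocab]
        metric_tokens = [t for t in rest if t not in channel_vocab]
        if not found:
            raise FeatureNameError(
                f"{name!r}: no channel token found for measurement type "
                f"{mtype!r} (vocabulary {sorted(channel_vocab)})"
            )
        found_channels = tuple(found)
    metric = "_".join(metric_tokens)
    if not metric:
        if mtype == "Correlation_Correlation":
            metric = "Correlation"  # implicit for this measurement type
        else:
            raise FeatureNameError(f"{name!r}: missing metric-name token")
    return FeatureDescriptor(
        raw_name=name,
        dispersion_prefix=dispersion,
        compartment=compartment,
        measurement_type=mtype,
        channels=found_channels,
        metric_name=metric,
    )


def is_parseable(name: str, channels: Sequence[str] = DEFAULT_CHANNELS) -> bool:
    """True if ``name`` follows the naming convention."""
    try:
        parse_feature_name(name, channels)
    except FeatureNameError:
        return False
    return True
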