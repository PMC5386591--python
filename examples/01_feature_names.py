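"""Parse CellProfiler-convention feature names into structured parts.

Each name tokenizes into an optional 'mad' dispersion prefix, a cellular
compartment, a measurement type, channel(s) and a metric.
"""

from morphomap import parse_feature_name

for name in [
    "mad_Cytoplasm_Intensity_MeanIntensity_AGP",
    "Nuclei_AreaShape_Eccentricity",
    "Cells_Correlation_Correlation_DNA_RNA",
]:
    d = parse_feature_name(name)
    print(f"{name}")
    print(f"  prefix={d.dispersion_prefix}  compartment={d.compartment}  "
          f"type={d.measurement_type}  channels={list(d.channels)}  "
          f"metric={d.metric_name}")

# The first is the within-well spread (MAD) of mean cytoplasmic intensity
# in the actin/Golgi/plasma-membrane channel; the second a channel-free
# nuclear shape metric; the third the DNA-RNA pixel correlation in cells.
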