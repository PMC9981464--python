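"""Package-wide constants: founder strain order and letter codes.

The eight Diversity Outbred founder strains are referred to throughout by
the conventional single letters A..H, in the fixed order below. All
allele-effect vectors, genotype-probability arrays and simulated mosaics
use this order.
"""

FOUNDER_STRAINS = ("A/J", "B6", "129", "NOD", "NZO", "CAST", "PWK", "WSB")
FOUNDER_LETTERS = ("A", "B", "C", "D", "E", "F", "G", "H")
N_FOUNDERS = 8

#: default genetic-map density, centimorgans per megabase pair
DEFAULT_CM_PER_MBP = 0.5

#: missing-value token used in all text tables
NA_TOKEN = "NA"
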