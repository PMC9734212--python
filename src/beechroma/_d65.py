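"""CIE standard illuminant D65, relative spectral power distribution.

Energy units, normalised to 100 at 560 nm, tabulated at 10 nm from
300 to 830 nm.  Converted to photon (quantal) units on load by the
illuminant constructor.
"""

import numpy as np

D65_WAVELENGTH_NM = np.arange(300.0, 831.0, 10.0)

D65_RELATIVE_POWER = np.array([
    0.0341, 3.2945, 20.2360, 37.0535, 39.9488, 44.9117, 46.6383,
    52.0891, 49.9755, 54.6482, 82.7549, 91.4860, 93.4318, 86.6823,
    104.8650, 117.0080, 117.8120, 114.8610, 115.9230, 108.8110,
    109.3540, 107.8020, 104.7900, 107.6890, 104.4050, 104.0460,
    100.0000, 96.3342, 95.7880, 88.6856, 90.0062, 89.5991, 87.6987,
    83.2886, 83.6992, 80.0268, 80.2146, 82.2778, 78.2842, 69.7213,
    71.6091, 74.3490, 61.6040, 69.8856, 75.0870, 63.5927, 46.4182,
    66.8054, 63.3828, 63.8434, 59.4519, 50.6230, 51.9662, 50.5356,
])
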