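"""Isometric log-ratio balances of a soil composition.

Builds three soil samples (texture + total C and N on one simplex) and
prints the four balances of the standard partition. Each balance is positive
when its numerator subset (right of the ``|``) outweighs the denominator
subset, in log-ratio units.
"""

import pandas as pd

from sbipy import SOIL_PARTITION, close, ilr_all

soils = pd.DataFrame(
    {
        # percent by mass: texture triplet plus total N and C
        "Clay": [4.0, 11.0, 17.0],
        "Silt": [8.0, 24.0, 38.0],
        "Sand": [85.0, 62.0, 42.0],
        "N": [0.15, 0.18, 0.22],
        "C": [2.0, 2.4, 2.8],
    },
    index=["sandy_plot", "sandy_loam_plot", "loam_plot"],
)

balances = ilr_all(close(soils), SOIL_PARTITION)
print(balances.round(3))
print()
print("[Silt | Sand] shrinks from the sandy plot to the loam plot: the sand-")
print("to-silt ratio falls as texture gets finer. [Clay, Silt, Sand | N, C]")
print("is strongly negative everywhere because organic matter is a small")
print("fraction of soil mass.")
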