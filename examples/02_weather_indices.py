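"""Season weather indices: cumulative rain, rainfall evenness, degree-days.

Builds one 20-day series with uneven rainfall and prints PPT (mm), SDI
(0 = all rain on one day, 1 = perfectly even) and GDD (deg C-days at a
7 deg C base, accumulating the full daily mean on warm days).
"""

import numpy as np
import pandas as pd

from sbipy import DailyWeatherSeries, weather_indices

rng = np.random.default_rng(0)
days = 20
series = DailyWeatherSeries(
    dates=pd.date_range("2013-06-01", periods=days, freq="D"),
    rainfall=np.where(rng.random(days) < 0.4, rng.gamma(1.0, 8.0, days), 0.0),
    mean_temperature=12 + 8 * np.sin(np.pi * np.arange(days) / days),
)

for name, value in weather_indices(series).items():
    print(f"{name}\t{value:.3f}")
print()
print("SDI well below 1 reflects rain concentrated on a minority of days;")
print("GDD sums the daily means of the days at or above 7 deg C.")
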