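"""Bundled reference measurements.

``renneting_transition_times()`` returns the published comparison of the
two sol-gel transition clocks for 15 milk renneting batches run across
combinations of coagulation temperature (30/35/40 °C), milk pH
(6.3/6.5/6.7) and fat content (0.10/2.55/5.00 g/100 mL): CP2, the time of
the transition-phase concentration-profile maximum resolved from FT-NIR
spectra, and AT_G', the acceleration time of the elastic modulus from a
logistic fit of the rheological curing curve. Twelve batches span the
operating space; three are replicates of the center point. Both times are
in minutes.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["renneting_transition_times"]

_ROWS = [
    ("NOC_1", "T30 F0.10 pH6.5", 30, 0.10, 6.5, 14.5, 18.9),
    ("NOC_2", "T35 F0.10 pH6.3", 35, 0.10, 6.3, 6.0, 7.9),
    ("NOC_3", "T35 F0.10 pH6.7", 35, 0.10, 6.7, 9.0, 13.3),
    ("NOC_4", "T40 F0.10 pH6.5", 40, 0.10, 6.5, 8.0, 11.2),
    ("NOC_5", "T30 F2.55 pH6.3", 30, 2.55, 6.3, 7.3, 10.0),
    ("NOC_6", "T30 F2.55 pH6.7", 30, 2.55, 6.7, 17.0, 19.4),
    ("NOC_7", "T40 F2.55 pH6.3", 40, 2.55, 6.3, 6.5, 8.8),
    ("NOC_8", "T40 F2.55 pH6.7", 40, 2.55, 6.7, 7.0, 9.5),
    ("NOC_9", "T30 F5.00 pH6.5", 30, 5.00, 6.5, 8.3, 13.1),
    ("NOC_10", "T35 F5.00 pH6.3", 35, 5.00, 6.3, 8.0, 11.0),
    ("NOC_11", "T35 F5.00 pH6.7", 35, 5.00, 6.7, 8.5, 13.7),
    ("NOC_12", "T40 F5.00 pH6.5", 40, 5.00, 6.5, 5.5, 6.8),
    ("NOC_13a", "T35 F2.55 pH6.5", 35, 2.55, 6.5, 5.8, 8.9),
    ("NOC_13b", "T35 F2.55 pH6.5", 35, 2.55, 6.5, 7.5, 9.8),
    ("NOC_13c", "T35 F2.55 pH6.5", 35, 2.55, 6.5, 7.0, 9.4),
]


def renneting_transition_times() -> pd.DataFrame:
    """CP2 vs AT_G' reference table (15 batches; times in minutes)."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "batch",
            "sample_id",
            "temperature_C",
            "fat_g_per_100mL",
            "pH",
            "cp2_min",
            "at_gprime_min",
        ],
    )
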