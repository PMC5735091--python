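"""Bundled example data.

``mitogenome_capture_summary`` returns per-sample summary statistics for
twenty published Late Pleistocene woolly mammoth mitochondrial genomes
reconstructed by in-solution capture from central European material:
shotgun endogenous-DNA percentage, mean mitogenome fold coverage, percent
of the mitogenome covered, mean fragment length (bp), and mitochondrial
clade.  Useful for exercising the screening/QC operations on real-scale
numbers.
"""

from __future__ import annotations

import pandas as pd

_CAPTURE_SUMMARY = [
    # sample, site, endogenous_pct, coverage_fold, completeness_pct, frag_len_bp, clade
    ("JK2760", "Hohle Fels", 4.296, 86.54, 98, 80.95, "III"),
    ("JK2761", "Hohle Fels", 0.222, 5.29, 72, 79.02, "III"),
    ("JK2762", "Geissenkloesterle", 0.215, 22.23, 93, 79.04, "III"),
    ("JK2764", "Geissenkloesterle", 0.606, 243.18, 98, 73.35, "III"),
    ("JK2765", "Hohle Fels", 0.902, 109.99, 97, 70.40, "III"),
    ("JK2766", "Hohle Fels", 1.019, 79.49, 97, 79.00, "III"),
    ("JK2768", "Hohle Fels", 1.720, 60.40, 98, 87.13, "III"),
    ("JK2769", "Geissenkloesterle", 0.342, 27.95, 93, 74.68, "III"),
    ("JK2770", "Hohle Fels", 2.728, 164.57, 98, 82.25, "III"),
    ("JK2771", "Geissenkloesterle", 0.126, 8.89, 82, 82.26, "III"),
    ("JK2772", "Hohle Fels", 6.018, 230.59, 98, 73.93, "III"),
    ("JK2773", "Hohle Fels", 0.429, 29.41, 95, 79.81, "III"),
    ("JK2774", "Geissenkloesterle", 0.256, 5.68, 74, 74.37, "III"),
    ("JK2779", "Geissenkloesterle", 0.038, 11.63, 86, 78.58, "III"),
    ("JK2780", "Geissenkloesterle", 0.048, 7.27, 77, 78.24, "III"),
    ("JK2782", "Kesslerloch", 22.694, 108.30, 99, 90.14, "I"),
    ("JK2790", "Krakow Spadzista", 0.765, 216.37, 98, 72.02, "I"),
    ("JK2796", "Krakow Spadzista", 0.453, 6.72, 78, 67.91, "I"),
    ("JK2802", "Krakow Spadzista", 15.563, 522.97, 99, 77.40, "I"),
    ("JK2803", "Krakow Spadzista", 0.091, 11.86, 85, 68.59, "I"),
]


def mitogenome_capture_summary() -> pd.DataFrame:
    """Per-sample capture summary statistics as a DataFrame."""
    return pd.DataFrame(
        _CAPTURE_SUMMARY,
        columns=[
            "sample",
            "site",
            "endogenous_pct",
            "coverage_fold",
            "completeness_pct",
            "fragment_length_bp",
            "clade",
        ],
    )
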