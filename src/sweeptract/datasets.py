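"""Reference measurements for three professional opera singers.

MRI-derived piriform-fossa and vocal-tract dimensions for a mezzo-soprano
("Maristela"), a bari-tenor ("Bartholomew") and a bass-baritone ("Barnaby"),
each phonating sustained vowels, plus the measured-versus-simulated formant
frequencies of three of Barnaby's 3-D printed tracts.  Sinus lengths are the
average of the left and right piriform fossae in mm; volumes in cm^3.  These
records serve as worked-example inputs for the analytic predictors and the
reporting utilities.
"""

from __future__ import annotations

import pandas as pd

from .tubes import PiriformGeometry

__all__ = ["SINGER_PIRIFORM_GEOMETRY", "BARNABY_VOWELS",
           "FORMANT_COMPARISON", "formant_comparison_frame"]

#: piriform geometry per singer and vowel (length mm, volumes cm^3)
SINGER_PIRIFORM_GEOMETRY: tuple[PiriformGeometry, ...] = (
    PiriformGeometry(L_sinus=17.63, PV=3.47, VTV=44.58, label="Maristela /haad/"),
    PiriformGeometry(L_sinus=18.31, PV=1.70, VTV=37.32, label="Bartholomew /haad/"),
    PiriformGeometry(L_sinus=20.50, PV=1.69, VTV=80.49, label="Barnaby /haad/"),
    PiriformGeometry(L_sinus=19.97, PV=3.64, VTV=65.61, label="Barnaby /pawt/"),
    PiriformGeometry(L_sinus=19.00, PV=3.43, VTV=65.29, label="Barnaby /stern/"),
    PiriformGeometry(L_sinus=19.42, PV=4.79, VTV=57.67, label="Barnaby /food/"),
    PiriformGeometry(L_sinus=21.18, PV=3.58, VTV=65.48, label="Barnaby /neap/"),
)

#: the five Barnaby vowels, in the order above
BARNABY_VOWELS: tuple[PiriformGeometry, ...] = tuple(
    g for g in SINGER_PIRIFORM_GEOMETRY if g.label.startswith("Barnaby"))

#: simulated (num) vs measured (exp) formant frequencies, Hz, per vowel
FORMANT_COMPARISON: tuple[dict, ...] = (
    {"vowel": "/pawt/", "formant": "F1", "num_hz": 417, "exp_hz": 482},
    {"vowel": "/pawt/", "formant": "F2", "num_hz": 834, "exp_hz": 833},
    {"vowel": "/pawt/", "formant": "F3", "num_hz": 2334, "exp_hz": 2448},
    {"vowel": "/pawt/", "formant": "F4", "num_hz": 2647, "exp_hz": 2753},
    {"vowel": "/pawt/", "formant": "F5", "num_hz": 3414, "exp_hz": 3515},
    {"vowel": "/stern/", "formant": "F1", "num_hz": 483, "exp_hz": 523},
    {"vowel": "/stern/", "formant": "F2", "num_hz": 1134, "exp_hz": 1043},
    {"vowel": "/stern/", "formant": "F3", "num_hz": 2302, "exp_hz": 2256},
    {"vowel": "/stern/", "formant": "F4", "num_hz": 2778, "exp_hz": 2719},
    {"vowel": "/stern/", "formant": "F5", "num_hz": 3625, "exp_hz": 3173},
    {"vowel": "/food/", "formant": "F1", "num_hz": 264, "exp_hz": 283},
    {"vowel": "/food/", "formant": "F2", "num_hz": 867, "exp_hz": 821},
    {"vowel": "/food/", "formant": "F3", "num_hz": 2122, "exp_hz": 2193},
    {"vowel": "/food/", "formant": "F4", "num_hz": 2736, "exp_hz": 2774},
    {"vowel": "/food/", "formant": "F5", "num_hz": 3361, "exp_hz": 3464},
)


def formant_comparison_frame() -> pd.DataFrame:
    """The formant comparison records as a DataFrame."""
    return pd.DataFrame(FORMANT_COMPARISON)
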