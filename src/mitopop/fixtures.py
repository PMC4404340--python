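"""Transcribed published summary tables used as desk-scale fixtures.

Three fixtures are packaged as Python constants and can be materialised as
TSV files with :func:`make_fixtures`:

* the 64-haplotype frequency spectrum of the pooled barcode sample
  (n = 686 individuals);
* a 20-population matrix pair: pairwise FST below the diagonal and
  geographic distance (km) above it (country-level analysis);
* the corresponding 9-region matrix pair (continent / larger-region
  analysis).

These give exact desk-scale inputs for haplotype diversity and Mantel
isolation-by-distance without any sequence data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from mitopop.haplotypes import HaplotypeSet
from mitopop.seqio import LabeledMatrix, write_labeled_matrix

# 64 haplotype frequencies, ordered by haplotype number (H1..H64); sum = 686
HAPLOTYPE_FREQUENCIES: tuple[int, ...] = (
    1, 2, 1, 1, 1, 2, 1, 225, 2, 1,
    1, 1, 1, 1, 1, 1, 1, 3, 1, 1,
    2, 2, 32, 1, 1, 1, 1, 1, 1, 15,
    2, 1, 2, 4, 143, 1, 2, 2, 29, 6,
    1, 1, 1, 1, 1, 20, 1, 2, 2, 1,
    1, 1, 1, 143, 1, 1, 1, 2, 1, 1,
    1, 1, 1, 1,
)

COUNTRY_LABELS: tuple[str, ...] = (
    "India GJ", "India South", "India PB", "India JK", "Bangladesh",
    "Thailand", "Laos SK", "Laos VN", "Vietnam North", "Vietnam Binh Thuan",
    "Vietnam An Giang", "Malaysia East", "Malaysia West", "Indonesia JV",
    "Taiwan", "Benin South", "Benin North", "Benin Central", "Kenya NYZ",
    "Kenya Eastern",
)

# pairwise FST, lower triangle by row (row i lists columns 0..i-1)
_COUNTRY_FST_LOWER = [
    [-0.04],
    [0.11, 0.26],
    [0.26, 0.40, 0.40],
    [0.01, 0.13, -0.09, 0.34],
    [-0.02, 0.04, 0.03, 0.30, -0.02],
    [-0.04, -0.01, 0.09, 0.33, 0.01, 0.02],
    [-0.001, 0.05, -0.004, 0.34, -0.06, 0.01, -0.01],
    [0.11, 0.18, -0.06, 0.38, -0.03, 0.05, 0.12, 0.05],
    [0.15, 0.25, -0.06, 0.41, -0.02, 0.08, 0.16, 0.07, -0.02],
    [0.10, 0.19, -0.06, 0.38, -0.05, 0.03, 0.11, 0.03, -0.02, -0.02],
    [0.45, 0.60, 0.11, 0.57, 0.22, 0.30, 0.40, 0.27, 0.09, 0.05, 0.12],
    [0.29, 0.36, 0.02, 0.50, 0.10, 0.20, 0.29, 0.18, 0.04, 0.02, 0.06,
     -0.03],
    [0.65, 0.74, 0.38, 0.71, 0.50, 0.48, 0.56, 0.46, 0.27, 0.25, 0.33,
     0.03, 0.11],
    [0.02, 0.07, -0.01, 0.40, -0.05, 0.01, 0.03, -0.01, 0.04, 0.06, 0.02,
     0.29, 0.18, 0.47],
    [0.60, 0.67, 0.54, 0.68, 0.55, 0.59, 0.60, 0.54, 0.52, 0.53, 0.55,
     0.57, 0.52, 0.64, 0.58],
    [0.61, 0.72, 0.54, 0.66, 0.54, 0.59, 0.61, 0.54, 0.51, 0.52, 0.55,
     0.58, 0.52, 0.68, 0.60, -0.02],
    [0.52, 0.64, 0.44, 0.61, 0.44, 0.52, 0.53, 0.46, 0.44, 0.44, 0.47,
     0.49, 0.45, 0.60, 0.52, -0.02, -0.01],
    [0.82, 0.84, 0.79, 0.85, 0.80, 0.77, 0.76, 0.74, 0.71, 0.74, 0.77,
     0.80, 0.71, 0.82, 0.74, 0.14, 0.12, 0.26],
    [0.78, 0.82, 0.74, 0.81, 0.75, 0.73, 0.73, 0.70, 0.67, 0.69, 0.72,
     0.76, 0.67, 0.79, 0.71, 0.09, 0.07, 0.19, -0.01],
]

# geographic distances in km, upper triangle by row (row i lists i+1..19)
_COUNTRY_KM_UPPER = [
    [1334, 972, 1272, 1670, 3001, 3395, 3134, 3396, 3948, 3691, 5079, 3740,
     5260, 4823, 7723, 7443, 7693, 4917, 4627],
    [2156, 1508, 1807, 2379, 2920, 2721, 3130, 3270, 2962, 4306, 2731, 4139,
     4620, 8319, 8127, 8344, 5042, 4699],
    [1260, 1528, 3097, 3336, 3059, 3184, 3991, 3796, 5130, 4070, 5628, 4455,
     8034, 7691, 7961, 5612, 5356],
    [558, 1855, 2166, 1895, 2127, 2777, 2559, 3920, 2814, 4372, 3555, 8988,
     8697, 8951, 6126, 5818],
    [1580, 1818, 1542, 1737, 2463, 2273, 3602, 2636, 4181, 3151, 9379, 9080,
     9337, 6528, 6218],
    [587, 523, 999, 948, 704, 2081, 1184, 2650, 2352, 10638, 10401, 10637,
     7417, 7071],
    [277, 512, 711, 686, 1806, 1494, 2742, 1765, 11099, 10836, 11082, 7961,
     7619],
    [480, 971, 888, 2081, 1614, 2954, 1912, 10847, 10577, 10825, 7754, 7416],
    [1136, 1185, 2103, 2006, 3210, 1493, 11115, 10817, 11074, 8133, 7802],
    [324, 1143, 1113, 2078, 1843, 11560, 11344, 11576, 8273, 7920],
    [1389, 871, 2066, 2117, 11272, 11056, 11284, 7953, 7600],
    [1708, 1612, 1990, 12623, 12428, 12649, 9202, 8843],
    [1558, 2956, 10982, 10829, 11032, 7502, 7141],
    [3562, 12085, 12017, 12183, 8468, 8107],
    [12484, 12144, 12415, 9623, 9294],
    [514, 286, 3640, 3995],
    [291, 3671, 4012],
    [3778, 4127],
    [363],
]

REGION_LABELS: tuple[str, ...] = (
    "Asia (South)", "Asia (Southeast)", "Asia (East)", "Africa (Benin)",
    "Africa (Kenya)", "Oceania (Australia)", "Oceania (PNG)",
    "Latin America (Others)", "Latin America (Costa Rica)",
)

_REGION_FST_LOWER = [
    [0.1040],
    [0.0363, 0.0351],
    [0.5006, 0.4033, 0.4719],
    [0.7226, 0.6154, 0.7044, 0.1677],
    [0.2525, 0.4524, 0.2892, 0.3094, 0.5056],
    [0.9430, 0.9629, 0.9536, 0.9370, 0.9664, 0.5915],
    [0.9578, 0.9472, 0.9608, 0.9402, 0.9690, 0.6203, 0.8946],
    [0.9543, 0.9467, 0.9564, 0.9446, 0.9641, 0.7755, 0.9478, 0.0373],
]

_REGION_KM_UPPER = [
    [1855, 3555, 8951, 5818, 8124, 7292, 16559, 16135],
    [2352, 10637, 7071, 6269, 5498, 18085, 17245],
    [12415, 9294, 5509, 4201, 19303, 15386],
    [4127, 16025, 16049, 7608, 9501],
    [11913, 12044, 11017, 13616],
    [1611, 14964, 14468],
    [16115, 14373],
    [3971],
]


def _from_lower(labels, rows) -> LabeledMatrix:
    n = len(labels)
    m = np.zeros((n, n))
    for i, row in enumerate(rows):
        m[i + 1, : i + 1] = row
    m = m + m.T
    return LabeledMatrix(tuple(labels), m)


def _from_upper(labels, rows) -> LabeledMatrix:
    n = len(labels)
    m = np.zeros((n, n))
    for i, row in enumerate(rows):
        m[i, i + 1:] = row
    m = m + m.T
    return LabeledMatrix(tuple(labels), m)


def haplotype_frequency_fixture() -> HaplotypeSet:
    """The pooled 64-haplotype frequency spectrum (n = 686)."""
    return HaplotypeSet.from_frequencies(HAPLOTYPE_FREQUENCIES)


def country_fst_matrix() -> LabeledMatrix:
    return _from_lower(COUNTRY_LABELS, _COUNTRY_FST_LOWER)


def country_km_matrix() -> LabeledMatrix:
    return _from_upper(COUNTRY_LABELS, _COUNTRY_KM_UPPER)


def region_fst_matrix() -> LabeledMatrix:
    return _from_lower(REGION_LABELS, _REGION_FST_LOWER)


def region_km_matrix() -> LabeledMatrix:
    return _from_upper(REGION_LABELS, _REGION_KM_UPPER)


def make_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Write the packaged fixtures as TSV files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    freq_path = outdir / "haplotype_frequencies.tsv"
    with open(freq_path, "w") as fh:
        fh.write("haplotype\tfrequency\n")
        for i, f in enumerate(HAPLOTYPE_FREQUENCIES):
            fh.write(f"H{i + 1}\t{f}\n")
    paths["haplotype_frequencies"] = freq_path

    for name, fst, km in (
        ("country", country_fst_matrix(), country_km_matrix()),
        ("region", region_fst_matrix(), region_km_matrix()),
    ):
        p = outdir / f"{name}_fst_km.tsv"
        write_labeled_matrix(fst, p, upper=km)
        paths[f"{name}_fst_km"] = p
        pf = outdir / f"{name}_fst.tsv"
        write_labeled_matrix(fst, pf)
        paths[f"{name}_fst"] = pf
        pk = outdir / f"{name}_km.tsv"
        write_labeled_matrix(km, pk)
        paths[f"{name}_km"] = pk
    return paths
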