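"""Independent reference oracles used by the test suite.

These deliberately re-derive results by a different route than the package
(exact rational arithmetic, scipy labelling, direct formula evaluation) so
that agreement is evidence, not tautology.
"""

from fractions import Fraction

import numpy as np
from scipy import ndimage


def oracle_encode_csquare(lat, lon, resolution) -> str:
    """C-square code built digit by digit with exact rational arithmetic.

    Implements the published notation rules directly on the absolute
    coordinates of the (half-open) cell's center: global quadrant digit
    from the signs, the 10-degree lat digit and two lon digits, then one
    refinement cycle per ladder step — an intermediate-quadrant digit
    (1 low/low, 2 low-lat/high-lon, 3 high-lat/low-lon, 4 high/high) and,
    for divide-by-ten cycles, a lat and a lon digit.
    """
    lat, lon, res = Fraction(str(lat)), Fraction(str(lon)), Fraction(str(resolution))

    def axis_center(v, limit):
        # half-open cell index, clamped so the poles/antimeridian fall in
        # the last cell; the center is strictly interior
        i = (v / res).__floor__()
        n = int(limit / res)
        i = min(max(i, -n), n - 1)
        return (i + Fraction(1, 2)) * res

    lat_c, lon_c = axis_center(lat, 90), axis_center(lon, 180)

    if lat_c >= 0 and lon_c >= 0:
        q = 1
    elif lat_c < 0 and lon_c >= 0:
        q = 3
    elif lat_c < 0 and lon_c < 0:
        q = 5
    else:
        q = 7
    alat, alon = abs(lat_c), abs(lon_c)
    code = f"{q}{int(alat / 10)}{int(alon / 10):02d}"
    rlat, rlon = alat - int(alat / 10) * 10, alon - int(alon / 10) * 10
    size = Fraction(10)
    while size > res:
        half = size / 2
        iq = 1 + (2 if rlat >= half else 0) + (1 if rlon >= half else 0)
        if res == half:
            code += f":{iq}"
            size = half
        else:
            sub = size / 10
            dlat, dlon = int(rlat / sub), int(rlon / sub)
            code += f":{iq}{dlat}{dlon}"
            rlat -= dlat * sub
            rlon -= dlon * sub
            size = sub
    return code


def label_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a boolean mask via scipy.ndimage.label."""
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if connectivity == 4
        else np.ones((3, 3), dtype=int)
    )
    labels, n = ndimage.label(mask, structure=structure)
    return [set(zip(*np.nonzero(labels == k))) for k in range(1, n + 1)]


def fuzzy_linear_direct(x, lo, hi):
    """The printed piecewise formula, evaluated literally."""
    if x < lo:
        return 0.0
    if x > hi:
        return 1.0
    return (x - lo) / (hi - lo)
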