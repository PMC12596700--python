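"""WGS84 <-> UTM coordinate transforms.

Transverse Mercator on the WGS84 ellipsoid via the Krüger series in the third
flattening n, truncated at order n^6 (sub-millimeter accuracy anywhere within
a UTM zone, far inside the 1 m contract the spatial analysis needs). Both the
forward projection (geographic -> grid) and the inverse are provided; the
standard UTM constants are k0 = 0.9996, false easting 500 000 m and, for the
southern hemisphere, false northing 10 000 000 m.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["geographic_to_utm", "utm_to_geographic", "utm_central_meridian"]

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_K0 = 0.9996
_FALSE_EASTING = 500_000.0
_FALSE_NORTHING_SOUTH = 10_000_000.0

_N = _WGS84_F / (2.0 - _WGS84_F)  # third flattening
_E = np.sqrt(_WGS84_F * (2.0 - _WGS84_F))  # first eccentricity

# rectifying radius
_A_RECT = _WGS84_A / (1.0 + _N) * (1.0 + _N**2 / 4.0 + _N**4 / 64.0 + _N**6 / 256.0)

n = _N
_ALPHA = np.array(
    [
        n / 2 - 2 * n**2 / 3 + 5 * n**3 / 16 + 41 * n**4 / 180 - 127 * n**5 / 288 + 7891 * n**6 / 37800,
        13 * n**2 / 48 - 3 * n**3 / 5 + 557 * n**4 / 1440 + 281 * n**5 / 630 - 1983433 * n**6 / 1935360,
        61 * n**3 / 240 - 103 * n**4 / 140 + 15061 * n**5 / 26880 + 167603 * n**6 / 181440,
        49561 * n**4 / 161280 - 179 * n**5 / 168 + 6601661 * n**6 / 7257600,
        34729 * n**5 / 80640 - 3418889 * n**6 / 1995840,
        212378941 * n**6 / 319334400,
    ]
)
_BETA = np.array(
    [
        n / 2 - 2 * n**2 / 3 + 37 * n**3 / 96 - n**4 / 360 - 81 * n**5 / 512 + 96199 * n**6 / 604800,
        n**2 / 48 + n**3 / 15 - 437 * n**4 / 1440 + 46 * n**5 / 105 - 1118711 * n**6 / 3870720,
        17 * n**3 / 480 - 37 * n**4 / 840 - 209 * n**5 / 4480 + 5569 * n**6 / 90720,
        4397 * n**4 / 161280 - 11 * n**5 / 504 - 830251 * n**6 / 7257600,
        4583 * n**5 / 161280 - 108847 * n**6 / 3991680,
        20648693 * n**6 / 638668800,
    ]
)
del n


def utm_central_meridian(zone: int) -> float:
    """Central meridian of a UTM zone, in degrees east."""
    if not 1 <= zone <= 60:
        raise ValueError("UTM zone must be in 1..60")
    return zone * 6.0 - 183.0


def geographic_to_utm(
    lon: np.ndarray, lat: np.ndarray, zone: int = 39, south: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Project WGS84 degrees to UTM easting/northing in meters."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("geographic coordinates out of range")
    if np.any(np.abs(lon - utm_central_meridian(zone)) > 15.0):
        warnings.warn(
            f"coordinates far outside UTM zone {zone}; projection accuracy degrades",
            stacklevel=2,
        )
    lam = np.radians(lon - utm_central_meridian(zone))
    phi = np.radians(lat)

    tau = np.tan(phi)
    sigma = np.sinh(_E * np.arctanh(_E * np.sin(phi)))
    taup = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)

    xi_p = np.arctan2(taup, np.cos(lam))
    eta_p = np.arcsinh(np.sin(lam) / np.sqrt(taup**2 + np.cos(lam) ** 2))

    xi = xi_p.copy()
    eta = eta_p.copy()
    for j in range(1, 7):
        xi = xi + _ALPHA[j - 1] * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
        eta = eta + _ALPHA[j - 1] * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)

    easting = _FALSE_EASTING + _K0 * _A_RECT * eta
    northing = _K0 * _A_RECT * xi
    if south:
        northing = northing + _FALSE_NORTHING_SOUTH
    return easting, northing


def utm_to_geographic(
    easting: np.ndarray, northing: np.ndarray, zone: int = 39, south: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-project UTM meters back to WGS84 degrees (lon, lat)."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    y = northing - (_FALSE_NORTHING_SOUTH if south else 0.0)
    xi = y / (_K0 * _A_RECT)
    eta = (easting - _FALSE_EASTING) / (_K0 * _A_RECT)

    xi_p = xi.copy()
    eta_p = eta.copy()
    for j in range(1, 7):
        xi_p = xi_p - _BETA[j - 1] * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_p = eta_p - _BETA[j - 1] * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    taup = np.sin(xi_p) / np.sqrt(np.sinh(eta_p) ** 2 + np.cos(xi_p) ** 2)
    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))

    # invert tau' -> tau by Newton iteration on the conformal latitude map
    tau = taup / (1.0 - _E**2)  # spherical start
    for _ in range(8):
        sigma = np.sinh(_E * np.arctanh(_E * tau / np.sqrt(1.0 + tau**2)))
        taup_i = tau * np.sqrt(1.0 + sigma**2) - sigma * np.sqrt(1.0 + tau**2)
        dtau = (
            (taup - taup_i)
            * (1.0 + (1.0 - _E**2) * tau**2)
            / ((1.0 - _E**2) * np.sqrt((1.0 + taup_i**2) * (1.0 + tau**2)))
        )
        tau = tau + dtau
        if np.all(np.abs(dtau) < 1e-16):
            break

    lat = np.degrees(np.arctan(tau))
    lon = np.degrees(lam) + utm_central_meridian(zone)
    return lon, lat
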