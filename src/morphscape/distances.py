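"""Construction of the pairwise-distance matrices used by the inference stage.

All matrices share one label order per analysis: the morph-frequency
Euclidean distance (response), great-circle or planar geographic distance,
absolute environmental covariate differences, and the pairwise F_ST matrix
assembled from popgen results.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import MORPH_ORDER, DistanceMatrix, SiteTable
from .morphstats import FrequencyTable
from .popgen import FstResult

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def morph_distance_matrix(freqs: FrequencyTable) -> DistanceMatrix:
    """Euclidean distance between four-morph frequency vectors.

    dist(A, B) = sqrt(sum over morphs of (A_m - B_m)^2), bounded by
    sqrt(2) for probability vectors.
    """
    pops = freqs.populations
    p = freqs.data[list(MORPH_ORDER)].to_numpy(dtype=float)
    diff = p[:, None, :] - p[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(tuple(pops), d)


def geographic_distance_matrix(sites: SiteTable, method: str = "greatcircle") -> DistanceMatrix:
    """Pairwise geographic distances between sites.

    ``greatcircle`` (default) is the haversine distance in km on a
    spherical Earth; ``euclidean`` is the planar distance on raw decimal
    degrees, provided for comparisons with analyses that used unprojected
    coordinates.
    """
    lat = np.radians(sites.data["lat"].to_numpy(dtype=float))
    lon = np.radians(sites.data["lon"].to_numpy(dtype=float))
    if method == "greatcircle":
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
        np.fill_diagonal(d, 0.0)
    elif method == "euclidean":
        x = sites.data[["lat", "lon"]].to_numpy(dtype=float)
        diff = x[:, None, :] - x[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(tuple(sites.sites), d)


def covariate_distance_matrix(sites: SiteTable, variable: str) -> DistanceMatrix:
    """Absolute pairwise difference |x_A - x_B| of one site covariate."""
    x = sites.values(variable).to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    return DistanceMatrix(tuple(sites.sites), d)


def fst_distance_matrix(
    results: Sequence[FstResult],
    labels: Sequence[str] | None = None,
    clip_negative: bool = False,
) -> DistanceMatrix:
    """Assemble a labelled matrix from pairwise F_ST results.

    Small negative theta estimates are preserved by default (the matrix is
    a similarity-derived predictor, not a metric); ``clip_negative`` floors
    them at zero.
    """
    if labels is None:
        seen: dict[str, None] = {}
        for r in results:
            seen.setdefault(r.pop_a)
            seen.setdefault(r.pop_b)
        labels = list(seen)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    m = np.zeros((n, n))
    filled = np.zeros((n, n), dtype=bool)
    for r in results:
        i, j = idx[r.pop_a], idx[r.pop_b]
        v = max(r.theta, 0.0) if clip_negative else r.theta
        m[i, j] = m[j, i] = v
        filled[i, j] = filled[j, i] = True
    off = ~np.eye(n, dtype=bool)
    if not filled[off].all():
        raise ValueError("missing population pairs in F_ST results")
    return DistanceMatrix(tuple(labels), m)
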