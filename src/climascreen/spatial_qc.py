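"""Spatial quality control: grid thinning, minimum-specimen filtering and
Moran's I autocorrelation diagnostics.

Thinning keeps at most one record per species per grid cell to damp
uneven collection intensity; the retained record in each occupied cell is
drawn uniformly at random, reproducibly under a seed.  Cell assignment
uses half-open cells [k*c, (k+1)*c) indexed by (floor(lon/c), floor(lat/c));
a point on a cell boundary belongs to the higher-index cell.

Moran's I is computed with binary distance-band weights (w_ij = 1 iff
0 < d_ij <= lag, great-circle km), its expectation is -1/(n-1), and its
variance follows the normality assumption, giving a two-sided normal p.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km (haversine; Earth radius 6371.0088 km).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    p1, l1, p2, l2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.isscalar(lat1) and np.isscalar(lat2) else d


def _species_of(x):
    return x.species  # OccurrenceRecord and SpecimenClimate both expose it


def thin_to_grid(records: Sequence, cell_deg: float = 0.1, seed: int = 0) -> list:
    """Per species, retain one uniformly chosen record per occupied grid cell.

    Deterministic under ``seed`` and invariant to the input ordering of
    records (candidates inside a cell are ranked by coordinates before the
    draw).  Output preserves the input order of the retained records.
    Thinning an already-thinned set is the identity.
    """
    if not cell_deg > 0:
        raise ValueError("cell_deg must be positive")
    by_species: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        by_species[_species_of(rec)].append(i)

    keep: set[int] = set()
    root = np.random.SeedSequence(seed)
    # one independent child stream per species, in sorted-name order
    children = root.spawn(len(by_species))
    for child, name in zip(children, sorted(by_species)):
        rng = np.random.default_rng(child)
        cells: dict[tuple[int, int], list[int]] = defaultdict(list)
        for i in by_species[name]:
            r = records[i]
            cells[(int(np.floor(r.lon / cell_deg)), int(np.floor(r.lat / cell_deg)))].append(i)
        for key in sorted(cells):
            cand = sorted(cells[key], key=lambda i: (records[i].lat, records[i].lon,
                                                     records[i].record_id or ""))
            keep.add(cand[rng.integers(len(cand))])
    return [rec for i, rec in enumerate(records) if i in keep]


def filter_min_specimens(records: Sequence, min_n: int = 10) -> tuple[list, list[str]]:
    """Drop species represented by fewer than ``min_n`` records.

    Returns (kept records, sorted list of excluded species).  Applied
    after thinning and climate linking, mirroring the record-accounting
    order of the pipeline.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    counts: dict[str, int] = defaultdict(int)
    for rec in records:
        counts[_species_of(rec)] += 1
    excluded = sorted(s for s, c in counts.items() if c < min_n)
    bad = set(excluded)
    return [rec for rec in records if _species_of(rec) not in bad], excluded


@dataclass(frozen=True)
class MoranResult:
    species: str
    variable: str
    lag_km: float
    n: int
    I: float
    expected_I: float  # -1/(n-1)
    variance_I: float  # under the normality assumption
    p_value: float  # two-sided normal approximation


def morans_i(
    values: Sequence[float],
    lats: Sequence[float],
    lons: Sequence[float],
    lag_km: float,
    species: str = "",
    variable: str = "",
    weights: str = "binary",
) -> MoranResult:
    """Moran's I of ``values`` under a distance-band spatial weight matrix.

    I = (n/W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 iff 0 < d_ij <= lag_km (or 1/d_ij within the band when
    ``weights="inverse"``), W the total weight.  Expectation -1/(n-1);
    variance under the normality assumption; two-sided normal p.

    Raises if n < 3, the values are constant, or no pair falls within the
    lag (W = 0).
    """
    x = np.asarray(values, dtype=float)
    la = np.asarray(lats, dtype=float)
    lo = np.asarray(lons, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I requires n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("values have zero variance; I is undefined")
    d = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    band = (d > 0) & (d <= lag_km)
    if weights == "binary":
        w = band.astype(float)
    elif weights == "inverse":
        w = np.where(band, 1.0 / np.where(band, d, 1.0), 0.0)
    else:
        raise ValueError(f"unknown weight scheme {weights!r}")
    W = w.sum()
    if W == 0:
        raise ValueError(f"no pairs within lag {lag_km} km")

    z = x - x.mean()
    I = (n / W) * float(z @ w @ z) / float(z @ z)
    e_i = -1.0 / (n - 1)
    # normality-assumption variance (symmetric weights)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=0) + w.sum(axis=1)) ** 2).sum()
    var = (n * n * s1 - n * s2 + 3.0 * W * W) / (W * W * (n * n - 1.0)) - e_i**2
    var = max(var, 0.0)
    if var > 0:
        p = 2.0 * sps.norm.sf(abs(I - e_i) / np.sqrt(var))
    else:
        p = 1.0
    return MoranResult(species, variable, float(lag_km), n, float(I), e_i, float(var),
                       float(min(p, 1.0)))
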