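"""Per-species climate-niche profiles and clustering in median space.

A species' realized niche along each axis is summarized by the median of
the climate values at its specimens (the tolerance indicator), the
extrema, and the niche width (Rolland's range rule: maximum − minimum).
Species are then grouped by agglomerative clustering on the bivariate
(median PDQ, median MTCM) point, using squared Euclidean distances with
between-groups average linkage by default.  Because mm and °C are
incommensurable, both axes are z-score standardized before distances
unless standardization is switched off.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class SpeciesProfile:
    species: str
    n: int
    median_pdq: float  # mm
    median_mtcm: float  # °C
    min_pdq: float
    max_pdq: float
    min_mtcm: float
    max_mtcm: float

    @property
    def niche_width_pdq(self) -> float:
        """Rolland niche width: max − min PDQ (mm)."""
        return self.max_pdq - self.min_pdq

    @property
    def niche_width_mtcm(self) -> float:
        """Rolland niche width: max − min MTCM (°C)."""
        return self.max_mtcm - self.min_mtcm


def build_profiles(specimens: Sequence) -> list[SpeciesProfile]:
    """Aggregate specimen-level climate values per species.

    Medians are the mid-rank median (mean of the two central order
    statistics for even n).  Output is sorted by species label.
    """
    if not specimens:
        raise ValueError("no specimens to profile")
    by_sp: dict[str, list] = defaultdict(list)
    for s in specimens:
        by_sp[s.species].append(s)
    out = []
    for name in sorted(by_sp):
        pdq = np.array([s.pdq for s in by_sp[name]])
        mtcm = np.array([s.mtcm for s in by_sp[name]])
        out.append(
            SpeciesProfile(
                species=name,
                n=pdq.size,
                median_pdq=float(np.median(pdq)),
                median_mtcm=float(np.median(mtcm)),
                min_pdq=float(pdq.min()),
                max_pdq=float(pdq.max()),
                min_mtcm=float(mtcm.min()),
                max_mtcm=float(mtcm.max()),
            )
        )
    return out


@dataclass
class ClusterResult:
    k: int
    species: list[str]  # sorted labels, aligned with linkage leaf order
    assignment: dict[str, int]  # species -> cluster label in 1..k
    linkage: np.ndarray  # scipy (n-1, 4) merge history with heights


def cluster_species(
    profiles: Sequence[SpeciesProfile],
    k: int,
    standardize: bool = True,
    linkage_method: str = "average",
) -> ClusterResult:
    """Cut an agglomerative tree over (median_pdq, median_mtcm) into k groups.

    Distances are squared Euclidean; default linkage is between-groups
    average (Ward available via ``linkage_method``).  Species are sorted
    by label before clustering so the result is invariant to input order;
    cluster labels are renumbered 1..k in order of first appearance along
    the sorted species list.
    """
    profiles = sorted(profiles, key=lambda p: p.species)
    n = len(profiles)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    X = np.array([[p.median_pdq, p.median_mtcm] for p in profiles], dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite species medians")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    names = [p.species for p in profiles]
    if n == 1:
        return ClusterResult(1, names, {names[0]: 1}, np.empty((0, 4)))
    d = pdist(X, metric="sqeuclidean")
    Z = hierarchy.linkage(d, method=linkage_method)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    for lbl in raw:
        if lbl not in relabel:
            relabel[lbl] = len(relabel) + 1
    assignment = {name: relabel[lbl] for name, lbl in zip(names, raw)}
    return ClusterResult(int(raw.max() if k > 1 else 1), names, assignment, Z)


def to_newick(result: ClusterResult) -> str:
    """Serialize the merge history as a Newick dendrogram with branch
    lengths derived from merge heights (spaces in labels become '_')."""
    if len(result.species) == 1:
        return f"{result.species[0].replace(' ', '_')};"
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.species[node.id].replace(' ', '_')}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def profiles_table(
    profiles: Sequence[SpeciesProfile], clusters: ClusterResult | None = None
) -> pd.DataFrame:
    """Per-species summary table (optionally with cluster labels)."""
    df = pd.DataFrame(
        {
            "species": [p.species for p in profiles],
            "n": [p.n for p in profiles],
            "median_pdq_mm": [p.median_pdq for p in profiles],
            "median_mtcm_c": [p.median_mtcm for p in profiles],
            "min_pdq_mm": [p.min_pdq for p in profiles],
            "max_pdq_mm": [p.max_pdq for p in profiles],
            "min_mtcm_c": [p.min_mtcm for p in profiles],
            "max_mtcm_c": [p.max_mtcm for p in profiles],
            "niche_width_pdq_mm": [p.niche_width_pdq for p in profiles],
            "niche_width_mtcm_c": [p.niche_width_mtcm for p in profiles],
        }
    )
    if clusters is not None:
        df["cluster"] = [clusters.assignment[s] for s in df["species"]]
    return df
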