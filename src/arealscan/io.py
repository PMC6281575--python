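"""Tabular input handling: region geometry, adjacency, and cohort accounting.

The geometry model is deliberately minimal: one representative point per
areal unit (supplied already projected to a planar rectangular system, in
kilometres) plus an explicit undirected adjacency list.  No polygon handling
and no geodetic projection happen here — contiguity and coordinates are
inputs, exactly as a registry would supply them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "RegionMap",
    "CohortLedger",
    "load_region_map",
    "cohort_filter",
    "cohort_filter_flags",
]


@dataclass(frozen=True, eq=False)
class RegionMap:
    """Region ids, planar coordinates (km) and an undirected adjacency graph.

    ``edges`` holds unordered pairs of region ids.  The pairwise Euclidean
    distance matrix is computed once and cached.
    """

    region_ids: tuple[str, ...]
    coords: np.ndarray  # shape (n, 2), km
    edges: frozenset[frozenset]
    _dist: np.ndarray = field(init=False, repr=False, compare=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RegionMap)
            and self.region_ids == other.region_ids
            and np.array_equal(self.coords, other.coords)
            and self.edges == other.edges
        )

    def __post_init__(self) -> None:
        ids = self.region_ids
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region_id")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(ids), 2):
            raise ValueError(f"coords must be ({len(ids)}, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        known = set(ids)
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise ValueError(f"adjacency pair must join two distinct regions: {sorted(e)}")
            for rid in pair:
                if rid not in known:
                    raise ValueError(f"adjacency references unknown region_id {rid!r}")
        object.__setattr__(self, "coords", coords)
        d = cdist(coords, coords)
        np.fill_diagonal(d, 0.0)
        if np.any((d == 0) & ~np.eye(len(ids), dtype=bool)):
            warnings.warn("distinct regions with identical coordinates (zero distance)")
        object.__setattr__(self, "_dist", d)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def distances(self) -> np.ndarray:
        """Symmetric pairwise Euclidean distance matrix in km."""
        return self._dist

    def index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean n×n contiguity matrix (False diagonal)."""
        n = self.n_regions
        pos = {rid: i for i, rid in enumerate(self.region_ids)}
        a = np.zeros((n, n), dtype=bool)
        for e in self.edges:
            i, j = (pos[r] for r in tuple(e))
            a[i, j] = a[j, i] = True
        return a

    def neighbor_masks(self) -> list[int]:
        """Per-region neighbour sets as bitmasks (bit i = region_ids[i])."""
        a = self.adjacency_matrix()
        masks = []
        for i in range(self.n_regions):
            m = 0
            for j in np.flatnonzero(a[i]):
                m |= 1 << int(j)
            masks.append(m)
        return masks


def load_region_map(path_coords, path_adjacency) -> RegionMap:
    """Read ``regions.csv`` (region_id,x_km,y_km) and ``adjacency.csv``
    (region_a,region_b) into a validated :class:`RegionMap`.

    The adjacency file may list each undirected edge once, or list every
    edge in both directions; mixing the two conventions is rejected as an
    asymmetric edge list.
    """
    coords_df = pd.read_csv(path_coords, dtype={"region_id": str})
    for col in ("region_id", "x_km", "y_km"):
        if col not in coords_df.columns:
            raise ValueError(f"{path_coords}: missing column {col!r}")
    if coords_df["region_id"].duplicated().any():
        dupes = coords_df.loc[coords_df["region_id"].duplicated(), "region_id"].tolist()
        raise ValueError(f"duplicate region_id in {path_coords}: {dupes}")

    adj_df = pd.read_csv(path_adjacency, dtype=str)
    for col in ("region_a", "region_b"):
        if col not in adj_df.columns:
            raise ValueError(f"{path_adjacency}: missing column {col!r}")
    ordered = list(zip(adj_df["region_a"], adj_df["region_b"]))
    if any(a == b for a, b in ordered):
        raise ValueError("self-adjacency (region adjacent to itself)")
    seen = set(ordered)
    if len(seen) != len(ordered):
        raise ValueError("duplicate rows in adjacency list")
    reversed_present = [(b, a) in seen for a, b in ordered]
    if any(reversed_present) and not all(reversed_present):
        missing = [p for p, rev in zip(ordered, reversed_present) if not rev]
        raise ValueError(
            "asymmetric adjacency list: some edges listed in both directions, "
            f"others only once (e.g. {missing[0]})"
        )
    edges = frozenset(frozenset(p) for p in ordered)
    return RegionMap(
        region_ids=tuple(coords_df["region_id"]),
        coords=coords_df[["x_km", "y_km"]].to_numpy(dtype=float),
        edges=edges,
    )


@dataclass(frozen=True)
class CohortLedger:
    """Person-count bookkeeping for the screening cohort.

    Derived counts are computed, not supplied, so the accounting identities
    (analysed = examined − exclusions; undiagnosed = positive − tested)
    hold by construction; any negative intermediate rejects the input.
    """

    n_examined: int
    n_excluded_nonresident: int
    n_excluded_no_municipality: int
    n_positive: int
    n_confirmatory_tested: int
    n_registered: int | None = None
    n_analysed: int = field(init=False)
    n_undiagnosed_positive: int = field(init=False)

    def __post_init__(self) -> None:
        base = {
            "n_examined": self.n_examined,
            "n_excluded_nonresident": self.n_excluded_nonresident,
            "n_excluded_no_municipality": self.n_excluded_no_municipality,
            "n_positive": self.n_positive,
            "n_confirmatory_tested": self.n_confirmatory_tested,
        }
        for name, v in base.items():
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        analysed = self.n_examined - self.n_excluded_nonresident - self.n_excluded_no_municipality
        undiag = self.n_positive - self.n_confirmatory_tested
        if analysed < 0:
            raise ValueError("exclusions exceed examinees")
        if undiag < 0:
            raise ValueError("confirmatory-tested exceeds screen-positives")
        if self.n_registered is not None and self.n_registered < self.n_examined:
            raise ValueError("examined exceeds registered target population")
        object.__setattr__(self, "n_analysed", int(analysed))
        object.__setattr__(self, "n_undiagnosed_positive", int(undiag))


def cohort_filter(
    n_examined: int,
    n_excluded_nonresident: int,
    n_excluded_no_municipality: int,
    n_positive: int = 0,
    n_confirmatory_tested: int = 0,
    n_registered: int | None = None,
) -> CohortLedger:
    """Apply the cohort exclusion arithmetic and return a validated ledger."""
    return CohortLedger(
        n_examined=n_examined,
        n_excluded_nonresident=n_excluded_nonresident,
        n_excluded_no_municipality=n_excluded_no_municipality,
        n_positive=n_positive,
        n_confirmatory_tested=n_confirmatory_tested,
        n_registered=n_registered,
    )


def cohort_filter_flags(flags: pd.DataFrame, n_registered: int | None = None) -> CohortLedger:
    """Build the ledger from per-person indicator columns.

    Expected boolean columns: ``resident`` (lived in the study area at the
    reference date), ``has_municipality`` (residential municipality known),
    ``screen_positive``, ``confirmatory_tested``.  A person is analysed when
    resident and with known municipality.
    """
    for col in ("resident", "has_municipality"):
        if col not in flags.columns:
            raise ValueError(f"flags missing column {col!r}")
    resident = flags["resident"].astype(bool)
    has_mun = flags["has_municipality"].astype(bool)
    pos = flags["screen_positive"].astype(bool) if "screen_positive" in flags else pd.Series(False, index=flags.index)
    tested = flags["confirmatory_tested"].astype(bool) if "confirmatory_tested" in flags else pd.Series(False, index=flags.index)
    if (tested & ~pos).any():
        raise ValueError("confirmatory_tested set for screen-negative person")
    return CohortLedger(
        n_examined=len(flags),
        n_excluded_nonresident=int((~resident).sum()),
        # exclusions applied sequentially: municipality filter on residents only
        n_excluded_no_municipality=int((resident & ~has_mun).sum()),
        n_positive=int(pos.sum()),
        n_confirmatory_tested=int(tested.sum()),
        n_registered=n_registered,
    )
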