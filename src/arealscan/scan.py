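"""Spatial scan statistics for areal count data.

Two window families over a region map:

* **flexible** — every connected subset (under the supplied contiguity
  graph) of size ≤ K_max drawn from a seed region plus its K_max − 1
  nearest neighbours by Euclidean distance, containing the seed;
* **circular** — for each seed, the nested sets of the seed plus its
  j nearest regions, j = 0 .. K_max − 1.

For a window Z with observed count o_z and expected count e_z (grand totals
O and E), the one-sided Poisson log likelihood ratio is

    LLR(Z) = o_z ln(o_z/e_z) + (O − o_z) ln((O − o_z)/(E − e_z))

when the inside rate exceeds the outside rate, else 0 (with 0 ln 0 := 0).
The window maximising the LLR is the most likely cluster; its significance
comes from Monte Carlo replicates that re-allocate the O cases across
regions multinomially with probabilities e_i / E (the conditional null of
homogeneous risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .io import RegionMap

__all__ = [
    "ScanWindow",
    "ScanResult",
    "window_statistic",
    "enumerate_windows",
    "enumerate_windows_circular",
    "scan",
    "scan_circular",
]


@dataclass(frozen=True)
class ScanWindow:
    members: tuple[str, ...]
    observed: float
    expected: float
    llr: float
    rr_inside: float
    p_value: float | None = None


@dataclass(frozen=True)
class ScanResult:
    most_likely: ScanWindow
    secondary: tuple[ScanWindow, ...]
    p_value: float
    n_replicates: int
    mode: str
    k_max: int
    seed: int | None = None
    n_windows: int = 0

    def to_dict(self) -> dict:
        def win(w: ScanWindow) -> dict:
            return {
                "members": list(w.members),
                "observed": w.observed,
                "expected": w.expected,
                "relative_risk": w.rr_inside,
                "llr": w.llr,
                "p_value": w.p_value,
            }

        return {
            "mode": self.mode,
            "k_max": self.k_max,
            "n_replicates": self.n_replicates,
            "n_windows": self.n_windows,
            "seed": self.seed,
            "p_value": self.p_value,
            "most_likely": win(self.most_likely),
            "secondary": [win(w) for w in self.secondary],
        }


def _llr_vec(o_z, e_z, O, E):
    """Vectorised one-sided Poisson LLR; 0 where inside rate ≤ outside rate."""
    o_z = np.asarray(o_z, dtype=float)
    e_z = np.asarray(e_z, dtype=float)
    oc = O - o_z
    ec = E - e_z
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(o_z > 0, o_z * np.log(np.where(o_z > 0, o_z, 1.0) / e_z), 0.0)
        t2 = np.where(oc > 0, oc * np.log(np.where(oc > 0, oc, 1.0) / ec), 0.0)
        elevated = o_z * ec > e_z * oc  # o_z/e_z > (O-o_z)/(E-e_z), division-free
    return np.where(elevated, t1 + t2, 0.0)


def window_statistic(o_z: float, e_z: float, O: float, E_total: float) -> tuple[float, float]:
    """LLR and inside relative risk for a single window.

    Requires 0 ≤ o_z ≤ O and 0 < e_z < E_total.
    """
    if not 0 <= o_z <= O:
        raise ValueError(f"o_z must lie in [0, O]; got o_z={o_z}, O={O}")
    if not 0 < e_z < E_total:
        raise ValueError(f"e_z must lie strictly inside (0, E_total); got e_z={e_z}, E={E_total}")
    llr = float(_llr_vec(o_z, e_z, O, E_total))
    return llr, o_z / e_z


# ---------------------------------------------------------------------------
# Window enumeration (bitmask representation: bit i <-> region_ids[i])


def _candidate_order(dist_row: np.ndarray, region_ids: tuple[str, ...], seed_idx: int) -> list[int]:
    """Regions ordered by distance from the seed, ties by lexicographic id."""
    keys = sorted(range(len(region_ids)), key=lambda j: (dist_row[j], region_ids[j]))
    # seed itself always first (distance 0, but guard against coincident points)
    keys.remove(seed_idx)
    return [seed_idx] + keys


def _connected_supersets(seed_bit: int, cand_mask: int, nbr: list[int], max_size: int) -> list[int]:
    """All connected subsets of the candidate set containing the seed.

    Duplicate-free binary-partition enumeration: at each step one extension
    vertex is either included (growing the frontier by its neighbours) or
    permanently forbidden for this branch.
    """
    out = [seed_bit]
    all_mask = (1 << len(nbr)) - 1

    def neighbours_of(v_bit: int) -> int:
        return nbr[v_bit.bit_length() - 1]

    def rec(S: int, size: int, ext: int, forb: int) -> None:
        while ext:
            v = ext & -ext
            ext ^= v
            S2 = S | v
            out.append(S2)
            if size + 1 < max_size:
                ext2 = (ext | (neighbours_of(v) & cand_mask)) & ~S2 & ~forb & all_mask
                rec(S2, size + 1, ext2, forb)
            forb |= v

    if max_size > 1:
        rec(seed_bit, 1, neighbours_of(seed_bit) & cand_mask & ~seed_bit, 0)
    return out


def _flexible_masks(region_map: RegionMap, k_max: int) -> list[int]:
    n = region_map.n_regions
    if k_max > n:
        warnings.warn(f"K_max={k_max} exceeds number of regions ({n}); clamping")
        k_max = n
    if k_max < 1:
        raise ValueError("K_max must be >= 1")
    nbr = region_map.neighbor_masks()
    d = region_map.distances
    ids = region_map.region_ids
    seen: set[int] = set()
    masks: list[int] = []
    for i in range(n):
        order = _candidate_order(d[i], ids, i)
        cand = 0
        for j in order[:k_max]:
            cand |= 1 << j
        for m in _connected_supersets(1 << i, cand, nbr, k_max):
            if m not in seen:
                seen.add(m)
                masks.append(m)
    return masks


def _circular_masks(region_map: RegionMap, k_max: int) -> list[int]:
    n = region_map.n_regions
    if k_max > n:
        warnings.warn(f"K_max={k_max} exceeds number of regions ({n}); clamping")
        k_max = n
    if k_max < 1:
        raise ValueError("K_max must be >= 1")
    d = region_map.distances
    ids = region_map.region_ids
    seen: set[int] = set()
    masks: list[int] = []
    for i in range(n):
        order = _candidate_order(d[i], ids, i)
        m = 0
        for j in order[:k_max]:
            m |= 1 << j
            if m not in seen:
                seen.add(m)
                masks.append(m)
    return masks


def _mask_members(mask: int, region_ids: tuple[str, ...]) -> frozenset:
    return frozenset(region_ids[i] for i in range(len(region_ids)) if mask >> i & 1)


def enumerate_windows(region_map: RegionMap, k_max: int):
    """Yield the flexible-scan windows as frozensets of region ids."""
    for m in _flexible_masks(region_map, k_max):
        yield _mask_members(m, region_map.region_ids)


def enumerate_windows_circular(region_map: RegionMap, k_max: int):
    """Yield the circular-scan windows as frozensets of region ids."""
    for m in _circular_masks(region_map, k_max):
        yield _mask_members(m, region_map.region_ids)


# ---------------------------------------------------------------------------
# Scan proper


def _indicator_matrix(masks: list[int], n: int) -> sparse.csr_matrix:
    rows, cols = [], []
    for r, m in enumerate(masks):
        while m:
            v = m & -m
            m ^= v
            rows.append(r)
            cols.append(v.bit_length() - 1)
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(len(masks), n))


def _align(values, region_map: RegionMap) -> np.ndarray:
    if isinstance(values, pd.Series):
        v = values.reindex(list(region_map.region_ids))
        if v.isna().any():
            raise ValueError("values missing for some regions")
        return v.to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    if v.shape != (region_map.n_regions,):
        raise ValueError("values must have one entry per region")
    return v


def _best_window(masks, llr, sizes, region_ids):
    """Index of the max-LLR window; ties → smaller window, then lex members."""
    top = np.flatnonzero(llr == llr.max())
    if len(top) == 1:
        return int(top[0])
    return int(min(top, key=lambda i: (sizes[i], tuple(sorted(_mask_members(masks[i], region_ids))))))


def _scan_impl(
    o,
    e,
    region_map: RegionMap,
    masks: list[int],
    k_max: int,
    reps: int,
    seed: int,
    mode: str,
    n_secondary: int,
    rel_tol: float = 1e-6,
) -> ScanResult:
    o = _align(o, region_map)
    e = _align(e, region_map)
    O = o.sum()
    E = e.sum()
    if O == 0:
        # degenerate study: nothing to cluster
        first = min(region_map.region_ids)
        w = ScanWindow(members=(first,), observed=0.0, expected=float(e[region_map.index(first)]), llr=0.0, rr_inside=np.nan, p_value=1.0)
        return ScanResult(
            most_likely=w, secondary=(), p_value=1.0, n_replicates=reps,
            mode=mode, k_max=k_max, seed=seed, n_windows=len(masks),
        )
    if E <= 0:
        raise ValueError("total expected count must be positive")
    if abs(O - E) > rel_tol * max(O, E, 1.0):
        raise ValueError(f"scan requires sum(e) == sum(o); got O={O}, E={E}")
    if reps < 1:
        raise ValueError("need at least one Monte Carlo replicate")

    W = _indicator_matrix(masks, region_map.n_regions)
    o_z = W @ o
    e_z = W @ e
    valid = (e_z > 0) & (e_z < E)  # full-map or empty-expectation windows carry no signal
    llr = np.where(valid, _llr_vec(o_z, np.where(valid, e_z, 1.0), O, E), 0.0)
    sizes = W @ np.ones(region_map.n_regions)

    ids = region_map.region_ids
    best = _best_window(masks, llr, sizes, ids)

    # replicate maxima under the conditional multinomial null, chunked to
    # bound the (n_windows × chunk) workspace
    rng = np.random.default_rng(seed)
    probs = e / E
    rep_max = np.empty(reps)
    chunk = max(1, min(reps, int(4e6 / max(len(masks), 1)) or 1))
    done = 0
    e_z_safe = np.where(valid, e_z, 1.0)[:, None]
    while done < reps:
        c = min(chunk, reps - done)
        draws = rng.multinomial(int(round(O)), probs, size=c).T.astype(float)  # (n, c)
        OZ = W @ draws
        L = _llr_vec(OZ, e_z_safe, O, E)
        L[~valid, :] = 0.0
        rep_max[done : done + c] = L.max(axis=0)
        done += c

    def mc_p(stat: float) -> float:
        return (1 + int(np.sum(rep_max >= stat))) / (reps + 1)

    def make_window(i: int, with_p: bool = True) -> ScanWindow:
        members = tuple(sorted(_mask_members(masks[i], ids)))
        return ScanWindow(
            members=members,
            observed=float(o_z[i]),
            expected=float(e_z[i]),
            llr=float(llr[i]),
            rr_inside=float(o_z[i] / e_z[i]) if e_z[i] > 0 else np.nan,
            p_value=mc_p(float(llr[i])) if with_p else None,
        )

    most_likely = make_window(best)

    # non-overlapping secondary clusters in decreasing LLR order
    order = sorted(
        range(len(masks)),
        key=lambda i: (-llr[i], sizes[i], tuple(sorted(_mask_members(masks[i], ids)))),
    )
    secondary: list[ScanWindow] = []
    used = masks[best]
    for i in order:
        if len(secondary) >= n_secondary:
            break
        if i == best or llr[i] <= 0:
            continue
        if masks[i] & used:
            continue
        used |= masks[i]
        secondary.append(make_window(i))

    return ScanResult(
        most_likely=most_likely,
        secondary=tuple(secondary),
        p_value=most_likely.p_value,
        n_replicates=reps,
        mode=mode,
        k_max=k_max,
        seed=seed,
        n_windows=len(masks),
    )


def scan(
    o,
    e,
    region_map: RegionMap,
    k_max: int = 15,
    reps: int = 999,
    seed: int = 0,
    n_secondary: int = 5,
) -> ScanResult:
    """Flexibly shaped spatial scan: most likely cluster + Monte Carlo p."""
    masks = _flexible_masks(region_map, k_max)
    return _scan_impl(o, e, region_map, masks, min(k_max, region_map.n_regions), reps, seed, "flexible", n_secondary)


def scan_circular(
    o,
    e,
    region_map: RegionMap,
    k_max: int = 15,
    reps: int = 999,
    seed: int = 0,
    n_secondary: int = 5,
) -> ScanResult:
    """Circular (nearest-neighbour nested window) spatial scan."""
    masks = _circular_masks(region_map, k_max)
    return _scan_impl(o, e, region_map, masks, min(k_max, region_map.n_regions), reps, seed, "circular", n_secondary)
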