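"""Dense ER-alpha binding hubs from consensus ChIP-seq peak sets.

Common binding sites are the maximal genomic intervals covered simultaneously
by at least one peak from each of three cell-line peak sets (strict three-way
base-pair intersection, minimum overlap 1 bp).  Hubs are then called per
chromosome by clustering common-site midpoints with BIC-selected exact 1-D
k-means; each cluster becomes a hub spanning the extremes of its member
sites.  On real data these hubs are megabase-scale intervals where estrogen
receptor binding aggregates across cell lines — candidate long-range
regulatory anchors for rearrangement analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ckmeans1d import select_k

__all__ = ["ErHub", "common_sites", "call_hubs", "read_bed", "write_bed"]

BED_COLS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class ErHub:
    name: str
    chrom: str
    start: int
    end: int
    site_count: int

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def read_bed(path, source: str | None = None) -> pd.DataFrame:
    """Read a headerless BED3+ file into a (chrom, start, end[, source]) frame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2], names=BED_COLS, dtype={0: str})
    if (df.start >= df.end).any():
        raise ValueError(f"{path}: BED intervals must satisfy start < end")
    if source is not None:
        df["source"] = source
    return df


def write_bed(df: pd.DataFrame, path, name_col: str | None = None) -> None:
    cols = BED_COLS + ([name_col] if name_col else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def _merge(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent sorted [start, end) rows."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    iv = intervals[np.lexsort((intervals[:, 1], intervals[:, 0]))]
    out = [iv[0].tolist()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


def _intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersect two merged, sorted interval lists (two-pointer sweep)."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def common_sites(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame, peaks_c: pd.DataFrame) -> pd.DataFrame:
    """Maximal intervals covered by all three peak sets simultaneously.

    Each source is merged independently first, so the result is symmetric in
    its arguments and idempotent under re-merging.  Returns a BED-like frame
    sorted by (chrom, start).
    """
    chroms = sorted(set(peaks_a.chrom) | set(peaks_b.chrom) | set(peaks_c.chrom))
    rows = []
    for chrom in chroms:
        per = []
        for pk in (peaks_a, peaks_b, peaks_c):
            sub = pk[pk.chrom == chrom]
            per.append(_merge(sub[["start", "end"]].to_numpy(dtype=np.int64)))
        inter = _intersect(_intersect(per[0], per[1]), per[2])
        inter = _merge(inter)  # coalesce adjacent results
        for s, e in inter:
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=BED_COLS)


def call_hubs(sites: pd.DataFrame, k_range: tuple[int, int] = (1, 10)) -> list[ErHub]:
    """Aggregate common sites into hubs by per-chromosome optimal clustering.

    Chromosomes with fewer sites than the k-range lower bound yield a single
    hub with a warning.  Hubs are named H1, H2, ... in genomic order and
    never overlap within a chromosome (clusters are contiguous in sorted
    position order).
    """
    hubs = []
    for chrom, sub in sites.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"], kind="stable")
        mids = ((sub.start + sub.end) // 2).to_numpy(dtype=float)
        k_lo, k_hi = k_range
        if k_hi > mids.size:
            k_hi = mids.size
            k_lo = min(k_lo, k_hi)
        if mids.size < k_range[0]:
            warnings.warn(
                f"{chrom}: {mids.size} site(s) < k range lower bound {k_range[0]}; emitting a single hub",
                stacklevel=2,
            )
        res = select_k(mids, k_lo, k_hi)
        for c in range(res.k):
            mem = sub.iloc[np.flatnonzero(res.assignment == c)]
            hubs.append((chrom, int(mem.start.min()), int(mem.end.max()), len(mem)))
    hubs.sort(key=lambda h: (h[0], h[1]))
    return [ErHub(name=f"H{i + 1}", chrom=c, start=s, end=e, site_count=n) for i, (c, s, e, n) in enumerate(hubs)]


def hubs_frame(hubs: list[ErHub]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": h.name,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "site_count": h.site_count,
                "length_mb": h.length_mb,
            }
            for h in hubs
        ],
        columns=["name", "chrom", "start", "end", "site_count", "length_mb"],
    )
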