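"""Two-step geomapping of amplification-associated transcription coupling.

Step 1 screens every annotated gene for dosage coupling: the Pearson
correlation between its per-sample expression (log2 scale) and the copy
number of the 100-kb segment containing the gene midpoint.  Genes with
r >= 0.6 (inclusive) are called ATC loci.

Step 2 aggregates the ATC loci along each chromosome with exact optimal
univariate k-means clustering of their start positions (BIC-selected k) and
retains clusters passing three criteria: at least 15 member genes, total
span under 20 Mb, and a positional density above 1e-8 per bp.  Density is a
Gaussian kernel density estimate (Silverman bandwidth) over the chromosome's
ATC-gene positions, evaluated at member positions and maximised — a per-bp
density, which is the natural scale for a 1e-8 cutoff.

The model-style entry point is :class:`AtcGeomapper`:

>>> res = AtcGeomapper(cohort, annotation).fit()   # doctest: +SKIP
>>> print(res.summary())                           # doctest: +SKIP
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import Cohort

__all__ = [
    "AtcGeomapper",
    "AtcMapResults",
    "AtcRegion",
    "assign_gene_copynumber",
    "call_atc_regions",
    "correlate_gene",
    "log2_transform",
    "screen_atc_genes",
]


def log2_transform(expression):
    """log2(x + 1) of a raw nonnegative expression matrix or vector.

    The pseudocount keeps zero counts finite; negative input is rejected.
    """
    arr = expression.to_numpy() if hasattr(expression, "to_numpy") else np.asarray(expression, dtype=float)
    if np.nanmin(arr) < 0:
        raise ValueError("expression values must be >= 0 before log2 transformation")
    out = np.log2(arr + 1.0)
    if hasattr(expression, "to_numpy"):
        return pd.DataFrame(out, index=expression.index, columns=expression.columns)
    return out


def _segment_lookup(copy_number: pd.DataFrame):
    """Per-chromosome sorted segment starts and row indices for fast lookup."""
    lut = {}
    for chrom, sub in copy_number.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        order = np.argsort(starts, kind="stable")
        lut[chrom] = (starts[order], sub.index.to_numpy()[order], sub["end"].to_numpy()[order])
    return lut


def _segment_row_for(chrom: str, midpoint: int, lut) -> int:
    if chrom not in lut:
        raise KeyError(f"chromosome {chrom!r} absent from the copy-number segment grid")
    starts, rows, ends = lut[chrom]
    i = int(np.searchsorted(starts, midpoint, side="right")) - 1
    if 0 <= i < len(starts) and starts[i] <= midpoint < ends[i]:
        return int(rows[i])
    # midpoint falls in a gap: nearest segment on the same chromosome
    centers = (starts + ends) / 2.0
    return int(rows[int(np.argmin(np.abs(centers - midpoint)))])


def assign_gene_copynumber(gene, copy_number: pd.DataFrame, sample_cols: Sequence[str] | None = None) -> np.ndarray:
    """Per-sample copy-number vector of the segment containing the gene midpoint.

    ``gene`` is any mapping/record with chrom, start, end.  If the midpoint
    segment is missing from the grid, the nearest segment on the same
    chromosome is used.
    """
    if sample_cols is None:
        sample_cols = [c for c in copy_number.columns if c not in ("chrom", "start", "end")]
    lut = _segment_lookup(copy_number)
    mid = (int(gene["start"]) + int(gene["end"])) // 2
    row = _segment_row_for(str(gene["chrom"]), mid, lut)
    return copy_number.loc[row, list(sample_cols)].to_numpy(dtype=float)


def correlate_gene(expression: np.ndarray, copy_number: np.ndarray) -> float:
    """Pearson r between paired per-sample expression and copy number.

    Missing values are removed pairwise; fewer than 3 complete pairs or a
    zero-variance vector yields NaN (the undefined marker, excluded
    downstream).
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(copy_number, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and copy-number vectors must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def screen_atc_genes(cohort: "Cohort", genes: pd.DataFrame, r_threshold: float = 0.6) -> pd.DataFrame:
    """Screen genes for dosage coupling; keep those with r >= r_threshold.

    Returns the annotation columns plus ``r``, sorted by chromosome then
    start.  The threshold is inclusive.  Genes absent from the expression
    matrix, or with undefined correlation (zero variance, too few pairs),
    are dropped.
    """
    expr = cohort.expression
    cn = cohort.copy_number
    sample_cols = cohort.samples
    lut = _segment_lookup(cn)
    cn_vals = cn[sample_cols].to_numpy(dtype=float)

    present = genes[genes.gene_id.isin(expr.index)].reset_index(drop=True)
    if len(present) == 0:
        out = genes.iloc[0:0].copy()
        out["r"] = pd.Series(dtype=float)
        return out
    rows = np.array(
        [
            _segment_row_for(str(g.chrom), (int(g.start) + int(g.end)) // 2, lut)
            for g in present.itertuples()
        ]
    )
    # copy_number row labels equal positional indices after construction;
    # map labels to positions defensively
    pos_of_label = {lab: i for i, lab in enumerate(cn.index)}
    seg = cn_vals[[pos_of_label[r] for r in rows], :]
    e = expr.loc[present.gene_id].to_numpy(dtype=float)

    ec = e - e.mean(axis=1, keepdims=True)
    sc = seg - seg.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", ec, sc)
    den = np.sqrt(np.einsum("ij,ij->i", ec, ec) * np.einsum("ij,ij->i", sc, sc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)

    out = present.copy()
    out["r"] = r
    out = out[np.isfinite(out.r) & (out.r >= r_threshold)]
    return out.sort_values(["chrom", "start", "gene_id"], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class AtcRegion:
    """A genomic cluster of ATC loci passing the three selection criteria."""

    name: str
    chrom: str
    start: int  # min of member gene starts
    end: int  # max of member gene ends
    members: tuple[str, ...]  # gene ids in genomic order
    gene_count: int
    span_mb: float
    density: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "gene_count": self.gene_count,
            "span_mb": self.span_mb,
            "density": self.density,
            "members": ",".join(self.members),
        }


def _chromosome_density(positions: np.ndarray):
    """Silverman-bandwidth Gaussian KDE over ATC-gene positions (per bp).

    Degenerate inputs (fewer than 2 points or zero spread) cannot support a
    KDE; they return +inf for coincident points (infinitely dense) which the
    gene-count criterion then arbitrates.
    """
    if positions.size < 2 or np.ptp(positions) == 0:
        return lambda p: np.full(np.asarray(p, dtype=float).shape, np.inf)
    kde = stats.gaussian_kde(positions.astype(float), bw_method="silverman")
    return lambda p: kde(np.asarray(p, dtype=float))


def call_atc_regions(
    atc_genes: pd.DataFrame,
    min_genes: int = 15,
    max_span_mb: float = 20.0,
    min_density: float = 1e-8,
    k_range: tuple[int, int] = (1, 10),
) -> list[AtcRegion]:
    """Aggregate ATC loci into regions by optimal 1-D clustering + criteria.

    Per chromosome, gene start positions are clustered with BIC-selected
    exact k-means over ``k_range`` (upper bound clamped to the gene count
    with a warning); every cluster becomes a candidate region spanning the
    min start to max end of its members.  Candidates are retained when
    gene_count >= min_genes, span < max_span_mb (strict), and density >
    min_density (strict).  Regions are named A, B, C, ... in genomic order.
    """
    from .ckmeans1d import select_k

    if len(atc_genes) == 0:
        return []
    candidates = []
    for chrom, sub in atc_genes.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "gene_id"], kind="stable")
        pos = sub.start.to_numpy(dtype=float)
        k_lo, k_hi = k_range
        if k_hi > pos.size:
            warnings.warn(
                f"k range upper bound {k_hi} exceeds ATC gene count {pos.size} on {chrom}; clamping",
                stacklevel=2,
            )
            k_hi = pos.size
            k_lo = min(k_lo, k_hi)
        res = select_k(pos, k_lo, k_hi)
        dens = _chromosome_density(pos)
        labels = res.assignment
        for c in range(res.k):
            mem = sub.iloc[np.flatnonzero(labels == c)]
            start = int(mem.start.min())
            end = int(mem.end.max())
            candidates.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "members": tuple(mem.gene_id),
                    "gene_count": len(mem),
                    "span_mb": (end - start) / 1e6,
                    "density": float(np.max(dens(mem.start.to_numpy()))),
                }
            )
    kept = [
        c
        for c in candidates
        if c["gene_count"] >= min_genes and c["span_mb"] < max_span_mb and c["density"] > min_density
    ]
    kept.sort(key=lambda c: (c["chrom"], c["start"]))
    names = _region_names(len(kept))
    return [AtcRegion(name=names[i], **kept[i]) for i in range(len(kept))]


def _region_names(n: int) -> list[str]:
    # A..Z then A1, B1, ... for improbable overflow
    base = [chr(ord("A") + i) for i in range(26)]
    names = []
    for i in range(n):
        q, r = divmod(i, 26)
        names.append(base[r] if q == 0 else f"{base[r]}{q}")
    return names


class AtcGeomapper:
    """Two-step geomapping model over a cohort and a gene annotation.

    Parameters
    ----------
    cohort : Cohort
        Aligned expression (log2), segmented copy number and metadata.
    annotation : pd.DataFrame
        Gene table with gene_id, chrom, start, end, strand.
    """

    def __init__(self, cohort: "Cohort", annotation: pd.DataFrame) -> None:
        self.cohort = cohort
        self.annotation = annotation

    def fit(
        self,
        r_threshold: float = 0.6,
        min_genes: int = 15,
        max_span_mb: float = 20.0,
        min_density: float = 1e-8,
        k_range: tuple[int, int] = (1, 10),
    ) -> "AtcMapResults":
        atc_genes = screen_atc_genes(self.cohort, self.annotation, r_threshold=r_threshold)
        regions = call_atc_regions(
            atc_genes,
            min_genes=min_genes,
            max_span_mb=max_span_mb,
            min_density=min_density,
            k_range=k_range,
        )
        params = {
            "r_threshold": r_threshold,
            "min_genes": min_genes,
            "max_span_mb": max_span_mb,
            "min_density": min_density,
            "k_range": k_range,
        }
        return AtcMapResults(model=self, atc_genes=atc_genes, regions=regions, params=params)


@dataclass
class AtcMapResults:
    """Fitted geomapping results: the ATC gene table and called regions."""

    model: AtcGeomapper
    atc_genes: pd.DataFrame
    regions: list[AtcRegion]
    params: dict = field(default_factory=dict)

    def regions_frame(self) -> pd.DataFrame:
        cols = ["name", "chrom", "start", "end", "gene_count", "span_mb", "density", "members"]
        if not self.regions:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([r.as_dict() for r in self.regions])[cols]

    def summary(self) -> str:
        n_genes = len(self.model.annotation)
        lines = [
            "ATC geomapping results",
            "=" * 54,
            f"samples:              {self.model.cohort.n_samples}",
            f"genes screened:       {n_genes}",
            f"ATC loci (r >= {self.params.get('r_threshold', 0.6):g}): {len(self.atc_genes)}",
            f"ATC regions retained: {len(self.regions)}",
            "-" * 54,
        ]
        for r in self.regions:
            # 1-based inclusive coordinates for the human-readable report
            lines.append(
                f"  {r.name}  {r.chrom}:{r.start + 1:,}-{r.end:,}  "
                f"genes={r.gene_count}  span={r.span_mb:.2f} Mb  density={r.density:.3g}"
            )
        return "\n".join(lines)
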