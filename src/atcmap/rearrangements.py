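"""Rearrangement ingestion, filtering, classification and link counting.

Paired-breakpoint structural-variant calls (BreakDancer-style TSV or BEDPE)
are filtered on caller confidence (score strictly > 80 by default), split
into inter- vs intra-chromosomal strata, and tallied against "bait" genomic
regions: an event contributes to a bait if either breakpoint falls inside
it, and its partner breakpoint is binned either into 1-Mb genome bins
(Circos-style link tables) or into dense ER-alpha binding hubs.  Per-sample
group contrasts (e.g. ER-positive vs ER-negative event counts) use the
Mann-Whitney U test.

Coordinates are 0-based half-open internally; BreakDancer positions are
converted from 1-based on read and back on write.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EVENT_COLS",
    "LinkMatrix",
    "classify_event",
    "classify_events",
    "compare_groups",
    "count_links",
    "filter_events",
    "hub_link_matrix",
    "read_events",
    "write_events",
]

EVENT_COLS = [
    "sample",
    "chrom1",
    "pos1",
    "orient1",
    "chrom2",
    "pos2",
    "orient2",
    "svtype",
    "size",
    "score",
    "n_reads",
]

_BD_COLS = ["chrom1", "pos1", "orient1", "chrom2", "pos2", "orient2", "svtype", "size", "score", "n_reads", "sample"]


def read_events(path, format: str = "breakdancer") -> pd.DataFrame:
    """Read rearrangement calls into the canonical event frame.

    ``format="breakdancer"``: whitespace-separated columns (chr1, pos1,
    orient1, chr2, pos2, orient2, type, size, score, num_reads, sample),
    '#'-prefixed header/comment lines skipped, positions 1-based in the file.

    ``format="bedpe"``: 10-column BEDPE (chrom1 start1 end1 chrom2 start2
    end2 name score strand1 strand2) with optional extra columns svtype and
    n_reads; the name field carries the sample id; positions 0-based.
    """
    if format == "breakdancer":
        try:
            df = pd.read_csv(
                path,
                sep=r"\s+",
                comment="#",
                header=None,
                names=_BD_COLS,
                dtype={"chrom1": str, "chrom2": str, "sample": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"{path}: malformed BreakDancer-style file: {exc}") from exc
        if len(df) == 0:
            return pd.DataFrame(columns=EVENT_COLS)
        df["pos1"] = df["pos1"].astype(np.int64) - 1
        df["pos2"] = df["pos2"].astype(np.int64) - 1
        return df[EVENT_COLS].reset_index(drop=True)
    if format == "bedpe":
        names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "sample", "score", "orient1", "orient2", "svtype", "n_reads"]
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                dtype={0: str, 3: str, 6: str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValueError(f"{path}: malformed BEDPE file: {exc}") from exc
        if len(df) == 0:
            return pd.DataFrame(columns=EVENT_COLS)
        if df.shape[1] < 10:
            raise ValueError(f"{path}: BEDPE needs >= 10 columns, found {df.shape[1]}")
        df = df.iloc[:, : len(names)]
        df.columns = names[: df.shape[1]]
        if "svtype" not in df.columns:
            df["svtype"] = np.where(df.chrom1.astype(str) == df.chrom2.astype(str), "ITX", "CTX")
        if "n_reads" not in df.columns:
            df["n_reads"] = 0
        out = pd.DataFrame(
            {
                "sample": df["sample"].astype(str),
                "chrom1": df.chrom1.astype(str),
                "pos1": df.start1.astype(np.int64),
                "orient1": df.orient1,
                "chrom2": df.chrom2.astype(str),
                "pos2": df.start2.astype(np.int64),
                "orient2": df.orient2,
                "svtype": df.svtype,
                "size": np.abs(df.start2.astype(np.int64) - df.start1.astype(np.int64)),
                "score": df.score.astype(float),
                "n_reads": df.n_reads.astype(np.int64),
            }
        )
        return out
    raise ValueError(f"unknown rearrangement format {format!r} (use 'breakdancer' or 'bedpe')")


def write_events(events: pd.DataFrame, path, format: str = "breakdancer") -> None:
    """Write the canonical event frame as BreakDancer-style TSV or BEDPE."""
    ev = events.copy()
    if format == "breakdancer":
        ev["pos1"] = ev.pos1.astype(np.int64) + 1
        ev["pos2"] = ev.pos2.astype(np.int64) + 1
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(["Chr1", "Pos1", "Orientation1", "Chr2", "Pos2", "Orientation2", "Type", "Size", "Score", "num_Reads", "Sample"]) + "\n")
            ev[_BD_COLS].to_csv(fh, sep="\t", header=False, index=False, float_format="%.2f")
        return
    if format == "bedpe":
        out = pd.DataFrame(
            {
                "chrom1": ev.chrom1,
                "start1": ev.pos1.astype(np.int64),
                "end1": ev.pos1.astype(np.int64) + 1,
                "chrom2": ev.chrom2,
                "start2": ev.pos2.astype(np.int64),
                "end2": ev.pos2.astype(np.int64) + 1,
                "name": ev["sample"],
                "score": ev.score,
                "strand1": ev.orient1,
                "strand2": ev.orient2,
                "svtype": ev.svtype,
                "n_reads": ev.n_reads.astype(np.int64),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.2f")
        return
    raise ValueError(f"unknown rearrangement format {format!r}")


def filter_events(events: pd.DataFrame, min_score: float = 80.0) -> pd.DataFrame:
    """Keep events with confidence score strictly greater than min_score."""
    return events[events.score > min_score].reset_index(drop=True)


def classify_event(event) -> str:
    """'intra' iff both breakpoints share a chromosome, else 'inter'."""
    return "intra" if str(event["chrom1"]) == str(event["chrom2"]) else "inter"


def classify_events(events: pd.DataFrame) -> pd.Series:
    """Vectorised inter/intra classification of an event frame."""
    return pd.Series(
        np.where(events.chrom1.astype(str).to_numpy() == events.chrom2.astype(str).to_numpy(), "intra", "inter"),
        index=events.index,
        name="stratum",
    )


@dataclass
class LinkMatrix:
    """Bait x partner-bin rearrangement counts, stratified and per sample.

    ``counts`` is a long-format frame with columns (bait, partner_chrom,
    partner_bin, stratum, sample, count); ``partner_bin`` is the 0-based
    index of the enclosing bin (1-Mb by default) for genome-binned matrices,
    or -1 with ``partner_chrom`` holding the hub name (or "non_hub") for
    hub matrices.
    """

    counts: pd.DataFrame
    bait_names: tuple[str, ...]
    bin_bp: int | None  # None for hub-partner matrices

    def total(self) -> int:
        return int(self.counts["count"].sum())

    def pooled(self, stratum: str | None = None) -> pd.DataFrame:
        """Bait x partner pivot, pooled over samples (optionally one stratum)."""
        df = self.counts
        if stratum is not None:
            df = df[df.stratum == stratum]
        if self.bin_bp is not None:
            piv = df.pivot_table(
                index="bait", columns=["partner_chrom", "partner_bin"], values="count", aggfunc="sum", fill_value=0
            )
        else:
            piv = df.pivot_table(index="bait", columns="partner_chrom", values="count", aggfunc="sum", fill_value=0)
        return piv.reindex(list(self.bait_names), fill_value=0)

    def per_sample_totals(self) -> pd.Series:
        return self.counts.groupby("sample")["count"].sum()

    def to_circos_links(self, baits) -> pd.DataFrame:
        """Circos-style link table: chrA startA endA chrB startB endB count."""
        if self.bin_bp is None:
            raise ValueError("hub-partner matrices have no genomic partner bins")
        lookup = {b.name: b for b in baits}
        rows = []
        pooled = self.counts.groupby(["bait", "partner_chrom", "partner_bin"], as_index=False)["count"].sum()
        for rec in pooled.itertuples():
            b = lookup[rec.bait]
            s = int(rec.partner_bin) * self.bin_bp
            rows.append((b.chrom, b.start, b.end, rec.partner_chrom, s, s + self.bin_bp, int(rec.count)))
        return pd.DataFrame(rows, columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "count"])


def _bait_hit(chrom: str, pos: int, baits: Sequence) -> str | None:
    for b in baits:
        if chrom == b.chrom and b.start <= pos < b.end:
            return b.name
    return None


def _check_baits(baits: Sequence) -> None:
    by_chrom: dict[str, list] = {}
    for b in baits:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end, b.name))
    for chrom, iv in by_chrom.items():
        iv.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(iv, iv[1:]):
            if s2 < e1:
                raise ValueError(f"baits {n1} and {n2} overlap on {chrom}")


def _accumulate(events: pd.DataFrame, baits: Sequence, partner_of) -> list[tuple]:
    """Shared counting rule for genome-bin and hub partner assignment.

    An event contributes once per bait containing a breakpoint; the other
    end is the partner.  Both ends in the *same* bait -> a single intra
    count (partner = end 2).  Ends in two different baits -> one count for
    each bait.
    """
    incid = []
    strat = classify_events(events)
    for i, ev in enumerate(events.itertuples()):
        b1 = _bait_hit(str(ev.chrom1), int(ev.pos1), baits)
        b2 = _bait_hit(str(ev.chrom2), int(ev.pos2), baits)
        stratum = strat.iloc[i]
        if b1 is not None and b1 == b2:
            incid.append((b1, *partner_of(str(ev.chrom2), int(ev.pos2)), "intra", ev.sample))
            continue
        if b1 is not None:
            incid.append((b1, *partner_of(str(ev.chrom2), int(ev.pos2)), stratum, ev.sample))
        if b2 is not None:
            incid.append((b2, *partner_of(str(ev.chrom1), int(ev.pos1)), stratum, ev.sample))
    return incid


def _to_matrix(incid: list[tuple], baits: Sequence, bin_bp: int | None) -> LinkMatrix:
    cols = ["bait", "partner_chrom", "partner_bin", "stratum", "sample"]
    if incid:
        df = pd.DataFrame(incid, columns=cols)
        df = df.groupby(cols, as_index=False).size().rename(columns={"size": "count"})
        df = df.sort_values(cols, kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(columns=cols + ["count"])
    return LinkMatrix(counts=df, bait_names=tuple(b.name for b in baits), bin_bp=bin_bp)


def count_links(
    events: pd.DataFrame,
    baits: Sequence,
    bin_mb: float = 1.0,
    chrom_sizes: dict[str, int] | None = None,
) -> LinkMatrix:
    """Count filtered events against bait regions at ``bin_mb`` resolution.

    Bins are anchored at coordinate 0 of each chromosome.  With
    ``chrom_sizes`` given, breakpoints beyond the chromosome end are clamped
    into the last bin (with a warning).
    """
    _check_baits(baits)
    bin_bp = int(round(bin_mb * 1e6))

    import warnings as _warnings

    def partner_of(chrom: str, pos: int):
        b = pos // bin_bp
        if chrom_sizes is not None and chrom in chrom_sizes:
            last = (chrom_sizes[chrom] - 1) // bin_bp
            if b > last:
                _warnings.warn(f"breakpoint {chrom}:{pos} beyond chromosome length; clamped", stacklevel=2)
                b = last
        return (chrom, int(b))

    return _to_matrix(_accumulate(events, baits, partner_of), baits, bin_bp)


def hub_link_matrix(events: pd.DataFrame, baits: Sequence, hubs: Sequence) -> LinkMatrix:
    """Count events against baits with partner ends assigned to ER hubs.

    Partners falling in no hub land in the "non_hub" column.
    """
    _check_baits(baits)

    def partner_of(chrom: str, pos: int):
        for h in hubs:
            if chrom == h.chrom and h.start <= pos < h.end:
                return (h.name, -1)
        return ("non_hub", -1)

    return _to_matrix(_accumulate(events, baits, partner_of), baits, None)


class GroupComparison(NamedTuple):
    statistic: float  # Mann-Whitney U of the first group
    pvalue: float
    group_a: str
    group_b: str
    n_a: int
    n_b: int


def compare_groups(counts, labels) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of per-sample counts by group.

    Uses exact enumeration when both groups have <= 10 samples, otherwise
    the normal approximation with tie correction.  Exactly two group labels
    are required and both groups must be nonempty.
    """
    counts = pd.Series(np.asarray(counts, dtype=float))
    labels = pd.Series(list(labels))
    if len(counts) != len(labels):
        raise ValueError("counts and labels must align")
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"expected exactly two groups, got {uniq}")
    a = counts[labels.to_numpy() == uniq[0]].to_numpy()
    b = counts[labels.to_numpy() == uniq[1]].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if (len(a) <= 10 and len(b) <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(float(res.statistic), float(res.pvalue), str(uniq[0]), str(uniq[1]), len(a), len(b))
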