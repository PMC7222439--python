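"""Synthetic breast-tumor-like cohort generator with planted ground truth.

Every downstream stage of the package is exercised against cohorts produced
here: gene annotation, expression, 100-kb segmented copy number, sample
metadata, paired-breakpoint rearrangements and three ChIP-seq peak sets,
together with a manifest recording exactly what was planted.

The generative model:

* **Copy number** — segments start diploid (value 0; positive = amplified).
  Each planted region gains, per sample, with probability ``cn_gain_prob``
  a single amplitude drawn uniform(0.3, 1.5) applied to every segment it
  covers; background segments gain independently with a small probability.
* **Expression** (log2 scale, emitted raw as 2^y - 1) — planted "coupled"
  genes follow baseline + dosage_slope x copy_number + N(0, expr_noise_sd);
  background genes are independent of copy number but share a weak latent
  factor (``background_corr_sd``) so background co-expression exists.
* **Rearrangements** — for ER-positive samples a fraction
  ``hub_targeting_fraction`` of events puts one breakpoint uniformly inside
  a bait region and the other inside a hub; everything else lands uniformly
  on the genome.  Per-sample event counts are Poisson, with the ER-negative
  mean reduced by ``er_rate_ratio``.  Confidence scores place a configurable
  fraction at <= 80 to exercise the quality filter.
* **Peaks** — each planted hub carries shared binding sites jittered
  +/-200 bp per pseudo cell line, plus line-specific uniform noise peaks,
  so the three-way intersection isolates the hubs.
* **Survival** — exponential with hazard = baseline x
  exp(atc_hazard_coef x standardized cumulative ATC score), independently
  exponentially censored at a rate tuned to ``censor_rate``.

Everything is reproducible from the seed alone; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cio
from .rearrangements import EVENT_COLS, write_events

__all__ = ["PlantedRegion", "SimConfig", "CohortBundle", "simulate_cohort", "simulate_rearrangements"]

PEAK_SOURCES = ("lineA", "lineB", "lineC")  # pseudonyms for the three cell lines


class PlantedRegion(NamedTuple):
    chrom: str
    start: int
    end: int
    dosage_slope: float
    n_genes: int


class PlantedHub(NamedTuple):
    chrom: str
    start: int
    end: int


def _default_genome():
    return [("chr1", 80_000_000), ("chr2", 60_000_000)]


def _default_regions():
    return [
        PlantedRegion("chr1", 10_000_000, 18_000_000, 0.8, 30),
        PlantedRegion("chr1", 45_000_000, 53_000_000, 0.8, 30),
        PlantedRegion("chr2", 20_000_000, 28_000_000, 0.8, 30),
    ]


def _default_hubs():
    mb = 1_000_000
    spans = {"chr1": [2, 22, 34, 58, 70], "chr2": [2, 12, 33, 44, 54]}
    return [PlantedHub(c, s * mb, (s + 2) * mb) for c, starts in spans.items() for s in starts]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort; defaults are the baseline."""

    seed: int = 0
    n_samples: int = 200
    genome: list = field(default_factory=_default_genome)
    n_genes: int = 1000
    planted_regions: list = field(default_factory=_default_regions)
    background_corr_sd: float = 0.3
    expr_noise_sd: float = 0.5
    cn_gain_prob: float = 0.5
    er_positive_fraction: float = 0.6
    n_events_per_sample: float = 20
    hub_targeting_fraction: float = 0.7
    planted_hubs: list = field(default_factory=_default_hubs)
    peak_width_bp: int = 500
    survival_baseline_hazard: float = 1.0 / 1500.0  # per day
    atc_hazard_coef: float = 0.5
    censor_rate: float = 0.3
    # plumbing beyond the headline knobs
    er_rate_ratio: float = 3.0  # ER+ event rate / ER- event rate
    sub80_score_fraction: float = 0.2  # fraction of events with score <= 80
    background_cn_gain_prob: float = 0.05
    gene_length_bp: int = 10_000
    segment_bp: int = 100_000
    sites_per_hub: int = 8
    noise_peaks_per_line: int = 50
    peak_jitter_bp: int = 200

    def __post_init__(self) -> None:
        self.genome = [(str(c), int(n)) for c, n in self.genome]
        self.planted_regions = [PlantedRegion(str(r[0]), int(r[1]), int(r[2]), float(r[3]), int(r[4])) for r in self.planted_regions]
        self.planted_hubs = [PlantedHub(str(h[0]), int(h[1]), int(h[2])) for h in self.planted_hubs]
        sizes = dict(self.genome)
        for frac in (self.cn_gain_prob, self.er_positive_fraction, self.hub_targeting_fraction, self.censor_rate, self.sub80_score_fraction, self.background_cn_gain_prob):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1]; got {frac}")
        by_chrom: dict[str, list] = {}
        for r in self.planted_regions:
            if r.chrom not in sizes or not (0 <= r.start < r.end <= sizes[r.chrom]):
                raise ValueError(f"planted region {r} outside chromosome bounds")
            if r.n_genes * 10_000 > (r.end - r.start):
                raise ValueError(f"region {r.chrom}:{r.start}-{r.end} cannot hold {r.n_genes} genes at >= 1 gene / 10 kb")
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for chrom, iv in by_chrom.items():
            iv.sort()
            for (s1, e1), (s2, _) in zip(iv, iv[1:]):
                if s2 < e1:
                    raise ValueError(f"planted regions overlap on {chrom}")
        for h in self.planted_hubs:
            if h.chrom not in sizes or not (0 <= h.start < h.end <= sizes[h.chrom]):
                raise ValueError(f"planted hub {h} outside chromosome bounds")
        total_planted = sum(r.n_genes for r in self.planted_regions)
        if total_planted > self.n_genes:
            raise ValueError("more planted member genes than n_genes")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class CohortBundle:
    """All generated tables plus the ground-truth manifest."""

    annotation: pd.DataFrame
    expression_raw: pd.DataFrame  # genes x samples, raw RSEM-like scale
    copy_number: pd.DataFrame  # chrom, start, end, <samples>
    metadata: pd.DataFrame  # indexed by sample
    events: pd.DataFrame
    peaks: dict  # source -> BED-like frame
    manifest: dict

    def write(self, outdir) -> dict:
        """Write every table as plain text under ``outdir``; returns paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": out / "annotation.tsv",
            "expression": out / "expression.tsv",
            "copy_number": out / "copy_number.tsv",
            "metadata": out / "metadata.tsv",
            "events_breakdancer": out / "rearrangements.breakdancer.tsv",
            "events_bedpe": out / "rearrangements.bedpe",
            "manifest": out / "manifest.yaml",
        }
        cio.write_annotation(self.annotation, paths["annotation"])
        cio.write_expression(self.expression_raw, paths["expression"])
        cio.write_copy_number(self.copy_number, paths["copy_number"])
        cio.write_metadata(self.metadata, paths["metadata"])
        write_events(self.events, paths["events_breakdancer"], format="breakdancer")
        write_events(self.events, paths["events_bedpe"], format="bedpe")
        for src, pk in self.peaks.items():
            paths[f"peaks_{src}"] = out / f"peaks_{src}.bed"
            pk[["chrom", "start", "end"]].to_csv(paths[f"peaks_{src}"], sep="\t", header=False, index=False)
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(_plain(self.manifest), fh, sort_keys=True, default_flow_style=False)
        return paths


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    glen = cfg.gene_length_bp
    rows = []
    for ri, reg in enumerate(cfg.planted_regions):
        starts = np.sort(rng.integers(reg.start, reg.end - glen, size=reg.n_genes))
        for s in starts:
            rows.append((reg.chrom, int(s), int(s) + glen, ri))
    n_bg = cfg.n_genes - sum(r.n_genes for r in cfg.planted_regions)
    names = [c for c, _ in cfg.genome]
    lengths = np.array([n for _, n in cfg.genome], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_bg, p=lengths / lengths.sum())
    for ci in chrom_idx:
        s = int(rng.integers(0, cfg.genome[ci][1] - glen))
        rows.append((names[ci], s, s + glen, -1))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_idx"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    width = len(str(len(df)))
    df.insert(0, "gene_id", [f"G{i + 1:0{width}d}" for i in range(len(df))])
    df["strand"] = np.where(rng.random(len(df)) < 0.5, "+", "-")
    return df


def _segment_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, length in cfg.genome:
        starts = np.arange(0, length, cfg.segment_bp, dtype=np.int64)
        ends = np.minimum(starts + cfg.segment_bp, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def simulate_cohort(config: SimConfig) -> CohortBundle:
    """Generate the full synthetic cohort bundle from ``config``.

    Deterministic in ``config.seed``; see the module docstring for the
    generative model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]

    ann = _place_genes(cfg, rng)
    segs = _segment_frame(cfg)

    # --- copy number ---------------------------------------------------
    cn = np.zeros((len(segs), cfg.n_samples))
    seg_chrom = segs.chrom.to_numpy()
    seg_start = segs.start.to_numpy()
    seg_end = segs.end.to_numpy()
    region_amp = np.zeros((len(cfg.planted_regions), cfg.n_samples))
    in_any_region = np.zeros(len(segs), dtype=bool)
    for ri, reg in enumerate(cfg.planted_regions):
        gained = rng.random(cfg.n_samples) < cfg.cn_gain_prob
        amp = np.where(gained, rng.uniform(0.3, 1.5, size=cfg.n_samples), 0.0)
        region_amp[ri] = amp
        mask = (seg_chrom == reg.chrom) & (seg_end > reg.start) & (seg_start < reg.end)
        in_any_region |= mask
        cn[mask, :] = amp[None, :]
    bg = ~in_any_region
    bg_gain = (rng.random((int(bg.sum()), cfg.n_samples)) < cfg.background_cn_gain_prob)
    bg_amp = np.where(bg_gain, rng.uniform(0.3, 1.5, size=bg_gain.shape), 0.0)
    cn[bg, :] = bg_amp
    copy_number = pd.concat([segs, pd.DataFrame(cn, columns=samples)], axis=1)

    # --- expression (log2 scale, emitted raw) --------------------------
    n_genes = len(ann)
    baseline = rng.uniform(3.0, 8.0, size=n_genes)
    latent = rng.standard_normal(cfg.n_samples)
    noise = rng.standard_normal((n_genes, cfg.n_samples)) * cfg.expr_noise_sd
    log2e = baseline[:, None] + noise
    region_idx = ann.region_idx.to_numpy()
    coupled = region_idx >= 0
    for ri, reg in enumerate(cfg.planted_regions):
        gmask = region_idx == ri
        log2e[gmask, :] += reg.dosage_slope * region_amp[ri][None, :]
    log2e[~coupled, :] += cfg.background_corr_sd * latent[None, :]
    log2e = np.maximum(log2e, 0.0)
    expression_raw = pd.DataFrame(np.exp2(log2e) - 1.0, index=ann.gene_id, columns=samples)

    # --- metadata: ER status, subtype, survival ------------------------
    er_pos = rng.random(cfg.n_samples) < cfg.er_positive_fraction
    subtype = np.where(
        er_pos,
        np.where(rng.random(cfg.n_samples) < 0.6, "LumA", "LumB"),
        np.where(rng.random(cfg.n_samples) < 0.7, "Basal", "Her2"),
    )
    coupled_ids = ann.gene_id[coupled]
    sub = log2e[coupled, :]
    sd = sub.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (sub - sub.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    score = z.sum(axis=0)
    times, observed = simulate_survival(score, cfg, rng)
    metadata = pd.DataFrame(
        {
            "er_status": np.where(er_pos, "positive", "negative"),
            "subtype": subtype,
            "os_days": times,
            "os_event": observed,
        },
        index=pd.Index(samples, name="sample"),
    )

    # --- rearrangements and peaks --------------------------------------
    events = simulate_rearrangements(cfg, cfg.planted_regions, cfg.planted_hubs, metadata=metadata, rng=rng)
    peaks, hub_sites = _simulate_peaks(cfg, rng)

    manifest = {
        "seed": cfg.seed,
        "samples": samples,
        "planted_regions": [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "dosage_slope": r.dosage_slope,
                "n_genes": r.n_genes,
                "member_genes": list(ann.gene_id[region_idx == ri]),
                # detectable ground-truth boundary: the span of the planted
                # member genes (the configured interval includes gene-free
                # flanks that no screen can recover, even noise-free)
                "member_span": [
                    int(ann.start[region_idx == ri].min()),
                    int(ann.end[region_idx == ri].max()),
                ],
            }
            for ri, r in enumerate(cfg.planted_regions)
        ],
        "planted_hubs": [
            {
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "n_sites": len(hub_sites[hi]),
                # detectable ground truth: extent of the planted binding
                # sites themselves (the container interval has site-free
                # flanks no consensus caller can see)
                "site_span": [
                    int(hub_sites[hi].min()) - cfg.peak_width_bp // 2,
                    int(hub_sites[hi].max()) + cfg.peak_width_bp // 2,
                ],
            }
            for hi, h in enumerate(cfg.planted_hubs)
        ],
        "coupled_genes": list(coupled_ids),
        "n_events": int(len(events)),
        "config": _plain(asdict(cfg)),
    }
    return CohortBundle(
        annotation=ann[cio.ANNOTATION_COLS],
        expression_raw=expression_raw,
        copy_number=copy_number,
        metadata=metadata,
        events=events,
        peaks=peaks,
        manifest=manifest,
    )


def simulate_survival(score: np.ndarray, cfg: SimConfig, rng: np.random.Generator):
    """Exponential survival driven by the standardized ATC score.

    hazard_i = baseline x exp(coef x z_i); censoring is an independent
    exponential whose rate gives censoring probability ``censor_rate`` for
    an average (z = 0) subject.  Returns (times_days, event_flags).
    """
    score = np.asarray(score, dtype=float)
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    hazard = cfg.survival_baseline_hazard * np.exp(cfg.atc_hazard_coef * z)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censor_rate > 0:
        c_rate = cfg.survival_baseline_hazard * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=score.size)
    else:
        t_cens = np.full(score.size, np.inf)
    times = np.minimum(t_event, t_cens)
    observed = (t_event <= t_cens).astype(int)
    return np.round(times + 1.0, 1), observed  # +1 day floor keeps times > 0


def _as_interval(obj):
    if hasattr(obj, "chrom"):
        return (str(obj.chrom), int(obj.start), int(obj.end))
    c, s, e = obj[0], obj[1], obj[2]
    return (str(c), int(s), int(e))


def simulate_rearrangements(
    config: SimConfig,
    regions: Sequence,
    hubs: Sequence,
    metadata: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate paired-breakpoint events; see module docstring for the model.

    ``regions``/``hubs`` accept anything with chrom/start/end attributes or
    (chrom, start, end) triples.  ``metadata`` supplies per-sample ER status
    (drawn from the config when omitted).
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    baits = [_as_interval(r) for r in regions]
    hubiv = [_as_interval(h) for h in hubs]
    if cfg.hub_targeting_fraction > 0 and (not baits or not hubiv):
        raise ValueError("hub_targeting_fraction > 0 requires nonempty regions and hubs")
    sizes = dict(cfg.genome)
    for name, s, e in baits + hubiv:
        if name not in sizes or not (0 <= s < e <= sizes[name]):
            raise ValueError(f"interval {name}:{s}-{e} outside genome bounds")
    if metadata is None:
        samples = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
        er_pos = rng.random(cfg.n_samples) < cfg.er_positive_fraction
    else:
        samples = list(metadata.index)
        er_pos = (metadata.er_status == "positive").to_numpy()

    names = [c for c, _ in cfg.genome]
    lengths = np.array([n for _, n in cfg.genome], dtype=float)
    probs = lengths / lengths.sum()

    rows = []
    for si, sample in enumerate(samples):
        mean = cfg.n_events_per_sample if er_pos[si] else cfg.n_events_per_sample / cfg.er_rate_ratio
        n_ev = int(rng.poisson(mean))
        for _ in range(n_ev):
            targeted = er_pos[si] and rng.random() < cfg.hub_targeting_fraction
            if targeted:
                bc, bs, be = baits[int(rng.integers(len(baits)))]
                hc, hs, he = hubiv[int(rng.integers(len(hubiv)))]
                c1, p1 = bc, int(rng.integers(bs, be))
                c2, p2 = hc, int(rng.integers(hs, he))
            else:
                ci1, ci2 = rng.choice(len(names), size=2, p=probs)
                c1, p1 = names[ci1], int(rng.integers(0, sizes[names[ci1]]))
                c2, p2 = names[ci2], int(rng.integers(0, sizes[names[ci2]]))
            o1, o2 = ("+" if rng.random() < 0.5 else "-"), ("+" if rng.random() < 0.5 else "-")
            svtype = "ITX" if c1 == c2 else "CTX"
            size = abs(p2 - p1) if c1 == c2 else 0
            if rng.random() < cfg.sub80_score_fraction:
                score = float(np.round(rng.uniform(20.0, 80.0), 2))
            else:
                score = float(np.round(rng.uniform(81.0, 99.0), 2))
            n_reads = int(2 + rng.poisson(8))
            rows.append((sample, c1, p1, o1, c2, p2, o2, svtype, size, score, n_reads))
    if not rows:
        return pd.DataFrame(columns=EVENT_COLS)
    return pd.DataFrame(rows, columns=EVENT_COLS)


def _simulate_peaks(cfg: SimConfig, rng: np.random.Generator):
    """Three peak sets sharing jittered hub sites plus per-line noise peaks."""
    sizes = dict(cfg.genome)
    w = cfg.peak_width_bp
    j = cfg.peak_jitter_bp
    hub_sites = []
    for h in cfg.planted_hubs:
        lo, hi = h.start + w, h.end - w
        centers = np.sort(rng.integers(lo, hi, size=cfg.sites_per_hub))
        hub_sites.append(centers)
    peaks = {}
    for src in PEAK_SOURCES:
        rows = []
        for hi, h in enumerate(cfg.planted_hubs):
            jit = rng.integers(-j, j + 1, size=len(hub_sites[hi]))
            for c, dj in zip(hub_sites[hi], jit):
                s = max(0, int(c) - w // 2 + int(dj))
                e = min(sizes[h.chrom], s + w)
                rows.append((h.chrom, s, e))
        names = [c for c, _ in cfg.genome]
        lengths = np.array([n for _, n in cfg.genome], dtype=float)
        ci = rng.choice(len(names), size=cfg.noise_peaks_per_line, p=lengths / lengths.sum())
        for c in ci:
            s = int(rng.integers(0, sizes[names[c]] - w))
            rows.append((names[c], s, s + w))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        peaks[src] = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return peaks, hub_sites
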