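"""Seeded synthetic-data generators with emitted ground truth.

Every input the pipeline consumes can be generated here: per-sample
H3K27ac / H3K4me1 peak BEDs with planted double-positive regions,
single-mark decoys and super-enhancer clusters; gene models and expression
tables with controlled strata and element-distance placement; TF-occupancy
BEDs with specified per-element overlap probabilities; TSS-anchored loops
in BEDPE; and a negative-binomial Perturb-seq count matrix with planted
activation effects and multi-gRNA cells.

Planted entities are laid out with a guard spacing larger than both the
super-enhancer merge distance and twice the gene-association window, so
each planted feature can be recovered independently and the emitted truth
tables are exact. One global seed expands into per-component substreams
(landscape, genes, occupancy/loops, perturb, activity), so adding draws to
one generator does not perturb the others.

The generators emulate the statistical structure of multi-sample ChIP-seq
landscapes, not their sequence content: no reads, no signal tracks, no
genome sequence.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genes import STRATUM_BOUNDS, GeneModel, Loop
from .intervals import GenomeLayout, Interval, IntervalSet, write_bed, write_bedpe
from .perturb import PerturbExperiment


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's conditions as defaults.

    Landscape: three biopsy-like samples; planted double-positive regions
    appear in both marks (with bp jitter on peak edges) and drop out of a
    sample with probability ``dropout``; decoys carry one mark only. Valid
    super-enhancer clusters satisfy gap <= se_merge_gap and span >
    se_min_size by construction; decoys violate exactly one of the two.
    Occupancy probabilities, stratum association fractions, the gRNA
    identity mixture and the activity-expression correlation default to the
    study's reported operating point.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 4
    chrom_length: int = 60_000_000
    # samples and peaks
    n_samples: int = 3
    peak_width_log_mean: float = math.log(1000.0)  # lognormal, median ~1 kb
    peak_width_log_sd: float = 0.4
    jitter: int = 100
    dropout: float = 0.2
    # double-positive planting
    n_double_positive: int = 50
    n_single_mark_decoys: int = 30
    # super-enhancer planting
    se_merge_gap: int = 12500
    se_min_size: int = 15000
    n_se_clusters: int = 50
    n_se_decoys: int = 50
    # genes / expression
    n_genes: int = 400
    stratum_mix: dict = field(default_factory=lambda: {
        "inactive": 0.25, "low": 0.25, "mid": 0.25, "high": 0.25})
    assoc_fractions: dict = field(default_factory=lambda: {
        "high": 1.0 / 3.0, "low": 0.133})
    assoc_window: int = 100_000
    fpkm_high_cap: float = 150.0
    count_depth_factor: float = 40.0  # NB mean ~= depth_factor * FPKM
    count_dispersion: float = 0.3
    total_pairs: tuple = (50.0e6, 56.5e6, 65.0e6)
    # occupancy
    p_occupancy_se: float = 0.76
    p_occupancy_enh: float = 0.20
    # loops
    n_loops: int = 20
    anchor_width: int = 10_000
    loop_offset: int = 90_000
    peaks_per_loop: int = 7
    tss_anchored_fraction: float = 1.0
    # perturb-seq
    n_cells: int = 2000
    n_grnas: int = 8
    control_grna: str = "scramble"
    p_single_grna: float = 0.567
    p_multi_grna: float = 0.270
    n_perturb_genes: int = 50
    nb_base_log_mean: float = math.log(2.0)
    nb_base_log_sd: float = 1.0
    nb_dispersion: float = 0.5
    planted_fc: dict | None = None  # (grna, gene) -> FC; None = one 3x target per gRNA
    # activity-expression correlation
    n_specimens: int = 43
    activity_rho: float = 0.47

    def __post_init__(self) -> None:
        for name in ("dropout", "p_occupancy_se", "p_occupancy_enh",
                     "p_single_grna", "p_multi_grna", "tss_anchored_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_single_grna + self.p_multi_grna > 1.0:
            raise ValueError("gRNA identity probabilities exceed 1")
        if abs(sum(self.stratum_mix.values()) - 1.0) > 1e-9:
            raise ValueError("stratum_mix must sum to 1")
        if self.n_chromosomes < 3:
            raise ValueError("need >= 3 chromosomes (landscape / far genes / loops)")

    @property
    def layout(self) -> GenomeLayout:
        names = tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))
        return GenomeLayout(names, (self.chrom_length,) * self.n_chromosomes)

    @property
    def landscape_chroms(self) -> tuple[str, ...]:
        """Peak entities live on all but the last two chromosomes; the
        second-to-last holds far-placed genes, the last holds loops."""
        return self.layout.chrom_names[:-2]

    @property
    def far_gene_chrom(self) -> str:
        return self.layout.chrom_names[-2]

    @property
    def loop_chrom(self) -> str:
        return self.layout.chrom_names[-1]

    def spawn_rngs(self) -> dict[str, np.random.Generator]:
        names = ("landscape", "genes", "occloops", "perturb", "activity")
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


class _Allocator:
    """Hands out non-interfering genomic slots, left to right across chromosomes."""

    def __init__(self, layout: GenomeLayout, spacing: int,
                 chroms: tuple[str, ...] | None = None):
        self.layout = layout
        self.spacing = spacing
        self.chroms = chroms if chroms is not None else layout.chrom_names
        self._chrom_idx = 0
        self._cursor = spacing

    def take(self, span: int) -> tuple[str, int]:
        while self._chrom_idx < len(self.chroms):
            chrom = self.chroms[self._chrom_idx]
            limit = self.layout.length_of(chrom) - self.spacing
            if self._cursor + span <= limit:
                start = self._cursor
                self._cursor = start + span + self.spacing
                return chrom, start
            self._chrom_idx += 1
            self._cursor = self.spacing
        raise ValueError("genome too small for the requested planted elements; "
                         "increase chrom_length or n_chromosomes")


def _draw_width(rng: np.random.Generator, cfg: SimulationConfig,
                minimum: int = 200) -> int:
    return max(minimum, int(round(rng.lognormal(cfg.peak_width_log_mean,
                                                cfg.peak_width_log_sd))))


def _jittered(rng: np.random.Generator, iv: Interval, jitter: int) -> Interval:
    """Jitter both edges by up to +-jitter bp, keeping the centre bp covered."""
    if jitter == 0:
        return iv
    centre = (iv.start + iv.end) // 2
    start = min(iv.start + int(rng.integers(-jitter, jitter + 1)), centre - 1)
    end = max(iv.end + int(rng.integers(-jitter, jitter + 1)), centre + 1)
    return Interval(iv.chrom, max(0, start), end)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeTruth:
    """Ground truth for the planted peak landscape."""

    dp_regions: list[Interval]
    dp_present: pd.DataFrame          # region index x sample -> bool
    decoys: list[tuple[Interval, str]]  # (interval, mark)
    se_regions: list[Interval]          # expected stitched spans of valid clusters
    se_constituents: list[int]
    se_decoy_regions: list[tuple[Interval, str]]  # (overall span, violation kind)


@dataclass
class LandscapeData:
    layout: GenomeLayout
    sample_ids: list[str]
    k27: dict[str, IntervalSet]
    k4me1: dict[str, IntervalSet]
    truth: LandscapeTruth


def generate_landscape(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> LandscapeData:
    """Plant double-positive regions, single-mark decoys and SE clusters."""
    rng = rng if rng is not None else cfg.spawn_rngs()["landscape"]
    spacing = max(2 * cfg.assoc_window, 2 * cfg.se_merge_gap) + 10_000
    alloc = _Allocator(cfg.layout, spacing, cfg.landscape_chroms)
    samples = [f"sample{i + 1}" for i in range(cfg.n_samples)]
    k27: dict[str, list[Interval]] = {s: [] for s in samples}
    k4: dict[str, list[Interval]] = {s: [] for s in samples}

    # planted double-positive regions, with per-sample dropout and jitter
    dp_regions: list[Interval] = []
    present = np.ones((cfg.n_double_positive, cfg.n_samples), dtype=bool)
    for i in range(cfg.n_double_positive):
        w = _draw_width(rng, cfg)
        chrom, start = alloc.take(w)
        region = Interval(chrom, start, start + w)
        dp_regions.append(region)
        for j, s in enumerate(samples):
            if rng.random() < cfg.dropout:
                present[i, j] = False
                continue
            k27[s].append(_jittered(rng, region, cfg.jitter))
            k4[s].append(_jittered(rng, region, cfg.jitter))
    dp_present = pd.DataFrame(present, columns=samples)

    # single-mark decoys (half H3K27ac-only, half H3K4me1-only), in all samples
    decoys: list[tuple[Interval, str]] = []
    for i in range(cfg.n_single_mark_decoys):
        w = _draw_width(rng, cfg)
        chrom, start = alloc.take(w)
        region = Interval(chrom, start, start + w)
        mark = "H3K27ac" if i % 2 == 0 else "H3K4me1"
        decoys.append((region, mark))
        target = k27 if mark == "H3K27ac" else k4
        for s in samples:
            target[s].append(_jittered(rng, region, cfg.jitter))

    # valid SE clusters: gaps <= merge gap, span > min size (H3K27ac only)
    se_regions: list[Interval] = []
    se_constituents: list[int] = []
    for _ in range(cfg.n_se_clusters):
        peaks, span = _se_cluster(rng, cfg, valid=True)
        chrom, start = alloc.take(span)
        ivs = [Interval(chrom, start + a, start + b) for a, b in peaks]
        se_regions.append(Interval(chrom, ivs[0].start, ivs[-1].end))
        se_constituents.append(len(ivs))
        for s in samples:
            k27[s].extend(ivs)

    # decoy clusters violating exactly one condition
    se_decoys: list[tuple[Interval, str]] = []
    for i in range(cfg.n_se_decoys):
        kind = "gap" if i % 2 == 0 else "span"
        peaks, span = _se_cluster(rng, cfg, valid=False, violate=kind)
        chrom, start = alloc.take(span)
        ivs = [Interval(chrom, start + a, start + b) for a, b in peaks]
        se_decoys.append((Interval(chrom, ivs[0].start, ivs[-1].end), kind))
        for s in samples:
            k27[s].extend(ivs)

    data = LandscapeData(
        cfg.layout, samples,
        {s: IntervalSet(f"{s}_H3K27ac", sorted(k27[s])) for s in samples},
        {s: IntervalSet(f"{s}_H3K4me1", sorted(k4[s])) for s in samples},
        LandscapeTruth(dp_regions, dp_present, decoys,
                       se_regions, se_constituents, se_decoys),
    )
    _assert_se_construction(cfg, data)
    return data


def _se_cluster(rng: np.random.Generator, cfg: SimulationConfig, valid: bool,
                violate: str = "") -> tuple[list[tuple[int, int]], int]:
    """Build cluster peak offsets (relative to 0) and the overall span length.

    Valid clusters: every inter-peak gap <= se_merge_gap and total span
    strictly > se_min_size. Gap decoys: one gap > se_merge_gap splits the
    cluster into pieces each spanning <= se_min_size. Span decoys: gaps all
    <= se_merge_gap but the whole span <= se_min_size.
    """
    gap_hi = cfg.se_merge_gap
    if valid:
        peaks: list[tuple[int, int]] = []
        pos = 0
        while True:
            w = int(rng.integers(2000, 6001))
            peaks.append((pos, pos + w))
            if peaks[-1][1] - peaks[0][0] > cfg.se_min_size + 500 and len(peaks) >= 2:
                break
            pos = peaks[-1][1] + int(rng.integers(2000, gap_hi + 1))
        return peaks, peaks[-1][1]
    if violate == "span":
        w1, w2 = int(rng.integers(2000, 4001)), int(rng.integers(2000, 4001))
        gap = int(rng.integers(2000, min(gap_hi, cfg.se_min_size - w1 - w2 - 500) + 1))
        peaks = [(0, w1), (w1 + gap, w1 + gap + w2)]
        assert peaks[-1][1] <= cfg.se_min_size
        return peaks, peaks[-1][1]
    # gap violation: two pieces each > merge gap apart, each piece span <= min size
    piece = []
    for _ in range(2):
        w1, w2 = int(rng.integers(2000, 4001)), int(rng.integers(2000, 4001))
        g = int(rng.integers(2000, min(gap_hi, cfg.se_min_size - w1 - w2 - 500) + 1))
        piece.append([(0, w1), (w1 + g, w1 + g + w2)])
    sep = int(rng.integers(gap_hi + 1000, gap_hi + 8001))
    off = piece[0][-1][1] + sep
    peaks = piece[0] + [(a + off, b + off) for a, b in piece[1]]
    return peaks, peaks[-1][1]


def _assert_se_construction(cfg: SimulationConfig, data: LandscapeData) -> None:
    """Construction-time validity check: planted clusters pass the SE rule,
    decoys fail it (on the cluster's own peaks, in isolation)."""
    for iv in data.truth.se_regions:
        assert iv.length() > cfg.se_min_size
    for iv, kind in data.truth.se_decoy_regions:
        if kind == "span":
            assert iv.length() <= cfg.se_min_size


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------

@dataclass
class GenesData:
    genes: list[GeneModel]
    fpkm: pd.DataFrame
    counts: pd.DataFrame
    totals: pd.Series
    truth: pd.DataFrame  # gene_id, stratum, planted_element (index or -1)


def generate_genes_and_expression(cfg: SimulationConfig, land: LandscapeData,
                                  rng: np.random.Generator | None = None
                                  ) -> GenesData:
    """Place genes so stratum-association fractions hold exactly at truth level.

    For each stratum with a planted association fraction f, exactly
    round(f * n_elements) planted double-positive regions receive one gene
    of that stratum with TSS at a controlled distance inside the window;
    all other genes go to positions farther than the window from every
    planted element. Per-sample FPKM is drawn inside the gene's stratum
    bounds, so the emitted stratum classification is exact by construction.
    """
    rng = rng if rng is not None else cfg.spawn_rngs()["genes"]
    elements = land.truth.dp_regions
    n_el = len(elements)
    # exact stratum counts by largest remainder
    quotas = {s: cfg.stratum_mix.get(s, 0.0) * cfg.n_genes
              for s in ("inactive", "low", "mid", "high")}
    counts_per = {s: int(math.floor(q)) for s, q in quotas.items()}
    rem = cfg.n_genes - sum(counts_per.values())
    for s in sorted(quotas, key=lambda s: quotas[s] - math.floor(quotas[s]),
                    reverse=True)[:rem]:
        counts_per[s] += 1

    genes: list[GeneModel] = []
    truth_rows: list[dict] = []
    used: dict[str, int] = {s: 0 for s in counts_per}
    gid = 0
    for stratum, frac in cfg.assoc_fractions.items():
        n_planted = int(round(frac * n_el))
        if n_planted > counts_per.get(stratum, 0):
            raise ValueError(f"not enough {stratum} genes for the requested "
                             "association fraction; increase n_genes")
        chosen = rng.choice(n_el, size=n_planted, replace=False)
        for el_idx in sorted(int(i) for i in chosen):
            el = elements[el_idx]
            d = int(rng.integers(5000, cfg.assoc_window - 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(f"gene{gid:05d}", el.chrom, strand, el.end - 1 + d)
            genes.append(g)
            truth_rows.append({"gene_id": g.gene_id, "stratum": stratum,
                               "planted_element": el_idx, "distance": d})
            used[stratum] += 1
            gid += 1

    # remaining genes go to a dedicated chromosome that carries no elements,
    # so they are farther than the window from every planted element
    far_chrom = cfg.far_gene_chrom
    step = 50_000
    pos = 100_000
    limit = land.layout.length_of(far_chrom) - 100_000
    for stratum in ("inactive", "low", "mid", "high"):
        for _ in range(counts_per[stratum] - used[stratum]):
            if pos > limit:
                raise ValueError("genome too small for the requested far-placed "
                                 "genes; increase chrom_length")
            strand = "+" if rng.random() < 0.5 else "-"
            g = GeneModel(f"gene{gid:05d}", far_chrom, strand, pos)
            genes.append(g)
            truth_rows.append({"gene_id": g.gene_id, "stratum": stratum,
                               "planted_element": -1, "distance": -1})
            gid += 1
            pos += step

    truth = pd.DataFrame(truth_rows)
    samples = land.sample_ids
    fpkm = np.empty((len(genes), len(samples)))
    for i, row in enumerate(truth.itertuples()):
        lo, hi = STRATUM_BOUNDS[row.stratum]
        hi = min(hi, cfg.fpkm_high_cap)
        fpkm[i] = rng.uniform(lo, hi, size=len(samples))
    fpkm_df = pd.DataFrame(fpkm, index=truth["gene_id"], columns=samples)

    mu = cfg.count_depth_factor * fpkm
    n_shape = 1.0 / cfg.count_dispersion
    counts = rng.negative_binomial(n_shape, n_shape / (n_shape + np.maximum(mu, 1e-9)))
    counts_df = pd.DataFrame(counts, index=truth["gene_id"], columns=samples)
    totals = pd.Series(list(cfg.total_pairs)[:len(samples)], index=samples,
                       dtype=float)
    if len(totals) < len(samples):
        raise ValueError("total_pairs shorter than n_samples")
    return GenesData(genes, fpkm_df, counts_df, totals, truth)


# ---------------------------------------------------------------------------
# occupancy and loops
# ---------------------------------------------------------------------------

@dataclass
class OccupancyLoopsData:
    occupancy: IntervalSet
    se_occupied: list[bool]
    enh_occupied: list[bool]
    loops: list[Loop]
    loop_genes: list[GeneModel]
    loop_peaks: IntervalSet
    loop_truth: pd.DataFrame  # loop_idx, gene_id, tss_anchored, n_planted_peaks


def generate_occupancy_loops(cfg: SimulationConfig, land: LandscapeData,
                             rng: np.random.Generator | None = None
                             ) -> OccupancyLoopsData:
    """Occupancy intervals overlapping elements with set probabilities, and
    TSS-anchored loops with a fixed number of in-span candidate peaks."""
    rng = rng if rng is not None else cfg.spawn_rngs()["occloops"]
    occ: list[Interval] = []

    def maybe_occupy(iv: Interval, p: float) -> bool:
        if rng.random() < p:
            w = int(rng.integers(300, 1500))
            centre = int(rng.integers(iv.start, iv.end))
            occ.append(Interval(iv.chrom, max(0, centre - w // 2), centre + w // 2 + 1))
            return True
        return False

    se_occupied = [maybe_occupy(iv, cfg.p_occupancy_se)
                   for iv in land.truth.se_regions]
    enh_occupied = [maybe_occupy(iv, cfg.p_occupancy_enh)
                    for iv in land.truth.dp_regions]

    # loops live on their own chromosome, with dedicated genes and peaks
    loop_span = cfg.loop_offset + 2 * cfg.anchor_width
    loops: list[Loop] = []
    loop_genes: list[GeneModel] = []
    peaks: list[Interval] = []
    rows: list[dict] = []
    chrom = cfg.loop_chrom
    pos = 1_000_000
    step = loop_span + 2 * cfg.assoc_window + 20_000
    n_anchored = int(round(cfg.tss_anchored_fraction * cfg.n_loops))
    for i in range(cfg.n_loops):
        if pos + loop_span + step > land.layout.length_of(chrom):
            raise ValueError("genome too small for the requested loops")
        a1 = Interval(chrom, pos, pos + cfg.anchor_width)
        a2 = Interval(chrom, pos + cfg.anchor_width + cfg.loop_offset,
                      pos + 2 * cfg.anchor_width + cfg.loop_offset)
        loops.append(Loop(a1, a2))
        anchored = i < n_anchored
        gene_id = f"loopgene{i:03d}"
        if anchored:
            tss = int(rng.integers(a1.start, a1.end))
        else:
            tss = a2.end + cfg.assoc_window + 50_000  # outside both anchors
        loop_genes.append(GeneModel(gene_id, chrom, "+", tss))
        # k candidate peaks inside the span, plus one decoy beyond it
        inner_lo, inner_hi = a1.end + 1000, a2.start - 2000
        starts = sorted(rng.choice(
            np.arange(inner_lo, inner_hi - 1000, 1200), size=cfg.peaks_per_loop,
            replace=False))
        for s0 in starts:
            peaks.append(Interval(chrom, int(s0), int(s0) + 800))
        decoy = Interval(chrom, a2.end + 30_000, a2.end + 31_000)
        peaks.append(decoy)
        rows.append({"loop_idx": i, "gene_id": gene_id, "tss_anchored": anchored,
                     "n_planted_peaks": cfg.peaks_per_loop})
        pos += step
    return OccupancyLoopsData(
        IntervalSet("occupancy", sorted(occ)), se_occupied, enh_occupied,
        loops, loop_genes, IntervalSet("loop_peaks", sorted(peaks)),
        pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# perturb-seq
# ---------------------------------------------------------------------------

@dataclass
class PerturbData:
    experiment: PerturbExperiment
    truth: pd.DataFrame  # grna_id, gene_id, true_fc


def default_planted_fc(cfg: SimulationConfig) -> dict[tuple[str, str], float]:
    """One 3x responder gene per targeting gRNA (gene i responds to gRNA i)."""
    return {(f"g{i + 1}", f"tgene{i:03d}"): 3.0 for i in range(cfg.n_grnas)}


def generate_perturb(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None) -> PerturbData:
    """Negative-binomial cell x gene counts with planted activation effects.

    Cells receive 0, 1 or >=2 gRNA identities per the configured mixture
    (single includes the scramble control, drawn uniformly over all
    identities). A responder gene's NB mean is multiplied by its planted
    fold change in the single-gRNA cells of its gRNA.
    """
    rng = rng if rng is not None else cfg.spawn_rngs()["perturb"]
    grnas = [cfg.control_grna] + [f"g{i + 1}" for i in range(cfg.n_grnas)]
    planted = cfg.planted_fc if cfg.planted_fc is not None else default_planted_fc(cfg)
    gene_ids = [f"tgene{i:03d}" for i in range(cfg.n_perturb_genes)]
    for (g, t), fc in planted.items():
        if g not in grnas or t not in gene_ids:
            raise ValueError(f"planted effect references unknown gRNA/gene ({g}, {t})")
        if fc <= 0:
            raise ValueError("planted fold changes must be positive")

    base_mu = rng.lognormal(cfg.nb_base_log_mean, cfg.nb_base_log_sd,
                            size=cfg.n_perturb_genes)
    p_none = 1.0 - cfg.p_single_grna - cfg.p_multi_grna
    cats = rng.choice(3, size=cfg.n_cells,
                      p=[p_none, cfg.p_single_grna, cfg.p_multi_grna])
    assignments: dict[str, frozenset[str]] = {}
    cell_ids = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    mu = np.tile(base_mu, (cfg.n_cells, 1))
    for i, cell in enumerate(cell_ids):
        if cats[i] == 0:
            assignments[cell] = frozenset()
        elif cats[i] == 1:
            g = grnas[int(rng.integers(len(grnas)))]
            assignments[cell] = frozenset([g])
            for (pg, pt), fc in planted.items():
                if pg == g:
                    mu[i, gene_ids.index(pt)] *= fc
        else:
            k = 2 if rng.random() < 0.8 else 3
            picks = rng.choice(len(grnas), size=k, replace=False)
            assignments[cell] = frozenset(grnas[j] for j in picks)
    n_shape = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(n_shape, n_shape / (n_shape + mu))
    exp = PerturbExperiment(
        pd.DataFrame(counts, index=cell_ids, columns=gene_ids),
        assignments, cfg.control_grna)
    truth = pd.DataFrame([{"grna_id": g, "gene_id": t, "true_fc": fc}
                          for (g, t), fc in sorted(planted.items())])
    return PerturbData(exp, truth)


# ---------------------------------------------------------------------------
# activity-expression correlation
# ---------------------------------------------------------------------------

def generate_activity_expression(cfg: SimulationConfig,
                                 rng: np.random.Generator | None = None
                                 ) -> pd.DataFrame:
    """Bivariate-normal (activity score, expression) pairs with planted rho."""
    rng = rng if rng is not None else cfg.spawn_rngs()["activity"]
    rho = cfg.activity_rho
    cov = [[1.0, rho], [rho, 1.0]]
    xy = rng.multivariate_normal([0.0, 0.0], cov, size=cfg.n_specimens)
    return pd.DataFrame({
        "specimen": [f"specimen{i + 1}" for i in range(cfg.n_specimens)],
        "activity_score": xy[:, 0],
        "expression": 8.0 + 2.0 * xy[:, 1],  # arbitrary affine scale
    })


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all generators and write every pipeline input plus truth tables.

    Deterministic: identical (cfg, seed) produce byte-identical files.
    Returns a name -> path map (also recorded in manifest.json).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rngs = cfg.spawn_rngs()
    land = generate_landscape(cfg, rngs["landscape"])
    gdata = generate_genes_and_expression(cfg, land, rngs["genes"])
    odata = generate_occupancy_loops(cfg, land, rngs["occloops"])
    pdata = generate_perturb(cfg, rngs["perturb"])
    act = generate_activity_expression(cfg, rngs["activity"])

    paths: dict[str, Path] = {}

    def tsv(name: str, df: pd.DataFrame, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", **kw)
        paths[name] = p

    for s in land.sample_ids:
        for mark, sets in (("H3K27ac", land.k27), ("H3K4me1", land.k4me1)):
            p = outdir / f"{s}_{mark}.bed"
            write_bed(sets[s], p)
            paths[f"{s}_{mark}.bed"] = p

    dp = pd.DataFrame([{"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                       for iv in land.truth.dp_regions])
    dp = pd.concat([dp, land.truth.dp_present.add_prefix("present_")], axis=1)
    tsv("truth_double_positive.tsv", dp, index=False)
    tsv("truth_decoys.tsv", pd.DataFrame(
        [{"chrom": iv.chrom, "start": iv.start, "end": iv.end, "mark": m}
         for iv, m in land.truth.decoys]), index=False)
    tsv("truth_super_enhancers.tsv", pd.DataFrame(
        [{"chrom": iv.chrom, "start": iv.start, "end": iv.end,
          "n_constituents": n, "is_se": True}
         for iv, n in zip(land.truth.se_regions, land.truth.se_constituents)]
        + [{"chrom": iv.chrom, "start": iv.start, "end": iv.end,
            "n_constituents": 0, "is_se": False, "violation": kind}
           for iv, kind in land.truth.se_decoy_regions]), index=False)

    genes_df = pd.DataFrame([{"gene_id": g.gene_id, "chrom": g.chrom,
                              "strand": g.strand, "tss": g.tss}
                             for g in gdata.genes + odata.loop_genes])
    tsv("genes.tsv", genes_df, index=False)
    tsv("fpkm.tsv", gdata.fpkm, index_label="gene_id")
    tsv("counts.tsv", gdata.counts, index_label="gene_id")
    tsv("totals.tsv", gdata.totals.rename("total_pairs").to_frame(),
        index_label="sample")
    tsv("truth_genes.tsv", gdata.truth, index=False)

    write_bed(odata.occupancy, outdir / "occupancy.bed")
    paths["occupancy.bed"] = outdir / "occupancy.bed"
    tsv("truth_occupancy.tsv", pd.DataFrame({
        "kind": ["SE"] * len(odata.se_occupied) + ["enh"] * len(odata.enh_occupied),
        "occupied": list(odata.se_occupied) + list(odata.enh_occupied)}),
        index=False)
    write_bedpe([(lp.anchor1, lp.anchor2) for lp in odata.loops],
                outdir / "loops.bedpe")
    paths["loops.bedpe"] = outdir / "loops.bedpe"
    write_bed(odata.loop_peaks, outdir / "loop_peaks.bed")
    paths["loop_peaks.bed"] = outdir / "loop_peaks.bed"
    tsv("truth_loops.tsv", odata.loop_truth, index=False)

    from scipy import sparse
    from scipy.io import mmwrite
    mmwrite(outdir / "perturb_counts.mtx",
            sparse.coo_matrix(pdata.experiment.counts.values))
    paths["perturb_counts.mtx"] = outdir / "perturb_counts.mtx"
    (outdir / "perturb_cells.tsv").write_text(
        "\n".join(pdata.experiment.counts.index) + "\n")
    paths["perturb_cells.tsv"] = outdir / "perturb_cells.tsv"
    (outdir / "perturb_genes.tsv").write_text(
        "\n".join(pdata.experiment.counts.columns) + "\n")
    paths["perturb_genes.tsv"] = outdir / "perturb_genes.tsv"
    grna_rows = [{"cell_id": c, "grna_id": g, "umi_count": 1}
                 for c, gs in sorted(pdata.experiment.grna_assignments.items())
                 for g in sorted(gs)]
    tsv("grna_assignments.tsv", pd.DataFrame(grna_rows,
                                             columns=["cell_id", "grna_id",
                                                      "umi_count"]), index=False)
    tsv("truth_perturb.tsv", pdata.truth, index=False)
    tsv("activity_scores.tsv", act[["specimen", "activity_score"]], index=False)
    tsv("activity_expression.tsv", act, index=False)

    manifest = {"seed": cfg.seed,
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(cfg).items()
                           if not isinstance(v, dict) or k in
                           ("stratum_mix", "assoc_fractions")},
                "files": sorted(paths)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    paths["manifest.json"] = outdir / "manifest.json"
    return paths
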