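"""End-to-end orchestration: enhancers -> super enhancers -> consensus ->
gene linking -> colocalization -> loop candidates -> perturb calling,
with a summary report of the landscape's headline counts and fractions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .genes import (ExpressionTable, classify_stratum, colocalization_fraction,
                    associate_elements_to_genes, filter_active_genes,
                    loop_candidates, normalize_counts, pearson_r,
                    read_gene_models, read_loops,
                    stratum_association_fractions)
from .intervals import IntervalSet, read_bed, write_bed
from .landscape import (LandscapeConfig, call_double_positive,
                        call_super_enhancers, consensus, support_partition)
from .perturb import (PerturbConfig, PerturbExperiment, call_known_target,
                      calls_to_frame, filter_single_grna, normalize_cells)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths to every input plus all thresholds, with the study's defaults.

    Any input group may be omitted (None); the corresponding stage is
    skipped and its report fields stay empty.
    """

    # landscape inputs: sample -> BED path
    k27_beds: dict = field(default_factory=dict)
    k4me1_beds: dict = field(default_factory=dict)
    occupancy_bed: str | None = None
    # gene/expression inputs
    genes_tsv: str | None = None
    fpkm_tsv: str | None = None
    counts_tsv: str | None = None
    totals_tsv: str | None = None
    # loops
    loops_bedpe: str | None = None
    loop_peaks_bed: str | None = None
    loop_gene_ids: list = field(default_factory=list)
    # perturb
    perturb_counts: str | None = None
    perturb_cells: str | None = None
    perturb_genes: str | None = None
    grna_assignments: str | None = None
    control_grna: str = "scramble"
    perturb_targets: dict = field(default_factory=dict)  # grna -> target gene
    # activity correlation
    activity_expression_tsv: str | None = None
    # thresholds
    se_merge_gap: int = 12500
    se_min_size: int = 15000
    consensus_min_support: int | None = None
    assoc_window: int = 100_000
    fc_threshold: float = 1.5
    alpha: float = 0.05
    pseudocount: float = 0.01
    min_cells_per_group: int = 10
    # bookkeeping
    out_dir: str = "enhancerkit_out"
    seed: int | None = None

    def landscape_config(self) -> LandscapeConfig:
        return LandscapeConfig(self.se_merge_gap, self.se_min_size,
                               self.consensus_min_support)

    def perturb_config(self) -> PerturbConfig:
        return PerturbConfig(self.fc_threshold, self.alpha, self.pseudocount,
                             self.min_cells_per_group)

    def validate(self) -> None:
        n = len(self.k27_beds)
        if set(self.k27_beds) != set(self.k4me1_beds):
            raise ValueError("k27_beds and k4me1_beds must cover the same samples")
        if self.consensus_min_support is not None and n and \
                self.consensus_min_support > n:
            raise ValueError(f"consensus_min_support ({self.consensus_min_support}) "
                             f"exceeds the number of samples ({n})")
        self.landscape_config()
        self.perturb_config()
        if self.assoc_window <= 0:
            raise ValueError("assoc_window must be positive")

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    @classmethod
    def from_sim_dir(cls, simdir: str | Path, **overrides) -> "PipelineConfig":
        """Build a config from a ``simulate_to_dir`` output directory."""
        simdir = Path(simdir)
        manifest = json.loads((simdir / "manifest.json").read_text())
        files = set(manifest["files"])
        samples = sorted({f.split("_")[0] for f in files if f.endswith("_H3K27ac.bed")})
        perturb_targets = {}
        truth_p = simdir / "truth_perturb.tsv"
        if truth_p.exists():
            t = pd.read_csv(truth_p, sep="\t")
            perturb_targets = dict(zip(t["grna_id"], t["gene_id"]))
        loop_genes: list[str] = []
        truth_l = simdir / "truth_loops.tsv"
        if truth_l.exists():
            loop_genes = list(pd.read_csv(truth_l, sep="\t")["gene_id"])
        cfg = cls(
            k27_beds={s: str(simdir / f"{s}_H3K27ac.bed") for s in samples},
            k4me1_beds={s: str(simdir / f"{s}_H3K4me1.bed") for s in samples},
            occupancy_bed=str(simdir / "occupancy.bed"),
            genes_tsv=str(simdir / "genes.tsv"),
            fpkm_tsv=str(simdir / "fpkm.tsv"),
            counts_tsv=str(simdir / "counts.tsv"),
            totals_tsv=str(simdir / "totals.tsv"),
            loops_bedpe=str(simdir / "loops.bedpe"),
            loop_peaks_bed=str(simdir / "loop_peaks.bed"),
            loop_gene_ids=loop_genes,
            perturb_counts=str(simdir / "perturb_counts.mtx"),
            perturb_cells=str(simdir / "perturb_cells.tsv"),
            perturb_genes=str(simdir / "perturb_genes.tsv"),
            grna_assignments=str(simdir / "grna_assignments.tsv"),
            perturb_targets=perturb_targets,
            activity_expression_tsv=str(simdir / "activity_expression.tsv"),
            seed=manifest.get("seed"),
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    def config_hash(self) -> str:
        # identifies the analysis, not where it ran: paths reduce to basenames
        def basename(v):
            if isinstance(v, str) and ("/" in v or v.endswith((".bed", ".tsv",
                                                               ".bedpe", ".mtx"))):
                return Path(v).name
            if isinstance(v, dict):
                return {k: basename(x) for k, x in sorted(v.items())}
            return v
        d = {k: basename(v) for k, v in dataclasses.asdict(self).items()
             if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SummaryReport:
    """Headline counts and fractions of one pipeline run."""

    per_sample: dict = field(default_factory=dict)   # sample -> counts dict
    n_consensus_enhancers: int | None = None
    n_consensus_super_enhancers: int | None = None
    support_level_counts: dict = field(default_factory=dict)
    fraction_common: dict = field(default_factory=dict)
    stratum_fractions: dict = field(default_factory=dict)
    coloc_enh_pct: float | None = None
    coloc_se_pct: float | None = None
    loop_candidate_counts: dict = field(default_factory=dict)
    grna_fractions: dict = field(default_factory=dict)
    activation_calls: dict = field(default_factory=dict)  # grna -> activated bool
    activity_expression_r: float | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _provenance(cfg: PipelineConfig) -> str:
    return (f"# enhancerkit v{__version__} config_hash={cfg.config_hash()} "
            f"seed={cfg.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(cfg))
        df.to_csv(fh, sep="\t", **kw)


def run_pipeline(cfg: PipelineConfig) -> SummaryReport:
    """Execute all stages whose inputs are configured; write outputs to out_dir."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = SummaryReport()
    lcfg = cfg.landscape_config()

    samples = sorted(cfg.k27_beds)
    enhancer_sets = {}
    k27_sets = {}
    se_sets = {}
    for s in samples:
        k27 = read_bed(cfg.k27_beds[s], label=f"{s}_H3K27ac")
        k4 = read_bed(cfg.k4me1_beds[s], label=f"{s}_H3K4me1")
        k27_sets[s] = k27
        enh = call_double_positive(k27, k4, sample_id=s)
        ses = call_super_enhancers(k27, lcfg, sample_id=s)
        enhancer_sets[s] = enh
        se_sets[s] = ses
        write_bed(enh.as_interval_set(), out / f"{s}_enhancers.bed")
        write_bed(ses.as_interval_set(), out / f"{s}_super_enhancers.bed",
                  extra_columns=[(f"SE{i}", n, iv.length())
                                 for i, (iv, n) in enumerate(
                                     zip(ses.elements, ses.constituent_counts))])
        report.per_sample[s] = {
            "n_H3K27ac": len(k27), "n_H3K4me1": len(k4),
            "n_enhancers": len(enh), "n_super_enhancers": len(ses)}

    cons_enh = cons_se = None
    if len(samples) >= 2:
        cons_enh = consensus([enhancer_sets[s] for s in samples],
                             cfg.consensus_min_support)
        cons_se = consensus([se_sets[s].as_interval_set() for s in samples],
                            cfg.consensus_min_support)
        report.n_consensus_enhancers = len(cons_enh)
        report.n_consensus_super_enhancers = len(cons_se)
        write_bed(cons_enh.as_interval_set(), out / "consensus_enhancers.bed",
                  extra_columns=[(f"E{i}", n) for i, n in enumerate(cons_enh.support)])
        write_bed(cons_se.as_interval_set(), out / "consensus_super_enhancers.bed",
                  extra_columns=[(f"SE{i}", n) for i, n in enumerate(cons_se.support)])
        part = support_partition([k27_sets[s] for s in samples])
        report.support_level_counts = {str(k): v for k, v
                                       in sorted(part.support_level_counts.items())}
        report.fraction_common = part.fraction_common

    genes = strata = None
    if cfg.genes_tsv:
        genes = read_gene_models(cfg.genes_tsv)
    if cfg.fpkm_tsv or cfg.counts_tsv:
        expr = ExpressionTable.from_tsv(cfg.fpkm_tsv, cfg.counts_tsv)
        if cfg.counts_tsv and cfg.totals_tsv:
            totals = pd.read_csv(cfg.totals_tsv, sep="\t", index_col=0,
                                 comment="#").iloc[:, 0]
            norm = normalize_counts(expr.counts, totals)
            _write_tsv(norm, out / "normalized_counts.tsv", cfg,
                       index_label="gene_id")
            active_by_count = filter_active_genes(
                ExpressionTable(counts=norm), mode="mean_count")
            report.per_sample.setdefault("_all", {})["n_active_genes_mean_count"] = \
                len(active_by_count)
        if expr.fpkm is not None:
            strata = expr.strata()
            for s in expr.fpkm.columns:
                if s in report.per_sample:
                    report.per_sample[s]["n_active_genes"] = len(
                        filter_active_genes(expr, mode="fpkm", sample=s))
        if genes is not None and strata is not None and cons_enh is not None:
            elements = cons_enh.as_interval_set()
            assoc = associate_elements_to_genes(elements, genes, cfg.assoc_window)
            _write_tsv(pd.DataFrame(
                [{"chrom": a.element.chrom, "start": a.element.start,
                  "end": a.element.end, "gene_id": a.gene_id,
                  "distance": a.distance} for a in assoc]),
                out / "associations.tsv", cfg, index=False)
            if len(elements):
                report.stratum_fractions = stratum_association_fractions(
                    elements, assoc, strata)

    if cfg.occupancy_bed and cons_enh is not None:
        occ = read_bed(cfg.occupancy_bed, label="occupancy")
        if len(cons_enh):
            report.coloc_enh_pct = colocalization_fraction(
                cons_enh.as_interval_set(), occ)
        if cons_se is not None and len(cons_se):
            report.coloc_se_pct = colocalization_fraction(
                cons_se.as_interval_set(), occ)

    if cfg.loops_bedpe and cfg.loop_peaks_bed and genes is not None:
        loops = read_loops(cfg.loops_bedpe)
        peaks = read_bed(cfg.loop_peaks_bed, label="loop_peaks")
        by_id = {g.gene_id: g for g in genes}
        for gid in cfg.loop_gene_ids:
            if gid not in by_id:
                logger.warning("loop gene %s not in gene models; skipped", gid)
                continue
            sel, cands = loop_candidates(loops, by_id[gid], peaks)
            report.loop_candidate_counts[gid] = {
                "n_loops": len(sel), "n_candidates": len(cands)}

    if cfg.perturb_counts and cfg.grna_assignments:
        exp = PerturbExperiment.from_files(
            cfg.perturb_counts, cfg.grna_assignments, cfg.control_grna,
            cells_path=cfg.perturb_cells, genes_path=cfg.perturb_genes)
        groups, fractions = filter_single_grna(exp)
        report.grna_fractions = fractions
        norm = normalize_cells(exp.counts)
        pcfg = cfg.perturb_config()
        calls = []
        for grna, target in sorted(cfg.perturb_targets.items()):
            if grna not in groups or len(groups[grna]) < pcfg.min_cells_per_group:
                logger.warning("gRNA %s has too few single-gRNA cells; skipped", grna)
                continue
            call = call_known_target(norm, groups, grna, target,
                                     cfg.control_grna, pcfg)
            calls.append(call)
            report.activation_calls[grna] = bool(call.activated)
        if calls:
            _write_tsv(calls_to_frame(calls), out / "activation_calls.tsv",
                       cfg, index=False)

    if cfg.activity_expression_tsv:
        act = pd.read_csv(cfg.activity_expression_tsv, sep="\t", comment="#")
        if {"activity_score", "expression"} <= set(act.columns) and len(act) >= 3:
            report.activity_expression_r = pearson_r(act["activity_score"],
                                                     act["expression"])

    (out / "report.json").write_text(report.to_json() + "\n")
    rows = [{"sample": s, **v} for s, v in report.per_sample.items()]
    _write_tsv(pd.DataFrame(rows), out / "report.tsv", cfg, index=False)
    return report
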