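"""CRISPRa Perturb-seq activation calling.

Cells carry detected gRNA identities; only cells with exactly one gRNA are
grouped and analysed (multi- and zero-gRNA cells are excluded). Activation
of a known target gene is a fold change > 1.5 of the gRNA group's mean over
the scramble-control group's mean. Target discovery runs a per-gene
two-sided rank-sum test against the control group with Benjamini-Hochberg
correction, calling genes with fold change > 1.5 and adjusted p < 0.05.

Normalization is median-total scaling per cell (each cell's counts scaled
to the median cell total), a deliberately simple, documented stand-in for
heavier single-cell normalizations; fold changes are computed on the
scaled values in linear space. A raw-mean mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class PerturbConfig:
    """Decision thresholds for activation calling.

    fc_threshold: activation requires fold change strictly greater than this.
    alpha: discovery mode additionally requires adjusted p strictly below this.
    pseudocount: added to both group means before the ratio, stabilising
        fold changes when the control mean is ~0.
    min_cells_per_group: both groups must have at least this many cells.
    """

    fc_threshold: float = 1.5
    alpha: float = 0.05
    pseudocount: float = 0.01
    min_cells_per_group: int = 10

    def __post_init__(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


@dataclass
class ActivationCall:
    """One gRNA-gene verdict: fold change, (adjusted) p, and the activation flag."""

    grna_id: str
    gene_id: str
    fold_change: float
    activated: bool
    p_value: float | None = None
    adjusted_p: float | None = None


@dataclass
class PerturbExperiment:
    """Cell x gene counts with per-cell detected gRNA identities.

    counts: non-negative integer matrix, cells as rows.
    grna_assignments: cell id -> set of detected gRNA identities (may be empty).
    control_label: identity of the non-targeting / scramble control gRNA.
    """

    counts: pd.DataFrame
    grna_assignments: Mapping[str, frozenset[str]]
    control_label: str = "scramble"

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        all_grnas = set().union(*self.grna_assignments.values()) \
            if self.grna_assignments else set()
        if self.control_label not in all_grnas:
            raise ValueError(f"control gRNA {self.control_label!r} not present "
                             "among assigned identities")

    @classmethod
    def from_files(cls, counts_path: str | Path, grna_path: str | Path,
                   control_label: str = "scramble",
                   cells_path: str | Path | None = None,
                   genes_path: str | Path | None = None) -> "PerturbExperiment":
        """Load counts from MTX triplet (with cell/gene index files) or dense TSV,
        and gRNA assignments from TSV (cell_id, grna_id[, umi_count])."""
        counts_path = Path(counts_path)
        if counts_path.suffix == ".mtx":
            from scipy.io import mmread
            if cells_path is None or genes_path is None:
                raise ValueError("MTX input needs cells_path and genes_path")
            mat = mmread(counts_path).toarray()
            cells = [l.strip() for l in open(cells_path) if l.strip()]
            genes = [l.strip() for l in open(genes_path) if l.strip()]
            counts = pd.DataFrame(mat, index=cells, columns=genes)
        else:
            counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
        gdf = pd.read_csv(grna_path, sep="\t", comment="#")
        assignments: dict[str, set[str]] = {c: set() for c in counts.index}
        for cell, grna in zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1].astype(str)):
            assignments.setdefault(cell, set()).add(grna)
        return cls(counts, {c: frozenset(g) for c, g in assignments.items()},
                   control_label)


def filter_single_grna(exp: PerturbExperiment
                       ) -> tuple[dict[str, list[str]], dict[str, float]]:
    """Keep cells with exactly one detected gRNA, grouped by that gRNA.

    Returns (groups, fractions): groups maps gRNA id -> kept cell ids;
    fractions reports the none/single/multi proportions over all cells in
    the experiment. Zero-gRNA cells carry no identity and are excluded
    together with multi-gRNA cells.
    """
    groups: dict[str, list[str]] = {}
    n_none = n_single = n_multi = 0
    for cell in exp.counts.index:
        grnas = exp.grna_assignments.get(cell, frozenset())
        if len(grnas) == 0:
            n_none += 1
        elif len(grnas) == 1:
            n_single += 1
            groups.setdefault(next(iter(grnas)), []).append(cell)
        else:
            n_multi += 1
    total = len(exp.counts.index)
    fractions = {"none": n_none / total if total else 0.0,
                 "single": n_single / total if total else 0.0,
                 "multi": n_multi / total if total else 0.0}
    if not groups.get(exp.control_label):
        raise ValueError("control group is empty after single-gRNA filtering")
    return groups, fractions


def normalize_cells(counts: pd.DataFrame, mode: str = "median",
                    log: bool = False) -> pd.DataFrame:
    """Scale each cell's counts to the median cell total (optionally log1p).

    All-zero cells are dropped with a log entry. ``mode="raw"`` returns the
    counts unscaled (minus zero cells), for raw-mean fold changes.
    """
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.info("dropping %d all-zero cells", int(zero.sum()))
        counts = counts.loc[~zero]
        totals = totals.loc[~zero]
    if mode == "raw":
        out = counts.astype(float)
    elif mode == "median":
        median_total = float(np.median(totals.values))
        out = counts.mul(median_total / totals, axis=0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.log1p(out) if log else out


def _group_values(norm: pd.DataFrame, cells: Sequence[str],
                  gene: str | None = None):
    cells = [c for c in cells if c in norm.index]
    sub = norm.loc[cells]
    return sub[gene].values if gene is not None else sub


def call_known_target(norm: pd.DataFrame, groups: Mapping[str, Sequence[str]],
                      grna_id: str, target_gene: str, control_label: str,
                      cfg: PerturbConfig | None = None) -> ActivationCall:
    """Fold-change activation call for a gRNA with a known target gene.

    fold_change = (mean of target group + pseudocount) /
    (mean of control group + pseudocount); activated iff strictly above
    the threshold. No p-value in this mode.
    """
    cfg = cfg or PerturbConfig()
    t = _group_values(norm, groups[grna_id], target_gene)
    c = _group_values(norm, groups[control_label], target_gene)
    for name, vals in ((grna_id, t), (control_label, c)):
        if len(vals) < cfg.min_cells_per_group:
            raise ValueError(f"group {name!r} has {len(vals)} cells "
                             f"(< {cfg.min_cells_per_group})")
    fc = (float(np.mean(t)) + cfg.pseudocount) / (float(np.mean(c)) + cfg.pseudocount)
    return ActivationCall(grna_id, target_gene, fc, fc > cfg.fc_threshold)


def find_targets_de(norm: pd.DataFrame, groups: Mapping[str, Sequence[str]],
                    grna_id: str, control_label: str,
                    cfg: PerturbConfig | None = None) -> list[ActivationCall]:
    """Discovery-mode calling: per-gene rank-sum test vs control with BH FDR.

    Activation requires fold change > fc_threshold AND adjusted p < alpha.
    Results are ranked by adjusted p, then by |log fold change| descending.
    """
    cfg = cfg or PerturbConfig()
    t = _group_values(norm, groups[grna_id])
    c = _group_values(norm, groups[control_label])
    for name, sub in ((grna_id, t), (control_label, c)):
        if len(sub) < cfg.min_cells_per_group:
            raise ValueError(f"group {name!r} has {len(sub)} cells "
                             f"(< {cfg.min_cells_per_group})")
    genes = list(norm.columns)
    if len(genes) < 2:
        raise ValueError("discovery mode needs at least 2 genes")
    pvals = np.empty(len(genes))
    fcs = np.empty(len(genes))
    for i, g in enumerate(genes):
        tv, cv = t[g].values, c[g].values
        fcs[i] = (tv.mean() + cfg.pseudocount) / (cv.mean() + cfg.pseudocount)
        if np.all(tv == tv[0]) and np.all(cv == cv[0]) and tv[0] == cv[0]:
            pvals[i] = 1.0  # constant and equal: no evidence either way
        else:
            pvals[i] = stats.mannwhitneyu(tv, cv, alternative="two-sided").pvalue
    adj = benjamini_hochberg(pvals)
    calls = [ActivationCall(grna_id, g, float(fc),
                            bool(fc > cfg.fc_threshold and a < cfg.alpha),
                            p_value=float(p), adjusted_p=float(a))
             for g, fc, p, a in zip(genes, fcs, pvals, adj)]
    calls.sort(key=lambda c: (c.adjusted_p, -abs(np.log(c.fold_change))))
    return calls


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def calls_to_frame(calls: Sequence[ActivationCall]) -> pd.DataFrame:
    """Tabulate activation calls for TSV output."""
    return pd.DataFrame([{"grna_id": c.grna_id, "gene_id": c.gene_id,
                          "fold_change": c.fold_change, "p_value": c.p_value,
                          "adjusted_p": c.adjusted_p, "activated": c.activated}
                         for c in calls])
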