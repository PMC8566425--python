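"""Transcriptional immune-signature scoring and age-group testing.

Pipeline: collapse probe-level expression to genes by keeping, per gene,
the probe with the highest mean across all samples; z-score each gene row
(mean-center, unit variance); score a signature per sample as the mean of
its member genes' scaled values; compare young (age <= young_max, default
35) to older (age >= old_min, default 50) samples with the two-sided
Wilcoxon rank-sum test; adjust across all tested signatures with the
Holm-Bonferroni step-down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SignatureResult",
    "read_gmt",
    "write_gmt",
    "collapse_probes",
    "scale_genes",
    "score_signatures",
    "holm_adjust",
    "compare_age_groups",
]

log = logging.getLogger(__name__)


@dataclass
class SignatureResult:
    signature: str
    n_genes_present: int
    median_young: float
    median_old: float
    direction: str  # "up" | "down" with age
    statistic: float
    p_value: float
    adjusted_p: float


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT (name <tab> description <tab> genes...)."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = [g for g in parts[2:] if g]
    return out


def write_gmt(signatures: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in signatures.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def collapse_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Gene-level matrix keeping, per gene, the probe whose mean across all
    samples is maximal; ties break by probe identifier order.  Probes
    without annotation are dropped (count logged)."""
    if matrix.empty:
        raise ValueError("empty expression matrix")
    ann = annotation["gene"] if "gene" in annotation else annotation.iloc[:, 0]
    known = matrix.index.intersection(ann.index)
    dropped = len(matrix) - len(known)
    if dropped:
        log.info("dropped %d unannotated probes", dropped)
    sub = matrix.loc[known].sort_index()  # probe-id order fixes ties
    means = sub.mean(axis=1)
    genes = ann.loc[sub.index]
    best = means.groupby(genes).idxmax()
    out = sub.loc[best.to_numpy()]
    out.index = best.index
    return out.sort_index()


def scale_genes(gene_matrix: pd.DataFrame, center_only: bool = False) -> pd.DataFrame:
    """Row-wise scaling across samples: mean 0, and (unless center_only)
    sd 1.  Zero-variance genes are dropped with a log message."""
    centered = gene_matrix.sub(gene_matrix.mean(axis=1), axis=0)
    if center_only:
        return centered
    sd = gene_matrix.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.warning("dropped %d zero-variance genes", int(flat.sum()))
    return centered.loc[~flat].div(sd[~flat], axis=0)


def score_signatures(
    scaled: pd.DataFrame, signatures: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-sample signature scores: mean of the scaled values of member
    genes present in the matrix.  Signatures with no gene present get an
    all-NaN row (flagged absent, not zero)."""
    rows = {}
    for name, genes in signatures.items():
        present = scaled.index.intersection(genes)
        if len(present) < len(set(genes)):
            log.info("signature %s: %d/%d genes present", name, len(present), len(set(genes)))
        if len(present) == 0:
            rows[name] = pd.Series(np.nan, index=scaled.columns)
        else:
            rows[name] = scaled.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down: sorted p * (m - rank), cummax-enforced
    monotone, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    stepped = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def compare_age_groups(
    scores: pd.DataFrame,
    ages: pd.Series,
    young_max: float = 35.0,
    old_min: float = 50.0,
) -> list[SignatureResult]:
    """Two-sided Wilcoxon rank-sum per signature between young and older
    samples (mid-age samples excluded), Holm-adjusted across all tested
    signatures.  Direction is from group medians (older vs young)."""
    ages = ages.loc[scores.columns]
    young = scores.columns[(ages <= young_max).to_numpy()]
    old = scores.columns[(ages >= old_min).to_numpy()]
    if len(young) < 2 or len(old) < 2:
        raise ValueError("each age group needs at least 2 samples")
    tested, results = [], []
    for name, row in scores.iterrows():
        a, b = row[young].to_numpy(), row[old].to_numpy()
        if np.isnan(a).all() or np.isnan(b).all():
            continue
        stat, p = sps.ranksums(b, a)
        med_y, med_o = float(np.nanmedian(a)), float(np.nanmedian(b))
        tested.append(p)
        results.append(
            SignatureResult(
                signature=name,
                n_genes_present=-1,
                median_young=med_y,
                median_old=med_o,
                direction="up" if med_o >= med_y else "down",
                statistic=float(stat),
                p_value=float(p),
                adjusted_p=np.nan,
            )
        )
    adj = holm_adjust(np.array(tested)) if tested else np.array([])
    for res, a in zip(results, adj):
        res.adjusted_p = float(a)
    return results
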