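"""Synthetic probe-level expression matrices with planted signature shifts.

Emulates the structure of a log2-transformed, quantile-normalized
microarray study of reduction-mammoplasty breast tissue: multiple probes
per gene, sample ages spanning young (<= 35 y, n = 51 by default) and
older (>= 50 y, n = 23) groups plus an intermediate band excluded from
testing, and age-group mean shifts applied only to the member genes of
selected signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionSpec", "generate_expression"]


@dataclass
class ExpressionSpec:
    """Gene universe, sample-group sizes and planted effects.

    signature_effects maps signature name -> shift of the older group in
    units of the per-sample noise sd (positive = up with age).
    """

    n_genes: int = 400
    max_probes_per_gene: int = 3
    n_young: int = 51
    n_old: int = 23
    n_mid: int = 47  # samples with 35 < age < 50, excluded from testing
    signature_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    base_mean_sd: tuple[float, float] = (7.0, 1.0)
    probe_offset_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError("group sizes must be >= 2")
        if self.n_genes < 1 or self.max_probes_per_gene < 1:
            raise ValueError("need at least one gene and one probe per gene")
        if not all(np.isfinite(v) for v in self.signature_effects.values()):
            raise ValueError("signature shifts must be finite")


def gene_universe(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def generate_expression(
    spec: ExpressionSpec, signatures: dict[str, list[str]]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate (probe-level matrix, probe->gene annotation, sample ages).

    The matrix is probes x samples (log2 scale).  Every gene gets >= 1
    probe; effects from ``spec.signature_effects`` are added to the older
    group's samples on the member genes of the named signatures only.
    Signatures referencing genes outside the universe raise a ValueError
    listing the missing genes.
    """
    spec.validate()
    genes = gene_universe(spec.n_genes)
    gene_set = set(genes)
    missing = sorted(
        {g for name in spec.signature_effects for g in signatures.get(name, []) if g not in gene_set}
        | {g for name, members in signatures.items() for g in members if g not in gene_set}
    )
    if missing:
        raise ValueError(f"signatures reference unknown genes: {missing}")

    rng = np.random.default_rng(spec.seed)
    ages = np.concatenate(
        [
            rng.uniform(24.0, 35.0, size=spec.n_young),
            rng.uniform(36.0, 49.9, size=spec.n_mid),
            rng.uniform(50.0, 74.0, size=spec.n_old),
        ]
    )
    samples = [f"S{i:03d}" for i in range(len(ages))]
    old = ages >= 50.0

    # per-gene shift accumulated over all signatures containing the gene
    shift = dict.fromkeys(genes, 0.0)
    for name, eff in spec.signature_effects.items():
        if name not in signatures:
            raise ValueError(f"effect given for unknown signature {name!r}")
        for g in signatures[name]:
            shift[g] += eff * spec.noise_sd

    n_probes = rng.integers(1, spec.max_probes_per_gene + 1, size=spec.n_genes)
    probe_ids, probe_gene, rows = [], [], []
    for gi, g in enumerate(genes):
        base = rng.normal(*spec.base_mean_sd)
        for p in range(int(n_probes[gi])):
            pid = f"{g}_p{p}"
            probe_ids.append(pid)
            probe_gene.append(g)
            mu = base + rng.normal(0.0, spec.probe_offset_sd)
            vals = mu + rng.normal(0.0, spec.noise_sd, size=len(ages))
            if shift[g] != 0.0:
                vals = vals + np.where(old, shift[g], 0.0)
            rows.append(vals)

    matrix = pd.DataFrame(np.array(rows), index=probe_ids, columns=samples)
    annotation = pd.DataFrame({"probe": probe_ids, "gene": probe_gene}).set_index("probe")
    return matrix, annotation, pd.Series(ages, index=samples, name="age_y")
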