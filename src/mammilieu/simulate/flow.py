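"""Synthetic flow-cytometry event tables for the filtrate/PBMC panel.

Events are a mixture of truth-labeled populations — dead cells (7-AAD+),
CD45-negative non-leukocytes (epithelial/fibroblast/endothelial), and
CD45+ subsets (CD3+ T, CD19+ B, CD14+ monocyte/macrophage, other
leukocytes) — with per-channel log-normal intensities emitted as already
compensated values.  A configurable fraction of CD45+ events is planted
inside the gate's ambiguity band on one subset channel so that gated
subset percentages do not sum to 100, as in manual gating that discards
ambiguously positive events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FlowProfile", "generate_flow_events", "CHANNELS"]

CHANNELS = ("CD45", "CD3", "CD19", "CD14", "7AAD")

#: log10 intensity of positive / negative populations (means); gates ship
#: with a band between them.
_POS_LOG, _NEG_LOG = 3.0, 1.0
_BAND_LOG = 2.0  # ambiguous events sit here


@dataclass
class FlowProfile:
    """Mixture weights and noise for one synthetic sample."""

    n_events: int = 60_000
    viable_fraction: float = 0.92
    cd45_fraction: float = 0.11  # of viable mononuclear events
    subset_fractions: dict[str, float] = field(
        default_factory=lambda: {"CD3": 0.45, "CD19": 0.12, "CD14": 0.20}
    )
    ambiguous_fraction: float = 0.05  # of CD45+ events, planted in-band
    pos_log_sd: float = 0.12
    neg_log_sd: float = 0.18
    sample_id: str = "S0"
    donor_id: str = "D0"
    source: str = "filtrate"  # or "PBMC"
    seed: int = 0

    def validate(self) -> None:
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        fr = [self.viable_fraction, self.cd45_fraction, self.ambiguous_fraction]
        fr += list(self.subset_fractions.values())
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(self.subset_fractions.values()) + self.ambiguous_fraction > 1.0 + 1e-9:
            raise ValueError("subset + ambiguous fractions exceed 1")


def _lognorm(rng, n, mean_log, sd):
    return np.power(10.0, rng.normal(mean_log, sd, size=n))


def generate_flow_events(profile: FlowProfile) -> pd.DataFrame:
    """Event table with channel intensities and a ``truth`` label column.

    Truth labels: dead, non_leukocyte, T, B, mono, other_leukocyte,
    ambiguous.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    n = profile.n_events

    u = rng.random(n)
    dead = u >= profile.viable_fraction
    leuk = (~dead) & (rng.random(n) < profile.cd45_fraction)

    truth = np.full(n, "non_leukocyte", dtype=object)
    truth[dead] = "dead"
    sub_names = list(profile.subset_fractions)
    probs = [profile.subset_fractions[s] for s in sub_names] + [profile.ambiguous_fraction]
    probs.append(max(0.0, 1.0 - sum(probs)))
    labels = sub_names + ["ambiguous", "other_leukocyte"]
    name_map = {"CD3": "T", "CD19": "B", "CD14": "mono"}
    idx_leuk = np.flatnonzero(leuk)
    draw = rng.choice(len(labels), size=len(idx_leuk), p=np.array(probs) / sum(probs))
    for k, lab in enumerate(labels):
        truth[idx_leuk[draw == k]] = name_map.get(lab, lab)

    cols = {ch: _lognorm(rng, n, _NEG_LOG, profile.neg_log_sd) for ch in CHANNELS}
    cols["7AAD"][dead] = _lognorm(rng, int(dead.sum()), _POS_LOG, profile.pos_log_sd)
    is_cd45 = np.isin(truth, ["T", "B", "mono", "other_leukocyte", "ambiguous"])
    cols["CD45"][is_cd45] = _lognorm(rng, int(is_cd45.sum()), _POS_LOG, profile.pos_log_sd)
    for ch, lab in (("CD3", "T"), ("CD19", "B"), ("CD14", "mono")):
        m = truth == lab
        cols[ch][m] = _lognorm(rng, int(m.sum()), _POS_LOG, profile.pos_log_sd)
    amb = truth == "ambiguous"
    if amb.any():
        # park each ambiguous event inside the band on one subset channel
        pick = rng.choice(["CD3", "CD19", "CD14"], size=int(amb.sum()))
        for ch in ("CD3", "CD19", "CD14"):
            sel = np.flatnonzero(amb)[pick == ch]
            cols[ch][sel] = _lognorm(rng, len(sel), _BAND_LOG, 0.03)

    df = pd.DataFrame(cols)
    df["truth"] = truth
    df["sample_id"] = profile.sample_id
    df["donor_id"] = profile.donor_id
    df["source"] = profile.source
    return df
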