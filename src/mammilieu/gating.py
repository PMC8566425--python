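"""Flow-cytometry gating: viability exclusion, CD45 gating, subsets.

Gates are rectangular 1-D thresholds per channel with an ambiguity band:
events above the band are positive, below it negative, and events inside
the band are excluded as ambiguous, so gated subset percentages can sum to
less than 100 (the manual-gating behaviour of discarding ambiguously
positive events).  Dead cells (7-AAD positive) are removed first; samples
with fewer than 10,000 surviving viable events are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ChannelGate",
    "GateConfig",
    "InsufficientEventsError",
    "gate_viable",
    "classify_events",
    "gate_subsets",
    "blood_tissue_correlation",
]


class InsufficientEventsError(RuntimeError):
    """Sample has fewer viable events than the inclusion rule requires."""


@dataclass(frozen=True)
class ChannelGate:
    """Ambiguity band [low, high] on one channel: > high is positive,
    < low negative, inside the band ambiguous."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low <= 0 or self.high < self.low:
            raise ValueError("gate thresholds must be positive with high >= low")

    def status(self, values: np.ndarray) -> np.ndarray:
        """+1 positive, 0 ambiguous, -1 negative."""
        v = np.asarray(values, dtype=float)
        return np.where(v > self.high, 1, np.where(v < self.low, -1, 0))


def _default_gates() -> dict[str, ChannelGate]:
    # between the synthetic negative (10^1) and positive (10^3) populations
    band = ChannelGate(low=10**1.8, high=10**2.2)
    return {ch: band for ch in ("CD45", "CD3", "CD19", "CD14", "7AAD")}


@dataclass
class GateConfig:
    gates: dict[str, ChannelGate] = field(default_factory=_default_gates)
    min_viable_events: int = 10_000
    subset_channels: tuple[str, ...] = ("CD3", "CD19", "CD14")


def gate_viable(events: pd.DataFrame, config: GateConfig | None = None) -> pd.DataFrame:
    """Remove 7-AAD-positive (dead) events; raise if fewer than
    min_viable_events survive (sample excluded from analysis)."""
    config = config or GateConfig()
    if "7AAD" not in events.columns:
        raise ValueError("viability channel '7AAD' missing")
    status = config.gates["7AAD"].status(events["7AAD"].to_numpy())
    viable = events.loc[status <= 0]
    if len(viable) < config.min_viable_events:
        raise InsufficientEventsError(
            f"insufficient events: {len(viable)} viable < {config.min_viable_events}"
        )
    return viable


#: gated label per subset channel
_SUBSET_LABEL = {"CD3": "T", "CD19": "B", "CD14": "mono"}


def classify_events(viable: pd.DataFrame, config: GateConfig | None = None) -> pd.Series:
    """Per-event gate assignment among viable events.

    Labels: ``non_leukocyte`` (CD45 not positive), ``ambiguous`` (in a
    band, or positive for more than one subset marker), T / B / mono
    (positive for exactly that marker, others negative), and
    ``other_leukocyte`` (CD45+ but negative on all subset markers).
    """
    config = config or GateConfig()
    out = np.full(len(viable), "non_leukocyte", dtype=object)
    cd45 = config.gates["CD45"].status(viable["CD45"].to_numpy())
    pos = cd45 == 1
    status = {ch: config.gates[ch].status(viable[ch].to_numpy()) for ch in config.subset_channels}
    any_ambig = np.any([s == 0 for s in status.values()], axis=0)
    n_pos = np.sum([s == 1 for s in status.values()], axis=0)
    out[pos] = "other_leukocyte"
    out[pos & (any_ambig | (n_pos > 1))] = "ambiguous"
    for ch in config.subset_channels:
        out[pos & ~any_ambig & (n_pos == 1) & (status[ch] == 1)] = _SUBSET_LABEL.get(ch, ch)
    return pd.Series(out, index=viable.index, name="gated")


def gate_subsets(
    viable: pd.DataFrame, config: GateConfig | None = None
) -> dict[str, float | bool]:
    """Gate CD45 first, then subsets within CD45+.

    Returns percentages: ``cd45_pct_of_viable`` plus, for each subset
    channel, the percent of CD45+ events positive for exactly that channel
    (others negative).  Events ambiguous on any subset channel, or positive
    for more than one, are excluded from the numerators but stay in the
    CD45+ denominator, so subset percentages may sum below 100.
    """
    config = config or GateConfig()
    out: dict[str, float | bool] = {"flagged": False}
    gated = classify_events(viable, config)
    n_cd45 = int((gated != "non_leukocyte").sum())
    out["cd45_pct_of_viable"] = 100.0 * n_cd45 / len(viable) if len(viable) else np.nan
    if n_cd45 == 0:
        out["flagged"] = True
        for ch in config.subset_channels:
            out[f"{ch}_pct_of_cd45"] = np.nan
        return out
    for ch in config.subset_channels:
        lab = _SUBSET_LABEL.get(ch, ch)
        out[f"{ch}_pct_of_cd45"] = 100.0 * int((gated == lab).sum()) / n_cd45
    return out


def blood_tissue_correlation(paired: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of per-donor subset percentages between blood
    and tissue, per cell type.

    ``paired`` needs columns cell_type, tissue_pct, blood_pct (one row per
    donor x cell type).
    """
    rows = []
    for cell_type, grp in paired.groupby("cell_type"):
        x = grp["tissue_pct"].to_numpy(dtype=float)
        y = grp["blood_pct"].to_numpy(dtype=float)
        if len(x) < 3:
            raise ValueError(f"need >= 3 donor-matched pairs for {cell_type}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in {cell_type} percentages")
        r, p = sps.pearsonr(x, y)
        rows.append({"cell_type": cell_type, "n": len(x), "r": float(r), "p_value": float(p)})
    return pd.DataFrame(rows)
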