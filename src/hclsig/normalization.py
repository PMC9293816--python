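"""Three-stage nCounter normalization chain.

Stage order is fixed: positive-control scaling, negative-probe background
correction, housekeeping normalization.

1. Positive-control scaling corrects lane-to-lane hybridization efficiency:
   per lane i the geometric mean g_i of the positive spike-in probes is
   computed and every non-positive probe is multiplied by
   F_i = mean_j(g_j) / g_i, pulling all lanes to the common spike-in level.
2. Background correction estimates non-specific binding per lane as
   b_i = mean(negative probes) + k * sample SD(negative probes) (k = 2 by
   default) and subtracts b_i from endogenous and housekeeping counts,
   flooring at zero.
3. Housekeeping normalization corrects for RNA content: per lane the
   geometric mean h_i of the (background-corrected) housekeeping genes gives
   K_i = mean_j(h_j) / h_i, applied to the endogenous counts.

The reference for both scaling stages is the arithmetic mean over lanes of
the per-lane geometric means, the usual nCounter convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_io import CountMatrix, LaneFactors, PanelIOError

logger = logging.getLogger("hclsig")

#: Housekeeping genes of the 299-probe panel used for content normalization.
DEFAULT_HOUSEKEEPING = (
    "ACTB", "TBP", "RPL19", "RPLP0", "G6PD", "ABCF1", "B2M", "TPT1", "RPS23",
)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationConfig:
    housekeeping_genes: tuple[str, ...] = DEFAULT_HOUSEKEEPING
    background_sd_multiplier: float = 2.0
    floor_at_zero: bool = True
    geomean_zero_policy: str = "substitute_one"  # or "exclude_zeros"

    def __post_init__(self) -> None:
        if not self.housekeeping_genes:
            raise NormalizationError("housekeeping gene list must be non-empty")
        if self.background_sd_multiplier < 0:
            raise NormalizationError("background SD multiplier must be >= 0")
        if self.geomean_zero_policy not in ("substitute_one", "exclude_zeros"):
            raise NormalizationError(
                f"unknown geomean zero policy {self.geomean_zero_policy!r}"
            )


def _geomean_columns(values: pd.DataFrame, policy: str) -> pd.Series:
    """Per-lane geometric mean of the given probe rows, with zero handling.

    ``substitute_one`` replaces zeros by 1 inside the geometric mean only;
    ``exclude_zeros`` drops them (hard error if a lane is all zeros).
    """
    arr = values.to_numpy(dtype=float)
    if policy == "substitute_one":
        arr = np.where(arr == 0, 1.0, arr)
        return pd.Series(np.exp(np.log(arr).mean(axis=0)), index=values.columns)
    out = {}
    for lane in values.columns:
        col = values[lane].to_numpy(dtype=float)
        col = col[col > 0]
        if col.size == 0:
            raise NormalizationError(
                f"lane {lane!r}: geometric mean undefined (all values zero "
                f"under exclude_zeros)"
            )
        out[lane] = float(np.exp(np.log(col).mean()))
    return pd.Series(out)


def positive_control_scale(
    counts: CountMatrix,
    config: NormalizationConfig | None = None,
    factors: LaneFactors | None = None,
) -> tuple[CountMatrix, LaneFactors]:
    """Scale each lane to the common positive spike-in level.

    Multiplies every non-positive-class probe in lane i by
    F_i = mean_j(g_j) / g_i where g_i is the geometric mean of lane i's
    positive probes.
    """
    config = config or NormalizationConfig()
    counts.panel.require_normalizable()
    pos = counts.subset_rows(counts.panel.positive)
    if (pos.to_numpy() <= 0).any() and config.geomean_zero_policy != "substitute_one":
        lane = pos.columns[(pos <= 0).any(axis=0)][0]
        raise NormalizationError(
            f"lane {lane!r} has a zero positive-probe count; geometric mean "
            f"undefined"
        )
    g = _geomean_columns(pos, config.geomean_zero_policy)
    f = g.mean() / g
    values = counts.values.copy()
    non_pos = counts.panel.table.index[counts.panel.table["probe_class"] != "positive"]
    values.loc[non_pos] = values.loc[non_pos].mul(f, axis=1)
    factors = factors or LaneFactors.empty(counts.lanes)
    factors.table["positive_factor"] = f
    factors.validate()
    new_state = "positive_scaled" if counts.state == "raw" else counts.state
    out = counts.with_values(values, new_state, "positive-control scaling applied")
    return out, factors


def background_correct(
    counts: CountMatrix,
    config: NormalizationConfig | None = None,
    factors: LaneFactors | None = None,
) -> tuple[CountMatrix, LaneFactors]:
    """Subtract the per-lane background estimate mean(neg) + k*SD(neg).

    Sample SD (n-1 denominator) is used, so at least two negative probes are
    required.  Applied to endogenous and housekeeping probes; results are
    floored at zero unless configured otherwise.
    """
    config = config or NormalizationConfig()
    if counts.state not in ("raw", "positive_scaled"):
        raise NormalizationError(
            f"background correction expects raw or positive-scaled counts, "
            f"got {counts.state!r}"
        )
    neg = counts.subset_rows(counts.panel.negative)
    if len(neg) < 2:
        raise NormalizationError(
            f"background correction needs >= 2 negative probes, found {len(neg)}"
        )
    b = neg.mean(axis=0) + config.background_sd_multiplier * neg.std(axis=0, ddof=1)
    values = counts.values.copy()
    target = counts.panel.table.index[
        counts.panel.table["probe_class"].isin(["endogenous", "housekeeping"])
    ]
    corrected = values.loc[target].sub(b, axis=1)
    if config.floor_at_zero:
        corrected = corrected.clip(lower=0.0)
    values.loc[target] = corrected
    factors = factors or LaneFactors.empty(counts.lanes)
    factors.table["background"] = b
    factors.validate()
    out = counts.with_values(
        values, "background_corrected",
        f"background corrected (mean + {config.background_sd_multiplier} SD of negatives)",
    )
    return out, factors


def housekeeping_normalize(
    counts: CountMatrix,
    config: NormalizationConfig | None = None,
    factors: LaneFactors | None = None,
) -> tuple[CountMatrix, LaneFactors]:
    """Equalize lanes on the geometric mean of the housekeeping genes.

    Endogenous counts in lane i are multiplied by K_i = mean_j(h_j) / h_i.
    Housekeeping genes are matched case-insensitively against panel symbols.
    """
    config = config or NormalizationConfig()
    symbols = counts.panel.table["gene_symbol"].str.upper()
    wanted = {g.upper() for g in config.housekeeping_genes}
    hk_probes = counts.panel.table.index[
        symbols.isin(wanted)
        & (counts.panel.table["probe_class"] == "housekeeping")
    ]
    if len(hk_probes) == 0:
        # fall back to symbol match regardless of class (custom panels)
        hk_probes = counts.panel.table.index[symbols.isin(wanted)]
    found = {symbols[p] for p in hk_probes}
    missing = wanted - found
    if missing:
        raise NormalizationError(
            f"housekeeping gene(s) not in panel: {sorted(missing)}"
        )
    h = _geomean_columns(counts.subset_rows(hk_probes), config.geomean_zero_policy)
    if (h <= 0).any():
        lane = h.index[h <= 0][0]
        raise NormalizationError(f"lane {lane!r}: housekeeping geometric mean is 0")
    k = h.mean() / h
    values = counts.values.copy()
    endo = counts.panel.endogenous
    values.loc[endo] = values.loc[endo].mul(k, axis=1)
    factors = factors or LaneFactors.empty(counts.lanes)
    factors.table["housekeeping_factor"] = k
    factors.validate()
    out = counts.with_values(values, "normalized", "housekeeping normalization applied")
    return out, factors


def normalize_pipeline(
    counts: CountMatrix, config: NormalizationConfig | None = None
) -> tuple[CountMatrix, LaneFactors]:
    """Run the full chain positive -> background -> housekeeping."""
    config = config or NormalizationConfig()
    if counts.state != "raw":
        raise NormalizationError(f"pipeline expects raw counts, got {counts.state!r}")
    scaled, factors = positive_control_scale(counts, config)
    corrected, factors = background_correct(scaled, config, factors)
    normalized, factors = housekeeping_normalize(corrected, config, factors)
    return normalized, factors
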