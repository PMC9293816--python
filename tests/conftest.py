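"""Shared fixtures: tiny hand-constructed panels and count matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hclsig.panel_io import CountMatrix, ProbePanel


def make_panel(n_endo=5, n_pos=2, n_neg=2, n_hk=2, hk_symbols=None) -> ProbePanel:
    ids, symbols, classes = [], [], []
    for i in range(n_endo):
        ids.append(f"E{i+1}"), symbols.append(f"GENE{i+1}"), classes.append("endogenous")
    for i in range(n_hk):
        sym = hk_symbols[i] if hk_symbols else f"HK{i+1}"
        ids.append(f"H{i+1}"), symbols.append(sym), classes.append("housekeeping")
    for i in range(n_pos):
        ids.append(f"P{i+1}"), symbols.append(f"POS{i+1}"), classes.append("positive")
    for i in range(n_neg):
        ids.append(f"N{i+1}"), symbols.append(f"NEG{i+1}"), classes.append("negative")
    return ProbePanel(pd.DataFrame(
        {"gene_symbol": symbols, "probe_class": classes, "spike_concentration": np.nan},
        index=pd.Index(ids, name="probe_id"),
    ))


def make_counts(values: dict[str, list[float]], panel: ProbePanel | None = None,
                groups: dict[str, str] | None = None, state: str = "raw") -> CountMatrix:
    """Build a CountMatrix from lane -> per-probe count lists."""
    panel = panel or make_panel()
    df = pd.DataFrame(values, index=panel.table.index, dtype=float)
    meta = None
    if groups:
        meta = pd.DataFrame(
            {"group": [groups[l] for l in df.columns], "source_label": df.columns},
            index=pd.Index(df.columns, name="lane_id"),
        )
    return CountMatrix(panel=panel, values=df, state=state, lane_meta=meta)


@pytest.fixture
def small_panel() -> ProbePanel:
    return make_panel()


@pytest.fixture
def three_lane_counts(small_panel) -> CountMatrix:
    # 5 endogenous + 2 housekeeping + 2 positive + 2 negative probes
    return make_counts(
        {
            "L1": [25, 40, 7, 100, 0, 200, 300, 50, 80, 4, 6],
            "L2": [30, 35, 9, 110, 2, 210, 290, 50, 80, 5, 5],
            "L3": [20, 45, 8, 90, 1, 190, 310, 50, 80, 6, 4],
        },
        panel=small_panel,
    )


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up BH: p_(k) * m / k with a cumulative minimum from
    the largest rank down, mapped back to input order and capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out
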