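"""Synthetic nCounter experiments with planted ground truth.

The generator emulates the statistical situation of a blood-panel study of
hairy cell leukemia: unsorted leukemic samples are mixtures of malignant B
cells (fraction 0.3-0.9 of nucleated cells) with contaminating T cells and
monocytes; the reference groups are normal mononuclear cells (nMNC, 12-30%
normal B cells) and purified normal B cells (nB, >= 95% pure).  Each lane
carries a log-normal technical scale factor, a positive spike-in ladder, and
Poisson negative probes; endogenous counts are negative-binomial around the
lane-scaled mixture mean

    m_{g,i} = L_i * sum_c f_{c,i} * mu_{g,c} + background_lambda

with variance m + alpha * m^2 (alpha -> 0 recovers Poisson, the behavior of
technical nCounter replicates).

Planted structure makes every downstream module testable: a block of
B-lineage genes (high in both B cell types, low in T/monocytes) yields the
B-cell-specific set; a default of 17 genes up-regulated 3-9x in malignant B
cells yields the leukemia over-expression signature; 17 B-lineage genes
down-regulated 3-9x yield the under-expression set; and 25 genes differing
between the classical and variant malignant profiles make the cHCL/vHCL
contrast non-trivial.  Every realized parameter is emitted in a
:class:`SimulationTruth` ledger sufficient to recompute each expected count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deconv_de import SignatureSets
from .panel_io import CountMatrix, ProbePanel

logger = logging.getLogger("hclsig")

HOUSEKEEPING_SYMBOLS = (
    "ACTB", "TBP", "RPL19", "RPLP0", "G6PD", "ABCF1", "B2M", "TPT1", "RPS23",
)
CELL_TYPES = ("malignant_B", "normal_B", "T_mono_other")


class SimulationError(ValueError):
    pass


@dataclass
class ExperimentDesign:
    """Design of a simulated experiment; defaults mirror the study layout.

    13 leukemia lanes (11 classical + 2 variant), 8 nMNC, 3 nB; 290
    endogenous + 9 housekeeping genes; 6 positive spike-ins spanning a 128x
    geometric ladder and 8 negative probes.
    """

    n_chcl: int = 11
    n_vhcl: int = 2
    n_nmnc: int = 8
    n_nb: int = 3
    tumor_fraction: tuple[float, float] = (0.3, 0.9)
    b_fraction: tuple[float, float] = (0.12, 0.30)
    nb_purity: float = 0.95
    n_endogenous: int = 290
    n_housekeeping: int = 9
    n_positive: int = 6
    n_negative: int = 8
    lane_factor_sd: float = 0.25
    nb_dispersion: float = 0.05
    background_lambda: float = 8.0
    n_bcell_genes: int = 100
    bcell_t_mono_ratio: float = 0.1
    n_planted_up: int = 17
    n_planted_down: int = 17
    planted_fc_range: tuple[float, float] = (3.0, 9.0)
    n_chcl_vhcl_de: int = 25
    chcl_vhcl_fc_range: tuple[float, float] = (4.0, 16.0)
    baseline_log_mean: float = float(np.log(150.0))
    baseline_log_sd: float = 1.0
    hk_mean_range: tuple[float, float] = (300.0, 2000.0)
    positive_ladder_top: float = 16000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.tumor_fraction, self.b_fraction):
            if not (0 <= lo <= hi <= 1):
                raise SimulationError("fraction ranges must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.nb_purity <= 1):
            raise SimulationError("nb purity must lie in [0, 1]")
        if self.n_housekeeping != len(HOUSEKEEPING_SYMBOLS):
            raise SimulationError(
                f"housekeeping count fixed at {len(HOUSEKEEPING_SYMBOLS)}"
            )
        if min(self.n_chcl + self.n_vhcl, self.n_nmnc, self.n_nb) < 2:
            raise SimulationError("each analyzable group needs >= 2 lanes")

    def positive_ladder(self) -> np.ndarray:
        """Six spike-in levels in geometric progression over a 128x range."""
        ratio = 128.0 ** (1.0 / (self.n_positive - 1))
        return self.positive_ladder_top / ratio ** np.arange(self.n_positive)


@dataclass
class SimulationTruth:
    """Everything needed to recompute each lane's expected counts."""

    seed: int
    lane_groups: dict[str, str]
    lane_factors: dict[str, float]
    mixing_fractions: dict[str, dict[str, float]]  # lane -> cell type -> f
    profiles: pd.DataFrame  # genes x cell types (+ cHCL/vHCL variants), counts scale
    planted_up: dict[str, float]
    planted_down: dict[str, float]
    chcl_vhcl_de: dict[str, float]  # gene -> cHCL/vHCL fold (malignant profile)
    bcell_genes: list[str]
    background_lambda: float
    nb_dispersion: float

    def expected_mean(self, gene: str, lane: str) -> float:
        group = self.lane_groups[lane]
        profile_col = {
            "cHCL": "malignant_B_chcl", "vHCL": "malignant_B_vhcl",
        }.get(group)
        total = 0.0
        for ct, f in self.mixing_fractions[lane].items():
            col = profile_col if (ct == "malignant_B" and profile_col) else ct
            total += f * float(self.profiles.loc[gene, col])
        return self.lane_factors[lane] * total + self.background_lambda

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["profiles"] = self.profiles.round(6).to_dict(orient="index")
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        return path


def _make_profiles(design: ExperimentDesign, rng: np.random.Generator):
    """Draw per-cell-type expected expression and plant the DE structure."""
    genes = [f"G{i:03d}" for i in range(1, design.n_endogenous + 1)]
    base = np.exp(rng.normal(design.baseline_log_mean, design.baseline_log_sd,
                             size=design.n_endogenous))
    profiles = pd.DataFrame(
        {ct: base.copy() for ct in CELL_TYPES},
        index=pd.Index(genes, name="gene"),
    )
    # B-lineage block: expressed in both B cell types, depleted in T/monocytes
    bcell_genes = list(genes[: design.n_bcell_genes])
    profiles.loc[bcell_genes, "T_mono_other"] *= design.bcell_t_mono_ratio

    lo, hi = design.planted_fc_range
    # planted up: generic genes (outside the B block) so the malignant signal
    # must survive dilution against both references
    generic = genes[design.n_bcell_genes:]
    up = list(rng.choice(generic, size=design.n_planted_up, replace=False))
    planted_up = {g: float(fc) for g, fc in zip(up, rng.uniform(lo, hi, len(up)))}
    # planted down: B-lineage genes (a silenced non-B gene is undetectable in
    # a mixture; losing a B-program gene is the realistic analogue)
    down_pool = [g for g in bcell_genes if g not in planted_up]
    down = list(rng.choice(down_pool, size=design.n_planted_down, replace=False))
    planted_down = {g: float(fc) for g, fc in zip(down, rng.uniform(lo, hi, len(down)))}

    for g, fc in planted_up.items():
        profiles.loc[g, "malignant_B"] = profiles.loc[g, "normal_B"] * fc
    for g, fc in planted_down.items():
        profiles.loc[g, "malignant_B"] = profiles.loc[g, "normal_B"] / fc

    # classical-vs-variant differences on the malignant profile only
    clo, chi = design.chcl_vhcl_fc_range
    pool = [g for g in genes if g not in planted_up and g not in planted_down]
    cv = list(rng.choice(pool, size=design.n_chcl_vhcl_de, replace=False))
    cv_fc = rng.uniform(clo, chi, len(cv))
    signs = rng.random(len(cv)) < 0.5
    chcl_vhcl = {g: float(fc if s else 1.0 / fc)
                 for g, fc, s in zip(cv, cv_fc, signs)}
    profiles["malignant_B_chcl"] = profiles["malignant_B"]
    profiles["malignant_B_vhcl"] = profiles["malignant_B"]
    for g, fc in chcl_vhcl.items():
        m = profiles.loc[g, "malignant_B"]
        profiles.loc[g, "malignant_B_chcl"] = m * np.sqrt(fc)
        profiles.loc[g, "malignant_B_vhcl"] = m / np.sqrt(fc)
    return genes, profiles, planted_up, planted_down, chcl_vhcl, bcell_genes


def _mixing(design: ExperimentDesign, group: str, rng: np.random.Generator) -> dict[str, float]:
    if group in ("cHCL", "vHCL"):
        f_tumor = rng.uniform(*design.tumor_fraction)
        rest = 1.0 - f_tumor
        f_nb = 0.1 * rest  # small residual normal-B compartment
        return {"malignant_B": f_tumor, "normal_B": f_nb,
                "T_mono_other": rest - f_nb}
    if group == "nMNC":
        f_b = rng.uniform(*design.b_fraction)
        return {"malignant_B": 0.0, "normal_B": f_b, "T_mono_other": 1.0 - f_b}
    if group == "nB":
        f_b = rng.uniform(design.nb_purity, 1.0)
        return {"malignant_B": 0.0, "normal_B": f_b, "T_mono_other": 1.0 - f_b}
    raise SimulationError(f"unknown group {group!r}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with variance mean + alpha * mean^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    if alpha <= 0:
        return rng.poisson(mean)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_experiment(design: ExperimentDesign | None = None,
                        seed: int | None = None) -> tuple[CountMatrix, SimulationTruth]:
    """Generate a raw-state count matrix plus its ground-truth ledger."""
    design = design or ExperimentDesign()
    if seed is not None:
        design = dataclasses.replace(design, seed=seed)
    rng = np.random.default_rng(design.seed)

    genes, profiles, planted_up, planted_down, chcl_vhcl, bcell_genes = \
        _make_profiles(design, rng)

    lane_specs = (
        [("cHCL", f"HCL{i+1:02d}") for i in range(design.n_chcl)]
        + [("vHCL", f"HCL{design.n_chcl+i+1:02d}") for i in range(design.n_vhcl)]
        + [("nMNC", f"MNC{i+1:02d}") for i in range(design.n_nmnc)]
        + [("nB", f"NB{i+1:02d}") for i in range(design.n_nb)]
    )
    lanes = [lane for _, lane in lane_specs]
    groups = {lane: grp for grp, lane in lane_specs}

    hk_means = rng.uniform(*design.hk_mean_range, size=design.n_housekeeping)
    ladder = design.positive_ladder()

    lane_factors: dict[str, float] = {}
    fractions: dict[str, dict[str, float]] = {}
    columns: dict[str, np.ndarray] = {}
    for grp, lane in lane_specs:
        L = float(np.exp(rng.normal(0.0, design.lane_factor_sd)))
        fr = _mixing(design, grp, rng)
        lane_factors[lane] = L
        fractions[lane] = fr
        prof_col = {"cHCL": "malignant_B_chcl", "vHCL": "malignant_B_vhcl"}.get(grp)
        mix_mean = np.zeros(design.n_endogenous)
        for ct, f in fr.items():
            col = prof_col if (ct == "malignant_B" and prof_col) else ct
            mix_mean += f * profiles[col].to_numpy()
        endo_mean = L * mix_mean + design.background_lambda
        endo = _nb_draw(rng, endo_mean, design.nb_dispersion)
        hk = _nb_draw(rng, L * hk_means + design.background_lambda,
                      design.nb_dispersion)
        pos = np.maximum(np.round(L * ladder), 1).astype(int)
        neg = rng.poisson(design.background_lambda, size=design.n_negative)
        columns[lane] = np.concatenate([endo, hk, pos, neg])

    probe_ids = (
        genes
        + [f"HK_{s}" for s in HOUSEKEEPING_SYMBOLS]
        + [f"POS_{chr(65+i)}" for i in range(design.n_positive)]
        + [f"NEG_{chr(65+i)}" for i in range(design.n_negative)]
    )
    symbols = (
        genes
        + list(HOUSEKEEPING_SYMBOLS)
        + [f"POS_{chr(65+i)}" for i in range(design.n_positive)]
        + [f"NEG_{chr(65+i)}" for i in range(design.n_negative)]
    )
    classes = (
        ["endogenous"] * design.n_endogenous
        + ["housekeeping"] * design.n_housekeeping
        + ["positive"] * design.n_positive
        + ["negative"] * design.n_negative
    )
    spike = [np.nan] * len(probe_ids)
    for i in range(design.n_positive):
        spike[design.n_endogenous + design.n_housekeeping + i] = ladder[i]
    panel = ProbePanel(pd.DataFrame(
        {"gene_symbol": symbols, "probe_class": classes, "spike_concentration": spike},
        index=pd.Index(probe_ids, name="probe_id"),
    ))
    values = pd.DataFrame(columns, index=panel.table.index, columns=lanes)
    meta = pd.DataFrame(
        {"group": [groups[l] for l in lanes], "source_label": lanes},
        index=pd.Index(lanes, name="lane_id"),
    )
    cm = CountMatrix(panel=panel, values=values, state="raw", lane_meta=meta,
                     audit=[f"simulated experiment (seed {design.seed})"])
    truth = SimulationTruth(
        seed=design.seed, lane_groups=groups, lane_factors=lane_factors,
        mixing_fractions=fractions, profiles=profiles,
        planted_up=planted_up, planted_down=planted_down,
        chcl_vhcl_de=chcl_vhcl, bcell_genes=bcell_genes,
        background_lambda=design.background_lambda,
        nb_dispersion=design.nb_dispersion,
    )
    return cm, truth


def truth_recovery_report(truth: SimulationTruth, sets: SignatureSets,
                          universe: set[str] | None = None) -> dict[str, float]:
    """Score the recovered leukemia signature against the planted up genes.

    sensitivity = |recovered & planted| / |planted|; specificity over the
    non-planted endogenous genes; observed FDR = false members / |recovered|
    (0 for an empty recovery).
    """
    planted = set(truth.planted_up)
    recovered = set(sets.hcl_signature)
    if universe is None:
        universe = set(truth.profiles.index)
    if not recovered <= universe or not planted <= universe:
        raise SimulationError("recovered/planted sets exceed the gene universe")
    tp = len(recovered & planted)
    fp = len(recovered - planted)
    negatives = universe - planted
    tn = len(negatives - recovered)
    return {
        "sensitivity": tp / len(planted) if planted else 0.0,
        "specificity": tn / len(negatives) if negatives else 1.0,
        "fdr_observed": fp / len(recovered) if recovered else 0.0,
    }


def write_simulation(cm: CountMatrix, truth: SimulationTruth,
                     out_dir: str | Path) -> dict[str, Path]:
    """Write counts TSV, metadata TSV and truth JSON for a simulated run."""
    from .panel_io import write_count_matrix

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": write_count_matrix(cm, out_dir / "counts.tsv"),
        "metadata": out_dir / "metadata.tsv",
        "truth": truth.to_json(out_dir / "truth.json"),
    }
    assert cm.lane_meta is not None
    cm.lane_meta.to_csv(paths["metadata"], sep="\t")
    return paths
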