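"""Group-contrast differential expression and reference-group signature logic.

The study samples are unsorted white blood cells: leukemic lanes mix malignant
B cells (> 30%) with contaminating T cells and monocytes, while the reference
groups are either the same mixture without tumor (nMNC) or purified normal B
cells (nB).  "Deconvolution" here is set logic over group contrasts, not
numeric proportion estimation: a gene counts as B-cell specific when it is up
in nB vs nMNC, and as leukemia (HCL) specific when it is up in HCL vs *both*
references -- contaminant-driven genes fail the vs-nMNC contrast and
pan-B-cell genes fail the vs-nB contrast, so the intersection isolates the
malignant-B signal.

Each contrast compares the arithmetic group means of normalized counts.  The
selection filters are: expression >= 20 counts in the claimed-expressing
group, fold change >= 2 (or <= 1/2), and Benjamini-Hochberg adjusted p <= 0.05
from a two-sided t-test on log2(x+1) counts.  The default test pools the
group variances: the reference groups here are tiny (down to 2-3 lanes), and
with a 3-lane reference a per-gene Welch test has ~2 degrees of freedom and
essentially no power regardless of effect size.  Welch and Mann-Whitney
remain available through :class:`FilterCriteria`, which also exposes every
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel_io import CountMatrix

logger = logging.getLogger("hclsig")

HCL_GROUPS = ("cHCL", "vHCL")


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class FilterCriteria:
    """Selection thresholds for a group contrast.

    ``expression_group_rule`` decides which group's mean must clear
    ``min_expression``: the claimed-expressing (higher) group, either group,
    or both groups.  ``inclusive_thresholds`` switches between >=/<= (default)
    and strict comparisons.  ``test_method`` is one of ``welch``, ``pooled``,
    ``mannwhitney``.
    """

    min_expression: float = 20.0
    min_fold_change: float = 2.0
    alpha: float = 0.05
    adjust_method: str = "benjamini_hochberg"
    expression_group_rule: str = "higher_group"
    inclusive_thresholds: bool = True
    test_method: str = "pooled"
    zero_mean_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.min_expression < 0:
            raise DEError("min_expression must be >= 0")
        if self.min_fold_change < 1:
            raise DEError("min_fold_change must be >= 1")
        if not (0 < self.alpha < 1):
            raise DEError("alpha must be in (0, 1)")
        if self.adjust_method != "benjamini_hochberg":
            raise DEError(f"unsupported adjust method {self.adjust_method!r}")
        if self.expression_group_rule not in ("higher_group", "either_group", "both_groups"):
            raise DEError(f"unknown expression group rule {self.expression_group_rule!r}")
        if self.test_method not in ("welch", "pooled", "mannwhitney"):
            raise DEError(f"unknown test method {self.test_method!r}")


@dataclass
class ComparisonResult:
    """Per-gene statistics for one group-vs-group contrast.

    ``table`` is indexed by probe_id with columns gene_symbol, mean_a, mean_b,
    fold_change, log2_fc, p_raw, p_adj, passes_expression, passes_fc,
    passes_alpha, selected_up, selected_down.
    """

    group_a: str
    group_b: str
    criteria: FilterCriteria
    table: pd.DataFrame

    def genes_up(self) -> set[str]:
        return set(self.table.loc[self.table["selected_up"], "gene_symbol"])

    def genes_down(self) -> set[str]:
        return set(self.table.loc[self.table["selected_down"], "gene_symbol"])

    def gene_log2fc(self) -> pd.Series:
        """log2 fold change indexed by gene symbol (max |lfc| on symbol ties)."""
        t = self.table.assign(_abs=lambda d: d["log2_fc"].abs())
        t = t.sort_values("_abs").drop_duplicates("gene_symbol", keep="last")
        return t.set_index("gene_symbol")["log2_fc"]


@dataclass
class SignatureSets:
    """The derived gene sets: B-cell-specific, HCL-over vs each reference,
    their intersection (the headline leukemia signature), the HCL-under set,
    and the cHCL/vHCL difference lists."""

    bcell_specific: set[str] = field(default_factory=set)
    hcl_over_vs_nmnc: set[str] = field(default_factory=set)
    hcl_over_vs_nb: set[str] = field(default_factory=set)
    hcl_signature: set[str] = field(default_factory=set)
    hcl_under: set[str] = field(default_factory=set)
    chcl_over_vs_vhcl: set[str] = field(default_factory=set)
    vhcl_over_vs_chcl: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, set[str]]:
        return {k: getattr(self, k) for k in (
            "bcell_specific", "hcl_over_vs_nmnc", "hcl_over_vs_nb",
            "hcl_signature", "hcl_under", "chcl_over_vs_vhcl",
            "vhcl_over_vs_chcl",
        )}

    def venn_counts(self) -> dict[str, int]:
        return {
            "n_bcell_specific": len(self.bcell_specific),
            "n_over_vs_nmnc": len(self.hcl_over_vs_nmnc),
            "n_over_vs_nb": len(self.hcl_over_vs_nb),
            "n_signature": len(self.hcl_signature),
            "n_under": len(self.hcl_under),
        }


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DEError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------


def _p_values(a: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """Two-sided per-gene p values on log2(x+1) counts.

    Degenerate genes (zero variance in both groups) get p = 1 when the means
    agree and p = 0 when they differ: with no within-group spread any
    between-group difference is unambiguous at the resolution of the data.
    """
    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    if method == "mannwhitney":
        p = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided",
                               method="asymptotic").pvalue
    else:
        equal_var = method == "pooled"
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var).pvalue
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        same = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degenerate, np.where(same, 1.0, 0.0), p)
    return p


def compare_groups(
    norm: CountMatrix,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str],
    criteria: FilterCriteria | None = None,
) -> ComparisonResult:
    """Contrast two sample groups over all endogenous genes.

    ``group_a``/``group_b`` may be single labels or label collections (the
    pooled-HCL contrast passes ("cHCL", "vHCL")).  Fold change is
    mean_a / mean_b on normalized counts, with zero means floored at
    ``criteria.zero_mean_floor`` so reciprocal contrasts stay consistent.
    """
    criteria = criteria or FilterCriteria()
    if norm.state != "normalized":
        raise DEError(f"differential expression expects normalized counts, got {norm.state!r}")
    name_a = group_a if isinstance(group_a, str) else "+".join(group_a)
    name_b = group_b if isinstance(group_b, str) else "+".join(group_b)
    lanes_a = norm.lanes_in_group(group_a)
    lanes_b = norm.lanes_in_group(group_b)
    for name, lanes in ((name_a, lanes_a), (name_b, lanes_b)):
        if len(lanes) < 2:
            raise DEError(f"group {name!r} has {len(lanes)} lane(s); >= 2 required")
        if len(lanes) == 2:
            logger.warning("group %r has only 2 lanes; low statistical power", name)

    endo = norm.panel.endogenous
    a = norm.values.loc[endo, lanes_a].to_numpy()
    b = norm.values.loc[endo, lanes_b].to_numpy()
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)

    floor = criteria.zero_mean_floor
    num = np.where(mean_a > 0, mean_a, floor)
    den = np.where(mean_b > 0, mean_b, floor)
    fold = num / den
    p_raw = _p_values(a, b, criteria.test_method)
    p_adj = bh_adjust(p_raw)

    ge = (lambda x, t: x >= t) if criteria.inclusive_thresholds else (lambda x, t: x > t)
    le = (lambda x, t: x <= t) if criteria.inclusive_thresholds else (lambda x, t: x < t)

    fc_up = ge(fold, criteria.min_fold_change)
    fc_down = le(fold, 1.0 / criteria.min_fold_change)
    alpha_ok = le(p_adj, criteria.alpha)

    rule = criteria.expression_group_rule
    if rule == "higher_group":
        expr_up = ge(mean_a, criteria.min_expression)
        expr_down = ge(mean_b, criteria.min_expression)
    elif rule == "either_group":
        expr_up = expr_down = ge(np.maximum(mean_a, mean_b), criteria.min_expression)
    else:  # both_groups
        expr_up = expr_down = ge(np.minimum(mean_a, mean_b), criteria.min_expression)

    table = pd.DataFrame(
        {
            "gene_symbol": norm.panel.table.loc[endo, "gene_symbol"].to_numpy(),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "log2_fc": np.log2(fold),
            "p_raw": p_raw,
            "p_adj": p_adj,
            "passes_expression": ge(np.maximum(mean_a, mean_b), criteria.min_expression),
            "passes_fc": fc_up | fc_down,
            "passes_alpha": alpha_ok,
            "selected_up": fc_up & alpha_ok & expr_up,
            "selected_down": fc_down & alpha_ok & expr_down,
        },
        index=endo,
    )
    return ComparisonResult(group_a=name_a, group_b=name_b, criteria=criteria, table=table)


def derive_signatures(
    norm: CountMatrix,
    criteria: FilterCriteria | None = None,
    under_reference: str = "nB",
    include_chcl_vhcl: bool = True,
) -> SignatureSets:
    """Run the reference-group set logic and return all derived gene sets.

    - B-cell-specific: up in nB vs nMNC.
    - HCL over-expression: up in pooled HCL (cHCL + vHCL) vs nMNC, and vs nB;
      the leukemia signature is their intersection.
    - HCL under-expression: down in HCL vs ``under_reference`` ("nB", "nMNC",
      or "both" = intersection of the two).
    """
    criteria = criteria or FilterCriteria()
    if under_reference not in ("nB", "nMNC", "both"):
        raise DEError(f"unknown under-expression reference {under_reference!r}")
    sets = SignatureSets()
    sets.bcell_specific = compare_groups(norm, "nB", "nMNC", criteria).genes_up()
    vs_nmnc = compare_groups(norm, HCL_GROUPS, "nMNC", criteria)
    vs_nb = compare_groups(norm, HCL_GROUPS, "nB", criteria)
    sets.hcl_over_vs_nmnc = vs_nmnc.genes_up()
    sets.hcl_over_vs_nb = vs_nb.genes_up()
    sets.hcl_signature = sets.hcl_over_vs_nmnc & sets.hcl_over_vs_nb
    if under_reference == "nB":
        sets.hcl_under = vs_nb.genes_down()
    elif under_reference == "nMNC":
        sets.hcl_under = vs_nmnc.genes_down()
    else:
        sets.hcl_under = vs_nb.genes_down() & vs_nmnc.genes_down()
    if include_chcl_vhcl:
        try:
            _, over, under = compare_chcl_vhcl(norm, criteria)
            sets.chcl_over_vs_vhcl, sets.vhcl_over_vs_chcl = over, under
        except DEError as e:
            logger.warning("cHCL/vHCL contrast skipped: %s", e)
    assert sets.hcl_signature <= sets.hcl_over_vs_nmnc
    assert sets.hcl_signature <= sets.hcl_over_vs_nb
    return sets


def compare_chcl_vhcl(
    norm: CountMatrix, criteria: FilterCriteria | None = None
) -> tuple[ComparisonResult, set[str], set[str]]:
    """Contrast classical vs variant leukemia lanes.

    Returns the full ComparisonResult plus the cHCL-over and vHCL-over gene
    sets under the same selection criteria as the main contrasts.
    """
    result = compare_groups(norm, "cHCL", "vHCL", criteria)
    return result, result.genes_up(), result.genes_down()


def fold_change_correlation(
    norm: CountMatrix,
    group_x: str | Sequence[str],
    group_y: str | Sequence[str],
    reference_group: str | Sequence[str],
    criteria: FilterCriteria | None = None,
) -> dict[str, float]:
    """Pearson correlation of two groups' log2 fold changes vs a reference.

    The gene list is the union of genes selected (up or down) in either
    group-vs-reference contrast; r and its two-sided p come from the t
    transform of the sample correlation.
    """
    criteria = criteria or FilterCriteria()
    res_x = compare_groups(norm, group_x, reference_group, criteria)
    res_y = compare_groups(norm, group_y, reference_group, criteria)
    de_genes = (res_x.genes_up() | res_x.genes_down()
                | res_y.genes_up() | res_y.genes_down())
    if len(de_genes) < 3:
        raise DEError(
            f"need >= 3 differentially expressed genes for a correlation, "
            f"found {len(de_genes)}"
        )
    genes = sorted(de_genes)
    x = res_x.gene_log2fc().loc[genes]
    y = res_y.gene_log2fc().loc[genes]
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n_genes": len(genes)}


def signature_decision_grid(
    norm: CountMatrix, base: FilterCriteria | None = None
) -> list[tuple[dict, SignatureSets]]:
    """Derive signatures under every documented analysis choice.

    The published workflow leaves three choices open: the test statistic
    (pooled vs Welch t), threshold boundaries (inclusive vs strict), and the
    reference group for the under-expressed set (nB, nMNC, or both).  This
    enumerates all twelve combinations, returning (choice descriptor,
    SignatureSets) pairs so a reproduction attempt can report which
    configuration matches the published set sizes.
    """
    base = base or FilterCriteria()
    grid = []
    for test in ("pooled", "welch"):
        for inclusive in (True, False):
            crit = replace(base, test_method=test, inclusive_thresholds=inclusive)
            for under_ref in ("nB", "nMNC", "both"):
                sets = derive_signatures(norm, crit, under_reference=under_ref,
                                         include_chcl_vhcl=False)
                grid.append((
                    {"test_method": test, "inclusive_thresholds": inclusive,
                     "under_reference": under_ref},
                    sets,
                ))
    return grid


def volcano_table(result: ComparisonResult) -> pd.DataFrame:
    """Plot-ready per-gene table: log2FC, -log10 adjusted p, selection flag."""
    t = result.table
    return pd.DataFrame(
        {
            "gene_symbol": t["gene_symbol"],
            "log2_fc": t["log2_fc"],
            "neg_log10_p_adj": -np.log10(t["p_adj"].clip(lower=np.finfo(float).tiny)),
            "selected": t["selected_up"] | t["selected_down"],
        },
        index=t.index,
    )
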