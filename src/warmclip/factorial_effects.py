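"""Factorial effect estimation and interaction-direction classification.

Percent effects are defined relative to each block's own untreated control
(UU): the warming-alone effect W = 100 * (UW - UU) / UU, the clipping-alone
effect C = 100 * (CU - UU) / UU, the observed combined effect
OE = 100 * (CW - UU) / UU, and the predicted additive effect PE = W + C.
The combined treatment is called additive when OE does not differ
significantly from PE, synergistic when OE is significantly above PE, and
antagonistic when OE is significantly below PE.

No multiple-testing correction is applied across variables or gene
categories; raw p-values are reported against the significance tiers
(alpha = 0.05 significant, alpha = 0.10 marginal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np
import pandas as pd
from scipy import stats

from warmclip.design import TREATMENTS, treatment_code

if TYPE_CHECKING:  # pragma: no cover
    from warmclip.design import FactorialDesign
    from warmclip.geochip_preprocess import GeneSignalMatrix

EFFECT_COLUMNS = ("W", "C", "OE", "PE", "OE_minus_PE")

#: Treatment contrast -> array cell compared against UU.
CONTRAST_CELL = {"W": "UW", "C": "CU", "W+C": "CW"}


@dataclass
class EffectEstimate:
    """Per-block and mean percent effects for one variable."""

    variable: str
    per_block: pd.DataFrame  # index: block; columns: EFFECT_COLUMNS
    n_blocks: int

    @property
    def W(self) -> float:
        return float(self.per_block["W"].mean())

    @property
    def C(self) -> float:
        return float(self.per_block["C"].mean())

    @property
    def OE(self) -> float:
        return float(self.per_block["OE"].mean())

    @property
    def PE(self) -> float:
        return float(self.per_block["PE"].mean())

    @property
    def OE_minus_PE(self) -> float:
        return float(self.per_block["OE_minus_PE"].mean())


@dataclass
class InteractionCall:
    variable: str
    label: Literal["additive", "synergistic", "antagonistic"]
    p_value: float
    test_used: Literal["paired_t", "permutation_paired_t"]
    tier: Literal["significant", "marginal", "none"]


@dataclass
class CategoryEffect:
    """Percent change of one functional category under one treatment contrast."""

    category: str
    treatment: Literal["W", "C", "W+C"]
    pct_change: float
    n: int
    p_value: float


def _pivot_blocks(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    required = {"block", "warmed", "clipped", variable}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"property table missing columns: {sorted(missing)}")
    work = table[["block", "warmed", "clipped", variable]].copy()
    work["treatment"] = [
        treatment_code(w, c) for w, c in zip(work["warmed"], work["clipped"])
    ]
    cells = work.pivot_table(
        index="block", columns="treatment", values=variable, aggfunc="mean"
    )
    for trt in TREATMENTS:
        if trt not in cells.columns or cells[trt].isna().any():
            raise ValueError(
                f"incomplete design for {variable!r}: every block needs one "
                f"observation in each of {TREATMENTS}"
            )
    return cells[list(TREATMENTS)]


def compute_effects(table: pd.DataFrame, variable: str) -> EffectEstimate:
    """Compute W, C, OE, PE, and OE - PE for ``variable``.

    Parameters
    ----------
    table
        Long-format property table with columns ``block``, ``warmed``,
        ``clipped`` and one column per measured variable.
    variable
        Name of the variable column to analyse.

    Each block's percent effects use that block's own UU value as the
    denominator; the reported means are arithmetic means over blocks.
    """
    cells = _pivot_blocks(table, variable)
    zero_uu = cells.index[cells["UU"] == 0]
    if len(zero_uu):
        raise ValueError(
            f"UU value is zero in block(s) {list(zero_uu)} for {variable!r}; "
            "percent effects are undefined"
        )
    uu = cells["UU"]
    per_block = pd.DataFrame(index=cells.index)
    per_block["W"] = 100.0 * (cells["UW"] - uu) / uu
    per_block["C"] = 100.0 * (cells["CU"] - uu) / uu
    per_block["OE"] = 100.0 * (cells["CW"] - uu) / uu
    per_block["PE"] = per_block["W"] + per_block["C"]
    per_block["OE_minus_PE"] = per_block["OE"] - per_block["PE"]
    return EffectEstimate(variable=variable, per_block=per_block, n_blocks=len(cells))


def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical two-tailed paired t test on the differences x - y.

    Returns ``(t, p)`` with df = n - 1. All-zero differences give
    ``(0.0, 1.0)``; zero-variance differences with a nonzero mean are an
    error (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError(f"paired t test needs n >= 2, got n = {n}")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError(
            "differences have zero variance but nonzero mean; t is undefined"
        )
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def permutation_paired_t_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    exact_max_n: int = 20,
) -> float:
    """Two-tailed sign-flip permutation test for paired data.

    The null distribution is generated by flipping the signs of the paired
    differences; the statistic is the absolute mean difference (for fixed
    magnitudes this orders identically to |t|). For n <= ``exact_max_n``
    all 2^n sign assignments are enumerated and

        p = #{assignments with |mean| >= observed} / 2^n,

    the identity assignment included, so the minimum attainable p is
    2 / 2^n. For larger n, ``n_perm`` Monte-Carlo sign flips are drawn and
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError(f"permutation paired t test needs n >= 2, got n = {n}")
    d = x - y
    observed = abs(d.mean())
    # tolerance guards float ties between the observed stat and its own
    # sign-flip images
    tol = 1e-12 * max(1.0, float(np.abs(d).max()))
    if n <= exact_max_n:
        total = 2**n
        count = 0
        chunk = 1 << 16
        for start in range(0, total, chunk):
            codes = np.arange(start, min(start + chunk, total), dtype=np.uint64)
            bits = (codes[:, None] >> np.arange(n, dtype=np.uint64)) & 1
            signs = 1.0 - 2.0 * bits
            null = np.abs(signs @ d) / n
            count += int(np.sum(null >= observed - tol))
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null = np.abs(signs @ d) / n
    count = int(np.sum(null >= observed - tol))
    return (1 + count) / (n_perm + 1)


def classify_interaction(
    est: EffectEstimate,
    alpha: float = 0.05,
    marginal_alpha: float = 0.10,
    normality_alpha: float = 0.05,
    test: Literal["auto", "paired_t", "permutation_paired_t"] = "auto",
    n_perm: int = 9999,
    seed: int | None = None,
) -> InteractionCall:
    """Label the warming x clipping interaction for one variable.

    The per-block OE and PE vectors are compared as a paired sample. Under
    ``test="auto"`` the permutation test is used when Shapiro-Wilk rejects
    normality of the differences at ``normality_alpha`` (or when the
    differences are degenerate), otherwise the classical paired t test.
    The label is ``additive`` iff p > ``alpha``; otherwise the sign of
    mean(OE - PE) decides synergistic (positive) vs antagonistic.
    """
    oe = est.per_block["OE"].to_numpy()
    pe = est.per_block["PE"].to_numpy()
    d = oe - pe
    chosen = test
    if test == "auto":
        if np.ptp(d) == 0:
            # constant differences: Shapiro and the t test are both
            # undefined; the sign-flip test still is not
            chosen = "permutation_paired_t"
        else:
            sw_p = float(stats.shapiro(d).pvalue)
            chosen = (
                "permutation_paired_t" if sw_p < normality_alpha else "paired_t"
            )
    if chosen == "paired_t":
        _, p = paired_t_test(oe, pe)
    elif chosen == "permutation_paired_t":
        if np.all(d == 0):
            p = 1.0
        else:
            p = permutation_paired_t_test(oe, pe, n_perm=n_perm, seed=seed)
    else:
        raise ValueError(f"unknown test {test!r}")

    if p <= alpha:
        tier = "significant"
    elif p <= marginal_alpha:
        tier = "marginal"
    else:
        tier = "none"
    if p > alpha:
        label = "additive"
    elif d.mean() > 0:
        label = "synergistic"
    else:
        label = "antagonistic"
    return InteractionCall(
        variable=est.variable, label=label, p_value=float(p),
        test_used=chosen, tier=tier,
    )


def effects_report(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    alpha: float = 0.05,
    marginal_alpha: float = 0.10,
    n_perm: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tabulate effects and interaction calls for many variables at once."""
    if variables is None:
        variables = [
            c for c in table.columns if c not in ("block", "warmed", "clipped")
        ]
    rows = []
    for var in variables:
        est = compute_effects(table, var)
        call = classify_interaction(
            est, alpha=alpha, marginal_alpha=marginal_alpha,
            n_perm=n_perm, seed=seed,
        )
        rows.append(
            {
                "variable": var,
                "W": est.W,
                "C": est.C,
                "OE": est.OE,
                "PE": est.PE,
                "OE_minus_PE": est.OE_minus_PE,
                "p_value": call.p_value,
                "test_used": call.test_used,
                "tier": call.tier,
                "interaction": call.label,
            }
        )
    return pd.DataFrame(rows)


def gene_category_effects(
    matrix: "GeneSignalMatrix",
    design: "FactorialDesign",
    category: str,
    level: Literal["probe", "gene"] = "probe",
    n_perm: int = 9999,
    seed: int | None = None,
) -> dict[str, CategoryEffect]:
    """Percent signal change of one functional category per treatment contrast.

    Observations are probe-level by default (n = blocks x probe count in the
    category), paired against the same block's UU sample, on the rescaled
    linear signal scale. Returns one :class:`CategoryEffect` per contrast
    in {"W", "C", "W+C"}.
    """
    if level == "probe":
        values = matrix.probe_values_linear
        labels = matrix.probe_categories
    elif level == "gene":
        values = matrix.values_linear
        labels = matrix.categories
    else:
        raise ValueError(f"unknown level {level!r}")
    members = labels.index[labels == category]
    if len(members) == 0:
        raise ValueError(f"category {category!r} has no detected members")
    sub = values.loc[members]

    out: dict[str, CategoryEffect] = {}
    for contrast, cell in CONTRAST_CELL.items():
        trt_cols, uu_cols = [], []
        for block in design.blocks:
            t_id = design.sample_id(block, cell)
            u_id = design.sample_id(block, "UU")
            if t_id not in sub.columns or u_id not in sub.columns:
                raise ValueError(f"sample {t_id} or {u_id} absent from matrix")
            trt_cols.append(t_id)
            uu_cols.append(u_id)
        trt = sub[trt_cols].to_numpy().ravel()
        ctl = sub[uu_cols].to_numpy().ravel()
        if ctl.mean() == 0:
            raise ValueError(
                f"category {category!r}: zero mean UU signal, percent change "
                "undefined"
            )
        pct = 100.0 * (trt.mean() - ctl.mean()) / ctl.mean()
        p = permutation_paired_t_test(trt, ctl, n_perm=n_perm, seed=seed)
        out[contrast] = CategoryEffect(
            category=category, treatment=contrast, pct_change=float(pct),
            n=len(trt), p_value=float(p),
        )
    return out


def load_property_table(path) -> pd.DataFrame:
    """Read a TSV property table (columns: block, warmed, clipped, variables...)."""
    table = pd.read_csv(path, sep="\t")
    missing = {"block", "warmed", "clipped"} - set(table.columns)
    if missing:
        raise ValueError(f"property table missing columns: {sorted(missing)}")
    return table


def write_property_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
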