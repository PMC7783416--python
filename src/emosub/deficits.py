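"""Normative deficit classification and multi-deficit overlap analytics.

The person-centered core of the pipeline: per emotion domain, a
participant is "deficient" when their performance-oriented factor score
falls within the bottom q (default 10%) of the age-matched control
distribution, using the three age brackets 9-12 / 13-15 / 16-18.  The
resulting three binary flags place each participant in one of the eight
cells of a three-set Venn diagram, summarized per group with chi-square
contrasts of per-domain deficit frequency and compared against the
closed-form expectation under independent domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .config import CELL_FLAGS, CELLS, DOMAINS

FLAG_COLUMNS = tuple(f"{d}_deficit" for d in DOMAINS)


class EmptyBracketError(ValueError):
    """A bracket contains no control participants."""


@dataclass
class NormativeThresholds:
    """Per (domain, bracket) cutoffs plus the control counts behind them."""

    cutoffs: pd.DataFrame  # rows = brackets, columns = domains
    n_controls: pd.Series  # per bracket
    q: float
    method: str = "linear"


def empirical_quantile(x: np.ndarray, q: float, method: str = "linear") -> float:
    """The q-quantile of a sample under the configured order-statistic rule.

    "linear" interpolates between order statistics (the common
    spreadsheet/statistics default); "nearest_rank" takes the ceil(qn)-th
    smallest value.
    """
    x = np.asarray(x, dtype=float)
    if method == "linear":
        return float(np.quantile(x, q, method="linear"))
    if method == "nearest_rank":
        k = max(1, int(np.ceil(q * len(x))))
        return float(np.sort(x)[k - 1])
    raise ValueError(f"unknown quantile method {method!r}")


def estimate_thresholds(
    scores: pd.DataFrame,
    participants: pd.DataFrame,
    q: float = 0.10,
    method: str = "linear",
    min_controls: int = 20,
    control_group: str = "TDC",
) -> NormativeThresholds:
    """Estimate the per-domain, per-bracket normative cutoffs from controls.

    ``scores`` has one column per domain (performance-oriented, higher =
    better); ``participants`` supplies ``group`` and ``bracket`` aligned by
    row order.
    """
    if not 0 <= q < 1:
        raise ValueError("q must lie in [0, 1)")
    is_control = participants["group"].to_numpy() == control_group
    brackets = pd.unique(participants["bracket"].astype(str))
    cutoffs = {}
    counts = {}
    for bracket in sorted(brackets):
        mask = is_control & (participants["bracket"].astype(str).to_numpy() == bracket)
        n = int(mask.sum())
        if n == 0:
            raise EmptyBracketError(
                f"no control participants in age bracket {bracket}"
            )
        if n < min_controls:
            warnings.warn(
                f"bracket {bracket}: only {n} controls (minimum {min_controls}); "
                "normative cutoffs will be noisy",
                stacklevel=2,
            )
        counts[bracket] = n
        if q == 0:
            row = {
                d: float(scores.loc[mask, d].min()) - 1e-12 for d in scores.columns
            }
        else:
            row = {
                d: empirical_quantile(scores.loc[mask, d].to_numpy(), q, method)
                for d in scores.columns
            }
        cutoffs[bracket] = row
    return NormativeThresholds(
        cutoffs=pd.DataFrame(cutoffs).T[list(scores.columns)],
        n_controls=pd.Series(counts),
        q=q,
        method=method,
    )


def classify(
    scores: pd.DataFrame,
    thresholds: NormativeThresholds,
    participants: pd.DataFrame,
    boundary_inclusive: bool = True,
) -> pd.DataFrame:
    """Deficient/intact flags per domain, Venn cell and deficit count.

    A flag is true when the score falls at or below the bracket cutoff
    (the boundary counts as "within the bottom q"); the same rule applies
    to cases and controls.  Rows with missing scores are excluded with a
    warning listing their IDs.
    """
    brackets = participants["bracket"].astype(str)
    missing_thresh = set(brackets.unique()) - set(thresholds.cutoffs.index)
    if missing_thresh:
        raise KeyError(f"no thresholds for bracket(s): {sorted(missing_thresh)}")
    missing = scores.isna().any(axis=1).to_numpy()
    if missing.any():
        ids = participants.loc[missing, "id"].tolist() if "id" in participants else list(
            np.flatnonzero(missing)
        )
        warnings.warn(f"excluding {missing.sum()} rows with missing scores: {ids}",
                      stacklevel=2)
    cuts = thresholds.cutoffs.loc[brackets[~missing]].to_numpy()
    vals = scores.loc[~missing, thresholds.cutoffs.columns].to_numpy()
    flagged = vals <= cuts if boundary_inclusive else vals < cuts
    out = pd.DataFrame(index=scores.index[~missing])
    for j, domain in enumerate(thresholds.cutoffs.columns):
        out[f"{domain}_deficit"] = flagged[:, j]
    flag_arr = flagged.astype(int)
    cell_of = {v: k for k, v in CELL_FLAGS.items()}
    out["venn_cell"] = [cell_of[tuple(row)] for row in flag_arr]
    out["n_deficits"] = flag_arr.sum(axis=1)
    if "id" in participants:
        out.insert(0, "id", participants.loc[~missing, "id"].to_numpy())
    out["group"] = participants.loc[~missing, "group"].to_numpy()
    return out


@dataclass
class VennSummary:
    """Per-group cell/margin/aggregate proportions with counts and tests."""

    counts: pd.DataFrame  # rows = groups, columns = cells
    proportions: pd.DataFrame
    margins: pd.DataFrame  # per-domain deficit proportions
    aggregates: pd.DataFrame  # >=1 / exactly 1 / exactly 2 / all 3 / none
    domain_tests: pd.DataFrame  # chi2 contrasts of deficit frequency CD vs TDC

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(),
            "proportions": self.proportions.to_dict(),
            "margins": self.margins.to_dict(),
            "aggregates": self.aggregates.to_dict(),
            "domain_tests": self.domain_tests.to_dict(orient="index"),
        }


def venn_summary(flags: pd.DataFrame, groups: pd.Series | None = None) -> VennSummary:
    """Summarize deficit overlap per group and contrast domain frequencies.

    Proportions per Venn cell sum to 1 within each group; margins are the
    per-domain deficit rates; the CD-vs-TDC contrast per domain is a
    Pearson chi-square without continuity correction.
    """
    if groups is None:
        groups = flags["group"]
    groups = pd.Series(np.asarray(groups).astype(str), index=flags.index)
    group_names = sorted(groups.unique(), key=lambda g: (g != "CD", g))
    if any((groups == g).sum() == 0 for g in group_names):
        raise ValueError("empty group")
    counts = pd.DataFrame(0, index=group_names, columns=list(CELLS))
    for g in group_names:
        vc = flags.loc[groups == g, "venn_cell"].value_counts()
        for cell in CELLS:
            counts.loc[g, cell] = int(vc.get(cell, 0))
    n_per_group = counts.sum(axis=1)
    proportions = counts.div(n_per_group, axis=0)

    margins = pd.DataFrame(index=group_names, columns=list(DOMAINS), dtype=float)
    for g in group_names:
        sub = flags.loc[groups == g]
        for d in DOMAINS:
            margins.loc[g, d] = sub[f"{d}_deficit"].mean()

    agg = pd.DataFrame(index=group_names,
                       columns=[">=1", "exactly_1", "exactly_2", "all_3", "none"],
                       dtype=float)
    for g in group_names:
        nd = flags.loc[groups == g, "n_deficits"]
        agg.loc[g] = [
            (nd >= 1).mean(),
            (nd == 1).mean(),
            (nd == 2).mean(),
            (nd == 3).mean(),
            (nd == 0).mean(),
        ]

    tests = {}
    if {"CD", "TDC"} <= set(group_names):
        for d in DOMAINS:
            col = flags[f"{d}_deficit"]
            if col.nunique() < 2:  # no variation: chi-square undefined
                tests[d] = {"chi2": np.nan, "df": 1, "p": np.nan}
                continue
            table = np.array(
                [
                    [
                        int(flags.loc[groups == g, f"{d}_deficit"].sum()),
                        int((~flags.loc[groups == g, f"{d}_deficit"]).sum()),
                    ]
                    for g in ("CD", "TDC")
                ]
            )
            chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
            tests[d] = {"chi2": float(chi2), "df": int(dof), "p": float(p)}
    domain_tests = pd.DataFrame(tests).T if tests else pd.DataFrame(
        columns=["chi2", "df", "p"]
    )
    return VennSummary(
        counts=counts,
        proportions=proportions,
        margins=margins,
        aggregates=agg,
        domain_tests=domain_tests,
    )


def independence_expectation(q: float, k: int = 3) -> dict[str, float]:
    """Expected deficit-overlap proportions under fully independent domains.

    Binomial closed forms: P(>=1) = 1-(1-q)^k and P(exactly m) =
    C(k,m) q^m (1-q)^(k-m).  With q = 0.10 and k = 3 this gives 27.1%
    with at least one deficit and 0.1% with all three.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    out = {"ge_1": 1.0 - (1.0 - q) ** k}
    for m in range(k + 1):
        out[f"exactly_{m}"] = comb(k, m) * q**m * (1 - q) ** (k - m)
    out["all_k"] = q**k
    out["none"] = (1 - q) ** k
    return out


def plot_venn(summary: VennSummary, group: str = "CD", ax=None):
    """Three-circle deficit-overlap diagram for one group (optional figure).

    Drawn with plain matplotlib circles; cell labels carry the percentage
    of the group in each cell.
    """
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    centers = {"recognition": (-0.35, 0.25), "learning": (0.35, 0.25),
               "regulation": (0.0, -0.35)}
    colors = {"recognition": "#1f77b4", "learning": "#ff7f0e",
              "regulation": "#2ca02c"}
    for d, c in centers.items():
        ax.add_patch(Circle(c, 0.62, alpha=0.3, color=colors[d]))
        ax.annotate(
            f"{d}\n{100 * summary.margins.loc[group, d]:.1f}%",
            xy=c, xytext=(c[0] * 2.3, c[1] * 2.6), ha="center", fontsize=10,
        )
    prop = summary.proportions.loc[group]
    positions = {
        "REC": (-0.55, 0.45), "LRN": (0.55, 0.45), "REG": (0.0, -0.65),
        "REC+LRN": (0.0, 0.45), "REC+REG": (-0.35, -0.15),
        "LRN+REG": (0.35, -0.15), "REC+LRN+REG": (0.0, 0.1),
    }
    for cell, pos in positions.items():
        ax.annotate(f"{100 * prop[cell]:.1f}", xy=pos, ha="center", fontsize=9)
    ax.annotate(f"no deficit: {100 * prop['none']:.1f}%", xy=(0, -1.25),
                ha="center", fontsize=10)
    ax.set_xlim(-1.5, 1.5)
    ax.set_ylim(-1.5, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"Deficit overlap, {group} group")
    return ax
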