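"""Quantitative crosslinking-MS comparison between two conditions.

Workflow modelled on label-free XL-MS quantitation: crosslinked-peptide
peak areas from replicate LC-MS runs (reaction replicates x injection
replicates per condition) are scaled run-to-run by the total peak area of a
fixed panel of linear (non-crosslinked) peptides, each residue pair is
summarized per condition by the median over its runs, and condition changes
are assessed by a Welch t-test on log2 intensities.

Only residue pairs observed in both conditions are ratio-tested; pairs seen
in one condition only are flagged condition-unique and reported separately
rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "QuantTable",
    "normalize_runs",
    "summarize_replicates",
    "ratio_and_test",
    "significant_changes",
]


@dataclass
class QuantTable:
    """Crosslink peak areas across runs, with run metadata.

    Attributes
    ----------
    intensities : DataFrame
        Rows = residue pairs (index = pair id), columns = run ids, cells =
        peak areas (NaN = not observed in that run).
    runs : DataFrame
        One row per run: run_id, condition, reaction, injection.
    linear_totals : Series
        Per-run total peak area of the linear-peptide normalization panel
        (index = run id, strictly positive).
    annotations : DataFrame, optional
        Per-pair residue annotations (protein/residue columns), same index
        as ``intensities``.
    """

    intensities: pd.DataFrame
    runs: pd.DataFrame
    linear_totals: pd.Series
    annotations: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.runs = self.runs.set_index("run_id") if "run_id" in self.runs.columns else self.runs
        missing = set(self.intensities.columns) - set(self.runs.index)
        if missing:
            raise ValueError(f"runs without metadata: {sorted(missing)}")
        counts = self.runs.loc[list(self.intensities.columns), "condition"].value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly 2 conditions, got {list(counts.index)}")
        if (counts < 2).any():
            raise ValueError("each condition needs at least 2 runs")
        totals = self.linear_totals.reindex(self.intensities.columns)
        if totals.isna().any():
            bad = list(totals.index[totals.isna()])
            raise ValueError(f"missing linear-peptide totals for runs: {bad}")
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"non-positive linear-peptide totals for runs: {bad}")
        self.linear_totals = totals

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, in order of first appearance in the run
        metadata — ratios are first / second."""
        meta = self.runs.loc[list(self.intensities.columns), "condition"]
        return list(dict.fromkeys(meta))

    def runs_for(self, condition: str) -> list[str]:
        meta = self.runs.loc[list(self.intensities.columns)]
        return list(meta.index[meta["condition"] == condition])


def normalize_runs(table: QuantTable) -> QuantTable:
    """Scale each run so linear-peptide totals match their geometric mean.

    Each run's crosslink intensities are multiplied by
    ``geomean(totals) / run_total``; afterwards all normalized totals are
    identical, which makes the operation idempotent.
    """
    totals = table.linear_totals
    reference = float(np.exp(np.log(totals.to_numpy(float)).mean()))
    factors = reference / totals
    intens = table.intensities.mul(factors, axis=1)
    new_totals = totals * factors  # all equal to the reference
    return replace(
        table,
        intensities=intens,
        runs=table.runs.reset_index(),
        linear_totals=new_totals,
    )


def summarize_replicates(table: QuantTable) -> pd.DataFrame:
    """Per-pair, per-condition medians over available runs.

    Returns a frame indexed like the intensity table with columns
    ``median_<cond>`` and ``n_<cond>`` for each condition, plus
    ``unique_to`` ('' if quantified in both conditions, else the condition
    name, or 'none' if absent everywhere).
    """
    cond_a, cond_b = table.conditions
    out = {}
    for cond in (cond_a, cond_b):
        cols = table.runs_for(cond)
        block = table.intensities[cols]
        out[f"median_{cond}"] = block.median(axis=1, skipna=True)
        out[f"n_{cond}"] = block.notna().sum(axis=1)
    summary = pd.DataFrame(out, index=table.intensities.index)
    has_a = summary[f"n_{cond_a}"] > 0
    has_b = summary[f"n_{cond_b}"] > 0
    summary["unique_to"] = ""
    summary.loc[has_a & ~has_b, "unique_to"] = cond_a
    summary.loc[~has_a & has_b, "unique_to"] = cond_b
    summary.loc[~has_a & ~has_b, "unique_to"] = "none"
    return summary


def ratio_and_test(
    table: QuantTable,
    alpha: float = 0.05,
    collapse_injections: bool = False,
    multiple_testing: str | None = None,
) -> pd.DataFrame:
    """Condition ratio and Welch t-test per residue pair.

    Ratio = median(first condition) / median(second condition), conditions
    in sorted label order. The test is Welch's two-sample t on log2
    intensities; intensities are multiplicative, so the log transform makes
    run noise approximately additive. ``collapse_injections`` averages
    injection replicates within each reaction first (conservative n).
    ``multiple_testing='bh'`` adds Benjamini-Hochberg q-values and gates
    significance on q < alpha instead of raw p.

    Pairs lacking two observations in either condition are excluded from
    the test (their ``skip_reason`` says why); output is sorted by p-value.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    cond_a, cond_b = table.conditions
    summary = summarize_replicates(table)
    meta = table.runs.loc[list(table.intensities.columns)]

    def condition_block(cond: str) -> np.ndarray:
        cols = table.runs_for(cond)
        block = table.intensities[cols]
        if collapse_injections and "reaction" in meta.columns:
            block = block.T.groupby(meta.loc[cols, "reaction"]).mean().T
        return block.to_numpy(float)

    a = condition_block(cond_a)
    b = condition_block(cond_b)
    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    nonpos = (np.nan_to_num(a, nan=1.0) <= 0).any(axis=1) | (
        np.nan_to_num(b, nan=1.0) <= 0
    ).any(axis=1)
    testable = (n_a >= 2) & (n_b >= 2) & ~nonpos

    t_stat = np.full(len(a), np.nan)
    p_value = np.full(len(a), np.nan)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="Mean of empty slice")
        _warnings.filterwarnings("ignore", message="Degrees of freedom <= 0")
        la = np.where(a > 0, np.log2(a), np.nan)
        lb = np.where(b > 0, np.log2(b), np.nan)
        ma, mb = np.nanmean(la, axis=1), np.nanmean(lb, axis=1)
        va, vb = np.nanvar(la, axis=1, ddof=1), np.nanvar(lb, axis=1, ddof=1)
        sa, sb = va / n_a, vb / n_b
        denom = np.sqrt(sa + sb)
        ok = testable & (denom > 0)
        t_stat[ok] = (ma[ok] - mb[ok]) / denom[ok]
        # Welch-Satterthwaite degrees of freedom
        df = (sa + sb) ** 2 / (sa**2 / (n_a - 1) + sb**2 / (n_b - 1))
        p_value[ok] = 2.0 * stats.t.sf(np.abs(t_stat[ok]), df[ok])

    med_a = summary[f"median_{cond_a}"].to_numpy(float)
    med_b = summary[f"median_{cond_b}"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((med_a > 0) & (med_b > 0), med_a / med_b, np.nan)
    skip = np.where(
        (n_a < 2) | (n_b < 2),
        "<2 runs in a condition",
        np.where(nonpos, "non-positive intensity", np.where(denom <= 0, "zero variance", "")),
    )
    skip[np.isfinite(p_value)] = ""
    result = pd.DataFrame(
        {
            f"median_{cond_a}": med_a,
            f"median_{cond_b}": med_b,
            "n_a": n_a,
            "n_b": n_b,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "t_stat": t_stat,
            "p_value": p_value,
            "skip_reason": skip,
        },
        index=table.intensities.index,
    )

    tested = result["p_value"].notna()
    result["significant"] = False
    if multiple_testing is None:
        result.loc[tested, "significant"] = result.loc[tested, "p_value"] < alpha
    elif multiple_testing.lower() in ("bh", "fdr_bh", "benjamini-hochberg"):
        result["q_value"] = np.nan
        if tested.any():
            rej, q, *_ = multipletests(
                result.loc[tested, "p_value"].to_numpy(), alpha=alpha, method="fdr_bh"
            )
            result.loc[tested, "q_value"] = q
            result.loc[tested, "significant"] = rej
    else:
        raise ValueError(f"unknown multiple_testing scheme {multiple_testing!r}")
    if table.annotations is not None:
        result = result.join(table.annotations, how="left")
    return result.sort_values("p_value", na_position="last")


def significant_changes(result: pd.DataFrame) -> pd.DataFrame:
    """Subset of pairs flagged significant (empty frame if none).

    The returned frame keeps residue annotations, ratio and p-value — the
    table of condition-dependent crosslinks ready for CSV/JSON export.
    """
    return result[result["significant"].fillna(False)].copy()
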