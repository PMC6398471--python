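"""Two-condition quantitative XL-MS table generator.

Emulates the replicate design of a label-free crosslink quantitation
experiment: two conditions, each measured in reaction replicates with
injection replicates (default 3 x 2 = 6 runs per condition), log-normal
multiplicative noise on peak areas, per-run global scale factors (loading /
spray efficiency), and a panel of linear peptides whose summed area carries
the same per-run scale and therefore supports run-to-run normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..xlquant import QuantTable

__all__ = ["simulate_quant_xlms"]


def simulate_quant_xlms(
    n_links: int,
    changed: list[tuple[int, float]] | None = None,
    cv: float = 0.1,
    n_runs_per_condition: int = 6,
    seed: int = 0,
    n_linear: int = 38,
    conditions: tuple[str, str] = ("WT", "S6E"),
    run_scale_sd: float = 0.2,
    injections_per_reaction: int = 2,
) -> tuple[QuantTable, pd.DataFrame]:
    """Generate a :class:`~kymoxl.xlquant.QuantTable` with known changes.

    Parameters
    ----------
    changed : list of (link index, true log2 ratio)
        Links whose first-condition mean is scaled by 2**ratio relative to
        the second condition; all other links have true ratio 1.
    cv : float
        Coefficient of variation of the multiplicative measurement noise
        (log-normal, sigma = sqrt(ln(1+cv^2))). Must be positive.
    n_runs_per_condition : int
        Total runs per condition; labelled with reaction/injection replicate
        structure (``injections_per_reaction`` injections per reaction).
    n_linear : int
        Size of the linear-peptide normalization panel (38 mirrors a
        typical panel).
    run_scale_sd : float
        SD of per-run log-normal global scale factors.

    Returns ``(table, truth)`` where ``truth`` has one row per link with
    ``true_log2_ratio``.
    """
    if cv <= 0:
        raise ValueError("cv must be strictly positive")
    if n_runs_per_condition < 2:
        raise ValueError("need at least 2 runs per condition")
    if n_links < 1:
        raise ValueError("need at least one link")
    changed = list(changed or [])
    for idx, _ in changed:
        if not 0 <= idx < n_links:
            raise ValueError(f"changed link index {idx} out of range")

    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))

    pair_ids = [f"link_{i:03d}" for i in range(n_links)]
    base = 10 ** rng.uniform(4.0, 6.0, size=n_links)  # per-link abundance
    log2_ratio = np.zeros(n_links)
    for idx, r in changed:
        log2_ratio[idx] = r
    cond_mean = {conditions[0]: base * 2.0**log2_ratio, conditions[1]: base}

    linear_base = 10 ** rng.uniform(5.0, 7.0, size=n_linear)

    run_rows = []
    intensity_cols = {}
    totals = {}
    for cond in conditions:
        for j in range(n_runs_per_condition):
            reaction = j // injections_per_reaction + 1
            injection = j % injections_per_reaction + 1
            run_id = f"{cond}_r{reaction}i{injection}"
            run_rows.append(
                {
                    "run_id": run_id,
                    "condition": cond,
                    "reaction": f"{cond}_r{reaction}",
                    "injection": injection,
                }
            )
            scale = rng.lognormal(0.0, run_scale_sd)
            noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n_links)
            intensity_cols[run_id] = cond_mean[cond] * scale * noise
            lin_noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n_linear)
            totals[run_id] = float(np.sum(linear_base * scale * lin_noise))

    intensities = pd.DataFrame(intensity_cols, index=pair_ids)
    runs = pd.DataFrame(run_rows)
    linear_totals = pd.Series(totals, name="linear_total")
    annotations = pd.DataFrame(
        {
            "protein_a": "toy",
            "res_a": rng.integers(1, 300, size=n_links),
            "protein_b": "toy",
            "res_b": rng.integers(1, 300, size=n_links),
        },
        index=pair_ids,
    )
    table = QuantTable(intensities, runs, linear_totals, annotations)
    truth = pd.DataFrame({"pair": pair_ids, "true_log2_ratio": log2_ratio}).set_index("pair")
    return table, truth
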