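"""Sweep runner and summary statistics.

Reproduces the model's headline analyses: per-run summary statistics
(percentage of iterations with need above threshold, action percentages, mean
distance, mean care-clock), nine-level sweeps over a dimension averaged over
replicate seeds, Spearman-based monotone-trend checks against the directions
the attachment literature predicts, the level-dependent-offset (variable c0)
avoidant variant, and the coupling on/off sensitivity comparison.

The published runs are single 1,000-iteration simulations per level; here each
level is averaged over several seeds (default 10) so the trend statistics are
stable, and the per-seed spread is reported alongside the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import Dimension, SimulationConfig
from .simulation import Trajectory, run

#: Default nine-level grid of the dimensional sweep.
LEVELS = tuple(round(0.1 * k, 1) for k in range(1, 10))

Direction = Literal["increasing", "decreasing"]

#: Directions the attachment literature predicts for each tracked quantity.
#: Exploration always runs opposite to need/approach.
EXPECTED_TRENDS: Dict[Dimension, Dict[str, Direction]] = {
    "avoidance": {
        "pct_NR_above": "decreasing",
        "pct_NG_above": "decreasing",
        "pct_approach_child": "decreasing",
        "pct_approach_cg": "decreasing",
        "pct_explore_child": "increasing",
        "pct_explore_cg": "increasing",
    },
    "ambivalence": {
        "pct_NR_above": "increasing",
        "pct_NG_above": "decreasing",
        "pct_approach_child": "increasing",
        "pct_approach_cg": "decreasing",
        "pct_explore_child": "decreasing",
        "pct_explore_cg": "increasing",
    },
}


@dataclass(frozen=True)
class SummaryStats:
    """Per-run summary quantities (all percentages over the run's iterations)."""

    pct_NR_above: float
    pct_NG_above: float
    pct_approach_child: float
    pct_explore_child: float
    pct_conflict_child: float
    pct_approach_cg: float
    pct_explore_cg: float
    pct_conflict_cg: float
    mean_distance: float
    mean_K: float


def summarize(trajectory: Trajectory) -> SummaryStats:
    """Summary statistics of one run.

    Action percentages are disjoint: ``pct_explore`` counts only coherent
    explorations (need below threshold *and* perception below its margin);
    conflict-resolved iterations are tallied separately, so approach +
    explore + conflict = 100 per agent.  ``mean_distance`` uses the raw
    per-iteration distance (smoothing is presentation-only).
    """
    df = trajectory.to_dataframe()
    n = len(df)
    if n == 0:
        raise ValueError("cannot summarize an empty trajectory")
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n
    return SummaryStats(
        pct_NR_above=pct(df["N_R"] > df["T_R"]),
        pct_NG_above=pct(df["N_G"] > df["T_G"]),
        pct_approach_child=pct(df["action_a"] == "approach"),
        pct_explore_child=pct((df["action_a"] == "explore") & ~df["conflict_a"]),
        pct_conflict_child=pct(df["conflict_a"]),
        pct_approach_cg=pct(df["action_c"] == "approach"),
        pct_explore_cg=pct((df["action_c"] == "explore") & ~df["conflict_c"]),
        pct_conflict_cg=pct(df["conflict_c"]),
        mean_distance=float(df["d"].mean()),
        mean_K=float(df["K"].mean()),
    )


STAT_NAMES = tuple(SummaryStats.__dataclass_fields__)


def sweep(
    dimension: Dimension,
    n_seeds: int = 10,
    base_config: Optional[SimulationConfig] = None,
    levels: Sequence[float] = LEVELS,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Nine-level sweep of one dimension, averaged over replicate seeds.

    Enforces the adapted dyad (A_v = I_n or A_m = U_n) at every level.  The
    returned frame has one row per level with ``<stat>`` (mean over seeds) and
    ``<stat>_sd`` columns, plus ``dimension``, ``level`` and ``n_seeds``.
    Replicate ``k`` of level index ``j`` uses seed ``base_seed + 1000*j + k``.
    """
    if base_config is None:
        base_config = SimulationConfig(dimension=dimension)
    rows = []
    for j, level in enumerate(levels):
        per_seed: List[SummaryStats] = []
        for k in range(n_seeds):
            config = base_config.model_copy(
                update={
                    "dimension": dimension,
                    "levels": type(base_config.levels).adapted(dimension, level),
                    "seed": base_seed + 1000 * j + k,
                }
            )
            per_seed.append(summarize(run(config)))
        row: Dict[str, float] = {"dimension": dimension, "level": level, "n_seeds": n_seeds}
        for name in STAT_NAMES:
            vals = np.array([getattr(s, name) for s in per_seed], dtype=float)
            row[name] = float(vals.mean())
            row[name + "_sd"] = float(vals.std(ddof=1)) if n_seeds > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def trend_check(
    table: pd.DataFrame,
    expected: Optional[Dict[str, Direction]] = None,
    rho_threshold: float = 0.8,
) -> pd.DataFrame:
    """Spearman monotone-trend test of a sweep table against expected directions.

    For each tracked quantity, computes the rank correlation between the
    dimensional level and the seed-averaged statistic.  A trend passes when the
    correlation's sign matches the expected direction and |rho| >= threshold.
    A constant series has undefined rank correlation and fails with rho = NaN.
    """
    if expected is None:
        dims = table["dimension"].unique()
        if len(dims) != 1:
            raise ValueError("mixed-dimension table needs an explicit `expected` mapping")
        expected = EXPECTED_TRENDS[dims[0]]
    rows = []
    levels = table["level"].to_numpy(dtype=float)
    for quantity, direction in expected.items():
        values = table[quantity].to_numpy(dtype=float)
        if np.allclose(values, values[0]):
            rho = float("nan")
            passed = False
            note = "constant series: trend undefined"
        else:
            rho = float(stats.spearmanr(levels, values).statistic)
            sign_ok = (rho > 0) if direction == "increasing" else (rho < 0)
            passed = bool(sign_ok and abs(rho) >= rho_threshold)
            note = ""
        rows.append(
            {
                "quantity": quantity,
                "expected": direction,
                "rho": rho,
                "passed": passed,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def smooth(series: Sequence[float], window: int = 10) -> np.ndarray:
    """Centered moving average (presentation smoothing for distance curves).

    Length-preserving: windows shrink at the edges.  ``window=1`` is the
    identity.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def sensitivity_coupling(
    dimension: Dimension,
    n_seeds: int = 10,
    base_config: Optional[SimulationConfig] = None,
    base_seed: int = 0,
) -> Dict[str, object]:
    """Paired sweeps at the default coupling factor and at C_f = 0.

    Returns both sweep tables and their trend reports; the coupled system is
    expected to pass at least as many directional trend checks as the
    uncoupled one.
    """
    if base_config is None:
        base_config = SimulationConfig(dimension=dimension)
    field = "Cf_av" if dimension == "avoidance" else "Cf_am"
    uncoupled_config = base_config.model_copy(
        update={"consts": base_config.consts.model_copy(update={field: 0.0})}
    )
    coupled = sweep(dimension, n_seeds, base_config, base_seed=base_seed)
    uncoupled = sweep(dimension, n_seeds, uncoupled_config, base_seed=base_seed)
    report_coupled = trend_check(coupled)
    report_uncoupled = trend_check(uncoupled)
    return {
        "coupled": coupled,
        "uncoupled": uncoupled,
        "report_coupled": report_coupled,
        "report_uncoupled": report_uncoupled,
        "n_passed_coupled": int(report_coupled["passed"].sum()),
        "n_passed_uncoupled": int(report_uncoupled["passed"].sum()),
    }


def dynamic_range(table: pd.DataFrame, quantity: str) -> float:
    """Max - min of a seed-averaged statistic across the sweep levels."""
    values = table[quantity].to_numpy(dtype=float)
    return float(values.max() - values.min())


def plot_sweep(table: pd.DataFrame, path: Optional[str] = None):
    """Two-panel summary figure: needs (A) and actions (B) versus level.

    Child curves in black, caregiver in red, dashed for exploration; the mean
    inter-agent distance (blue) and care-clock (cyan) ride on twin axes.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_need, ax_act) = plt.subplots(1, 2, figsize=(10, 4))
    lv = table["level"]
    ax_need.plot(lv, table["pct_NR_above"], "k-o", label="child need")
    ax_need.plot(lv, table["pct_NG_above"], "r-o", label="caregiver need")
    ax2 = ax_need.twinx()
    ax2.plot(lv, table["mean_distance"], "b-", label="mean distance")
    ax2.plot(lv, table["mean_K"], "c-", label="mean K")
    ax_need.set_xlabel(f"{table['dimension'].iloc[0]} level")
    ax_need.set_ylabel("% iterations above threshold")
    ax_need.set_title("(A) Need")
    ax_need.legend(loc="upper center", fontsize=8)

    ax_act.plot(lv, table["pct_approach_child"], "k-o", label="child approach")
    ax_act.plot(lv, table["pct_explore_child"], "k--o", label="child explore")
    ax_act.plot(lv, table["pct_approach_cg"], "r-o", label="caregiver approach")
    ax_act.plot(lv, table["pct_explore_cg"], "r--o", label="caregiver explore")
    ax_act.set_xlabel(f"{table['dimension'].iloc[0]} level")
    ax_act.set_ylabel("% iterations")
    ax_act.set_title("(B) Action")
    ax_act.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
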