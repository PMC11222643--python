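"""From per-arm survival curves to individual treatment effects and
treatment recommendations.

The individual treatment effect is measured on the restricted-survival-
time (RST) scale: the area under a patient's predicted survival curve up
to a horizon tau (default 120 months), contrasted between the treated and
untreated scenarios,

    ITE_RST(x; tau) = int_0^tau S1(t|x) dt - int_0^tau S0(t|x) dt,

in months of expected survival gained within 10 years under chemotherapy.
A patient is recommended chemotherapy iff the ITE is strictly positive
(an exact zero recommends no chemotherapy — the conservative, avoid-
overtreatment tie-break).  A guideline comparator implements the NCCN
rule: chemotherapy for node-positive disease, or node-negative T1-T3
tumors larger than 10 mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SurvivalCurves", "ite_rst", "recommend", "nccn_recommend",
           "consistency_labels", "build_ite_table", "derive_stages"]

DEFAULT_TAU = 120.0


@dataclass
class SurvivalCurves:
    """Per-patient predicted survival under both treatment scenarios on a
    common time grid (months)."""

    patient_ids: np.ndarray
    grid: np.ndarray
    S0: np.ndarray  # (patients, grid), untreated scenario
    S1: np.ndarray  # (patients, grid), treated scenario

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.S0 = np.atleast_2d(np.asarray(self.S0, float))
        self.S1 = np.atleast_2d(np.asarray(self.S1, float))
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("time grid must be strictly increasing")


def ite_rst(curves: SurvivalCurves, tau: float = DEFAULT_TAU) -> np.ndarray:
    """Trapezoidal integral of S1 - S0 over [0, tau], per patient (months)."""
    grid = curves.grid
    if grid[-1] < tau - 1e-9:
        raise ValueError(f"time grid ends at {grid[-1]} but tau={tau}")
    mask = grid <= tau + 1e-9
    g = grid[mask]
    diff = curves.S1[:, mask] - curves.S0[:, mask]
    return np.trapezoid(diff, g, axis=1)


def recommend(ite_values, tie_value: int = 0) -> np.ndarray:
    """1 (recommend chemotherapy) iff ITE_RST > 0; exact ties get
    ``tie_value`` (default 0, avoiding overtreatment)."""
    ite_values = np.asarray(ite_values, float)
    if not np.all(np.isfinite(ite_values)):
        raise ValueError("ITE values must be finite")
    rec = (ite_values > 0).astype(int)
    if tie_value:
        rec[ite_values == 0] = tie_value
    return rec


def derive_stages(tumor_size_mm, positive_nodes) -> tuple[np.ndarray, np.ndarray]:
    """AJCC-style T stage from tumor size (T1 <= 20 mm < T2 <= 50 mm < T3)
    and N stage from positive node count (N0 = 0, N1 = 1-3, N2 = 4-9,
    N3 >= 10).  T4 (chest-wall/skin involvement) is not derivable from
    size alone and is never produced."""
    size = np.asarray(tumor_size_mm, float)
    nodes = np.asarray(positive_nodes, int)
    t_stage = np.where(size <= 20, 1, np.where(size <= 50, 2, 3))
    n_stage = np.where(nodes == 0, 0,
                       np.where(nodes <= 3, 1, np.where(nodes <= 9, 2, 3)))
    return t_stage, n_stage


def nccn_recommend(t_stage, tumor_size_mm, n_stage) -> np.ndarray:
    """Guideline rule: chemotherapy iff node-positive, or node-negative
    T1-T3 with tumor size > 10 mm.  Stages outside the quoted rule (T4)
    fall back to the node-positivity criterion."""
    t_stage = np.asarray(t_stage, int)
    size = np.asarray(tumor_size_mm, float)
    n_stage = np.asarray(n_stage, int)
    node_positive = n_stage >= 1
    small_t = (t_stage >= 1) & (t_stage <= 3)
    return (node_positive | (small_t & ~node_positive & (size > 10.0))).astype(int)


def consistency_labels(recommended, actual) -> np.ndarray:
    """Boolean per patient: actual treatment matched the recommendation
    (the "Consis." group); False marks the "Inconsis." group."""
    recommended = np.asarray(recommended, int)
    actual = np.asarray(actual, int)
    if recommended.shape != actual.shape:
        raise ValueError("recommended and actual must have the same length")
    return recommended == actual


def build_ite_table(patient_ids, ite_values, actual, tau: float = DEFAULT_TAU,
                    tie_value: int = 0) -> pd.DataFrame:
    """Assemble the per-patient effect/recommendation table."""
    ite_values = np.asarray(ite_values, float)
    if np.any(np.abs(ite_values) > tau + 1e-6):
        raise ValueError("ITE_RST outside [-tau, tau]")
    rec = recommend(ite_values, tie_value=tie_value)
    cons = consistency_labels(rec, actual)
    return pd.DataFrame({
        "patient_id": np.asarray(patient_ids),
        "ite_rst": ite_values,
        "recommended": rec,
        "actual": np.asarray(actual, int),
        "consistent": cons,
    })
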