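"""Cancer-biomarker screening from expression-level predictions.

A protein with n normal-tissue and m cancer-tissue images gets a voted
expression level per condition, and an independent two-sample t-test on
the per-image expected ordinal expression scores (2*p_high + p_medium)
gives a P value for expression change.  A protein is an expression
biomarker at P < alpha; combining with the subcellular-location-change
P values of the companion location predictor (consumed as a table, one
row per protein x compartment), a protein is flagged as a biomarker when
either route is significant.  The bundled ``table1_lbd.csv`` transcribes
the published screen of the 22-protein literature biomarker dataset
(LBD) for colon cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from .classify import PredictionResult
from .synthetic import LEVELS

__all__ = [
    "ProteinPredictions",
    "ScreenRow",
    "vote_level",
    "expression_score",
    "expression_change_test",
    "screen",
    "screen_pvalues",
    "load_table1",
]

DEFAULT_ALPHA = 0.05


@dataclass
class ProteinPredictions:
    protein_id: str
    normal: list[PredictionResult]
    cancer: list[PredictionResult]


@dataclass
class ScreenRow:
    protein_id: str
    level_normal: str
    level_cancer: str
    p_expression: float
    p_locations: list[tuple[str, float]] = field(default_factory=list)
    expression_flag: bool = False
    location_flag: bool = False
    biomarker_flag: bool = False
    degenerate: bool = False  # zero-variance t-test convention applied


def vote_level(predictions: list[PredictionResult]) -> str:
    """Majority vote over predicted labels.

    Ties break by the largest summed probability among the tied classes,
    then by the fixed high > medium > low order.
    """
    if not predictions:
        raise ValueError("cannot vote over an empty prediction list")
    counts = {lev: 0 for lev in LEVELS}
    prob_sums = {lev: 0.0 for lev in LEVELS}
    for p in predictions:
        counts[p.label] += 1
        for i, lev in enumerate(LEVELS):
            prob_sums[lev] += float(p.probs[i])
    top = max(counts.values())
    tied = [lev for lev in LEVELS if counts[lev] == top]
    if len(tied) == 1:
        return tied[0]
    best = max(prob_sums[lev] for lev in tied)
    for lev in tied:  # LEVELS order breaks exact probability ties
        if prob_sums[lev] == best:
            return lev
    return tied[0]


def expression_score(pred: PredictionResult) -> float:
    """Expected ordinal level: 0*p_low + 1*p_medium + 2*p_high, in [0, 2]."""
    return float(2.0 * pred.probs[0] + 1.0 * pred.probs[1])


def _t_test(a: np.ndarray, b: np.ndarray, welch: bool) -> tuple[float, bool]:
    """Two-sided two-sample t P value with zero-variance conventions.

    Both groups constant: equal means -> P = 1; unequal means -> P = 0
    (flagged degenerate in either case).
    """
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return (1.0, True) if a[0] == b[0] else (0.0, True)
    import warnings

    with warnings.catch_warnings():
        # scipy warns on near-identical groups; the statistic is still defined
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _sstats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if np.isnan(p):  # numerically degenerate variance
        return (1.0, True) if abs(a.mean() - b.mean()) < 1e-12 else (0.0, True)
    return p, False


def expression_change_test(
    prot: ProteinPredictions,
    welch: bool = False,
    mode: str = "scalar",
) -> tuple[float, bool]:
    """P value for expression change between normal and cancer images.

    ``mode='scalar'`` (default) runs a pooled-variance two-sided t-test on
    the expected-ordinal-level scores of the two image groups.
    ``mode='per_class'`` tests each probability component separately and
    Bonferroni-combines (3 x min P, capped at 1).  Returns (P, degenerate)
    where the flag marks the zero-variance conventions.
    """
    if mode == "scalar":
        a = np.array([expression_score(p) for p in prot.normal])
        b = np.array([expression_score(p) for p in prot.cancer])
        return _t_test(a, b, welch)
    if mode == "per_class":
        ps, degen = [], False
        for i in range(3):
            a = np.array([float(p.probs[i]) for p in prot.normal])
            b = np.array([float(p.probs[i]) for p in prot.cancer])
            p_i, d_i = _t_test(a, b, welch)
            ps.append(p_i)
            degen |= d_i
        return min(1.0, 3.0 * min(ps)), degen
    raise ValueError(f"unknown test mode {mode!r}")


def _location_pairs(location_p_table: pd.DataFrame | None, protein: str):
    if location_p_table is None or len(location_p_table) == 0:
        return []
    sub = location_p_table[location_p_table["protein"] == protein]
    return [
        (str(r["compartment"]), float(r["p_location"]))
        for _, r in sub.iterrows()
        if np.isfinite(r["p_location"])
    ]


def screen(
    proteins: list[ProteinPredictions],
    location_p_table: pd.DataFrame | None = None,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
    mode: str = "scalar",
    bh_correct: bool = False,
) -> tuple[list[ScreenRow], float]:
    """Flag expression/location biomarkers; returns rows + detection rate (%).

    Per protein: voted levels per condition, the expression-change P value,
    expression_flag = (P < alpha), location_flag = any compartment P <
    alpha, biomarker_flag = either.  ``bh_correct`` optionally applies
    Benjamini-Hochberg across the expression P values before flagging (off
    by default, matching the uncorrected published screen).
    """
    ids = [p.protein_id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein IDs in screen input")
    p_exprs, degen_flags = [], []
    for prot in proteins:
        p, d = expression_change_test(prot, welch=welch, mode=mode)
        p_exprs.append(p)
        degen_flags.append(d)
    p_for_flag = _bh_adjust(np.array(p_exprs)) if bh_correct else np.array(p_exprs)

    rows: list[ScreenRow] = []
    for prot, p_raw, p_adj, degen in zip(proteins, p_exprs, p_for_flag, degen_flags):
        locs = _location_pairs(location_p_table, prot.protein_id)
        expression_flag = bool(p_adj < alpha)
        location_flag = any(p < alpha for _, p in locs)
        rows.append(
            ScreenRow(
                protein_id=prot.protein_id,
                level_normal=vote_level(prot.normal),
                level_cancer=vote_level(prot.cancer),
                p_expression=float(p_raw),
                p_locations=locs,
                expression_flag=expression_flag,
                location_flag=location_flag,
                biomarker_flag=expression_flag or location_flag,
                degenerate=degen,
            )
        )
    rate = 100.0 * sum(r.biomarker_flag for r in rows) / len(rows) if rows else 0.0
    return rows, rate


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def screen_pvalues(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    use_expression: bool = True,
    use_location: bool = True,
) -> tuple[list[ScreenRow], float]:
    """Screen from a precomputed P-value table (Table 1 layout).

    ``table`` has one row per protein x compartment with columns
    ``protein, level_normal, level_cancer, p_expression, compartment,
    p_location``.  Either route can be switched off to reproduce the
    expression-only or location-only screens.
    """
    rows: list[ScreenRow] = []
    for protein, sub in table.groupby("protein", sort=False):
        first = sub.iloc[0]
        if (sub["p_expression"] != first["p_expression"]).any():
            raise ValueError(f"inconsistent expression P for protein {protein}")
        locs = [
            (str(r["compartment"]), float(r["p_location"]))
            for _, r in sub.iterrows()
            if np.isfinite(r["p_location"])
        ]
        p_expr = float(first["p_expression"])
        expression_flag = use_expression and p_expr < alpha
        location_flag = use_location and any(p < alpha for _, p in locs)
        rows.append(
            ScreenRow(
                protein_id=str(protein),
                level_normal=str(first.get("level_normal", "")),
                level_cancer=str(first.get("level_cancer", "")),
                p_expression=p_expr,
                p_locations=locs,
                expression_flag=bool(expression_flag),
                location_flag=bool(location_flag),
                biomarker_flag=bool(expression_flag or location_flag),
            )
        )
    rate = 100.0 * sum(r.biomarker_flag for r in rows) / len(rows) if rows else 0.0
    return rows, rate


def load_table1() -> pd.DataFrame:
    """The bundled transcription of the published 22-protein LBD screen."""
    with resources.files("ihcscreen.data").joinpath("table1_lbd.csv").open() as fh:
        return pd.read_csv(fh)


def rows_to_frame(rows: list[ScreenRow]) -> pd.DataFrame:
    """Flatten screen rows to a tidy table (one row per protein)."""
    return pd.DataFrame(
        {
            "protein": [r.protein_id for r in rows],
            "level_normal": [r.level_normal for r in rows],
            "level_cancer": [r.level_cancer for r in rows],
            "p_expression": [r.p_expression for r in rows],
            "p_locations": [
                ";".join(f"{c}:{p:.3g}" for c, p in r.p_locations) for r in rows
            ],
            "expression_flag": [r.expression_flag for r in rows],
            "location_flag": [r.location_flag for r in rows],
            "biomarker_flag": [r.biomarker_flag for r in rows],
        }
    )
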