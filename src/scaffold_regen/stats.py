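"""Cohort statistics: exact Wilcoxon signed-rank, stiffness regression,
responder classification and summaries.

Sample sizes here are tiny (n = 6 scaffolds per design, 12 animals), so the
Wilcoxon signed-rank test is computed exactly by enumerating all ``2^n``
sign assignments of the ranked absolute differences (zeros dropped, tied
ranks averaged) rather than by normal approximation.

The stiffness covariate spans ~200-7000 MPa, so the ingrowth-vs-stiffness
regression is run on log10(apparent modulus), mirroring the exponential
spacing of the scaffold designs.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import linregress, rankdata

from .designs import APPARENT_MODULUS_MPA, DESIGNS, compliance_rank

__all__ = [
    "DegenerateTestError",
    "wilcoxon_signed_rank_exact",
    "pair_design_values",
    "stiffness_regression",
    "classify_responders",
    "summarize_cohort",
    "cohort_report",
]


class DegenerateTestError(ValueError):
    """All paired differences are zero; the test statistic is undefined."""


def wilcoxon_signed_rank_exact(x, y) -> tuple[float, float]:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped and tied absolute differences receive
    averaged ranks.  The two-sided p-value is computed from the exact
    conditional null distribution obtained by enumerating all ``2^n`` sign
    assignments of the observed ranks.  Returns ``(W_plus, p)`` where
    ``W_plus`` is the positive-rank sum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    d = x - y
    d = d[np.abs(d) > 1e-12]
    n = len(d)
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    if n > 20:
        raise ValueError("exact enumeration limited to n <= 20")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    # exact null: every sign vector equally likely given |d| ranks
    signs = np.array(np.meshgrid(*([[0.0, 1.0]] * n),
                                 indexing="ij")).reshape(n, -1)
    w_all = ranks @ signs
    p_le = float((w_all <= w_plus + 1e-9).mean())
    p_ge = float((w_all >= w_plus - 1e-9).mean())
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_plus, p


def pair_design_values(table: pd.DataFrame, design_a: str, design_b: str,
                       pairing: str = "within_animal_then_rank",
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Form n=6 paired samples for a between-design comparison.

    Each design appears in 6 animals but the two designs co-occur in only a
    few of them.  ``within_animal_then_rank`` pairs co-occurring values by
    animal and the remaining values by rank order; ``rank`` pairs all
    values by rank order.
    """
    a_rows = table[table["design"] == design_a]
    b_rows = table[table["design"] == design_b]
    if pairing == "rank":
        return (np.sort(a_rows["fraction_pct"].to_numpy()),
                np.sort(b_rows["fraction_pct"].to_numpy()))
    if pairing != "within_animal_then_rank":
        raise ValueError(f"unknown pairing {pairing!r}")
    shared = sorted(set(a_rows["animal_id"]) & set(b_rows["animal_id"]))
    xa = [float(a_rows.set_index("animal_id")["fraction_pct"][i])
          for i in shared]
    xb = [float(b_rows.set_index("animal_id")["fraction_pct"][i])
          for i in shared]
    rest_a = np.sort(a_rows[~a_rows["animal_id"].isin(shared)]
                     ["fraction_pct"].to_numpy())
    rest_b = np.sort(b_rows[~b_rows["animal_id"].isin(shared)]
                     ["fraction_pct"].to_numpy())
    return (np.concatenate([xa, rest_a]), np.concatenate([xb, rest_b]))


def stiffness_regression(table: pd.DataFrame) -> dict:
    """OLS of ingrowth fraction on log10(apparent modulus).

    Returns slope (pp per decade of stiffness), r^2 and the two-sided
    p-value of the slope t-statistic.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    e = table["modulus_mpa"].to_numpy(float)
    if np.any(e <= 0):
        raise ValueError("moduli must be positive")
    x = np.log10(e)
    if np.ptp(x) < 1e-12:
        raise ValueError("constant stiffness covariate")
    fit = linregress(x, table["fraction_pct"].to_numpy(float))
    return {"slope": float(fit.slope), "r2": float(fit.rvalue**2),
            "p": float(fit.pvalue), "n": int(len(table))}


def _two_means_split_1d(values: np.ndarray) -> np.ndarray:
    """Exact 1D two-cluster split minimizing within-cluster SSE.

    Returns a boolean mask marking the upper cluster.
    """
    order = np.argsort(values)
    v = values[order]
    n = len(v)
    best_k, best_sse = None, np.inf
    for k in range(1, n):
        lo, hi = v[:k], v[k:]
        sse = (((lo - lo.mean()) ** 2).sum()
               + ((hi - hi.mean()) ** 2).sum())
        if sse < best_sse:
            best_sse, best_k = sse, k
    upper = np.zeros(n, dtype=bool)
    upper[order[best_k:]] = True
    return upper


def classify_responders(table: pd.DataFrame) -> pd.DataFrame:
    """Split animals into strong/weak responders.

    Per animal the signed paired difference (compliant-leg minus stiffer-leg
    ingrowth, compliance ranked by direction-averaged modulus) is computed,
    then the differences are split into two clusters by an exact 1D
    two-means; the upper cluster is labelled strong.

    Returns a frame with animal_id, paired_difference_pp, responder_est.
    """
    rows = []
    for animal, grp in table.groupby("animal_id"):
        if len(grp) != 2:
            raise ValueError(f"animal {animal} must have exactly 2 rows")
        grp = grp.sort_values("design",
                              key=lambda s: s.map(compliance_rank))
        compliant, stiffer = grp.iloc[0], grp.iloc[1]
        rows.append({
            "animal_id": animal,
            "compliant_design": compliant["design"],
            "stiffer_design": stiffer["design"],
            "paired_difference_pp": float(compliant["fraction_pct"]
                                          - stiffer["fraction_pct"]),
        })
    out = pd.DataFrame(rows)
    diffs = out["paired_difference_pp"].to_numpy()
    if np.ptp(diffs) < 1e-12:
        warnings.warn("identical paired differences: single cluster",
                      stacklevel=2)
        out["responder_est"] = "strong"
        return out
    upper = _two_means_split_1d(diffs)
    out["responder_est"] = np.where(upper, "strong", "weak")
    return out


def summarize_cohort(table: pd.DataFrame,
                     responders: pd.DataFrame) -> dict:
    """Group summaries: mean paired difference per responder class, overall
    fraction range, and per-design mean fractions (1 decimal)."""
    if responders.empty:
        raise ValueError("empty responder table")
    merged = responders.set_index("animal_id")
    strong = merged[merged["responder_est"] == "strong"]
    weak = merged[merged["responder_est"] == "weak"]
    frac = table["fraction_pct"]
    per_design = {d: round(float(g["fraction_pct"].mean()), 1)
                  for d, g in table.groupby("design")}
    return {
        "strong_mean_difference_pp": round(
            float(strong["paired_difference_pp"].mean()), 1)
        if len(strong) else None,
        "weak_mean_difference_pp": round(
            float(weak["paired_difference_pp"].mean()), 1)
        if len(weak) else None,
        "n_strong": int(len(strong)),
        "n_weak": int(len(weak)),
        "fraction_min_pct": round(float(frac.min()), 1),
        "fraction_max_pct": round(float(frac.max()), 1),
        "per_design_mean_pct": per_design,
    }


def cohort_report(table: pd.DataFrame,
                  pairing: str = "within_animal_then_rank") -> dict:
    """Full statistical report for a quantified cohort table.

    ``table`` needs columns animal_id, leg, design, modulus_mpa,
    fraction_pct (24 rows, 6 per design, 2 per animal).  The report carries
    the 6 pairwise design comparisons (unadjusted two-sided exact Wilcoxon,
    both pairing variants), the log-stiffness regression, the responder
    classification and the group summaries.
    """
    counts = table["design"].value_counts()
    if sorted(counts.index) != sorted(DESIGNS) or counts.nunique() != 1:
        warnings.warn("table is not a balanced 4x6 cohort", stacklevel=2)
    pairwise = {}
    for a, b in combinations(sorted(DESIGNS), 2):
        entry = {}
        for variant in ("within_animal_then_rank", "rank"):
            xa, xb = pair_design_values(table, a, b, pairing=variant)
            try:
                w, p = wilcoxon_signed_rank_exact(xa, xb)
                entry[variant] = {"W": w, "p": p,
                                  "significant": bool(p < 0.05)}
            except DegenerateTestError:
                entry[variant] = {"W": None, "p": None,
                                  "significant": False}
        pairwise[f"{a}_vs_{b}"] = entry
    responders = classify_responders(table)
    return {
        "pairwise_wilcoxon": pairwise,
        "pairing_note": ("primary pairing: within-animal pairs where the "
                         "designs co-occur, remaining values by rank order"),
        "regression": stiffness_regression(table),
        "responders": responders.to_dict(orient="records"),
        "summary": summarize_cohort(table, responders),
    }
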