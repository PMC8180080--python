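"""Per-compound univariate statistics and the two-phase marker screen.

Phase 1 keeps compounds whose two-sided Wilcoxon rank-sum p-value clears a
Bonferroni-corrected family-wise threshold (alpha / m over all m compounds
tested).  Phase 2 keeps phase-1 survivors detected (abundance > 0) in
strictly more than a cutoff fraction of the case samples.  A Shapiro-Wilk
normality gate is computed for reporting only; the pipeline is
unconditionally nonparametric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ProfileMatrix


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling the family-wise error rate.

    With alpha = 0.05 over a 922-compound profile this is the 5.42e-5
    screening level.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled sample is small (<= 20) and untied;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and untied) else "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    if np.isnan(p):  # all pooled values tied: no evidence either way
        return 1.0
    return float(min(p, 1.0))


def rank_sum_pvalues(case_block: np.ndarray, control_block: np.ndarray) -> np.ndarray:
    """Vectorised two-sided rank-sum p-values, one per matrix row.

    Uses the tie-corrected normal approximation with continuity correction;
    intended for the per-round screens where every pooled sample is large.
    """
    res = stats.mannwhitneyu(
        case_block, control_block, alternative="two-sided", method="asymptotic", axis=-1
    )
    p = np.asarray(res.pvalue, dtype=float)
    p[np.isnan(p)] = 1.0  # rows with every pooled value tied
    return np.minimum(p, 1.0)


def compare_categorical(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 count table.

    Returns (statistic, p-value) with df = 1.  Used for cohort demographics
    comparisons (gender, risk factors, hematuria).
    """
    obs = np.asarray(table)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise ValueError("table must contain non-negative integer counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    assert dof == 1
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# normality gate (advisory)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalityReport:
    """Shapiro-Wilk p-values per compound and group, plus a dataset verdict.

    ``non_normal`` is True when the minimum Bonferroni-adjusted p-value is
    below ``alpha``; the verdict is advisory — downstream screening always
    uses the rank test.
    """

    table: pd.DataFrame  # columns: compound_id, p_case, p_control
    non_normal: bool
    min_adjusted_p: float


def shapiro_wilk_gate(pm: ProfileMatrix, alpha: float = 0.05) -> NormalityReport:
    """Per-compound, per-group Shapiro-Wilk normality test.

    A compound constant within a group has an undefined p there (recorded as
    NaN, not fatal).  The dataset-level verdict Bonferroni-adjusts over all
    defined p-values.
    """
    mask = pm.case_mask
    rows = []
    for c, row in zip(pm.compounds, pm.abundance):
        ps = []
        for grp_vals in (row[mask], row[~mask]):
            if grp_vals.size < 3 or np.ptp(grp_vals) == 0:
                ps.append(math.nan)
            else:
                ps.append(float(stats.shapiro(grp_vals).pvalue))
        rows.append((c.compound_id, ps[0], ps[1]))
    table = pd.DataFrame(rows, columns=["compound_id", "p_case", "p_control"])
    finite = table[["p_case", "p_control"]].to_numpy().ravel()
    finite = finite[np.isfinite(finite)]
    if finite.size == 0:
        return NormalityReport(table, False, math.nan)
    min_adj = float(min(finite.min() * finite.size, 1.0))
    return NormalityReport(table, min_adj < alpha, min_adj)


# ---------------------------------------------------------------------------
# two-phase screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the two-phase screen for one compound."""

    compound_id: str
    p_value: float
    alpha_adjusted: float
    detection_fraction_case: float
    passed_phase1: bool
    passed_phase2: bool


def detection_fraction_filter(
    pm: ProfileMatrix, compound_id: str, case_ids, cutoff: float
) -> tuple[float, bool]:
    """Fraction of ``case_ids`` with non-zero abundance; passes iff the
    fraction strictly exceeds ``cutoff`` ("more than 60%" is strict)."""
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("case_ids must be non-empty")
    row = pm.values(compound_id)
    idx = [pm.sample_ids.index(s) for s in case_ids]
    frac = float(np.count_nonzero(row[idx] > 0) / len(idx))
    return frac, frac > cutoff


def screen_arrays(
    abundance: np.ndarray,
    case_mask: np.ndarray,
    alpha: float,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Array-level two-phase screen over all compounds at once.

    Returns (p_values, detection_fraction_case, passed_phase1,
    passed_phase2, alpha_adjusted).  The Bonferroni denominator is the total
    number of compounds tested, not the survivor count.  This is the fast
    path used inside the leave-one-out loop.
    """
    m = abundance.shape[0]
    alpha_adj = bonferroni_threshold(alpha, m)
    case_block = abundance[:, case_mask]
    control_block = abundance[:, ~case_mask]
    n_pooled = abundance.shape[1]
    if n_pooled <= 20:
        pvals = np.array(
            [wilcoxon_rank_sum(case_block[i], control_block[i]) for i in range(m)]
        )
    else:
        pvals = rank_sum_pvalues(case_block, control_block)
    det_frac = np.count_nonzero(case_block > 0, axis=1) / case_block.shape[1]
    pass1 = pvals < alpha_adj
    pass2 = pass1 & (det_frac > cutoff)
    return pvals, det_frac, pass1, pass2, alpha_adj


def screen_candidates(
    pm_training: ProfileMatrix, alpha: float = 0.05, cutoff: float = 0.6
) -> list[ScreeningResult]:
    """Run the two-phase screen on a training profile.

    Phase 1: rank-sum p below alpha / m (m = all compounds).  Phase 2:
    detection fraction among training cases strictly above ``cutoff``.
    Results are sorted by ascending p-value.
    """
    pvals, det_frac, pass1, pass2, alpha_adj = screen_arrays(
        pm_training.abundance, pm_training.case_mask, alpha, cutoff
    )
    results = [
        ScreeningResult(
            compound_id=c.compound_id,
            p_value=float(pvals[i]),
            alpha_adjusted=alpha_adj,
            detection_fraction_case=float(det_frac[i]),
            passed_phase1=bool(pass1[i]),
            passed_phase2=bool(pass2[i]),
        )
        for i, c in enumerate(pm_training.compounds)
    ]
    results.sort(key=lambda r: (r.p_value, r.compound_id))
    return results


def screening_table(results: list[ScreeningResult]) -> pd.DataFrame:
    """Serialisable TSV-ready view of screening results."""
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in results],
            "p_value": [r.p_value for r in results],
            "alpha_adjusted": [r.alpha_adjusted for r in results],
            "detection_fraction_case": [r.detection_fraction_case for r in results],
            "passed_phase1": [r.passed_phase1 for r in results],
            "passed_phase2": [r.passed_phase2 for r in results],
        }
    )
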