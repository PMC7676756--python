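"""Renal handling and oral carnitine bioavailability.

The kidney conserves carnitine aggressively and clears TMAO efficiently,
so spot-urine measurements referenced to creatinine carry most of the
signal about how much of an oral carnitine dose escaped microbial
conversion.  This module implements the clinical fractional-excretion
estimator (the FeNa formula applied to carnitine and TMAO), creatinine
normalisation of urine concentrations, a paired Wilcoxon signed-rank test
with Pratt handling of zero differences, and the pre/post supplementation
group contrast table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "fractional_excretion",
    "creatinine_normalize",
    "WilcoxonResult",
    "paired_change_test",
    "bioavailability_contrast",
]


def _check_positive(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value}")
    return value


def fractional_excretion(u_x: float, p_x: float, u_cr: float, p_cr: float) -> float:
    """Fractional excretion of analyte X in percent.

    ``(urine_X * plasma_creatinine) / (plasma_X * urine_creatinine) * 100``
    from paired spot samples.  ``u_x``/``p_x`` must share one unit and
    ``u_cr``/``p_cr`` another; the ratio cancels both, so the result is
    invariant to rescaling either pair.
    """
    u_x = _check_positive("u_x (urine analyte)", u_x)
    p_x = _check_positive("p_x (plasma analyte)", p_x)
    u_cr = _check_positive("u_cr (urine creatinine)", u_cr)
    p_cr = _check_positive("p_cr (plasma creatinine)", p_cr)
    return (u_x * p_cr) / (p_x * u_cr) * 100.0


def creatinine_normalize(u_x: float, u_cr: float) -> float:
    """Urine analyte referenced to creatinine, in mmol analyte per mol creatinine.

    Both inputs must be molar concentrations in the same unit; the output is
    ``u_x / u_cr * 1000`` (mol/mol scaled to mmol/mol).
    """
    u_cr = _check_positive("u_cr (urine creatinine)", u_cr)
    u_x = float(u_x)
    if not np.isfinite(u_x) or u_x < 0:
        raise ValueError(f"u_x must be >= 0, got {u_x}")
    return u_x / u_cr * 1000.0


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank statistic W+ (Pratt ranks) and its two-sided p-value."""

    statistic: float
    p_value: float
    n: int
    n_zero: int
    method: str


def _exact_two_sided_p(w_doubled: int, doubled_ranks: np.ndarray) -> float:
    # Exact null pmf of W+ (doubled so midranks become integers) by
    # convolution over the 2^m equiprobable sign assignments.
    total = int(doubled_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total - r + 1]
        pmf = 0.5 * (pmf + shifted)
    p_le = float(pmf[: w_doubled + 1].sum())
    p_ge = float(pmf[w_doubled:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(differences: np.ndarray, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are handled by the Pratt convention: they enter the
    ranking of absolute differences but are excluded from signing.  The
    null distribution is enumerated exactly (over sign assignments of the
    non-zero midranks) for n <= ``exact_max_n``; larger samples use the
    normal approximation with tie/zero variance correction and a 0.5
    continuity correction.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size < 3:
        raise ValueError("need at least 3 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    n = d.size
    nonzero = d != 0
    n_zero = int(n - nonzero.sum())
    ranks = stats.rankdata(np.abs(d))  # midranks over all pairs, zeros included
    w_plus = float(ranks[d > 0].sum())
    if n_zero == n:
        warnings.warn("all paired differences are zero; p-value is 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, n, n_zero, "degenerate")

    nz_ranks = ranks[nonzero]
    if n <= exact_max_n:
        doubled = np.round(2 * nz_ranks).astype(int)
        p = _exact_two_sided_p(int(round(2 * w_plus)), doubled)
        return WilcoxonResult(w_plus, p, n, n_zero, "exact")

    # Normal approximation under Pratt: zeros keep their ranks but never
    # contribute to W+, shifting the mean/variance terms below.
    z = n_zero
    mean = (n * (n + 1) - z * (z + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - z * (z + 1) * (2 * z + 1)) / 24.0
    _, tie_counts = np.unique(nz_ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, n_zero, "normal")
    diff = w_plus - mean
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    zstat = (diff - cc) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(zstat)))
    return WilcoxonResult(w_plus, p, n, n_zero, "normal")


def paired_change_test(pre: np.ndarray, post: np.ndarray) -> WilcoxonResult:
    """Paired nonparametric pre/post comparison (Wilcoxon signed-rank, Pratt)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    return wilcoxon_signed_rank(post - pre)


def bioavailability_contrast(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-group pre/post summary of creatinine-normalised urine analytes.

    Parameters
    ----------
    measurements
        Tidy frame with columns ``subject_id``, ``group`` (e.g. producer
        phenotype or diet), ``phase`` (``pre_supplement``/``post_supplement``),
        ``analyte`` and ``value`` (mmol/mol creatinine).

    Returns
    -------
    DataFrame with one row per (group, phase, analyte): mean, SEM, n and the
    paired Wilcoxon p-value for the pre/post change (repeated on both phase
    rows).  Subjects lacking one of the two phases are dropped and counted.
    """
    required = {"subject_id", "group", "phase", "analyte", "value"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    rows = []
    n_dropped = 0
    for (group, analyte), sub in measurements.groupby(["group", "analyte"], sort=True):
        wide = sub.pivot_table(index="subject_id", columns="phase", values="value")
        for phase_col in ("pre_supplement", "post_supplement"):
            if phase_col not in wide:
                wide[phase_col] = np.nan
        paired = wide.dropna(subset=["pre_supplement", "post_supplement"])
        n_dropped += len(wide) - len(paired)
        n = len(paired)
        if n >= 3:
            test = paired_change_test(
                paired["pre_supplement"].to_numpy(), paired["post_supplement"].to_numpy()
            )
            p = test.p_value
        else:
            p = np.nan
        for phase in ("pre_supplement", "post_supplement"):
            vals = paired[phase]
            rows.append(
                {
                    "group": group,
                    "phase": phase,
                    "analyte": analyte,
                    "mean": float(vals.mean()) if n else np.nan,
                    "sem": float(vals.sem()) if n > 1 else np.nan,
                    "n": n,
                    "p_paired": p,
                }
            )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unmatched subject-analyte pairs", stacklevel=2)
    return pd.DataFrame(rows, columns=["group", "phase", "analyte", "mean", "sem", "n", "p_paired"])
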