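"""Oral carnitine challenge test (OCCT) phenotyping.

The OCCT doses a fasting subject with oral L-carnitine and samples plasma
and urine at 0, 24 and 48 h.  Gut-microbial conversion of carnitine to
trimethylamine (TMA), oxidised in the liver to TMAO, makes the height of
the resulting TMAO excursion a read-out of the microbiota's TMA-producing
capacity.  Subjects are dichotomised into low/high TMAO producers by the
peak concentration of the challenge curve: plasma TMAO_MAX strictly above
10 uM, or the regression-mapped urine equivalent (>= 162.79 mmol TMAO per
mol creatinine).

This module holds the curve container, the two productivity statistics
(TMAO_MAX and trapezoidal TMAO_AUC), the producer classification rule, the
fasting-TMAO screen, the urine-cutoff mapping from paired plasma/urine
maxima, and the pre/post supplementation phenotype transition table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PLASMA_CUTOFF_UM",
    "URINE_CUTOFF_MMOL_PER_MOL",
    "FASTING_THRESHOLD_UM",
    "OcctCurve",
    "PhenotypeCall",
    "tmao_max",
    "tmao_auc",
    "classify_producer",
    "fasting_screen",
    "urine_cutoff_from_regression",
    "phenotype_call",
    "phenotype_shift_table",
]

#: Plasma TMAO_MAX cutoff (uM) separating low from high producers (strict ">").
PLASMA_CUTOFF_UM = 10.0
#: Urine TMAO_MAX cutoff (mmol/mol creatinine), applied inclusively (">=").
URINE_CUTOFF_MMOL_PER_MOL = 162.79
#: Fasting plasma TMAO screening threshold (uM).
FASTING_THRESHOLD_UM = 6.2

Fluid = Literal["plasma", "urine"]
Phase = Literal["pre_supplement", "post_supplement"]

_FLUIDS = ("plasma", "urine")
_PHASES = ("pre_supplement", "post_supplement")


@dataclass(frozen=True)
class OcctCurve:
    """One subject's timed TMAO/carnitine concentrations in one fluid.

    Units are uM for plasma and mmol analyte per mol creatinine for urine.
    ``timepoints`` are hours since the carnitine dose; the first point is
    the fasting baseline at 0 h.
    """

    subject_id: str
    fluid: str
    timepoints: np.ndarray
    tmao: np.ndarray
    carnitine: np.ndarray | None = None
    phase: str = "pre_supplement"

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        y = np.asarray(self.tmao, dtype=float)
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "tmao", y)
        if self.fluid not in _FLUIDS:
            raise ValueError(f"fluid must be one of {_FLUIDS}, got {self.fluid!r}")
        if self.phase not in _PHASES:
            raise ValueError(f"phase must be one of {_PHASES}, got {self.phase!r}")
        if t.ndim != 1 or t.size < 2:
            raise ValueError("curve needs at least two timepoints")
        if not np.all(np.isfinite(t)) or t[0] != 0:
            raise ValueError("timepoints must be finite and start at 0 (baseline)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if y.shape != t.shape:
            raise ValueError("tmao vector length must match timepoints")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValueError("tmao concentrations must be finite and >= 0")
        if self.carnitine is not None:
            c = np.asarray(self.carnitine, dtype=float)
            object.__setattr__(self, "carnitine", c)
            if c.shape != t.shape:
                raise ValueError("carnitine vector length must match timepoints")
            if not np.all(np.isfinite(c)) or np.any(c < 0):
                raise ValueError("carnitine concentrations must be finite and >= 0")

    @property
    def baseline_tmao(self) -> float:
        """Fasting (t = 0) TMAO concentration."""
        return float(self.tmao[0])


@dataclass(frozen=True)
class PhenotypeCall:
    """Per-subject productivity statistics and the low/high producer label."""

    subject_id: str
    fluid: str
    tmao_max: float
    tmao_auc: float
    phenotype: Literal["low", "high"]
    cutoff: float
    cutoff_basis: Literal["plasma_10uM", "urine_mapped", "custom"]
    phase: str = "pre_supplement"


def tmao_max(curve: OcctCurve) -> float:
    """Maximum TMAO concentration over the challenge, baseline included."""
    return float(np.max(curve.tmao))


def tmao_auc(curve: OcctCurve) -> float:
    """Trapezoidal area under the TMAO curve (concentration x hours).

    Computed over the observed timepoints with no baseline subtraction, so
    a constant curve at concentration c over [0, T] integrates to c*T.
    """
    return float(np.trapezoid(curve.tmao, curve.timepoints))


def classify_producer(
    stat: float, cutoff: float, inclusive: bool = False
) -> Literal["low", "high"]:
    """Dichotomise a productivity statistic into ``low`` or ``high``.

    Parameters
    ----------
    stat
        TMAO_MAX (or TMAO_AUC) value, >= 0.
    cutoff
        Positive decision threshold.
    inclusive
        If False (the plasma convention), ``high`` requires ``stat > cutoff``
        and equality yields ``low``.  If True (the urine convention),
        ``stat >= cutoff`` is called ``high``.
    """
    if not np.isfinite(stat) or stat < 0:
        raise ValueError(f"productivity statistic must be >= 0, got {stat}")
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    hit = stat >= cutoff if inclusive else stat > cutoff
    return "high" if hit else "low"


def fasting_screen(baseline_tmao: float, threshold: float = FASTING_THRESHOLD_UM) -> bool:
    """True iff the fasting (t = 0) plasma TMAO exceeds ``threshold`` (strict)."""
    if not np.isfinite(baseline_tmao) or baseline_tmao < 0:
        raise ValueError(f"baseline TMAO must be >= 0, got {baseline_tmao}")
    return bool(baseline_tmao > threshold)


def urine_cutoff_from_regression(
    paired_maxima: Iterable[tuple[float, float]] | np.ndarray,
    plasma_cutoff: float = PLASMA_CUTOFF_UM,
) -> float:
    """Map the plasma cutoff onto the urine scale by OLS through paired maxima.

    Fits ``urine = a * plasma + b`` over per-subject (plasma TMAO_MAX,
    urine TMAO_MAX) pairs and returns the fitted urine value at
    ``plasma_cutoff``.  Exact (zero-residual) when the pairs are colinear.
    """
    pairs = np.asarray(list(paired_maxima) if not isinstance(paired_maxima, np.ndarray) else paired_maxima, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (plasma, urine) pairs")
    plasma, urine = pairs[:, 0], pairs[:, 1]
    if np.ptp(plasma) == 0:
        raise ValueError("degenerate design: plasma maxima are all identical")
    slope, intercept = np.polyfit(plasma, urine, 1)
    return float(slope * plasma_cutoff + intercept)


def phenotype_call(
    curve: OcctCurve,
    cutoff: float | None = None,
    inclusive: bool | None = None,
) -> PhenotypeCall:
    """Summarise one curve into a :class:`PhenotypeCall`.

    Defaults follow the fluid: plasma uses the strict 10 uM rule, urine the
    inclusive 162.79 mmol/mol creatinine rule.  Passing an explicit cutoff
    marks the call as ``custom``.
    """
    if cutoff is None:
        basis = "plasma_10uM" if curve.fluid == "plasma" else "urine_mapped"
        cutoff = PLASMA_CUTOFF_UM if curve.fluid == "plasma" else URINE_CUTOFF_MMOL_PER_MOL
    else:
        basis = "custom"
    if inclusive is None:
        inclusive = curve.fluid == "urine"
    peak = tmao_max(curve)
    return PhenotypeCall(
        subject_id=curve.subject_id,
        fluid=curve.fluid,
        tmao_max=peak,
        tmao_auc=tmao_auc(curve),
        phenotype=classify_producer(peak, cutoff, inclusive=inclusive),
        cutoff=float(cutoff),
        cutoff_basis=basis,
        phase=curve.phase,
    )


def _labels(calls: Sequence[PhenotypeCall] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(calls, Mapping):
        return dict(calls)
    return {c.subject_id: c.phenotype for c in calls}


def phenotype_shift_table(
    pre: Sequence[PhenotypeCall] | Mapping[str, str],
    post: Sequence[PhenotypeCall] | Mapping[str, str],
) -> pd.DataFrame:
    """2x2 pre/post phenotype transition counts.

    Rows index the pre-supplementation label, columns the post label;
    marginals therefore sum to the cohort size.
    """
    pre_l, post_l = _labels(pre), _labels(post)
    if set(pre_l) != set(post_l):
        missing = set(pre_l) ^ set(post_l)
        raise ValueError(f"pre/post subject sets differ (e.g. {sorted(missing)[:3]})")
    table = pd.DataFrame(
        0, index=pd.Index(["low", "high"], name="pre"),
        columns=pd.Index(["low", "high"], name="post"), dtype=int
    )
    for sid, a in pre_l.items():
        table.loc[a, post_l[sid]] += 1
    return table


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Round-half-up integer percentage, the convention for reported cohort
    proportions (e.g. 25/56 -> 45, 31/56 -> 55)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return int(np.floor(100.0 * numerator / denominator + 0.5))
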