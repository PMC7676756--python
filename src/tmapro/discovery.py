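"""Key-taxon discovery from humanized gnotobiotic (hGM) mice and
presence/absence diagnostics.

Germ-free mice colonised with human donor microbiota inherit a subset of
the donor's OTUs; only groups whose donor carried the TMA-producing
consortium acquire the ability to convert a deuterated carnitine dose into
d9-TMA/d9-TMAO.  Candidate key taxa are found by set algebra: the OTUs in
every producer mouse (the core), restricted to the producer donor's
inventory, minus everything observed in any non-producer mouse.  Candidate
taxa are then evaluated as OR-of-presence diagnostic rules against the
human producer phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .community import OtuTable

__all__ = [
    "HgmGroup",
    "HgmExperiment",
    "DiagnosticResult",
    "d9_producer_call",
    "core_otus",
    "candidate_taxa",
    "producer_enriched_taxa",
    "diagnostic_metrics",
    "combination_search",
]


@dataclass(frozen=True)
class HgmGroup:
    """One hGM group: a donor, its mice (presence sets) and producer status."""

    name: str
    donor_id: str
    producer: bool
    mice: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        if len(self.mice) < 1:
            raise ValueError(f"group {self.name!r} has no mice")


@dataclass(frozen=True)
class HgmExperiment:
    """Donor inventories plus the colonised mouse groups."""

    groups: tuple[HgmGroup, ...]
    donors: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        for g in self.groups:
            if g.donor_id not in self.donors:
                raise ValueError(f"group {g.name!r} references unknown donor {g.donor_id!r}")

    @property
    def producer_groups(self) -> tuple[HgmGroup, ...]:
        return tuple(g for g in self.groups if g.producer)


def d9_producer_call(
    curves: pd.DataFrame,
    lod: float | None = None,
    analytes: Sequence[str] = ("d9-TMA", "d9-TMAO"),
) -> bool:
    """Producer call from a d9-labelled metabolite time course.

    True iff any post-gavage (time > 0) d9-TMA or d9-TMAO value exceeds the
    limit of detection.  ``lod`` defaults to the smallest positive value in
    the frame, so an all-zero series is a non-producer and any rising
    signal is a producer.
    """
    required = {"time_h", "analyte", "value"}
    if not required.issubset(curves.columns):
        raise ValueError(f"curves must have columns {sorted(required)}")
    if len(curves) == 0:
        raise ValueError("empty d9 time series")
    if lod is None:
        positive = curves["value"].to_numpy()
        positive = positive[positive > 0]
        lod = float(positive.min()) if positive.size else 0.0
    mask = curves["analyte"].isin(analytes) & (curves["time_h"] > 0)
    return bool((curves.loc[mask, "value"] > lod).any())


def core_otus(group: HgmGroup) -> frozenset:
    """OTUs present in every mouse of the group (set intersection)."""
    sets = list(group.mice.values())
    core = frozenset(sets[0])
    for s in sets[1:]:
        core &= s
    return core


def candidate_taxa(
    experiment: HgmExperiment,
    producer_group: str | None = None,
    exclude: str = "observed",
) -> frozenset:
    """Candidate key taxa by core/donor/exclusion set algebra.

    ``(core of producer mice) ∩ (producer donor inventory)`` minus, by
    default, the union of every OTU observed in any mouse of any
    non-producer group (``exclude="observed"``).  ``exclude="core"`` is the
    variant subtracting only the non-producer groups' cores.
    """
    producers = experiment.producer_groups
    if producer_group is not None:
        producers = tuple(g for g in producers if g.name == producer_group)
    if len(producers) == 0:
        raise ValueError("experiment has no producer group")
    if len(producers) > 1:
        raise ValueError(
            "multiple producer groups; pass producer_group= to select one"
        )
    producer = producers[0]
    core = core_otus(producer) & experiment.donors[producer.donor_id]
    excluded: set = set()
    for g in experiment.groups:
        if g.producer:
            continue
        if exclude == "observed":
            for s in g.mice.values():
                excluded |= s
        elif exclude == "core":
            excluded |= core_otus(g)
        else:
            raise ValueError("exclude must be 'observed' or 'core'")
    return frozenset(core - excluded)


def producer_enriched_taxa(
    mouse_table: OtuTable,
    producer_flags: pd.Series,
    fdr_threshold: float = 0.01,
    require_in_every_producer_mouse: bool = True,
    level: str = "genus",
) -> pd.DataFrame:
    """Taxa significantly more abundant in producer mice (BH-FDR).

    Counts are aggregated to ``level`` (currently genus, via the taxonomy
    lineages), compared between producer and non-producer mice by
    Mann-Whitney with BH adjustment, and optionally restricted to taxa
    present in every producer mouse.
    """
    from .community import differential_abundance, relative_abundance

    if level != "genus":
        raise ValueError("only genus-level aggregation is supported")
    flags = producer_flags.loc[mouse_table.counts.index].astype(bool)
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError("need at least 2 mice per group")
    genus = mouse_table.genus_table()
    groups = pd.Series(
        np.where(flags.to_numpy(), "producer", "nonproducer"), index=genus.counts.index
    )
    hits = differential_abundance(genus, groups, fdr_threshold=fdr_threshold)
    hits = hits[hits["enriched_in"] == "producer"]
    if require_in_every_producer_mouse:
        producer_counts = genus.counts.loc[flags[flags].index]
        everywhere = (producer_counts > 0).all(axis=0)
        hits = hits[hits["otu_id"].map(everywhere)]
    return hits.rename(columns={"otu_id": "taxon"}).reset_index(drop=True)


@dataclass(frozen=True)
class DiagnosticResult:
    """Confusion counts and derived metrics for a presence/absence rule."""

    rule: tuple[str, ...]
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.n_positive if self.n_positive else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.n_negative if self.n_negative else float("nan")

    @property
    def ppv(self) -> float | None:
        """Positive predictive value in percent; None when no positive calls."""
        return 100.0 * self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def npv(self) -> float | None:
        return 100.0 * self.tn / (self.tn + self.fn) if (self.tn + self.fn) else None

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return 100.0 * (self.tp + self.tn) / total

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 100.0

    def as_dict(self, ndigits: int = 1) -> dict:
        """Reporting form: counts plus percentages rounded to one decimal."""
        rnd = lambda v: None if v is None else round(v, ndigits)
        return {
            "rule": list(self.rule),
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": rnd(self.sensitivity),
            "specificity": rnd(self.specificity),
            "ppv": rnd(self.ppv),
            "npv": rnd(self.npv),
            "accuracy": rnd(self.accuracy),
        }


def diagnostic_metrics(
    detected: Sequence[bool] | np.ndarray,
    positive: Sequence[bool] | np.ndarray,
    rule: Iterable[str] = (),
) -> DiagnosticResult:
    """Confusion counts of a detection vector against the true phenotype."""
    det = np.asarray(detected, dtype=bool)
    pos = np.asarray(positive, dtype=bool)
    if det.shape != pos.shape:
        raise ValueError("detected and positive vectors must have equal length")
    if det.size == 0:
        raise ValueError("empty input")
    return DiagnosticResult(
        rule=tuple(sorted(rule)),
        tp=int((det & pos).sum()),
        fp=int((det & ~pos).sum()),
        tn=int((~det & ~pos).sum()),
        fn=int((~det & pos).sum()),
    )


_CRITERIA = ("accuracy", "youden", "sensitivity", "specificity", "ppv")


def combination_search(
    candidates: Sequence[str],
    presence_matrix: pd.DataFrame,
    positives: Sequence[bool] | np.ndarray,
    criterion: str = "accuracy",
    max_candidates: int = 20,
) -> pd.DataFrame:
    """Exhaustive evaluation of OR-of-presence rules over candidate taxa.

    Every non-empty subset of ``candidates`` is scored as "detected iff any
    member taxon present" via :func:`diagnostic_metrics` and ranked by
    ``criterion`` (descending), breaking ties by higher specificity, then
    smaller subset, then lexicographic rule.  All metric columns are
    reported so alternative criteria can be inspected.
    """
    candidates = list(dict.fromkeys(candidates))
    if len(candidates) == 0:
        raise ValueError("no candidate taxa")
    if len(candidates) > max_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the exhaustive-search cap "
            f"({max_candidates}); restrict the candidate list"
        )
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    missing = [c for c in candidates if c not in presence_matrix.columns]
    if missing:
        raise KeyError(f"candidates absent from presence matrix: {missing}")
    pos = np.asarray(positives, dtype=bool)
    rows = []
    for size in range(1, len(candidates) + 1):
        for subset in combinations(candidates, size):
            detected = presence_matrix[list(subset)].to_numpy(dtype=bool).any(axis=1)
            res = diagnostic_metrics(detected, pos, rule=subset)
            rows.append(
                {
                    "rule": res.rule,
                    "size": size,
                    "tp": res.tp,
                    "fp": res.fp,
                    "tn": res.tn,
                    "fn": res.fn,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                    "ppv": -np.inf if res.ppv is None else res.ppv,
                    "npv": -np.inf if res.npv is None else res.npv,
                    "accuracy": res.accuracy,
                    "youden": res.youden,
                }
            )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        by=[criterion, "specificity", "size", "rule"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out[["ppv", "npv"]] = out[["ppv", "npv"]].replace(-np.inf, np.nan)
    return out
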