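"""OTU-table processing and community statistics.

Count tables enter pre-binned (samples x OTUs, integer read counts with
taxonomy strings).  The module covers single rarefaction to a fixed depth,
relative abundance, alpha diversity (Shannon, observed OTUs, Chao1),
Bray-Curtis dissimilarity, principal coordinates analysis, one-way
PERMANOVA with permutation p-values, Mann-Whitney/Benjamini-Hochberg
differential abundance, and presence calls for individual taxa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OtuTable",
    "rarefy",
    "relative_abundance",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "PermanovaResult",
    "permanova",
    "differential_abundance",
    "presence",
    "DEFAULT_RAREFACTION_DEPTH",
]

logger = logging.getLogger(__name__)

#: Single-rarefaction depth (reads per sample) used throughout the analysis.
DEFAULT_RAREFACTION_DEPTH = 61_600


class OtuTable:
    """Samples x OTUs integer count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id with one column per OTU id;
        non-negative integers.
    taxonomy
        Optional per-OTU lineage string (semicolon-delimited ranks), indexed
        by OTU id.
    sample_metadata
        Optional per-sample key/value frame indexed by sample id (diet,
        phase, producer status, ...).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        taxonomy: pd.Series | None = None,
        sample_metadata: pd.DataFrame | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            raise ValueError("sample ids must be unique")
        if counts.columns.has_duplicates:
            raise ValueError("OTU ids must be unique")
        values = counts.to_numpy()
        if values.size and (not np.issubdtype(values.dtype, np.integer)):
            if not np.allclose(values, np.round(values)) or np.any(~np.isfinite(values)):
                raise ValueError("counts must be integers")
            counts = counts.round().astype(np.int64)
        if values.size and np.any(counts.to_numpy() < 0):
            raise ValueError("counts must be >= 0")
        counts = counts.astype(np.int64)
        counts.index.name = "sample_id"
        counts.columns.name = None
        self.counts = counts
        if taxonomy is not None:
            taxonomy = taxonomy.reindex(counts.columns)
        self.taxonomy = taxonomy
        if sample_metadata is not None:
            missing = counts.index.difference(sample_metadata.index)
            if len(missing):
                raise ValueError(f"sample metadata missing for {list(missing[:3])}")
            sample_metadata = sample_metadata.loc[counts.index]
        self.sample_metadata = sample_metadata

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "OtuTable":
        meta = None if self.sample_metadata is None else self.sample_metadata.loc[sample_ids]
        return OtuTable(self.counts.loc[sample_ids], self.taxonomy, meta)

    def filter_min_total(self, min_total: int = 2) -> "OtuTable":
        """Drop OTUs whose total count across samples is below ``min_total``.

        The default removes singletons, the standard low-confidence filter
        applied before rarefaction.
        """
        keep = self.counts.sum(axis=0) >= min_total
        tax = None if self.taxonomy is None else self.taxonomy[keep[keep].index]
        return OtuTable(self.counts.loc[:, keep[keep].index], tax, self.sample_metadata)

    def genus_table(self) -> "OtuTable":
        """Aggregate counts to genus level using the taxonomy lineages.

        The genus is the ``g__`` token of the lineage; OTUs without one are
        pooled under ``g__unclassified``.
        """
        if self.taxonomy is None:
            raise ValueError("genus aggregation requires taxonomy annotations")
        genera = self.taxonomy.fillna("").map(_extract_genus)
        agg = self.counts.T.groupby(genera.values).sum().T
        agg.columns.name = None
        return OtuTable(agg, None, self.sample_metadata)


def _extract_genus(lineage: str) -> str:
    for token in str(lineage).split(";"):
        token = token.strip()
        if token.startswith("g__") and len(token) > 3:
            return token
    return "g__unclassified"


def rarefy(
    table: OtuTable,
    depth: int = DEFAULT_RAREFACTION_DEPTH,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> OtuTable:
    """Single rarefaction: subsample each sample to exactly ``depth`` reads.

    Draws are uniform without replacement (multivariate hypergeometric), so
    each retained sample sums exactly to ``depth`` and the output support is
    a subset of the input support.  Samples with fewer than ``depth`` total
    reads are dropped (and logged), not scaled.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    if rng is None:
        rng = np.random.default_rng(seed)
    totals = table.sample_sums()
    keep = totals[totals >= depth].index
    dropped = totals.index.difference(keep)
    if len(dropped):
        logger.info("rarefy: dropped %d samples below depth %d: %s",
                    len(dropped), depth, list(dropped[:5]))
    out = np.empty((len(keep), table.n_otus), dtype=np.int64)
    for i, sid in enumerate(keep):
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=keep, columns=table.counts.columns)
    meta = None if table.sample_metadata is None else table.sample_metadata.loc[keep]
    return OtuTable(counts, table.taxonomy, meta)


def relative_abundance(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalised fractions; every sample row sums to 1."""
    counts = table.counts if isinstance(table, OtuTable) else table
    sums = counts.sum(axis=1)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    return counts.div(sums, axis=0)


def _shannon(row: np.ndarray) -> float:
    p = row[row > 0] / row.sum()
    return float(-(p * np.log(p)).sum())


def _chao1(row: np.ndarray) -> float:
    s_obs = int((row > 0).sum())
    f1 = int((row == 1).sum())
    f2 = int((row == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    # bias-corrected form, needed when no doubletons are present
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample Shannon index (natural log), observed OTUs and Chao1.

    Chao1 is ``S_obs + F1^2 / (2 F2)`` with the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when there are no doubletons,
    which also makes Chao1 equal observed richness when singletons are
    absent.
    """
    counts = table.counts.to_numpy()
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("empty sample: all counts are zero")
    return pd.DataFrame(
        {
            "shannon": [_shannon(r) for r in counts],
            "observed_otus": (counts > 0).sum(axis=1),
            "chao1": [_chao1(r) for r in counts],
        },
        index=table.counts.index,
    )


def bray_curtis(table: OtuTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    ``d(i, j) = sum |x_i - x_j| / sum (x_i + x_j)`` over OTUs, computed on
    the rows as given (counts or relative abundances).
    """
    counts = table.counts if isinstance(table, OtuTable) else table
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    condensed = pdist(counts.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in counts.index])


def pcoa(dist: DistanceMatrix) -> OrdinationResults:
    """Principal coordinates analysis (classical scaling of the Gower matrix).

    Eigenvalues are reported in descending order including any negative
    ones; sample coordinates span the positive-eigenvalue axes.
    """
    if not isinstance(dist, DistanceMatrix):
        dist = DistanceMatrix(np.asarray(dist))  # raises on asymmetry
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns about negative eigenvalues
        return _skbio_pcoa(dist, method="eigh")


@dataclass(frozen=True)
class PermanovaResult:
    """One-way PERMANOVA decomposition of a distance matrix."""

    statistic: float  # pseudo-F
    r_squared: float  # SS_between / SS_total
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Within-group sum of squares from squared distances."""
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss_within


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA (ADONIS) on a distance matrix.

    Partitions the total sum of squared distances into between- and
    within-group components, returning the pseudo-F statistic, R^2 and the
    permutation p-value ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    R^2 depends only on the observed labelling; only the p-value is
    stochastic, and it is reproducible under a fixed seed.
    """
    labels = np.asarray(
        grouping.loc[list(dist.ids)] if isinstance(grouping, pd.Series) else grouping
    )
    n = len(dist.ids)
    if labels.shape[0] != n:
        raise ValueError("grouping length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 samples")
    a = len(groups)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _permanova_ss(d2, labels, groups)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore"):
        f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = labels[rng.permutation(n)]
        ss_w = _permanova_ss(d2, perm, groups)
        with np.errstate(divide="ignore"):
            f_perm = ((ss_total - ss_w) / (a - 1)) / (ss_w / (n - a))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations, n, a)


def _mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both groups have <= 20 observations and the
    pooled data are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def differential_abundance(
    table: OtuTable,
    groups: pd.Series | np.ndarray,
    fdr_threshold: float = 0.01,
    return_all: bool = False,
) -> pd.DataFrame:
    """Per-OTU two-group differential abundance with BH-FDR control.

    Relative abundances are compared between the two groups by a two-sided
    Mann-Whitney U test; p-values are Benjamini-Hochberg adjusted.
    Constant-abundance OTUs get p = 1.  The result lists OTUs with adjusted
    p below ``fdr_threshold`` (or all OTUs if ``return_all``), annotated
    with the group whose mean relative abundance is higher.
    """
    labels = np.asarray(
        groups.loc[table.counts.index] if isinstance(groups, pd.Series) else groups
    )
    names = np.unique(labels)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(names)}")
    ra = relative_abundance(table)
    mask = labels == names[0]
    a, b = ra.to_numpy()[mask], ra.to_numpy()[~mask]
    pvals = np.array([_mann_whitney_p(a[:, j], b[:, j]) for j in range(ra.shape[1])])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    direction = np.where(a.mean(axis=0) >= b.mean(axis=0), names[0], names[1])
    result = pd.DataFrame(
        {
            "otu_id": ra.columns,
            "p_value": pvals,
            "q_value": qvals,
            "enriched_in": direction,
        }
    )
    if table.taxonomy is not None:
        result["taxonomy"] = table.taxonomy.reindex(ra.columns).to_numpy()
    result = result.sort_values(["q_value", "p_value", "otu_id"], kind="mergesort")
    if return_all:
        return result.reset_index(drop=True)
    return result[result["q_value"] < fdr_threshold].reset_index(drop=True)


def presence(table: OtuTable, otu_id: str, min_reads: int = 1) -> pd.Series:
    """Boolean per-sample presence call: count >= ``min_reads``."""
    if otu_id not in table.counts.columns:
        raise KeyError(f"unknown OTU id {otu_id!r}")
    return table.counts[otu_id] >= min_reads
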