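"""Synthetic study generator.

Emulates the structure of the carnitine-supplementation study so every
analysis stage runs offline: a 56-subject cohort (33 omnivores, 23
vegetarians, 45% high TMAO producers), pre/post oral carnitine challenge
curves with plasma peaks at 24-48 h and a near-linear urine/plasma TMAO
relationship, a 1637-OTU count table over the 112 subject-phase samples
with two planted rare key taxa carried only by high-producer samples (plus
a 37-OTU block correlated with productivity), and a humanized gnotobiotic
mouse experiment with a 353-OTU donor inventory, a 78-OTU producer core,
3 producer-unique candidate OTUs and 8 producer-enriched marker genera.

All draws descend from a single seed; identical seeds give identical
studies.  Planted cardinalities (carrier counts 13/12 with overlap 3, the
7 low-to-high phenotype shifts, the hGM set sizes) are emulation of the
source study's printed detections, not inference about real biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import OtuTable
from .discovery import HgmExperiment, HgmGroup
from .occt import OcctCurve

__all__ = [
    "KeyTaxonSpec",
    "HgmConfig",
    "GeneratorConfig",
    "SyntheticStudy",
    "simulate_cohort",
    "simulate_supplementation",
    "simulate_occt",
    "simulate_otu_table",
    "simulate_hgm",
    "simulate_study",
]


@dataclass(frozen=True)
class KeyTaxonSpec:
    """A planted rare key taxon and its carrier counts by sample status."""

    name: str
    taxonomy: str
    rel_abundance: float = 8e-5
    n_high_carriers: int = 13
    n_low_carriers: int = 0


@dataclass(frozen=True)
class HgmConfig:
    """Sizes and signal levels of the gnotobiotic-mouse fixture."""

    n_groups: int = 4
    mice_per_group: int = 11
    donor_inventory_size: int = 353
    producer_core_size: int = 78
    n_unique_candidates: int = 3
    n_marker_genera: int = 8  # producer-enriched genera, present in every producer mouse
    extras_shared_with_others: int = 100
    nonproducer_unique_extras: int = 125
    producer_extra_presence: float = 0.45
    nonproducer_core_presence: float = 0.95
    nonproducer_other_presence: float = 0.7
    d9_timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 24.0)
    d9_lod: float = 0.05

    def __post_init__(self) -> None:
        markers = 2 * self.n_marker_genera
        if self.n_unique_candidates + markers > self.producer_core_size:
            raise ValueError("candidates plus marker OTUs exceed the producer core size")
        if self.producer_core_size > self.donor_inventory_size:
            raise ValueError("producer core cannot exceed the donor inventory")
        if self.n_groups < 2 or self.mice_per_group < 1:
            raise ValueError("need >= 2 groups with >= 1 mouse each")


def _default_key_taxa() -> tuple[KeyTaxonSpec, ...]:
    return (
        KeyTaxonSpec(
            name="Emergencia_timonensis",
            taxonomy=(
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Family_XIII;g__Emergencia;s__timonensis"
            ),
            rel_abundance=8e-5,
            n_high_carriers=13,
            n_low_carriers=0,
        ),
        KeyTaxonSpec(
            name="Ihubacter_massiliensis",
            taxonomy=(
                "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;"
                "f__Family_XIII;g__[Eubacterium]_nodatum_group;s__Ihubacter_massiliensis"
            ),
            rel_abundance=8e-5,
            n_high_carriers=12,
            n_low_carriers=2,
        ),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the cohort facts the analysis assumes: 56 subjects split
    33/23 by diet, 45% high producers before supplementation, 7 low-to-high
    (and 6 high-to-low) phenotype transitions so the 112 subject-phase
    samples split 51 high / 61 low, a urine/plasma TMAO slope of 16.279
    mapping the 10 uM plasma cutoff to 162.79 mmol/mol creatinine, and a
    1637-OTU universe rarefied at 61,600 reads/sample.
    """

    n_subjects: int = 56
    n_omnivores: int = 33
    n_vegetarians: int = 23
    high_producer_fraction: float = 0.45
    n_high_vegetarians: int = 6
    # challenge-curve kinetics (plasma uM)
    plasma_cutoff: float = 10.0
    high_peak_range: tuple[float, float] = (11.0, 32.0)
    low_peak_range: tuple[float, float] = (1.5, 9.0)
    baseline_range: tuple[float, float] = (1.0, 4.0)
    peak_at_24h_probability: float = 0.7
    timepoints: tuple[float, ...] = (0.0, 24.0, 48.0)
    # supplementation effect
    supplement_factor: float | None = None  # None => calibrated to n_low_to_high
    n_low_to_high: int = 7
    n_high_to_low: int = 6
    # fasting-TMAO flags among omnivores (strictly above flag_level)
    n_fasting_flagged_pre: int = 1
    n_fasting_flagged_post: int = 7
    fasting_flag_level: float = 10.0
    # urine chemistry
    urine_plasma_slope: float = 16.279
    urine_noise_sd: float = 4.0
    plasma_creatinine_mean_uM: float = 57.66
    plasma_creatinine_sd_uM: float = 5.0
    urine_creatinine_mean_mM: float = 10.0
    urine_creatinine_sd_mM: float = 2.0
    plasma_carnitine_mean_uM: float = 33.0
    plasma_carnitine_sd_uM: float = 5.0
    # fasting urine carnitine (mmol/mol creatinine), by pre-phase phenotype
    urine_carnitine_low_pre_mean: float = 4.79
    urine_carnitine_low_post_ratio: float = 3.49
    urine_carnitine_high_pre_mean: float = 17.18
    urine_carnitine_high_post_ratio: float = 0.65
    urine_carnitine_log_sigma: float = 0.7
    # fasting urine TMAO (mmol/mol creatinine), by pre-phase phenotype
    urine_tmao_low_pre_mean: float = 25.0
    urine_tmao_low_post_ratio: float = 1.3
    urine_tmao_high_pre_mean: float = 90.0
    urine_tmao_high_post_ratio: float = 1.9
    urine_tmao_log_sigma: float = 0.6
    # OTU table
    n_otus: int = 1637
    rarefaction_depth: int = 61_600
    n_signal_otus: int = 39  # correlated block size, key taxa included
    signal_beta_range: tuple[float, float] = (0.25, 0.6)  # log10 units per response SD
    abundance_noise_log10: float = 0.35
    otu_mean_log10_sd: float = 1.0
    carrier_weighting: float = 2.0  # softmax pull of carriers toward high response
    key_taxa: tuple[KeyTaxonSpec, ...] = field(default_factory=_default_key_taxa)
    key_taxa_overlap: int = 3
    depth_factor: float = 1.0  # >1 samples deeper so rarefaction is non-trivial
    hgm: HgmConfig = field(default_factory=HgmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_omnivores + self.n_vegetarians != self.n_subjects:
            raise ValueError("diet counts must sum to n_subjects")
        if not 0.0 <= self.high_producer_fraction <= 1.0:
            raise ValueError("high_producer_fraction must be in [0, 1]")
        if self.n_high_vegetarians > min(self.n_vegetarians, self.n_high_pre):
            raise ValueError("n_high_vegetarians exceeds available subjects")
        if self.n_low_to_high > self.n_subjects - self.n_high_pre:
            raise ValueError("n_low_to_high exceeds the low-producer count")
        if self.n_high_to_low > self.n_high_pre:
            raise ValueError("n_high_to_low exceeds the high-producer count")
        if len(self.key_taxa) >= 2 and self.key_taxa_overlap > min(
            t.n_high_carriers for t in self.key_taxa[:2]
        ):
            raise ValueError("key-taxa overlap exceeds a carrier count")
        if self.n_signal_otus > self.n_otus:
            raise ValueError("signal block larger than the OTU universe")
        if self.depth_factor < 1.0:
            raise ValueError("depth_factor must be >= 1")

    @property
    def n_high_pre(self) -> int:
        """Pre-supplement high-producer count (round-half-up of the fraction)."""
        return int(np.floor(self.high_producer_fraction * self.n_subjects + 0.5))


@dataclass
class SyntheticStudy:
    """Everything one synthetic study run produces."""

    config: GeneratorConfig
    cohort: pd.DataFrame
    curves: list[OcctCurve]
    measurements: pd.DataFrame
    otu_table: OtuTable
    hgm_experiment: HgmExperiment
    hgm_mouse_table: OtuTable
    hgm_d9_curves: pd.DataFrame
    truth: dict


def _streams(seed: int, n: int = 6) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float, size=None):
    """Log-normal draws with the requested arithmetic mean."""
    return rng.lognormal(np.log(mean) - sigma**2 / 2.0, sigma, size=size)


# ---------------------------------------------------------------------------
# cohort and supplementation
# ---------------------------------------------------------------------------

def simulate_cohort(config: GeneratorConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Subject table with diet, pre-phase phenotype and productivity.

    Productivity is the plasma TMAO_MAX (uM) the subject's challenge curve
    peaks at; phenotype is ``high`` iff productivity exceeds the plasma
    cutoff.  Reproducible under the config seed.
    """
    if rng is None:
        rng = _streams(config.seed)[0]
    n = config.n_subjects
    ids = [f"S{i + 1:02d}" for i in range(n)]
    diet = np.array(
        ["omnivore"] * config.n_omnivores + ["vegetarian"] * config.n_vegetarians
    )
    n_high = config.n_high_pre
    n_high_veg = min(config.n_high_vegetarians, n_high)
    n_high_omn = n_high - n_high_veg
    omn_idx = np.flatnonzero(diet == "omnivore")
    veg_idx = np.flatnonzero(diet == "vegetarian")
    high_idx = np.concatenate(
        [
            rng.choice(omn_idx, size=n_high_omn, replace=False),
            rng.choice(veg_idx, size=n_high_veg, replace=False),
        ]
    )
    phenotype = np.full(n, "low", dtype=object)
    phenotype[high_idx] = "high"

    productivity = np.where(
        phenotype == "high",
        rng.uniform(*config.high_peak_range, size=n),
        rng.uniform(*config.low_peak_range, size=n),
    )
    baseline = np.minimum(rng.uniform(*config.baseline_range, size=n), 0.8 * productivity)

    cohort = pd.DataFrame(
        {
            "diet": diet,
            "phenotype_pre": phenotype,
            "productivity_pre": productivity,
            "baseline_pre": baseline,
        },
        index=pd.Index(ids, name="subject_id"),
    )

    # plant the fasting-TMAO flags among pre-phase high-producer omnivores
    eligible = cohort.index[(cohort.diet == "omnivore") & (cohort.phenotype_pre == "high")]
    flagged = rng.choice(
        eligible, size=min(config.n_fasting_flagged_pre, len(eligible)), replace=False
    )
    lvl = config.fasting_flag_level
    cohort.loc[flagged, "baseline_pre"] = rng.uniform(lvl + 0.5, lvl + 3.0, size=len(flagged))
    cohort["productivity_pre"] = np.maximum(
        cohort["productivity_pre"], cohort["baseline_pre"] + 1.0
    )
    return cohort


def _calibrated_factor(low_peaks: np.ndarray, cutoff: float, k: int) -> float:
    """Multiplier sending exactly ``k`` of the sorted low peaks above cutoff."""
    p = np.sort(low_peaks)[::-1]
    if k == 0:
        return 0.99 * cutoff / p[0]
    if k >= p.size:
        return 1.05 * cutoff / p[-1]
    return 2.0 * cutoff / (p[k - 1] + p[k])


def simulate_supplementation(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Post-supplementation productivity, phenotype and fasting baselines.

    Low producers are multiplied by a common factor, calibrated (when
    ``supplement_factor`` is None) so exactly ``n_low_to_high`` cross the
    plasma cutoff; high producers are unchanged except for the configured
    number of regressions below the cutoff, which match the post-phase
    sample-status margins.  With ``supplement_factor=1`` nothing shifts.
    """
    if rng is None:
        rng = _streams(config.seed)[1]
    cohort = cohort.copy()
    low = cohort.phenotype_pre == "low"
    cutoff = config.plasma_cutoff
    factor = config.supplement_factor
    if factor is None:
        factor = _calibrated_factor(
            cohort.loc[low, "productivity_pre"].to_numpy(), cutoff, config.n_low_to_high
        )
    post = cohort["productivity_pre"].to_numpy().copy()
    post[low.to_numpy()] *= factor

    high_ids = cohort.index[~low]
    n_regress = config.n_high_to_low if config.supplement_factor is None else 0
    regressors = rng.choice(high_ids, size=min(n_regress, len(high_ids)), replace=False)
    reg_mask = cohort.index.isin(regressors)
    post[reg_mask] = rng.uniform(0.6 * cutoff, 0.94 * cutoff, size=reg_mask.sum())

    cohort["supplement_factor"] = factor
    cohort["productivity_post"] = post
    cohort["phenotype_post"] = np.where(post > cutoff, "high", "low")

    # post-phase fasting baselines: planted flags among post-high omnivores
    base_post = np.minimum(
        cohort["baseline_pre"].to_numpy() * rng.lognormal(0.0, 0.15, size=len(cohort)),
        np.minimum(6.0, 0.8 * post),
    )
    base_post = np.maximum(base_post, 0.3)
    cohort["baseline_post"] = base_post
    eligible = cohort.index[
        (cohort.diet == "omnivore") & (cohort.phenotype_post == "high")
    ]
    n_flag = min(config.n_fasting_flagged_post, len(eligible))
    flagged = rng.choice(eligible, size=n_flag, replace=False)
    lvl = config.fasting_flag_level
    cohort.loc[flagged, "baseline_post"] = rng.uniform(lvl + 0.5, lvl + 4.0, size=n_flag)
    cohort["productivity_post"] = np.maximum(
        cohort["productivity_post"], cohort["baseline_post"] + 1.0
    )
    return cohort


# ---------------------------------------------------------------------------
# challenge curves and fasting chemistry
# ---------------------------------------------------------------------------

def _plasma_curve(baseline: float, peak: float, peak_at_24: bool) -> np.ndarray:
    mid = baseline + 0.55 * (peak - baseline)
    return np.array([baseline, peak, mid] if peak_at_24 else [baseline, mid, peak])


def simulate_occt(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[OcctCurve], pd.DataFrame]:
    """Plasma and urine challenge curves plus the long measurement table.

    Plasma TMAO rises from a low fasting baseline to the subject's
    productivity parameter at 24 or 48 h.  Urine TMAO follows
    ``slope * plasma`` with additive Gaussian noise truncated at zero, so
    with the noise disabled the cohort regression reproduces
    ``slope * plasma_cutoff`` exactly.  Fasting urine carnitine follows the
    planted per-phenotype pre/post means; creatinine in both fluids is
    drawn per subject-phase.  Units: plasma uM, urine mmol/mol creatinine,
    plasma creatinine uM, urine creatinine mM.
    """
    if rng is None:
        rng = _streams(config.seed)[2]
    if "productivity_post" not in cohort.columns:
        raise ValueError("cohort lacks post-phase columns; run simulate_supplementation")
    t = np.asarray(config.timepoints)
    curves: list[OcctCurve] = []
    rows: list[dict] = []

    plasma_carn = rng.normal(
        config.plasma_carnitine_mean_uM, config.plasma_carnitine_sd_uM, size=len(cohort)
    ).clip(15.0, 60.0)

    sigma_c = config.urine_carnitine_log_sigma
    sigma_t = config.urine_tmao_log_sigma
    for si, (sid, subj) in enumerate(cohort.iterrows()):
        is_high_pre = subj.phenotype_pre == "high"
        ucarn_pre = _lognormal_mean(
            rng,
            config.urine_carnitine_high_pre_mean if is_high_pre else config.urine_carnitine_low_pre_mean,
            sigma_c,
        )
        ucarn_post = ucarn_pre * (
            config.urine_carnitine_high_post_ratio if is_high_pre else config.urine_carnitine_low_post_ratio
        ) * rng.lognormal(-0.08, 0.4)
        utmao_pre = _lognormal_mean(
            rng,
            config.urine_tmao_high_pre_mean if is_high_pre else config.urine_tmao_low_pre_mean,
            sigma_t,
        )
        utmao_post = utmao_pre * (
            config.urine_tmao_high_post_ratio if is_high_pre else config.urine_tmao_low_post_ratio
        ) * rng.lognormal(-0.05, 0.35)

        for phase, suffix in (("pre_supplement", "pre"), ("post_supplement", "post")):
            baseline = float(subj[f"baseline_{suffix}"])
            peak = float(subj[f"productivity_{suffix}"])
            peak_at_24 = bool(rng.random() < config.peak_at_24h_probability)
            p_tmao = _plasma_curve(baseline, peak, peak_at_24)
            p_carn = plasma_carn[si] * rng.lognormal(0.0, 0.03, size=t.size)
            u_tmao = np.clip(
                config.urine_plasma_slope * p_tmao
                + rng.normal(0.0, config.urine_noise_sd, size=t.size),
                0.0,
                None,
            )
            fasting_ucarn = ucarn_pre if suffix == "pre" else ucarn_post
            u_carn = fasting_ucarn * rng.lognormal(0.0, 0.2, size=t.size)
            u_carn[0] = fasting_ucarn
            # fasting urine TMAO overrides the slope relation at t=0 only in
            # the sense of the spot sample used for bioavailability; the
            # challenge curve keeps the slope-linked values.
            p_cr = float(
                rng.normal(config.plasma_creatinine_mean_uM, config.plasma_creatinine_sd_uM)
            )
            p_cr = min(max(p_cr, 40.0), 85.0)
            u_cr = float(
                rng.normal(config.urine_creatinine_mean_mM, config.urine_creatinine_sd_mM)
            )
            u_cr = min(max(u_cr, 4.0), 18.0)

            curves.append(
                OcctCurve(sid, "plasma", t, p_tmao, carnitine=p_carn, phase=phase)
            )
            curves.append(
                OcctCurve(sid, "urine", t, u_tmao, carnitine=u_carn, phase=phase)
            )
            for i, hour in enumerate(t):
                rows.append(dict(subject_id=sid, phase=phase, fluid="plasma",
                                 time_h=hour, analyte="tmao", value=p_tmao[i], unit="uM"))
                rows.append(dict(subject_id=sid, phase=phase, fluid="plasma",
                                 time_h=hour, analyte="carnitine", value=p_carn[i], unit="uM"))
                rows.append(dict(subject_id=sid, phase=phase, fluid="urine",
                                 time_h=hour, analyte="tmao", value=u_tmao[i],
                                 unit="mmol/mol creatinine"))
                rows.append(dict(subject_id=sid, phase=phase, fluid="urine",
                                 time_h=hour, analyte="carnitine", value=u_carn[i],
                                 unit="mmol/mol creatinine"))
            rows.append(dict(subject_id=sid, phase=phase, fluid="plasma", time_h=0.0,
                             analyte="creatinine", value=p_cr, unit="uM"))
            rows.append(dict(subject_id=sid, phase=phase, fluid="urine", time_h=0.0,
                             analyte="creatinine", value=u_cr, unit="mM"))
            rows.append(dict(subject_id=sid, phase=phase, fluid="urine", time_h=0.0,
                             analyte="tmao_fasting", value=utmao_pre if suffix == "pre" else utmao_post,
                             unit="mmol/mol creatinine"))
    measurements = pd.DataFrame(rows)
    return curves, measurements


# ---------------------------------------------------------------------------
# human OTU table
# ---------------------------------------------------------------------------

def _sample_frame(cohort: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """One row per subject-phase sample with status and noise-free response."""
    recs = []
    for sid, subj in cohort.iterrows():
        for phase, suffix in (("pre_supplement", "pre"), ("post_supplement", "post")):
            prod = float(subj[f"productivity_{suffix}"])
            recs.append(
                {
                    "sample_id": f"{sid}_{suffix}",
                    "subject_id": sid,
                    "phase": phase,
                    "diet": subj.diet,
                    "producer_status": "high" if prod > config.plasma_cutoff else "low",
                    "response_log10_utmao": np.log10(config.urine_plasma_slope * prod),
                }
            )
    return pd.DataFrame(recs).set_index("sample_id")


def _weighted_choice(
    rng: np.random.Generator, pool: np.ndarray, z: np.ndarray, size: int, weighting: float
) -> np.ndarray:
    """Sample without replacement with softmax(z)-proportional probabilities."""
    if size == 0:
        return np.array([], dtype=pool.dtype)
    w = np.exp(weighting * (z - z.max()))
    return rng.choice(pool, size=size, replace=False, p=w / w.sum())


def simulate_otu_table(
    cohort: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[OtuTable, dict]:
    """112-sample (56 subjects x 2 phases) OTU count table with planted signal.

    Non-key OTUs follow independent log-normal abundances; a block of
    ``n_signal_otus - len(key_taxa)`` OTUs scales log-linearly with the
    sample's productivity response.  Key taxa are planted at
    ``rel_abundance`` in the configured number of carrier samples (chosen
    among high-status samples with productivity-weighted probability, plus
    the configured low-status carriers) and are absent elsewhere.  Counts
    are multinomial at ``rarefaction_depth * depth_factor`` per sample.
    """
    if rng is None:
        rng = _streams(config.seed)[3]
    samples = _sample_frame(cohort, config)
    n_samples = len(samples)
    status = samples["producer_status"].to_numpy()
    high_pool = np.flatnonzero(status == "high")
    low_pool = np.flatnonzero(status == "low")
    for spec in config.key_taxa:
        if spec.n_high_carriers > high_pool.size:
            raise ValueError(
                f"{spec.name}: {spec.n_high_carriers} carriers exceed the "
                f"{high_pool.size} high-status samples"
            )
        if spec.n_low_carriers > low_pool.size:
            raise ValueError(f"{spec.name}: low carriers exceed low-status samples")

    n_key = len(config.key_taxa)
    n_background = config.n_otus - n_key
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n_background)]
    key_ids = [f"OTU_{n_background + i + 1:04d}" for i in range(n_key)]
    taxonomy = pd.Series(
        [
            (
                f"k__Bacteria;p__Phylum_{i % 12:02d};c__Class_{i % 30:02d};"
                f"o__Order_{i % 60:02d};f__Family_{i % 90:02d};"
                f"g__Genus_{i % 150:03d};s__sp_{i + 1:04d}"
            )
            for i in range(n_background)
        ]
        + [spec.taxonomy for spec in config.key_taxa],
        index=otu_ids + key_ids,
    )

    z = samples["response_log10_utmao"].to_numpy()
    z = (z - z.mean()) / z.std()

    n_block = max(config.n_signal_otus - n_key, 0)
    block_idx = rng.choice(n_background, size=n_block, replace=False)
    beta = np.zeros(n_background)
    beta[block_idx] = rng.uniform(*config.signal_beta_range, size=n_block)

    mu = rng.normal(0.0, config.otu_mean_log10_sd, size=n_background)
    eps = rng.normal(0.0, config.abundance_noise_log10, size=(n_samples, n_background))
    log10_w = mu[None, :] + beta[None, :] * z[:, None] + eps
    weights = 10.0**log10_w
    probs = weights / weights.sum(axis=1, keepdims=True)

    # carriers per key taxon; overlap between the first two taxa is planted
    carriers: dict[str, np.ndarray] = {}
    z_high = z[high_pool]
    if n_key:
        first = config.key_taxa[0]
        c0 = _weighted_choice(
            rng, high_pool, z_high, first.n_high_carriers, config.carrier_weighting
        )
        carriers[key_ids[0]] = np.concatenate(
            [c0, rng.choice(low_pool, size=first.n_low_carriers, replace=False)]
        ).astype(int)
    if n_key >= 2:
        second = config.key_taxa[1]
        overlap = min(config.key_taxa_overlap, second.n_high_carriers, c0.size)
        shared = rng.choice(c0, size=overlap, replace=False)
        rest_pool = np.setdiff1d(high_pool, c0)
        z_rest = z[rest_pool]
        fresh = _weighted_choice(
            rng, rest_pool, z_rest, second.n_high_carriers - overlap, config.carrier_weighting
        )
        lows = rng.choice(low_pool, size=second.n_low_carriers, replace=False)
        carriers[key_ids[1]] = np.concatenate([shared, fresh, lows]).astype(int)
    for extra_i in range(2, n_key):
        spec = config.key_taxa[extra_i]
        ch = _weighted_choice(rng, high_pool, z_high, spec.n_high_carriers, config.carrier_weighting)
        lows = rng.choice(low_pool, size=spec.n_low_carriers, replace=False)
        carriers[key_ids[extra_i]] = np.concatenate([ch, lows]).astype(int)

    depth = int(round(config.rarefaction_depth * config.depth_factor))
    key_reads = {
        key_ids[i]: max(1, int(round(config.key_taxa[i].rel_abundance * depth)))
        for i in range(n_key)
    }
    counts = np.zeros((n_samples, config.n_otus), dtype=np.int64)
    for s in range(n_samples):
        planted = 0
        for ki, kid in enumerate(key_ids):
            if s in carriers[kid]:
                counts[s, n_background + ki] = key_reads[kid]
                planted += key_reads[kid]
        counts[s, :n_background] = rng.multinomial(depth - planted, probs[s])

    table = OtuTable(
        pd.DataFrame(counts, index=samples.index, columns=otu_ids + key_ids),
        taxonomy=taxonomy,
        sample_metadata=samples,
    )
    truth = {
        "key_taxa": {
            config.key_taxa[i].name: {
                "otu_id": key_ids[i],
                "carrier_samples": sorted(samples.index[carriers[key_ids[i]]]),
                "n_high_carriers": int(np.isin(carriers[key_ids[i]], high_pool).sum()),
                "n_low_carriers": int(np.isin(carriers[key_ids[i]], low_pool).sum()),
                "reads_per_carrier": key_reads[key_ids[i]],
            }
            for i in range(n_key)
        },
        "signal_otus": sorted(np.array(otu_ids)[block_idx].tolist() + key_ids),
        "n_high_samples": int(high_pool.size),
        "n_low_samples": int(low_pool.size),
    }
    return table, truth


# ---------------------------------------------------------------------------
# gnotobiotic mouse experiment
# ---------------------------------------------------------------------------

def simulate_hgm(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[HgmExperiment, OtuTable, pd.DataFrame, dict]:
    """hGM fixture: donors, mouse presence/count table, d9 time courses.

    One producer group whose mice share a core of ``producer_core_size``
    OTUs drawn from a ``donor_inventory_size``-OTU donor; exactly
    ``n_unique_candidates`` core OTUs are absent from every non-producer
    mouse.  ``n_marker_genera`` genera are abundant in (and present in
    every) producer mouse.  Producer mice get d9-TMA/d9-TMAO excursions
    above the detection limit, non-producers stay at zero; d9-gBB rises
    then falls only in producers.
    """
    if rng is None:
        rng = _streams(config.seed)[4]
    h = config.hgm
    n_markers = 2 * h.n_marker_genera
    n_commons = h.producer_core_size - h.n_unique_candidates - n_markers
    n_extras = h.donor_inventory_size - h.producer_core_size

    candidate_ids = [f"HOTU_C{i + 1}" for i in range(h.n_unique_candidates)]
    marker_ids = [f"HOTU_M{i + 1:03d}" for i in range(n_markers)]
    common_ids = [f"HOTU_S{i + 1:03d}" for i in range(n_commons)]
    extra_ids = [f"HOTU_E{i + 1:03d}" for i in range(n_extras)]

    marker_genera = ["g__[Eubacterium]_nodatum_group"] + [
        f"g__Marker_{i:02d}" for i in range(2, h.n_marker_genera + 1)
    ]
    candidate_tax = [
        "k__Bacteria;f__Family_XIII;g__[Eubacterium]_nodatum_group;s__Ihubacter_massiliensis",
        "k__Bacteria;f__Bifidobacteriaceae;g__Bifidobacterium;s__bifidum",
        "k__Bacteria;f__Ruminococcaceae;s__unclassified",
    ]
    while len(candidate_tax) < h.n_unique_candidates:
        candidate_tax.append(f"k__Bacteria;g__Candidate_{len(candidate_tax) + 1}")
    taxonomy = {}
    for i, cid in enumerate(candidate_ids):
        taxonomy[cid] = candidate_tax[i]
    for i, mid in enumerate(marker_ids):
        taxonomy[mid] = f"k__Bacteria;{marker_genera[i // 2]};s__marker_sp_{i + 1}"
    # commons: first three are Bifidobacterium, next three unclassified, the
    # rest generic genera -- keeps the candidate genera dominated by taxa
    # common to all groups
    for i, sid in enumerate(common_ids):
        if i < 3:
            genus = "g__Bifidobacterium"
        elif i < 6:
            genus = "f__Ruminococcaceae"  # no genus token -> pooled unclassified
        else:
            genus = f"g__Common_{i % 25:02d}"
        taxonomy[sid] = f"k__Bacteria;{genus};s__common_sp_{i + 1}"
    for i, eid in enumerate(extra_ids):
        taxonomy[eid] = f"k__Bacteria;g__Common_{i % 25:02d};s__extra_sp_{i + 1}"

    core = candidate_ids + marker_ids + common_ids
    producer_donor = frozenset(core + extra_ids)

    group_names = [f"hGM_G{i + 1}" for i in range(h.n_groups)]
    producer_group = group_names[0]
    donor_ids = {g: f"D{i + 1:02d}" for i, g in enumerate(group_names)}

    donors: dict[str, frozenset] = {donor_ids[producer_group]: producer_donor}
    shared_core = [o for o in core if o not in candidate_ids]
    nonproducer_donor_sets: dict[str, list[str]] = {}
    for g in group_names[1:]:
        shared_extras = rng.choice(
            extra_ids, size=min(h.extras_shared_with_others, n_extras), replace=False
        ).tolist()
        unique = [f"HOTU_{g[-2:]}U{i + 1:03d}" for i in range(h.nonproducer_unique_extras)]
        for i, uid in enumerate(unique):
            taxonomy[uid] = f"k__Bacteria;g__Common_{i % 25:02d};s__unique_sp_{uid[-3:]}"
        inventory = shared_core + shared_extras + unique
        donors[donor_ids[g]] = frozenset(inventory)
        nonproducer_donor_sets[g] = inventory

    # --- mouse presence sets -------------------------------------------
    mice: dict[str, dict[str, set]] = {}
    producer_mice = [f"{producer_group}_m{i + 1:02d}" for i in range(h.mice_per_group)]
    mice[producer_group] = {}
    extra_presence = {}
    for m in producer_mice:
        present = set(core)
        take = rng.random(n_extras) < h.producer_extra_presence
        present |= {extra_ids[i] for i in np.flatnonzero(take)}
        mice[producer_group][m] = present
    # keep the producer core exactly at the planted size: no extra OTU may
    # be present in every producer mouse
    for eid in extra_ids:
        if all(eid in s for s in mice[producer_group].values()):
            victim = producer_mice[int(rng.integers(len(producer_mice)))]
            mice[producer_group][victim].discard(eid)

    for g in group_names[1:]:
        mice[g] = {}
        inventory = nonproducer_donor_sets[g]
        for i in range(h.mice_per_group):
            m = f"{g}_m{i + 1:02d}"
            take = rng.random(len(inventory)) < (
                np.where(np.isin(inventory, shared_core), h.nonproducer_core_presence,
                         h.nonproducer_other_presence)
            )
            mice[g][m] = {inventory[j] for j in np.flatnonzero(take)}
    # every non-candidate core OTU must be observed in some non-producer
    # mouse, so the exclusion leaves exactly the planted candidates
    nonproducer_groups = group_names[1:]
    for otu in shared_core:
        if not any(otu in s for g in nonproducer_groups for s in mice[g].values()):
            g = nonproducer_groups[int(rng.integers(len(nonproducer_groups)))]
            m = list(mice[g])[int(rng.integers(h.mice_per_group))]
            mice[g][m].add(otu)

    groups = tuple(
        HgmGroup(
            name=g,
            donor_id=donor_ids[g],
            producer=(g == producer_group),
            mice={m: frozenset(s) for m, s in mice[g].items()},
        )
        for g in group_names
    )
    experiment = HgmExperiment(groups=groups, donors=donors)

    # --- counts ---------------------------------------------------------
    all_otus = sorted({o for g in mice.values() for s in g.values() for o in s})
    otu_index = {o: i for i, o in enumerate(all_otus)}
    mouse_rows = []
    mouse_ids = []
    meta_rows = []
    for g in group_names:
        is_producer = g == producer_group
        for m, present in mice[g].items():
            row = np.zeros(len(all_otus), dtype=np.int64)
            for o in present:
                if o in candidate_ids:
                    c = 5 if is_producer else 0
                elif o in marker_ids:
                    c = _lognormal_mean(rng, 800.0 if is_producer else 10.0, 0.4)
                elif o in common_ids[:6]:
                    c = _lognormal_mean(rng, 500.0, 0.4)
                else:
                    c = _lognormal_mean(rng, 100.0, 0.6)
                row[otu_index[o]] = max(int(round(c)), 1) if (c or is_producer) else 0
            mouse_rows.append(row)
            mouse_ids.append(m)
            meta_rows.append({"group": g, "producer_group": is_producer})
    mouse_table = OtuTable(
        pd.DataFrame(np.vstack(mouse_rows), index=mouse_ids, columns=all_otus),
        taxonomy=pd.Series({o: taxonomy[o] for o in all_otus}),
        sample_metadata=pd.DataFrame(meta_rows, index=mouse_ids),
    )

    # --- d9 time courses ------------------------------------------------
    t = np.asarray(h.d9_timepoints)
    tma_shape = np.array([0.0, 0.5, 1.0, 0.8, 0.3])
    tmao_shape = np.array([0.0, 0.3, 0.8, 1.0, 0.5])
    gbb_prod_shape = np.array([0.0, 1.0, 1.5, 0.8, 0.3])
    gbb_non_shape = np.array([0.0, 0.8, 1.2, 1.6, 2.0])
    d9_rows = []
    for g in group_names:
        is_producer = g == producer_group
        for m in mice[g]:
            amp = rng.uniform(2.0, 6.0) if is_producer else 0.0
            gbb = rng.uniform(1.0, 3.0)
            series = {
                "d9-TMA": amp * tma_shape,
                "d9-TMAO": amp * tmao_shape,
                "d9-gBB": gbb * (gbb_prod_shape if is_producer else gbb_non_shape),
            }
            for analyte, vals in series.items():
                for ti, hour in enumerate(t):
                    d9_rows.append(
                        dict(group=g, mouse_id=m, time_h=float(hour),
                             analyte=analyte, value=float(vals[ti]))
                    )
    d9_curves = pd.DataFrame(d9_rows)

    truth = {
        "producer_group": producer_group,
        "producer_donor": donor_ids[producer_group],
        "donor_inventory_size": len(producer_donor),
        "core_size": h.producer_core_size,
        "candidate_otus": candidate_ids,
        "marker_genera": marker_genera,
        "n_producer_mice": h.mice_per_group,
    }
    return experiment, mouse_table, d9_curves, truth


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Generate the complete synthetic study from one seed."""
    if config is None:
        config = GeneratorConfig()
    s_cohort, s_supp, s_occt, s_otu, s_hgm, _ = _streams(config.seed)
    cohort = simulate_cohort(config, rng=s_cohort)
    cohort = simulate_supplementation(cohort, config, rng=s_supp)
    curves, measurements = simulate_occt(cohort, config, rng=s_occt)
    otu_table, otu_truth = simulate_otu_table(cohort, config, rng=s_otu)
    experiment, mouse_table, d9_curves, hgm_truth = simulate_hgm(config, rng=s_hgm)

    shifts = int(
        ((cohort.phenotype_pre == "low") & (cohort.phenotype_post == "high")).sum()
    )
    regressions = int(
        ((cohort.phenotype_pre == "high") & (cohort.phenotype_post == "low")).sum()
    )
    truth = {
        "n_subjects": config.n_subjects,
        "n_high_pre": int((cohort.phenotype_pre == "high").sum()),
        "n_low_pre": int((cohort.phenotype_pre == "low").sum()),
        "n_low_to_high": shifts,
        "n_high_to_low": regressions,
        "n_fasting_flagged_pre": config.n_fasting_flagged_pre,
        "n_fasting_flagged_post": config.n_fasting_flagged_post,
        "urine_plasma_slope": config.urine_plasma_slope,
        "urine_cutoff": config.urine_plasma_slope * config.plasma_cutoff,
        **otu_truth,
        "hgm": hgm_truth,
    }
    return SyntheticStudy(
        config=config,
        cohort=cohort,
        curves=curves,
        measurements=measurements,
        otu_table=otu_table,
        hgm_experiment=experiment,
        hgm_mouse_table=mouse_table,
        hgm_d9_curves=d9_curves,
        truth=truth,
    )
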