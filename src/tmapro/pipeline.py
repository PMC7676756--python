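"""End-to-end orchestration of the analysis stages.

``run_pipeline`` ties phenotyping, bioavailability, community statistics,
the phenotype classifier and taxon discovery into one run over a fixture
directory, writing per-stage TSV/JSON artifacts plus a deterministic
machine-readable summary of every headline statistic.  ``analyze_study``
is the in-memory core shared by the CLI and by programmatic callers.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (
    OtuTable,
    alpha_diversity,
    bray_curtis,
    differential_abundance,
    pcoa,
    permanova,
    presence,
    rarefy,
)
from .discovery import (
    HgmExperiment,
    HgmGroup,
    candidate_taxa,
    combination_search,
    core_otus,
    d9_producer_call,
    diagnostic_metrics,
    producer_enriched_taxa,
)
from .io import (
    curves_from_measurements,
    read_hgm_dir,
    read_measurements,
    read_otu_table,
    write_distance_matrix,
)
from .model import ProducerPhenotypeModel
from .occt import (
    FASTING_THRESHOLD_UM,
    PLASMA_CUTOFF_UM,
    fasting_screen,
    phenotype_call,
    phenotype_shift_table,
    round_half_up_percent,
    urine_cutoff_from_regression,
)
from .renal import bioavailability_contrast, fractional_excretion

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StudyInputs", "analyze_study", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Pipeline thresholds, sizes and seeds (defaults follow the analysis)."""

    input_dir: str | Path | None = None
    output_dir: str | Path | None = None
    plasma_cutoff: float = PLASMA_CUTOFF_UM
    fasting_threshold: float = FASTING_THRESHOLD_UM
    fasting_flag_level: float = 10.0
    k_features: int = 39
    rarefaction_depth: int = 61_600
    min_total_count: int = 2
    fdr_threshold: float = 0.01
    n_permutations: int = 999
    n_trees: int = 500
    loocv_n_trees: int | None = None  # defaults to n_trees
    include_all_features_model: bool = False
    d9_lod: float = 0.05
    diagnostic_taxa: tuple[tuple[str, str], ...] = (
        ("E_timonensis", "s__timonensis"),
        ("I_massiliensis", "Ihubacter_massiliensis"),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plasma_cutoff", "fasting_threshold", "fasting_flag_level",
                     "rarefaction_depth", "fdr_threshold", "n_permutations", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class StudyInputs:
    """In-memory bundle of everything the pipeline consumes."""

    measurements: pd.DataFrame
    curves: list
    otu_table: OtuTable
    hgm_donors: dict
    hgm_mouse_table: OtuTable
    hgm_d9_curves: pd.DataFrame
    hgm_group_donors: dict | None = None

    @classmethod
    def from_synthetic(cls, study) -> "StudyInputs":
        return cls(
            measurements=study.measurements,
            curves=study.curves,
            otu_table=study.otu_table,
            hgm_donors=dict(study.hgm_experiment.donors),
            hgm_mouse_table=study.hgm_mouse_table,
            hgm_d9_curves=study.hgm_d9_curves,
            hgm_group_donors={g.name: g.donor_id for g in study.hgm_experiment.groups},
        )

    @classmethod
    def from_directory(cls, indir) -> "StudyInputs":
        indir = Path(indir)
        measurements = read_measurements(indir / "measurements.csv")
        curves = curves_from_measurements(measurements)
        table = read_otu_table(indir / "otu_table.tsv", indir / "sample_metadata.tsv")
        hgm = read_hgm_dir(indir / "hgm")
        return cls(
            measurements=measurements,
            curves=curves,
            otu_table=table,
            hgm_donors=hgm["donors"],
            hgm_mouse_table=hgm["mouse_table"],
            hgm_d9_curves=hgm["d9_curves"],
            hgm_group_donors=hgm["group_donors"],
        )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _phenotype_stage(inputs: StudyInputs, cfg: RunConfig) -> dict:
    plasma = [c for c in inputs.curves if c.fluid == "plasma"]
    urine = {(c.subject_id, c.phase): c for c in inputs.curves if c.fluid == "urine"}
    calls = {"pre_supplement": {}, "post_supplement": {}}
    records = []
    for curve in plasma:
        call = phenotype_call(curve, cutoff=cfg.plasma_cutoff)
        call = dataclasses.replace(call, cutoff_basis="plasma_10uM")
        calls[curve.phase][curve.subject_id] = call
        records.append(dataclasses.asdict(call))
    pre = {sid: c.phenotype for sid, c in calls["pre_supplement"].items()}
    post = {sid: c.phenotype for sid, c in calls["post_supplement"].items()}
    n = len(pre)
    n_high = sum(1 for v in pre.values() if v == "high")
    shift = phenotype_shift_table(pre, post)

    # paired plasma/urine maxima (pre phase) -> urine-scale cutoff
    pairs = []
    for sid, call in calls["pre_supplement"].items():
        ucurve = urine.get((sid, "pre_supplement"))
        if ucurve is not None:
            pairs.append((call.tmao_max, float(np.max(ucurve.tmao))))
    urine_cutoff = (
        urine_cutoff_from_regression(pairs, cfg.plasma_cutoff) if len(pairs) >= 3 else None
    )

    # fasting screens on plasma baselines
    fasting = {}
    for level, tag in ((cfg.fasting_threshold, "screen_6p2"), (cfg.fasting_flag_level, "flag_10")):
        for phase in ("pre_supplement", "post_supplement"):
            flags = {
                c.subject_id: fasting_screen(c.baseline_tmao, level)
                for c in plasma
                if c.phase == phase
            }
            fasting[f"{tag}_{phase}"] = flags

    return {
        "calls": calls,
        "table": pd.DataFrame(records),
        "n_subjects": n,
        "n_high_pre": n_high,
        "n_low_pre": n - n_high,
        "pct_high_pre": round_half_up_percent(n_high, n),
        "pct_low_pre": round_half_up_percent(n - n_high, n),
        "shift_table": shift,
        "urine_cutoff": urine_cutoff,
        "fasting": fasting,
        "pre_labels": pre,
        "post_labels": post,
    }


def _fasting_flag_counts(inputs: StudyInputs, pheno: dict) -> dict:
    """Omnivore fasting-TMAO flag proportions at the 10 uM level."""
    meta = inputs.otu_table.sample_metadata
    if meta is not None and "diet" in meta.columns:
        diets = meta.drop_duplicates("subject_id").set_index("subject_id")["diet"]
    else:
        diets = None
    out = {}
    for phase in ("pre_supplement", "post_supplement"):
        flags = pheno["fasting"][f"flag_10_{phase}"]
        if diets is not None:
            omn = [sid for sid in flags if diets.get(sid) == "omnivore"]
        else:
            omn = list(flags)
        hits = sum(flags[sid] for sid in omn)
        out[phase] = {
            "n_flagged": int(hits),
            "n_omnivores": len(omn),
            "pct": round_half_up_percent(hits, len(omn)) if omn else None,
        }
    return out


def _bioavailability_stage(inputs: StudyInputs, pheno: dict) -> dict:
    m = inputs.measurements
    fasting = m[(m.time_h == 0) & (m.fluid == "urine")]
    group_of = pheno["pre_labels"]
    rows = []
    for _, rec in fasting.iterrows():
        if rec.analyte not in ("carnitine", "tmao_fasting"):
            continue
        grp = group_of.get(rec.subject_id)
        if grp is None:
            continue
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": f"{grp}_producer",
                "phase": rec.phase,
                "analyte": "urine_tmao" if rec.analyte == "tmao_fasting" else "urine_carnitine",
                "value": rec.value,
            }
        )
    tidy = pd.DataFrame(rows)
    contrast = bioavailability_contrast(tidy) if len(tidy) else pd.DataFrame()

    # per-sample fractional excretion at baseline (pre phase)
    fe_rows = []
    base = m[m.time_h == 0]
    for (sid, phase), sub in base.groupby(["subject_id", "phase"]):
        try:
            p_tmao = float(sub[(sub.fluid == "plasma") & (sub.analyte == "tmao")]["value"].iloc[0])
            p_carn = float(sub[(sub.fluid == "plasma") & (sub.analyte == "carnitine")]["value"].iloc[0])
            p_cr = float(sub[(sub.fluid == "plasma") & (sub.analyte == "creatinine")]["value"].iloc[0])
            u_cr_mM = float(sub[(sub.fluid == "urine") & (sub.analyte == "creatinine")]["value"].iloc[0])
            u_tmao_mmolmol = float(sub[(sub.fluid == "urine") & (sub.analyte == "tmao")]["value"].iloc[0])
            u_carn_mmolmol = float(sub[(sub.fluid == "urine") & (sub.analyte == "carnitine")]["value"].iloc[0])
        except IndexError:
            continue
        u_cr_uM = 1000.0 * u_cr_mM
        u_tmao_uM = u_tmao_mmolmol * u_cr_mM  # mmol/mol * mM == uM
        u_carn_uM = u_carn_mmolmol * u_cr_mM
        if min(p_tmao, p_carn, p_cr, u_cr_uM) <= 0 or min(u_tmao_uM, u_carn_uM) <= 0:
            continue
        fe_rows.append(
            {
                "subject_id": sid,
                "phase": phase,
                "fe_tmao": fractional_excretion(u_tmao_uM, p_tmao, u_cr_uM, p_cr),
                "fe_carnitine": fractional_excretion(u_carn_uM, p_carn, u_cr_uM, p_cr),
            }
        )
    fe = pd.DataFrame(fe_rows)
    medians = {}
    if len(fe):
        pre = fe[fe.phase == "pre_supplement"]
        medians = {
            "median_fe_tmao_pre": float(pre["fe_tmao"].median()),
            "median_fe_carnitine_pre": float(pre["fe_carnitine"].median()),
        }
    return {"contrast": contrast, "fe": fe, **medians}


def _microbiome_stage(inputs: StudyInputs, cfg: RunConfig) -> dict:
    # rarefy to the fixed depth, then drop low-total (singleton) OTUs from
    # the final table; fixtures sampled at exactly the depth pass unchanged
    rare = rarefy(inputs.otu_table, depth=cfg.rarefaction_depth, seed=cfg.seed)
    rare = rare.filter_min_total(cfg.min_total_count)
    meta = rare.sample_metadata
    if meta is None or "producer_status" not in meta.columns:
        raise ValueError("OTU table metadata must carry 'producer_status'")
    status = meta["producer_status"]
    alpha = alpha_diversity(rare)
    dm = bray_curtis(rare)
    ordination = pcoa(dm)
    perm = permanova(dm, status, n_permutations=cfg.n_permutations, seed=cfg.seed)
    da = differential_abundance(rare, status, fdr_threshold=cfg.fdr_threshold)
    return {
        "table": rare,
        "alpha": alpha,
        "distance": dm,
        "pcoa": ordination,
        "permanova": perm,
        "differential": da,
        "status": status,
    }


def _diagnostics_stage(micro: dict, cfg: RunConfig) -> dict:
    rare: OtuTable = micro["table"]
    status = micro["status"]
    positive = (status == "high").to_numpy()
    taxa = {}
    for label, token in cfg.diagnostic_taxa:
        if rare.taxonomy is None:
            continue
        hits = rare.taxonomy[rare.taxonomy.fillna("").str.contains(token, regex=False)]
        if len(hits) == 1:
            taxa[label] = hits.index[0]
    results = {}
    pres = {}
    for label, otu in taxa.items():
        vec = presence(rare, otu).to_numpy()
        pres[label] = vec
        results[label] = diagnostic_metrics(vec, positive, rule=(label,))
    if len(pres) >= 2:
        labels = list(pres)
        union = np.logical_or.reduce([pres[l] for l in labels])
        results["combined"] = diagnostic_metrics(union, positive, rule=labels)
        matrix = pd.DataFrame(pres, index=rare.counts.index)
        combos = combination_search(labels, matrix, positive, criterion="accuracy")
    else:
        combos = pd.DataFrame()
    n_samples = len(positive)
    prevalence = {
        label: round(100.0 * float(pres[label].sum()) / n_samples, 1) for label in pres
    }
    return {"taxa": taxa, "results": results, "prevalence": prevalence, "combinations": combos}


def _model_stage(inputs: StudyInputs, micro: dict, cfg: RunConfig) -> dict:
    rare: OtuTable = micro["table"]
    status = micro["status"]
    # measured response: log10 urine TMAO_MAX of the matching subject-phase
    urine_max = {}
    for c in inputs.curves:
        if c.fluid == "urine":
            suffix = "pre" if c.phase == "pre_supplement" else "post"
            urine_max[f"{c.subject_id}_{suffix}"] = max(float(np.max(c.tmao)), 1e-3)
    meta = rare.sample_metadata
    response = pd.Series(
        {sid: np.log10(urine_max[sid]) for sid in rare.counts.index if sid in urine_max}
    )
    if len(response) != rare.n_samples:
        raise ValueError("urine TMAO_MAX response missing for some samples")
    labels = (status == "high").astype(int)
    model = ProducerPhenotypeModel.from_otu_table(
        rare, response, labels, k=cfg.k_features, n_trees=cfg.n_trees, seed=cfg.seed
    )
    results = model.fit()
    loocv = results.loocv_roc(n_trees=cfg.loocv_n_trees or cfg.n_trees)
    out = {
        "model": model,
        "results": results,
        "ranking": model.ranking_,
        "selected": model.feature_ids,
        "loocv": loocv,
    }
    if cfg.include_all_features_model:
        all_model = ProducerPhenotypeModel.from_otu_table(
            rare, response, labels, k=None, n_trees=cfg.n_trees, seed=cfg.seed
        )
        out["loocv_all_features"] = all_model.fit().loocv_roc(
            n_trees=cfg.loocv_n_trees or cfg.n_trees
        )
    return out


def _discovery_stage(inputs: StudyInputs, cfg: RunConfig) -> dict:
    d9 = inputs.hgm_d9_curves
    mouse_meta = inputs.hgm_mouse_table.sample_metadata
    groups = sorted(d9["group"].unique())
    producer_flags = {}
    mouse_calls = {}
    for g in groups:
        calls = {
            m: d9_producer_call(sub, lod=cfg.d9_lod)
            for m, sub in d9[d9.group == g].groupby("mouse_id")
        }
        mouse_calls[g] = calls
        producer_flags[g] = any(calls.values())

    presence_sets = {
        g: {
            m: frozenset(
                inputs.hgm_mouse_table.counts.columns[
                    inputs.hgm_mouse_table.counts.loc[m] > 0
                ]
            )
            for m in mouse_meta.index[mouse_meta.group == g]
        }
        for g in groups
    }
    group_donors = inputs.hgm_group_donors or {}
    hgm_groups = tuple(
        HgmGroup(
            name=g,
            donor_id=group_donors.get(g, g),
            producer=producer_flags[g],
            mice=presence_sets[g],
        )
        for g in groups
    )
    donors = dict(inputs.hgm_donors)
    for g in hgm_groups:  # tolerate fixtures without donor records for a group
        donors.setdefault(g.donor_id, frozenset().union(*g.mice.values()))
    experiment = HgmExperiment(groups=hgm_groups, donors=donors)

    producer_group = next(g for g in hgm_groups if g.producer)
    core = core_otus(producer_group)
    candidates = candidate_taxa(experiment)
    per_mouse_producer = pd.Series(
        {
            m: producer_flags[mouse_meta.loc[m, "group"]]
            for m in inputs.hgm_mouse_table.counts.index
        }
    )
    enriched = producer_enriched_taxa(
        inputs.hgm_mouse_table, per_mouse_producer, fdr_threshold=cfg.fdr_threshold
    )
    return {
        "experiment": experiment,
        "producer_group": producer_group.name,
        "n_producer_mice": int(sum(mouse_calls[producer_group.name].values())),
        "core": core,
        "donor_size": len(donors[producer_group.donor_id]),
        "candidates": sorted(candidates),
        "enriched_genera": enriched,
        "producer_flags": producer_flags,
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def analyze_study(inputs: StudyInputs, cfg: RunConfig | None = None) -> dict:
    """Run every stage in memory and return stage results plus the summary."""
    cfg = cfg or RunConfig()
    pheno = _phenotype_stage(inputs, cfg)
    flags = _fasting_flag_counts(inputs, pheno)
    bio = _bioavailability_stage(inputs, pheno)
    micro = _microbiome_stage(inputs, cfg)
    diag = _diagnostics_stage(micro, cfg)
    model = _model_stage(inputs, micro, cfg)
    disc = _discovery_stage(inputs, cfg)

    shift = pheno["shift_table"]
    summary = {
        "phenotype": {
            "n_subjects": pheno["n_subjects"],
            "n_high_pre": pheno["n_high_pre"],
            "n_low_pre": pheno["n_low_pre"],
            "pct_high_pre": pheno["pct_high_pre"],
            "pct_low_pre": pheno["pct_low_pre"],
            "low_to_high": int(shift.loc["low", "high"]),
            "high_to_low": int(shift.loc["high", "low"]),
            "urine_cutoff_mmol_per_mol": None
            if pheno["urine_cutoff"] is None
            else round(pheno["urine_cutoff"], 2),
            "fasting_flags_omnivores": {
                phase: flags[phase] for phase in flags
            },
        },
        "bioavailability": {
            k: round(v, 2)
            for k, v in bio.items()
            if k.startswith("median_fe")
        },
        "microbiome": {
            "n_samples": micro["table"].n_samples,
            "n_otus": micro["table"].n_otus,
            "mean_shannon": round(float(micro["alpha"]["shannon"].mean()), 3),
            "permanova_r2": round(micro["permanova"].r_squared, 4),
            "permanova_p": round(micro["permanova"].p_value, 4),
            "n_differential_otus": int(len(micro["differential"])),
        },
        "diagnostics": {
            label: res.as_dict() for label, res in diag["results"].items()
        },
        "prevalence_pct": diag["prevalence"],
        "model": {
            "n_selected_features": len(model["selected"]),
            "loocv_auroc": round(model["loocv"].auroc, 3),
            "loocv_optimal_cutoff": round(model["loocv"].optimal_cutoff, 3),
            **(
                {"loocv_auroc_all_features": round(model["loocv_all_features"].auroc, 3)}
                if "loocv_all_features" in model
                else {}
            ),
        },
        "hgm": {
            "producer_group": disc["producer_group"],
            "n_producer_mice": disc["n_producer_mice"],
            "donor_inventory_size": disc["donor_size"],
            "core_size": len(disc["core"]),
            "n_candidate_taxa": len(disc["candidates"]),
            "candidate_taxa": disc["candidates"],
            "n_enriched_genera": int(len(disc["enriched_genera"])),
            "enriched_genera": disc["enriched_genera"]["taxon"].tolist(),
        },
        "provenance": {
            "tmapro_version": __version__,
            "seed": cfg.seed,
            "config": {
                k: (str(v) if isinstance(v, (Path,)) else v)
                for k, v in dataclasses.asdict(cfg).items()
                if k not in ("input_dir", "output_dir")
            },
        },
    }
    return {
        "phenotype": pheno,
        "fasting_flags": flags,
        "bioavailability": bio,
        "microbiome": micro,
        "diagnostics": diag,
        "model": model,
        "discovery": disc,
        "summary": _jsonify(summary),
    }


def _jsonify(obj):
    """Recursively coerce numpy scalars so the summary serialises cleanly."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based run: validate, load, analyze, write artifacts and summary."""
    if cfg.input_dir is None or cfg.output_dir is None:
        raise ValueError("run_pipeline needs input_dir and output_dir")
    indir, outdir = Path(cfg.input_dir), Path(cfg.output_dir)
    report = validate_inputs(indir)
    failures = [r for r in report if not r["ok"]]
    if failures:
        raise ValueError(f"input validation failed: {failures[0]}")
    inputs = StudyInputs.from_directory(indir)
    results = analyze_study(inputs, cfg)
    outdir.mkdir(parents=True, exist_ok=True)

    results["phenotype"]["table"].to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    results["phenotype"]["shift_table"].to_csv(outdir / "phenotype_shifts.tsv", sep="\t")
    bio = results["bioavailability"]
    if len(bio["contrast"]):
        bio["contrast"].to_csv(outdir / "bioavailability_contrast.tsv", sep="\t", index=False)
    micro = results["microbiome"]
    micro["alpha"].to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    write_distance_matrix(micro["distance"], outdir / "bray_curtis.tsv")
    micro["pcoa"].samples.iloc[:, :2].to_csv(outdir / "pcoa_coordinates.tsv", sep="\t")
    micro["differential"].to_csv(outdir / "differential_abundance.tsv", sep="\t", index=False)
    model = results["model"]
    if model["ranking"] is not None:
        model["ranking"].to_csv(outdir / "feature_ranking.tsv", sep="\t", index=False)
    roc = model["loocv"]
    pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivities,
            "specificity": roc.specificities,
        }
    ).to_csv(outdir / "loocv_roc.tsv", sep="\t", index=False)
    diag = results["diagnostics"]
    if len(diag["combinations"]):
        out = diag["combinations"].copy()
        out["rule"] = out["rule"].map(lambda r: "|".join(r))
        out.to_csv(outdir / "diagnostic_combinations.tsv", sep="\t", index=False)
    disc = results["discovery"]
    pd.DataFrame({"otu_id": disc["candidates"]}).to_csv(
        outdir / "candidate_taxa.tsv", sep="\t", index=False
    )
    disc["enriched_genera"].to_csv(outdir / "enriched_genera.tsv", sep="\t", index=False)

    (outdir / "summary.json").write_text(
        json.dumps(results["summary"], indent=2, sort_keys=True) + "\n"
    )
    return results


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

_KNOWN_FLUIDS = {"plasma", "urine"}
_KNOWN_PHASES = {"pre_supplement", "post_supplement"}


def validate_inputs(indir, strict: bool = False) -> list[dict]:
    """Per-file schema report for a fixture directory; never mutates inputs."""
    indir = Path(indir)
    report = []

    def check(path, fn):
        entry = {"file": str(path), "ok": True, "issues": []}
        if not path.exists():
            entry["ok"] = False
            entry["issues"].append("missing file")
        else:
            try:
                entry["issues"] = fn(path)
                entry["ok"] = not entry["issues"]
            except Exception as exc:  # unreadable / malformed
                if strict:
                    raise
                entry["ok"] = False
                entry["issues"] = [f"unreadable: {exc}"]
        report.append(entry)

    def _measurements(path):
        df = read_measurements(path)
        issues = []
        bad_fluid = ~df["fluid"].isin(_KNOWN_FLUIDS)
        if bad_fluid.any():
            row = df.index[bad_fluid][0]
            issues.append(
                f"row {row}: unknown fluid {df.loc[row, 'fluid']!r} "
                f"(expected one of {sorted(_KNOWN_FLUIDS)})"
            )
        bad_phase = ~df["phase"].isin(_KNOWN_PHASES)
        if bad_phase.any():
            row = df.index[bad_phase][0]
            issues.append(
                f"row {row}: unknown phase {df.loc[row, 'phase']!r} "
                f"(expected one of {sorted(_KNOWN_PHASES)})"
            )
        neg = df["value"] < 0
        if neg.any():
            row = df.index[neg][0]
            issues.append(f"row {row}: negative value {df.loc[row, 'value']}")
        return issues

    def _otu(path):
        df = pd.read_csv(path, sep="\t", index_col=0)
        issues = []
        counts = df.drop(columns=["taxonomy"], errors="ignore")
        numeric = counts.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            col = numeric.columns[numeric.isna().any()][0]
            issues.append(f"non-numeric count in sample column {col!r}")
        elif (numeric < 0).any().any():
            col = numeric.columns[(numeric < 0).any()][0]
            row = numeric.index[(numeric[col] < 0)][0]
            issues.append(f"negative count at OTU {row!r}, sample {col!r}")
        if df.index.has_duplicates:
            issues.append("duplicate OTU ids")
        return issues

    def _mice(path):
        df = pd.read_csv(path, sep="\t")
        issues = []
        for col in ("group", "mouse_id", "otu_id", "count"):
            if col not in df.columns:
                issues.append(f"missing column {col!r}")
        if not issues and (df["count"] < 0).any():
            issues.append("negative mouse OTU count")
        return issues

    check(indir / "measurements.csv", _measurements)
    check(indir / "otu_table.tsv", _otu)
    check(indir / "hgm" / "mice.tsv", _mice)
    check(indir / "hgm" / "donors.tsv", lambda p: [] if len(pd.read_csv(p, sep="\t")) else ["empty donor table"])
    check(indir / "hgm" / "d9_curves.tsv", lambda p: [] if {"mouse_id", "time_h", "analyte", "value"}.issubset(pd.read_csv(p, sep="\t").columns) else ["missing d9 columns"])
    return report
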