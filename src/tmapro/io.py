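"""Readers and writers for the study's plain-text formats.

Measurements travel as one long-format CSV (subject_id, phase, fluid,
time_h, analyte, value, unit).  OTU tables are TSV with OTUs as rows,
samples as columns and a trailing ``taxonomy`` column; sample metadata is
a separate TSV.  The gnotobiotic-mouse experiment is a directory of TSVs
(donors, per-mouse OTU counts, taxonomy, d9 time courses).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .community import OtuTable
from .occt import OcctCurve

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "curves_from_measurements",
    "read_otu_table",
    "write_otu_table",
    "read_hgm_dir",
    "write_hgm_dir",
    "write_distance_matrix",
    "write_study",
]

MEASUREMENT_COLUMNS = ["subject_id", "phase", "fluid", "time_h", "analyte", "value", "unit"]


def write_measurements(measurements: pd.DataFrame, path) -> None:
    measurements[MEASUREMENT_COLUMNS].to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement file {path} lacks columns {missing}")
    return df


def curves_from_measurements(
    measurements: pd.DataFrame,
    required_times: tuple[float, ...] = (0.0, 24.0, 48.0),
    allow_partial: bool = False,
) -> list[OcctCurve]:
    """Assemble challenge curves from the long measurement table.

    Curves missing one of ``required_times`` are rejected unless
    ``allow_partial`` is set, in which case any curve with >= 2 timepoints
    (including baseline) is built with a warning.
    """
    curves = []
    tmao = measurements[measurements.analyte == "tmao"]
    carn = measurements[measurements.analyte == "carnitine"]
    for (sid, phase, fluid), sub in tmao.groupby(
        ["subject_id", "phase", "fluid"], sort=True
    ):
        sub = sub.sort_values("time_h")
        times = sub["time_h"].to_numpy(dtype=float)
        if set(required_times) - set(times):
            if not allow_partial:
                raise ValueError(
                    f"curve {sid}/{phase}/{fluid} is missing timepoints "
                    f"{sorted(set(required_times) - set(times))}; pass "
                    "allow_partial=True to accept incomplete curves"
                )
            warnings.warn(
                f"curve {sid}/{phase}/{fluid} uses {len(times)} available timepoints",
                stacklevel=2,
            )
        csub = carn[
            (carn.subject_id == sid) & (carn.phase == phase) & (carn.fluid == fluid)
        ].sort_values("time_h")
        carn_values = None
        if len(csub) == len(sub) and np.array_equal(
            csub["time_h"].to_numpy(dtype=float), times
        ):
            carn_values = csub["value"].to_numpy(dtype=float)
        curves.append(
            OcctCurve(
                subject_id=str(sid),
                fluid=str(fluid),
                timepoints=times,
                tmao=sub["value"].to_numpy(dtype=float),
                carnitine=carn_values,
                phase=str(phase),
            )
        )
    return curves


def write_otu_table(table: OtuTable, counts_path, metadata_path=None) -> None:
    """OTUs as rows, samples as columns, trailing taxonomy column."""
    out = table.counts.T.copy()
    out.index.name = "otu_id"
    out["taxonomy"] = (
        table.taxonomy.reindex(out.index) if table.taxonomy is not None else ""
    )
    out.to_csv(counts_path, sep="\t")
    if metadata_path is not None and table.sample_metadata is not None:
        meta = table.sample_metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def read_otu_table(counts_path, metadata_path=None) -> OtuTable:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    taxonomy = None
    if "taxonomy" in df.columns:
        taxonomy = df.pop("taxonomy").astype(str)
    meta = None
    if metadata_path is not None and Path(metadata_path).exists():
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return OtuTable(df.T, taxonomy=taxonomy, sample_metadata=meta)


def write_distance_matrix(dm, path) -> None:
    pd.DataFrame(np.asarray(dm.data), index=list(dm.ids), columns=list(dm.ids)).to_csv(
        path, sep="\t"
    )


# ---------------------------------------------------------------------------
# hGM experiment directory
# ---------------------------------------------------------------------------

def write_hgm_dir(
    donors: dict[str, frozenset],
    mouse_table: OtuTable,
    d9_curves: pd.DataFrame,
    outdir,
    group_donors: dict[str, str] | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    donor_rows = [
        {"donor_id": d, "otu_id": o} for d, inv in sorted(donors.items()) for o in sorted(inv)
    ]
    pd.DataFrame(donor_rows).to_csv(outdir / "donors.tsv", sep="\t", index=False)

    meta = mouse_table.sample_metadata
    rows = []
    for mouse in mouse_table.counts.index:
        group = meta.loc[mouse, "group"] if meta is not None else "unknown"
        row = mouse_table.counts.loc[mouse]
        for otu, count in row[row > 0].items():
            rows.append({"group": group, "mouse_id": mouse, "otu_id": otu, "count": int(count)})
    pd.DataFrame(rows).to_csv(outdir / "mice.tsv", sep="\t", index=False)

    if mouse_table.taxonomy is not None:
        tax = mouse_table.taxonomy.rename("taxonomy").to_frame()
        tax.index.name = "otu_id"
        tax.to_csv(outdir / "taxonomy.tsv", sep="\t")
    d9_curves.to_csv(outdir / "d9_curves.tsv", sep="\t", index=False)
    if group_donors:
        pd.DataFrame(
            [{"group": g, "donor_id": d} for g, d in sorted(group_donors.items())]
        ).to_csv(outdir / "groups.tsv", sep="\t", index=False)


def read_hgm_dir(indir) -> dict:
    """Raw hGM pieces: donor inventories, mouse count table, d9 curves.

    Producer status is not stored; the caller derives it from the d9 time
    courses.
    """
    indir = Path(indir)
    donors_df = pd.read_csv(indir / "donors.tsv", sep="\t")
    donors = {
        d: frozenset(sub["otu_id"]) for d, sub in donors_df.groupby("donor_id")
    }
    mice_df = pd.read_csv(indir / "mice.tsv", sep="\t")
    counts = mice_df.pivot_table(
        index="mouse_id", columns="otu_id", values="count", fill_value=0, aggfunc="sum"
    ).astype(np.int64)
    counts.columns.name = None
    groups = mice_df.drop_duplicates("mouse_id").set_index("mouse_id")["group"]
    taxonomy = None
    tax_path = indir / "taxonomy.tsv"
    if tax_path.exists():
        taxonomy = pd.read_csv(tax_path, sep="\t", index_col=0)["taxonomy"]
    meta = groups.loc[counts.index].rename("group").to_frame()
    mouse_table = OtuTable(counts, taxonomy=taxonomy, sample_metadata=meta)
    d9 = pd.read_csv(indir / "d9_curves.tsv", sep="\t")
    group_donors = None
    groups_path = indir / "groups.tsv"
    if groups_path.exists():
        gd = pd.read_csv(groups_path, sep="\t")
        group_donors = dict(zip(gd["group"], gd["donor_id"]))
    return {
        "donors": donors,
        "mouse_table": mouse_table,
        "d9_curves": d9,
        "group_donors": group_donors,
    }


def write_study(study, outdir) -> None:
    """Write a full synthetic-study fixture directory.

    Layout: measurements.csv, otu_table.tsv, sample_metadata.tsv, hgm/
    (donors.tsv, mice.tsv, taxonomy.tsv, d9_curves.tsv, groups.tsv),
    truth.json and generator_config.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_measurements(study.measurements, outdir / "measurements.csv")
    write_otu_table(
        study.otu_table, outdir / "otu_table.tsv", outdir / "sample_metadata.tsv"
    )
    group_donors = {g.name: g.donor_id for g in study.hgm_experiment.groups}
    write_hgm_dir(
        dict(study.hgm_experiment.donors),
        study.hgm_mouse_table,
        study.hgm_d9_curves,
        outdir / "hgm",
        group_donors=group_donors,
    )
    (outdir / "truth.json").write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    cfg = dataclasses.asdict(study.config)
    (outdir / "generator_config.json").write_text(
        json.dumps(cfg, indent=2, sort_keys=True, default=str)
    )
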