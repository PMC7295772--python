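"""CSV interchange and report writing.

CSV with a header row is the interchange format throughout (UTF-8, '.'
decimal separator).  Readers validate the declared schema strictly — a
missing mandatory column raises :class:`SchemaError` naming the column, and
invalid rows are reported with their line numbers — while unknown columns
are preserved untouched.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .biometry import FishRecord
from .detection import OocyteRecord
from .errors import SchemaError
from .histology import AtresiaSample, PofSample

OOCYTE_COLUMNS = [
    "fish_id", "micrograph_id", "diameter_um", "major_um", "minor_um",
    "area_um2", "roundness", "ellipticity", "mean_grey",
    "passed_filter", "rejection_reason",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing mandatory column(s): {', '.join(missing)}")


def read_biometry_csv(path: str | Path) -> list[FishRecord]:
    """Read a per-fish biometry table (fish_id, tl_cm, bw_g, ow_g)."""
    df = pd.read_csv(path)
    _require_columns(df, ["fish_id", "tl_cm", "bw_g", "ow_g"], "biometry CSV")
    records, problems = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                FishRecord(
                    fish_id=str(row["fish_id"]),
                    tl_cm=float(row["tl_cm"]),
                    bw_g=float(row["bw_g"]),
                    ow_g=float(row["ow_g"]),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise SchemaError("biometry CSV has invalid rows:\n" + "\n".join(problems))
    return records


def write_oocyte_csv(
    path: str | Path,
    per_micrograph: Sequence[tuple[str, str, Sequence[OocyteRecord]]],
) -> pd.DataFrame:
    """Write per-oocyte records as (fish_id, micrograph_id, records) groups."""
    rows = []
    for fish_id, micro_id, records in per_micrograph:
        for r in records:
            rows.append(
                {
                    "fish_id": fish_id,
                    "micrograph_id": micro_id,
                    "diameter_um": r.diameter_um,
                    "major_um": r.major_um,
                    "minor_um": r.minor_um,
                    "area_um2": r.area_um2,
                    "roundness": r.roundness,
                    "ellipticity": r.ellipticity,
                    "mean_grey": r.mean_grey,
                    "passed_filter": r.passed_filter,
                    "rejection_reason": r.rejection_reason,
                }
            )
    df = pd.DataFrame(rows, columns=OOCYTE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_oocyte_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-oocyte CSV as written by :func:`write_oocyte_csv`."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["fish_id", "diameter_um", "passed_filter"], "oocyte CSV"
    )
    bad = df.index[df["diameter_um"] <= 0].tolist()
    if bad:
        lines = ", ".join(str(i + 2) for i in bad)
        raise SchemaError(f"oocyte CSV has non-positive diameters on line(s) {lines}")
    return df


def read_atresia_csv(path: str | Path) -> list[AtresiaSample]:
    """Read atresia counts (fish_id, n_alpha, n_normal [, n_ea, n_larc, n_lanc])."""
    df = pd.read_csv(path)
    _require_columns(df, ["fish_id", "n_alpha", "n_normal"], "atresia CSV")
    out, problems = [], []
    for i, row in df.iterrows():
        try:
            subs = {
                k: (int(row[k]) if k in df.columns and pd.notna(row[k]) else None)
                for k in ("n_ea", "n_larc", "n_lanc")
            }
            out.append(
                AtresiaSample(
                    fish_id=str(row["fish_id"]),
                    n_alpha=int(row["n_alpha"]),
                    n_normal=int(row["n_normal"]),
                    **subs,
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {i + 2}: {exc}")
    if problems:
        raise SchemaError("atresia CSV has invalid rows:\n" + "\n".join(problems))
    return out


def read_pof_csv(
    fields_path: str | Path, areas_path: str | Path | None = None
) -> list[PofSample]:
    """Read POF stereology tables.

    ``fields_path``: one row per counting field (fish_id, points_on_pof,
    pof_profiles [, field_area_mm2, grid_points, ow_g, bw_g]).
    ``areas_path``: one row per measured POF profile (fish_id, area_mm2).
    """
    fdf = pd.read_csv(fields_path)
    _require_columns(fdf, ["fish_id", "points_on_pof", "pof_profiles"], "POF fields CSV")
    areas: dict[str, list[float]] = {}
    if areas_path is not None:
        adf = pd.read_csv(areas_path)
        _require_columns(adf, ["fish_id", "area_mm2"], "POF areas CSV")
        for fid, grp in adf.groupby("fish_id"):
            areas[str(fid)] = [float(a) for a in grp["area_mm2"]]
    samples = []
    for fid, grp in fdf.groupby("fish_id", sort=False):
        first = grp.iloc[0]
        samples.append(
            PofSample(
                fish_id=str(fid),
                points_on_pof=tuple(int(p) for p in grp["points_on_pof"]),
                pof_profiles=tuple(int(p) for p in grp["pof_profiles"]),
                pof_areas_mm2=tuple(areas.get(str(fid), ())),
                n_fields=len(grp),
                field_area_mm2=float(first.get("field_area_mm2", 6.0)),
                grid_points=int(first.get("grid_points", 256)),
                ow_g=float(first.get("ow_g", 0.0)),
                bw_g=float(first.get("bw_g", 0.0)),
            )
        )
    return samples


def write_study_csvs(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study bundle as the standard CSV layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["biometry"] = out / "biometry.csv"
    study.biometry_frame.to_csv(paths["biometry"], index=False)

    paths["truth"] = out / "ground_truth.csv"
    study.truth_frame.to_csv(paths["truth"], index=False)

    rows = []
    for f in study.fish:
        for d, lab in zip(f.cohort.diameters_um, f.cohort.labels):
            rows.append(
                {
                    "fish_id": f.fish_id,
                    "micrograph_id": "sim",
                    "diameter_um": d,
                    "true_class": lab,
                    "passed_filter": True,
                }
            )
    paths["diameters"] = out / "oocyte_diameters.csv"
    pd.DataFrame(rows).to_csv(paths["diameters"], index=False)

    paths["atresia"] = out / "atresia.csv"
    pd.DataFrame(
        [
            {"fish_id": f.fish_id, "n_alpha": f.atresia.n_alpha,
             "n_normal": f.atresia.n_normal}
            for f in study.fish
        ]
    ).to_csv(paths["atresia"], index=False)

    field_rows, area_rows = [], []
    for f in study.fish:
        for pts, prof in zip(f.pof.points_on_pof, f.pof.pof_profiles):
            field_rows.append(
                {"fish_id": f.fish_id, "points_on_pof": pts, "pof_profiles": prof,
                 "field_area_mm2": f.pof.field_area_mm2,
                 "grid_points": f.pof.grid_points,
                 "ow_g": f.pof.ow_g, "bw_g": f.pof.bw_g}
            )
        for a in f.pof.pof_areas_mm2:
            area_rows.append({"fish_id": f.fish_id, "area_mm2": a})
    paths["pof_fields"] = out / "pof_fields.csv"
    pd.DataFrame(field_rows).to_csv(paths["pof_fields"], index=False)
    paths["pof_areas"] = out / "pof_areas.csv"
    pd.DataFrame(area_rows, columns=["fish_id", "area_mm2"]).to_csv(
        paths["pof_areas"], index=False
    )
    return paths
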