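"""Per-category summaries and OSFD profile figures."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .osfd import OSFD, smooth_osfd


def orc_summary(df: pd.DataFrame, metric: str, group_col: str = "orc") -> pd.DataFrame:
    """Tukey-style per-category summary: median and the 25/75% hinges."""
    if metric not in df.columns or group_col not in df.columns:
        raise KeyError(f"need columns {metric!r} and {group_col!r}")
    rows = []
    for orc, sub in df.groupby(group_col):
        v = sub[metric].dropna()
        rows.append(
            {
                group_col: orc,
                "n": len(v),
                "median": v.quantile(0.5),
                "lower_hinge": v.quantile(0.25),
                "upper_hinge": v.quantile(0.75),
            }
        )
    return pd.DataFrame(rows)


def pof_orc_summary(metrics_df: pd.DataFrame, group_col: str = "orc") -> pd.DataFrame:
    """Per-category POF summary: median size, relative fecundity, and the
    proportion of recent spawners at the 0.10 / 0.11 mm^2 size thresholds."""
    rows = []
    for orc, sub in metrics_df.groupby(group_col):
        xsa = sub["pof_xsa_mm2"].dropna()
        rows.append(
            {
                group_col: orc,
                "n": len(sub),
                "median_pof_xsa_mm2": xsa.median() if len(xsa) else np.nan,
                "median_rf_pof": sub["rf_pof"].median(),
                "prop_pof_xsa_gt_010": float((xsa > 0.10).mean()) if len(xsa) else 0.0,
                "prop_pof_xsa_gt_011": float((xsa > 0.11).mean()) if len(xsa) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def plot_osfd_profiles(
    osfds: Sequence[OSFD],
    orcs: Mapping[str, int],
    path: str | Path,
    fom_onset_um: float = 875.0,
) -> None:
    """Ridge-style smoothed OSFD profiles, ordered by category then by the
    largest oocyte present; the dashed line marks approximate hydration
    onset (annotation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = sorted(
        osfds, key=lambda o: (orcs.get(o.fish_id, 0), float(o.diameters_um.max()))
    )
    fig, ax = plt.subplots(figsize=(7, max(3, 0.4 * len(ordered))))
    for i, o in enumerate(ordered):
        if o.density is None:
            smooth_osfd(o)
        dens = o.density / o.density.max()
        ax.fill_between(o.grid_um, i, i + 0.9 * dens, alpha=0.7, lw=0.5)
        ax.text(o.grid_um[-1], i + 0.2, f"{o.fish_id} (ORC {orcs.get(o.fish_id, '?')})",
                fontsize=6, ha="right")
    ax.axvline(fom_onset_um, ls="--", color="grey", lw=0.8)
    ax.set_xlabel("oocyte diameter (µm)")
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
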