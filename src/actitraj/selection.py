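"""Sweep over class counts and apply the profile-count selection rule."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lclmm import LclmmFit, LclmmSpec, fit

TABLE_COLUMNS = [
    "G", "aic", "bic", "lowest_mean_posterior", "entropy",
    "min_class_share", "converged", "best_start",
]


@dataclass
class FitTable:
    table: pd.DataFrame
    fits: dict[int, LclmmFit]


def sweep(data: pd.DataFrame, base_spec: LclmmSpec, G_list: list[int]) -> FitTable:
    """Fit one model per requested class count under a shared seed protocol.

    Non-convergence is recorded in the table, not raised.
    """
    rows = []
    fits: dict[int, LclmmFit] = {}
    for G in G_list:
        spec = replace(base_spec, n_classes=G)
        try:
            result = fit(spec, data)
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            rows.append(
                {
                    "G": G, "aic": np.nan, "bic": np.nan,
                    "lowest_mean_posterior": np.nan, "entropy": np.nan,
                    "min_class_share": np.nan, "converged": False,
                    "best_start": -1, "error": str(exc),
                }
            )
            continue
        fits[G] = result
        shares = result.class_sizes / len(result.subject_ids)
        rows.append(
            {
                "G": G,
                "aic": result.aic,
                "bic": result.bic,
                "lowest_mean_posterior": result.lowest_mean_posterior,
                "entropy": result.entropy,
                "min_class_share": float(shares.min()),
                "converged": result.converged,
                "best_start": result.best_start,
                "error": "",
            }
        )
    return FitTable(table=pd.DataFrame(rows), fits=fits)


def select(table: pd.DataFrame, min_class_share: float = 0.05) -> dict:
    """Choose the class count from a fit-index table.

    Among converged rows meeting the minimum-class-size floor, prefer the
    highest lowest-mean-posterior, then the highest entropy; ties go to the
    smaller class count (parsimony).  AIC/BIC are reported in the rationale
    but are not dispositive.  Substantive meaningfulness of the profiles is
    a human judgement; candidates are only flagged here.
    """
    converged = table[table["converged"].astype(bool)].copy()
    if converged.empty:
        raise ValueError("no converged fits to select from")
    # the single-class fit is a reference only: its posterior and entropy are
    # 1 by definition, so it never competes on these criteria
    if (converged["G"] >= 2).any():
        converged = converged[converged["G"] >= 2]
    eligible = converged
    if "min_class_share" in converged.columns:
        share = converged["min_class_share"]
        eligible = converged[share.isna() | (share >= min_class_share)]
        if eligible.empty:
            eligible = converged
    ranked = eligible.sort_values(
        by=["lowest_mean_posterior", "entropy", "G"],
        ascending=[False, False, True],
        kind="stable",
    )
    chosen = int(ranked.iloc[0]["G"])
    rationale = {
        "chosen_G": chosen,
        "rule": "max lowest_mean_posterior, then max entropy, then smallest G",
        "min_class_share_floor": min_class_share,
        "candidates": table[[c for c in TABLE_COLUMNS if c in table.columns]]
        .to_dict(orient="records"),
        "aic_argmin": int(converged.loc[converged["aic"].idxmin(), "G"])
        if converged["aic"].notna().any() else None,
        "bic_argmin": int(converged.loc[converged["bic"].idxmin(), "G"])
        if converged["bic"].notna().any() else None,
        "note": "AIC/BIC reported but not dispositive; profile meaningfulness "
                "requires human review of the trajectory tables",
    }
    return rationale


def write_selection(rationale: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(rationale, indent=2, sort_keys=True))
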