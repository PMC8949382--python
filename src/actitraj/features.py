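"""Per-wave time-use feature vectors, pooled z-scoring and collinearity pruning.

Fifteen features per participant-wave: mean and between-day SD of daily
sedentary/light/moderate-to-vigorous minutes, daily means of bout minutes
and bout counts for sedentary and moderate-to-vigorous behaviour, daily mean
total counts and steps, and the three isometric log-ratio pivot coordinates
of the mean three-part time-use composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .processing import WAVE_KEY

FEATURE_NAMES = [
    "mean_sb", "mean_lipa", "mean_mvpa",
    "sd_sb", "sd_lipa", "sd_mvpa",
    "sb_bout_minutes", "mvpa_bout_minutes",
    "sb_bout_count", "mvpa_bout_count",
    "total_counts", "steps",
    "ilr_sb", "ilr_lipa", "ilr_mvpa",
]

#: features kept under the "preset" pruning policy (the complement of the
#: ten features excluded for multicollinearity in the reproduction target)
PRESET_RETAINED = ["mean_sb", "mean_lipa", "mean_mvpa", "sd_mvpa", "ilr_sb"]

ZERO_REPLACEMENT = 0.5  # min/day substituted for zero composition parts


def ilr_coordinates(sb, lipa, mvpa, zero_replacement: float = ZERO_REPLACEMENT):
    """Pivot coordinates of a 3-part composition.

    For each part x with remaining parts y, z the coordinate is
    ``sqrt(2/3) * ln(x / sqrt(y*z))``; the three coordinates sum to zero and
    are invariant to rescaling all parts.  Zero parts are replaced by
    ``zero_replacement`` (flagged via the fourth return element); negative
    parts are rejected.
    """
    parts = np.asarray([sb, lipa, mvpa], dtype=float)
    if (parts < 0).any():
        raise ValueError("composition parts must be non-negative")
    replaced = bool((parts == 0).any())
    parts = np.where(parts == 0, zero_replacement, parts)
    logs = np.log(parts)
    # sqrt(2/3)*(ln x - (ln y + ln z)/2) == sqrt(3/2)*(ln x - mean(ln))
    coords = np.sqrt(1.5) * (logs - logs.mean())
    return float(coords[0]), float(coords[1]), float(coords[2]), replaced


def build_feature_vectors(valid_days: pd.DataFrame) -> pd.DataFrame:
    """One 15-feature row per participant-wave from its valid-day summaries.

    SDs use the n-1 formula; bout totals and counts enter as per-day means
    so waves with different day counts are comparable.
    """
    rows = []
    for (pid, wave), grp in valid_days.groupby(WAVE_KEY, sort=True):
        mean_sb = float(grp["sb_minutes"].mean())
        mean_lipa = float(grp["lipa_minutes"].mean())
        mean_mvpa = float(grp["mvpa_minutes"].mean())
        ilr_sb, ilr_lipa, ilr_mvpa, replaced = ilr_coordinates(mean_sb, mean_lipa, mean_mvpa)
        rows.append(
            {
                "participant_id": pid,
                "wave_month": wave,
                "n_valid_days": len(grp),
                "mean_wear": float(grp["wear_minutes"].mean()),
                "mean_sb": mean_sb,
                "mean_lipa": mean_lipa,
                "mean_mvpa": mean_mvpa,
                "sd_sb": float(grp["sb_minutes"].std(ddof=1)),
                "sd_lipa": float(grp["lipa_minutes"].std(ddof=1)),
                "sd_mvpa": float(grp["mvpa_minutes"].std(ddof=1)),
                "sb_bout_minutes": float(grp["sb_bout_minutes"].mean()),
                "mvpa_bout_minutes": float(grp["mvpa_bout_minutes"].mean()),
                "sb_bout_count": float(grp["sb_bout_count"].mean()),
                "mvpa_bout_count": float(grp["mvpa_bout_count"].mean()),
                "total_counts": float(grp["total_counts"].mean()),
                "steps": float(grp["total_steps"].mean()),
                "ilr_sb": ilr_sb,
                "ilr_lipa": ilr_lipa,
                "ilr_mvpa": ilr_mvpa,
                "ilr_zero_replaced": replaced,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StandardizedPanel:
    """z-scored feature panel plus the pooled scaling constants."""

    z: pd.DataFrame
    means: pd.Series
    sds: pd.Series

    def inverse_transform(self, z: pd.DataFrame) -> pd.DataFrame:
        return z * self.sds[z.columns] + self.means[z.columns]


def standardize(panel: pd.DataFrame, features: list[str] | None = None) -> StandardizedPanel:
    """Pool all participant-waves and z-score each feature (single mean/SD).

    Rejects constant features by name; SD uses the n-1 formula.
    """
    features = features or [f for f in FEATURE_NAMES if f in panel.columns]
    if len(panel) < 2:
        raise ValueError("standardize needs at least two participant-waves")
    values = panel[features].astype(float)
    means = values.mean()
    sds = values.std(ddof=1)
    dead = sds.index[(sds == 0) | sds.isna()].tolist()
    if dead:
        raise ValueError(f"zero-variance feature(s): {dead}")
    z = (values - means) / sds
    keep = [c for c in ("participant_id", "wave_month") if c in panel.columns]
    z = pd.concat([panel[keep].reset_index(drop=True), z.reset_index(drop=True)], axis=1)
    return StandardizedPanel(z=z, means=means, sds=sds)


@dataclass
class PruningReport:
    correlations: pd.DataFrame
    threshold: float
    policy: str
    excluded: list[str]
    retained: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "policy": self.policy,
            "threshold": self.threshold,
            "excluded": self.excluded,
            "retained": self.retained,
            "correlations": self.correlations.round(6).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def prune_collinear(
    panel: pd.DataFrame, threshold: float = 0.9, policy: str = "greedy"
) -> PruningReport:
    """Drop collinear features by Spearman correlation.

    ``policy="greedy"``: while any retained pair has |rho| >= threshold,
    drop the member of the worst pair with the larger mean absolute
    correlation to the other retained features (ties: the later feature in
    the canonical ordering).  ``policy="preset"``: keep exactly
    :data:`PRESET_RETAINED`, the reproduction default.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    missing = [f for f in FEATURE_NAMES if f not in panel.columns]
    if missing:
        raise ValueError(f"panel missing features: {missing}")
    values = panel[FEATURE_NAMES].to_numpy(dtype=float)
    rho = stats.spearmanr(values).statistic
    rho = np.atleast_2d(rho)
    np.fill_diagonal(rho, 1.0)
    corr = pd.DataFrame(rho, index=FEATURE_NAMES, columns=FEATURE_NAMES)

    if policy == "preset":
        retained = list(PRESET_RETAINED)
        excluded = [f for f in FEATURE_NAMES if f not in retained]
    elif policy == "greedy":
        retained = list(FEATURE_NAMES)
        excluded = []
        while True:
            sub = corr.loc[retained, retained].abs().to_numpy()
            np.fill_diagonal(sub, 0.0)
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            if sub[i, j] < threshold:
                break
            burden_i = sub[i].mean()
            burden_j = sub[j].mean()
            if burden_i > burden_j:
                drop = retained[i]
            elif burden_j > burden_i:
                drop = retained[j]
            else:  # tie: drop the later feature in canonical order
                drop = retained[max(i, j)]
            retained.remove(drop)
            excluded.append(drop)
    else:
        raise ValueError(f"unknown pruning policy: {policy!r}")
    return PruningReport(
        correlations=corr, threshold=threshold, policy=policy,
        excluded=excluded, retained=retained,
    )
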