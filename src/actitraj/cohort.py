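"""Seeded synthetic cohort generation.

Builds minute-epoch accelerometer streams with known class structure so the
whole pipeline can be exercised against ground truth: each participant
belongs to a latent class whose per-wave daily targets for sedentary, light
and moderate-to-vigorous minutes drive a semi-Markov state process; counts
are drawn inside disjoint cut-point ranges so processing recovers the state;
days carry a nocturnal non-wear block and optional long daytime non-wear
insertions; baseline covariates are drawn from class-specific distributions.

Count magnitudes within a state are conventions (the cut-point ranges are
what matters downstream): sedentary minutes are 0 with probability
``P_ZERO_SB`` else uniform on [1, 99], light uniform on [100, 1951],
moderate-to-vigorous uniform on [1952, 5724].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .processing import ProcessingRules

DAY_MINUTES = 1440
#: nominal waking wear window used to validate behaviour targets (minutes)
WEAR_WINDOW = 840
P_ZERO_SB = 0.35
SB_DWELL, LIPA_DWELL = 20.0, 6.0
NOCTURNAL_RANGE = (480, 660)
INSERTION_RANGE = (90, 150)
#: wear minutes forced non-zero at each wear/non-wear boundary so that short
#: sedentary zero runs cannot be absorbed into an adjacent non-wear block
GUARD_MINUTES = 3


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int
    class_proportions: tuple[float, ...]
    waves: tuple[int, ...] = (0, 6, 12, 18, 24)
    wave_missingness_prob: float = 0.1
    days_per_wave: tuple[int, int] = (3, 7)
    epoch_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        props = np.asarray(self.class_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12 or (props < 0).any():
            raise ValueError("class_proportions must be non-negative and sum to 1")
        if list(self.waves) != sorted(set(self.waves)):
            raise ValueError("waves must be strictly increasing")
        if not (0 <= self.wave_missingness_prob < 1):
            raise ValueError("wave_missingness_prob must be in [0, 1)")
        lo, hi = self.days_per_wave
        if not (1 <= lo <= hi):
            raise ValueError("days_per_wave range invalid")
        if self.epoch_length != 60:
            raise ValueError("only 60 s epochs are supported")


@dataclass(frozen=True)
class WaveTargets:
    """Target mean daily minutes per behaviour and their between-day SDs."""

    sb: float
    lipa: float
    mvpa: float
    sb_sd: float = 20.0
    lipa_sd: float = 12.0
    mvpa_sd: float = 4.0

    def __post_init__(self) -> None:
        if min(self.sb, self.lipa, self.mvpa) < 0:
            raise ValueError("behaviour targets must be non-negative")


@dataclass(frozen=True)
class ClassProfileSpec:
    name: str
    wave_targets: tuple[WaveTargets, ...]
    nonwear_rate: float = 0.25
    mvpa_bout_propensity: float = 0.5
    steps_per_mvpa_min: float = 110.0
    steps_per_lipa_min: float = 35.0
    age_mean: float = 64.0
    age_sd: float = 7.5
    prop_female: float = 0.4
    bmi_mean: float = 30.0
    bmi_sd: float = 4.5
    p_hypertension: float = 0.75
    p_copd: float = 0.10
    p_other_disease: float = 0.19
    rand_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not (0 <= self.mvpa_bout_propensity <= 1):
            raise ValueError("mvpa_bout_propensity must be in [0, 1]")
        if abs(sum(self.rand_probs) - 1.0) > 1e-9:
            raise ValueError("rand_probs must sum to 1")


@dataclass
class GroundTruth:
    """True class labels and the class-wave behaviour means behind each wave."""

    labels: pd.DataFrame        # participant_id, true_class (1-based)
    wave_means: pd.DataFrame    # participant_id, wave_month, true_sb/lipa/mvpa


def _check_feasible(profiles: list[ClassProfileSpec], waves: tuple[int, ...]) -> None:
    for g, prof in enumerate(profiles, start=1):
        if len(prof.wave_targets) != len(waves):
            raise ValueError(f"class {g} ({prof.name}): needs one target set per wave")
        for wave, t in zip(waves, prof.wave_targets):
            total = t.sb + t.lipa + t.mvpa
            if total > WEAR_WINDOW:
                raise ValueError(
                    f"infeasible targets for class {g} ({prof.name}) at wave {wave}: "
                    f"SB+LIPA+MVPA = {total:.0f} min exceeds the {WEAR_WINDOW} min wear window"
                )


def _state_runs(quotas: dict[str, int], dwell: dict[str, float], rng: np.random.Generator) -> list[tuple[str, int]]:
    """Split each state's minute quota into geometric-dwell runs, then shuffle."""
    runs: list[tuple[str, int]] = []
    for state, quota in quotas.items():
        remaining = quota
        p = min(1.0, 1.0 / max(dwell[state], 1.0))
        while remaining > 0:
            length = min(int(rng.geometric(p)), remaining)
            runs.append((state, length))
            remaining -= length
    order = rng.permutation(len(runs))
    return [runs[i] for i in order]


def _draw_counts(state: str, n: int, rng: np.random.Generator) -> np.ndarray:
    if state == "SB":
        counts = rng.integers(1, 100, size=n)
        counts[rng.random(n) < P_ZERO_SB] = 0
        return counts
    if state == "LIPA":
        return rng.integers(100, 1952, size=n)
    return rng.integers(1952, 5725, size=n)


def _draw_steps(state: str, n: int, prof: ClassProfileSpec, rng: np.random.Generator) -> np.ndarray:
    if state == "SB":
        return np.zeros(n, dtype=int)
    rate = prof.steps_per_lipa_min if state == "LIPA" else prof.steps_per_mvpa_min
    return rng.poisson(rate, size=n)


def _generate_day(prof: ClassProfileSpec, targets: WaveTargets, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One 1440-minute day of (counts, steps) for a class-wave."""
    quotas = {}
    for state, mean, sd in (
        ("SB", targets.sb, targets.sb_sd),
        ("LIPA", targets.lipa, targets.lipa_sd),
        ("MVPA", targets.mvpa, targets.mvpa_sd),
    ):
        quotas[state] = 0 if mean == 0 else max(0, int(round(rng.normal(mean, sd))))
    wear = sum(quotas.values())

    n_ins = rng.poisson(prof.nonwear_rate)
    ins_lengths = [int(rng.integers(*INSERTION_RANGE)) for _ in range(n_ins)]
    nocturnal = DAY_MINUTES - wear - sum(ins_lengths)
    while ins_lengths and nocturnal < NOCTURNAL_RANGE[0]:
        nocturnal += ins_lengths.pop()
    if nocturnal < ProcessingRules().nonwear_window:
        raise ValueError("behaviour targets leave no room for a nocturnal non-wear block")

    mvpa_dwell = 3.0 + 12.0 * prof.mvpa_bout_propensity
    dwell = {"SB": SB_DWELL, "LIPA": LIPA_DWELL, "MVPA": mvpa_dwell}
    runs = _state_runs(quotas, dwell, rng)
    segments: list[tuple[str, int]] = [("NW", nocturnal)]
    if runs and ins_lengths:
        # scatter daytime insertions between wear runs
        positions = sorted(rng.integers(1, len(runs) + 1, size=len(ins_lengths)), reverse=True)
        for pos, length in zip(positions, ins_lengths):
            runs.insert(pos, ("NW", length))
    segments.extend(runs)

    counts = np.zeros(DAY_MINUTES, dtype=int)
    steps = np.zeros(DAY_MINUTES, dtype=int)
    cursor = 0
    for state, length in segments:
        if state != "NW":
            counts[cursor:cursor + length] = _draw_counts(state, length, rng)
            steps[cursor:cursor + length] = _draw_steps(state, length, prof, rng)
        cursor += length
    assert cursor == DAY_MINUTES

    # guard wear minutes at wear/non-wear boundaries: zero sedentary minutes
    # there would otherwise be absorbed into the adjacent non-wear run
    boundary = 0
    for state, length in segments:
        if state == "NW":
            for k in range(max(0, boundary - GUARD_MINUTES), boundary):
                if counts[k] == 0 and _was_wear(segments, k):
                    counts[k] = int(rng.integers(1, 100))
            stop = min(DAY_MINUTES, boundary + length + GUARD_MINUTES)
            for k in range(boundary + length, stop):
                if counts[k] == 0 and _was_wear(segments, k):
                    counts[k] = int(rng.integers(1, 100))
        boundary += length
    return counts, steps


def _was_wear(segments: list[tuple[str, int]], minute: int) -> bool:
    cursor = 0
    for state, length in segments:
        if cursor <= minute < cursor + length:
            return state != "NW"
        cursor += length
    return False


def generate_cohort(
    spec: CohortSpec, profiles: list[ClassProfileSpec]
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (epoch table, covariate table, ground truth) for one cohort."""
    if len(profiles) != len(spec.class_proportions):
        raise ValueError("need one profile per class proportion")
    _check_feasible(profiles, spec.waves)
    rng = np.random.default_rng(spec.seed)
    rand_levels = ("multi", "single", "control")

    epoch_frames = []
    cov_rows = []
    label_rows = []
    mean_rows = []
    for pid in range(1, spec.n_participants + 1):
        g = int(rng.choice(len(profiles), p=spec.class_proportions))
        prof = profiles[g]
        label_rows.append({"participant_id": pid, "true_class": g + 1})
        cov_rows.append(
            {
                "participant_id": pid,
                "age": round(float(rng.normal(prof.age_mean, prof.age_sd)), 1),
                "gender": "F" if rng.random() < prof.prop_female else "M",
                "bmi": round(float(rng.normal(prof.bmi_mean, prof.bmi_sd)), 1),
                "randomisation": rand_levels[int(rng.choice(3, p=prof.rand_probs))],
                "hypertension": int(rng.random() < prof.p_hypertension),
                "copd": int(rng.random() < prof.p_copd),
                "other_disease": int(rng.random() < prof.p_other_disease),
            }
        )
        present = rng.random(len(spec.waves)) >= spec.wave_missingness_prob
        if not present.any():
            present[rng.integers(len(spec.waves))] = True
        for w_idx, wave in enumerate(spec.waves):
            if not present[w_idx]:
                continue
            targets = prof.wave_targets[w_idx]
            mean_rows.append(
                {
                    "participant_id": pid,
                    "wave_month": wave,
                    "true_sb": targets.sb,
                    "true_lipa": targets.lipa,
                    "true_mvpa": targets.mvpa,
                }
            )
            n_days = int(rng.integers(spec.days_per_wave[0], spec.days_per_wave[1] + 1))
            for day in range(1, n_days + 1):
                counts, steps = _generate_day(prof, targets, rng)
                epoch_frames.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "wave_month": wave,
                            "day_index": day,
                            "epoch_index": np.arange(DAY_MINUTES),
                            "counts": counts,
                            "steps": steps,
                        }
                    )
                )
    epochs = pd.concat(epoch_frames, ignore_index=True)
    covariates = pd.DataFrame(cov_rows)
    truth = GroundTruth(labels=pd.DataFrame(label_rows), wave_means=pd.DataFrame(mean_rows))
    return epochs, covariates, truth


# ---------------------------------------------------------------------------
# presets with known separation structure

def _flat_profile(name: str = "flat", **kw) -> ClassProfileSpec:
    targets = tuple(WaveTargets(sb=640, lipa=180, mvpa=20, mvpa_sd=7.0) for _ in range(5))
    defaults = dict(age_mean=67.0, age_sd=6.0, mvpa_bout_propensity=0.3)
    defaults.update(kw)
    return ClassProfileSpec(name=name, wave_targets=targets, **defaults)


def _increasing_profile(name: str = "increasing", **kw) -> ClassProfileSpec:
    # baseline near the flat class, then diverging: the separation is in the
    # trajectory; baseline guideline achievement overlaps between classes
    mvpa = (24.0, 32.0, 40.0, 47.5, 55.0)
    sb = (620.0, 598.0, 575.0, 553.0, 530.0)
    targets = tuple(WaveTargets(sb=s, lipa=195.0, mvpa=m, mvpa_sd=7.0) for s, m in zip(sb, mvpa))
    defaults = dict(age_mean=59.0, age_sd=6.0, mvpa_bout_propensity=0.8)
    defaults.update(kw)
    return ClassProfileSpec(name=name, wave_targets=targets, **defaults)


def high_separation_preset(n: int = 200, seed: int = 1) -> tuple[CohortSpec, list[ClassProfileSpec]]:
    """Two classes whose moderate-to-vigorous trajectories diverge strongly."""
    spec = CohortSpec(n_participants=n, class_proportions=(0.3, 0.7), seed=seed)
    return spec, [_increasing_profile(), _flat_profile()]


def zero_separation_preset(n: int = 200, seed: int = 1) -> tuple[CohortSpec, list[ClassProfileSpec]]:
    """Two nominal classes with identical generating distributions."""
    spec = CohortSpec(n_participants=n, class_proportions=(0.5, 0.5), seed=seed)
    return spec, [_flat_profile("flat_a"), _flat_profile("flat_b")]


# ---------------------------------------------------------------------------
# hand-specified worked fixtures for oracle tests

#: (length, counts value, steps value) wear segments following the nocturnal
#: block of the worked day; constants per segment so summaries are
#: hand-computable
WORKED_DAY_SEGMENTS = (
    (600, 0, 0),      # nocturnal non-wear
    (40, 50, 0),      # SB
    (35, 0, 0),       # SB zeros (short of the non-wear window, not adjacent to it)
    (30, 80, 0),      # SB -> one 105-min SB run so far
    (20, 100, 20),    # LIPA
    (12, 2500, 110),  # MVPA bout of 12
    (1, 1000, 30),    # LIPA breaks the bout
    (9, 3000, 120),   # MVPA run of 9: not a bout
    (200, 30, 0),     # SB bout of 200
    (30, 1951, 40),   # LIPA at the upper cut-point
    (10, 2500, 115),  # MVPA bout of 10 exactly
    (453, 20, 0),     # SB bout of 453
)


def _expand(segments) -> tuple[np.ndarray, np.ndarray]:
    counts = np.concatenate([np.full(n, c, dtype=int) for n, c, _ in segments])
    steps = np.concatenate([np.full(n, s, dtype=int) for n, _, s in segments])
    return counts, steps


def generate_worked_fixture() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Tiny epoch series with known non-wear runs, bouts and classifications.

    Returns a mapping name -> (counts, steps); every series is <= 1440 epochs.
    """
    fixtures: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    def add(name, counts):
        arr = np.asarray(counts, dtype=int)
        fixtures[name] = (arr, np.zeros_like(arr))

    add("zeros_90", np.zeros(90))
    add("zeros_89", np.zeros(89))
    add("interrupted_92", np.r_[np.zeros(45), [5, 5], np.zeros(45)])
    add("interrupted_93", np.r_[np.zeros(45), [5, 5, 5], np.zeros(45)])
    add("mvpa_12", np.r_[np.full(12, 2000), np.full(20, 50)])
    fixtures["worked_day"] = _expand(WORKED_DAY_SEGMENTS)
    return fixtures


# ---------------------------------------------------------------------------
# plain-text writers

def write_cohort(outdir: str | Path, epochs: pd.DataFrame, covariates: pd.DataFrame, truth: GroundTruth) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "epochs": outdir / "epochs.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.csv",
        "truth_wave_means": outdir / "truth_wave_means.csv",
    }
    epochs.to_csv(paths["epochs"], index=False)
    covariates.to_csv(paths["covariates"], index=False)
    truth.labels.to_csv(paths["truth"], index=False)
    truth.wave_means.to_csv(paths["truth_wave_means"], index=False)
    return paths
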