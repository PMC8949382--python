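"""Shared fixtures and independent oracle implementations.

The oracles here are written against the stated rules directly (index-wise
scans, closed forms) and deliberately share no code with the package's
run-length/vectorised implementations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from actitraj.lclmm import LclmmParams


# ---------------------------------------------------------------------------
# independent oracles

def oracle_nonwear(counts, window=90, allowance=2):
    """Single-pass index scan for the non-wear rule; True = wear."""
    counts = list(counts)
    n = len(counts)
    wear = [True] * n
    i = 0
    while i < n:
        if counts[i] != 0:
            i += 1
            continue
        zeros = 0
        last_zero = i
        pos = i
        while pos < n:
            if counts[pos] == 0:
                zeros += 1
                last_zero = pos
                pos += 1
            else:
                k = pos
                while k < n and counts[k] != 0:
                    k += 1
                if k - pos <= allowance and k < n:
                    pos = k
                else:
                    break
        if zeros >= window:
            for q in range(i, last_zero + 1):
                wear[q] = False
        i = last_zero + 1
    return wear


def oracle_bouts(classes, target, min_length):
    """Index-wise maximal-run scan for bouts."""
    bouts = []
    i, n = 0, len(classes)
    while i < n:
        if classes[i] == target:
            j = i
            while j < n and classes[j] == target:
                j += 1
            if j - i >= min_length:
                bouts.append((i, j - i))
            i = j
        else:
            i += 1
    return bouts


def oracle_classify(count, rules):
    """Per-epoch comparator for the intensity cut-points (wear epochs)."""
    if count <= rules.sb_upper:
        return 1
    if count <= rules.lipa_upper:
        return 2
    return 3


# ---------------------------------------------------------------------------
# model-level simulator for the latent-class mixed model (independent of the
# fitting code: draws classes, random effects and noise directly)

def simulate_lclmm_panel(params: LclmmParams, n: int, times, seed: int, miss: float = 0.0):
    """Returns (long DataFrame with y0..y{K-1}, true 0-based labels)."""
    rng = np.random.default_rng(seed)
    G, K, _ = params.beta.shape
    labels = rng.choice(G, size=n, p=params.pi)
    rows = []
    times = np.asarray(times, dtype=float)
    for i in range(n):
        g = labels[i]
        keep = rng.random(len(times)) >= miss
        if not keep.any():
            keep[rng.integers(len(times))] = True
        t = times[keep]
        X = np.column_stack([np.ones_like(t), t])
        ys = []
        for k in range(K):
            b = rng.multivariate_normal(np.zeros(2), params.re_cov[k])
            ys.append(X @ (params.beta[g, k] + b)
                      + rng.normal(0.0, np.sqrt(params.sigma2[k]), len(t)))
        for j, tt in enumerate(t):
            row = {"participant_id": i + 1, "time_years": float(tt)}
            for k in range(K):
                row[f"y{k}"] = float(ys[k][j])
            rows.append(row)
    return pd.DataFrame(rows), labels


def two_class_params(slope_sep=(1.2, 1.0), pi=(0.6, 0.4)) -> LclmmParams:
    """Two classes, two outcomes, slope separation >= 1 z/yr by default."""
    return LclmmParams(
        pi=np.asarray(pi, dtype=float),
        beta=np.array([
            [[0.0, 0.0], [0.2, 0.0]],
            [[-0.4, slope_sep[0]], [-0.2, slope_sep[1]]],
        ]),
        re_cov=np.stack([np.diag([0.3, 0.05]), np.diag([0.3, 0.05])]),
        sigma2=np.array([0.25, 0.25]),
    )


def aligned_agreement(assignments, labels) -> float:
    """Best label-permutation agreement for two classes."""
    a = np.asarray(assignments)
    l = np.asarray(labels)
    return max(float((a == l).mean()), float((a == 1 - l).mean()))


# ---------------------------------------------------------------------------
# shared fixtures

@pytest.fixture(scope="session")
def worked_fixtures():
    from actitraj.cohort import generate_worked_fixture

    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """A processed high-separation cohort shared across test modules."""
    from actitraj.cohort import high_separation_preset, generate_cohort
    from actitraj.processing import process_epochs, filter_valid_waves, wave_guidelines

    spec, profiles = high_separation_preset(n=40, seed=11)
    epochs, covariates, truth = generate_cohort(spec, profiles)
    days = process_epochs(epochs)
    retained, waves, accounting = filter_valid_waves(days)
    guidelines = wave_guidelines(retained)
    return {
        "epochs": epochs,
        "covariates": covariates,
        "truth": truth,
        "days": days,
        "retained_days": retained,
        "waves": waves,
        "accounting": accounting,
        "guidelines": guidelines,
    }
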