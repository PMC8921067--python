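"""Diversity, ordination and exact small-sample differential statistics.

Replicated in-vitro cultures (typically n = 4 per condition) call for an
exact rank test: the two-tailed Mann–Whitney p value is computed by full
enumeration of group labelings for small samples, so the smallest
attainable p at 4 vs 4 is 2/70 ≈ 0.0286 — the "P = 0.03" floor seen
throughout small-replicate culture studies.  Taxa and community
phenotypes are additionally classified as altered when their mean
relative abundance shifts more than fivefold against control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_ENUMERATION_LIMIT = 12


def shannon_diversity(abundances: Sequence[float]) -> float:
    """Shannon index H = −Σ aᵢ ln aᵢ (natural-log units) of a closed composition."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    if abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1; got {a.sum():.6f}")
    positive = a[a > 0]
    return float(-(positive * np.log(positive)).sum())


def bray_curtis(sample_a: pd.Series, sample_b: pd.Series) -> float:
    """Bray–Curtis dissimilarity 1 − Σ min(aᵢ, bᵢ) between closed compositions."""
    if isinstance(sample_a, pd.Series) and isinstance(sample_b, pd.Series):
        if not sample_a.index.equals(sample_b.index):
            raise ValueError("samples are indexed by different taxa")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples have different lengths")
    return float(1.0 - np.minimum(a, b).sum())


def bray_curtis_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray–Curtis distances for a samples × taxa relative table."""
    n = data.shape[0]
    values = data.to_numpy(dtype=float)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = 1.0 - np.minimum(values[i], values[j]).sum()
    return pd.DataFrame(out, index=data.index, columns=data.index)


@dataclass
class PCoAResult:
    """Classical-scaling embedding with the full eigenvalue spectrum.

    ``coordinates`` spans the axes with positive eigenvalues;
    ``eigenvalues`` keeps the whole spectrum (negative values included —
    Bray–Curtis is not Euclidean, so they carry real information about
    embedding distortion); ``proportion_explained`` is each positive
    eigenvalue over the positive-eigenvalue total.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(distance_matrix: pd.DataFrame, atol: float = 1e-8) -> PCoAResult:
    """Principal coordinates analysis via Gower double-centering."""
    d = distance_matrix.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=atol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=atol):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = -0.5 * centering @ (d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh(gower)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > atol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    axes = [f"PCo{i + 1}" for i in range(int(positive.sum()))]
    proportions = eigvals[positive] / eigvals[positive].sum() if positive.any() else np.array([])
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=distance_matrix.index, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=proportions,
    )


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney_exact(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test, exact for small samples.

    Mid-ranks handle ties.  When n_a + n_b ≤ 12 the null distribution of U
    is built by enumerating all C(n_a+n_b, n_a) group labelings of the
    observed values; the two-tailed p doubles the probability of a U at
    least as extreme as observed (toward the nearer tail), capped at 1.
    Larger samples fall back to the tie-corrected normal approximation.

    Returns ``(U, p)`` with U the statistic of ``group_a``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_total = a.size, pooled.size
    u_obs = _u_statistic(ranks[:n_a], n_a)
    if n_total > EXACT_ENUMERATION_LIMIT:
        result = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return u_obs, float(result.pvalue)
    mean_u = n_a * (n_total - n_a) / 2.0
    total = math.comb(n_total, n_a)
    tol = 1e-9
    count = 0
    for subset in combinations(range(n_total), n_a):
        u = _u_statistic(ranks[list(subset)], n_a)
        if u_obs <= mean_u:
            count += u <= u_obs + tol
        else:
            count += u >= u_obs - tol
    return u_obs, min(1.0, 2.0 * count / total)


@dataclass(frozen=True)
class ModulationCall:
    """Fold-change classification of one feature against control."""

    direction: str  # increased | decreased | unaltered
    fold_ratio: float  # treatment/control mean ratio (inf/0 at detection edges)
    marker: str | None = None  # "new" | "lost" when one side is undetected


def classify_modulation(
    control_mean: float,
    treatment_mean: float,
    fold_threshold: float = 5.0,
    detection_limit: float = 0.0,
) -> ModulationCall:
    """Classify a feature as increased/decreased (>fold_threshold) or unaltered.

    A feature undetected in control but detected under treatment is
    "new" (counted as increased); the reverse is "lost" (decreased).
    """
    if control_mean < 0 or treatment_mean < 0:
        raise ValueError("mean abundances must be nonnegative")
    if fold_threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    control_detected = control_mean > detection_limit
    treatment_detected = treatment_mean > detection_limit
    if not control_detected and treatment_detected:
        return ModulationCall("increased", math.inf, "new")
    if control_detected and not treatment_detected:
        return ModulationCall("decreased", 0.0, "lost")
    if not control_detected and not treatment_detected:
        return ModulationCall("unaltered", math.nan)
    ratio = treatment_mean / control_mean
    if ratio > fold_threshold:
        return ModulationCall("increased", ratio)
    if 1.0 / ratio > fold_threshold:
        return ModulationCall("decreased", ratio)
    return ModulationCall("unaltered", ratio)


def differential_table(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    control: str = "control",
    fold_threshold: float = 5.0,
    detection_limit: float = 0.0,
) -> pd.DataFrame:
    """Per-feature contrasts of every condition against control.

    ``values`` is samples × features (relative abundances or CPIs);
    ``metadata`` maps sample → condition.  Every feature × non-control
    condition yields one row with means, fold classification and the
    exact two-tailed Mann–Whitney p of its replicate values vs control —
    no feature is silently filtered.  A Benjamini–Hochberg ``q`` column
    (per condition) is emitted for convenience but never gates output.
    """
    conditions = metadata.loc[values.index, "condition"].astype(str)
    if control not in set(conditions):
        raise ValueError(f"control condition {control!r} not present")
    control_rows = values.loc[conditions[conditions == control].index]
    if control_rows.shape[0] < 2:
        raise ValueError("control needs at least 2 replicates")
    records = []
    for condition in [c for c in pd.unique(conditions) if c != control]:
        treat_rows = values.loc[conditions[conditions == condition].index]
        if treat_rows.shape[0] < 2:
            raise ValueError(f"condition {condition!r} needs at least 2 replicates")
        for feature in values.columns:
            c_mean = float(control_rows[feature].mean())
            t_mean = float(treat_rows[feature].mean())
            call = classify_modulation(c_mean, t_mean, fold_threshold, detection_limit)
            u, p = mann_whitney_exact(treat_rows[feature], control_rows[feature])
            records.append(
                {
                    "feature": feature,
                    "condition": condition,
                    "control_mean": c_mean,
                    "treatment_mean": t_mean,
                    "fold_ratio": call.fold_ratio,
                    "marker": call.marker,
                    "direction": call.direction,
                    "U": u,
                    "p": p,
                }
            )
    out = pd.DataFrame.from_records(records)
    out["q"] = np.nan
    for condition, idx in out.groupby("condition").groups.items():
        out.loc[idx, "q"] = _benjamini_hochberg(out.loc[idx, "p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_index in range(m - 1, -1, -1):
        i = order[rank_index]
        running_min = min(running_min, p[i] * m / (rank_index + 1))
        adjusted[i] = running_min
    return adjusted


def summarize_modulation(diff: pd.DataFrame) -> pd.DataFrame:
    """Per-condition counts of increased / decreased / altered / unaltered."""
    rows = []
    for condition, sub in diff.groupby("condition"):
        increased = int((sub["direction"] == "increased").sum())
        decreased = int((sub["direction"] == "decreased").sum())
        rows.append(
            {
                "condition": condition,
                "increased": increased,
                "decreased": decreased,
                "altered": increased + decreased,
                "unaltered": int((sub["direction"] == "unaltered").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("condition")
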