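"""Multi-reader score arithmetic: ordinal medians and Fleiss' kappa.

Visual image quality is scored per scan by several readers on a 4-point
ordinal scale (0 non-diagnostic, 1 poor, 2 moderate, 3 good) and
summarized by the median; lesion counts are reported in ordinal bins.
Chance-corrected inter-reader agreement uses Fleiss' kappa for a fixed
number of raters, with the large-sample standard error and normal 95 %
interval.

A small latent-quality reader simulator is included for generating
realistic rating tables from measured SNR values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KappaResult",
    "median_score",
    "fleiss_kappa",
    "simulate_ratings",
    "ratings_to_long",
    "read_ratings_csv",
]

VISUAL_SCALE = (0, 1, 2, 3)  # non-diagnostic, poor, moderate, good


@dataclass(frozen=True)
class KappaResult:
    """Fleiss' kappa with large-sample SE and normal 95 % CI."""

    kappa: float
    se: float
    ci95: tuple[float, float]
    degenerate: bool = False


def median_score(ratings: Sequence[int]) -> int:
    """Median of ordinal ratings; the lower median for an even count.

    The lower median keeps the result an attained category, so one
    outlying vote (e.g. a single non-diagnostic score among three) never
    drags the summary to a category no majority supports.
    """
    if len(ratings) == 0:
        raise ValueError("need at least one rating")
    ordered = sorted(ratings)
    return ordered[(len(ordered) - 1) // 2]


def _rating_counts(
    table: np.ndarray, categories: Sequence[int] | None
) -> tuple[np.ndarray, np.ndarray]:
    """Subjects×categories count matrix from a subjects×raters table."""
    table = np.asarray(table)
    if table.ndim != 2:
        raise ValueError("ratings must be a subjects × raters matrix")
    n_subjects, n_raters = table.shape
    if n_subjects < 2 or n_raters < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    cats = np.unique(table) if categories is None else np.asarray(categories)
    if not np.isin(table, cats).all():
        raise ValueError("table contains ratings outside the declared categories")
    counts = np.stack([(table == c).sum(axis=1) for c in cats], axis=1)
    return counts, cats


def fleiss_kappa(
    table: np.ndarray, categories: Sequence[int] | None = None
) -> KappaResult:
    """Fleiss' kappa for a subjects × raters matrix of category labels.

    κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) where P̄ is the mean per-subject pairwise
    agreement and P̄ₑ the chance agreement from the category marginals.
    The SE is the Fleiss–Nee–Landis large-sample form (null variance).
    A table whose marginals put all mass in one category has P̄ₑ = 1 and
    undefined κ; a flagged degenerate result is returned.
    """
    counts, _ = _rating_counts(table, categories)
    n_subjects, _ = counts.shape
    n = int(counts.sum(axis=1)[0])
    if not (counts.sum(axis=1) == n).all():
        raise ValueError("all subjects must have the same number of ratings")
    p_j = counts.sum(axis=0) / (n_subjects * n)
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        return KappaResult(
            kappa=float("nan"), se=float("nan"), ci95=(float("nan"), float("nan")),
            degenerate=True,
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    q_j = 1.0 - p_j
    spq = float((p_j * q_j).sum())
    var = (
        2.0
        / (n_subjects * n * (n - 1))
        * (spq**2 - float((p_j * q_j * (q_j - p_j)).sum()))
        / spq**2
    )
    se = float(np.sqrt(var))
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci95=(float(kappa - 1.959963984540054 * se), float(kappa + 1.959963984540054 * se)),
    )


def simulate_ratings(
    snr_values: Sequence[float],
    n_raters: int = 3,
    thresholds: Sequence[float] = (3.0, 4.5, 6.2),
    reader_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Latent-quality ordinal reader model (synthetic rating tables).

    Each scan's latent quality is its SNR; each rater perceives it with
    additive normal noise (``reader_sd``) and grades it against the
    ordinal ``thresholds`` (scores 0..len(thresholds)).  Returns a
    subjects × raters integer matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snr = np.asarray(snr_values, dtype=float)
    perceived = snr[:, None] + rng.normal(0.0, reader_sd, size=(snr.size, n_raters))
    return np.searchsorted(np.asarray(thresholds), perceived.ravel()).reshape(
        perceived.shape
    )


def ratings_to_long(table: np.ndarray) -> pd.DataFrame:
    """Long-format ratings (subject_id, rater_id, category) for CSV export."""
    table = np.asarray(table)
    subjects, raters = np.indices(table.shape)
    return pd.DataFrame(
        {
            "subject_id": subjects.ravel(),
            "rater_id": raters.ravel(),
            "category": table.ravel(),
        }
    )


def read_ratings_csv(path: str | Path) -> np.ndarray:
    """Read long-format ratings back into a subjects × raters matrix."""
    frame = pd.read_csv(path)
    wide = frame.pivot(index="subject_id", columns="rater_id", values="category")
    if wide.isna().any().any():
        raise ValueError("ratings table is incomplete (missing subject/rater cells)")
    return wide.to_numpy(dtype=int)
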