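"""Anteroposterior ventilation profiles and comparison statistics.

The profile vd is the row-wise (anterior to posterior) distribution of tidal
image mass over 32 horizontal bands, normalized to 100%.  Model-vs-reference
agreement is summarized by the per-subject profile RMSE, pooled Pearson
correlation and a non-parametric Bland-Altman analysis (median bias, 2.5th to
97.5th percentile limits of agreement, linear-interpolation quantiles); model
variants are compared with a Kruskal-Wallis test followed by Tukey-Kramer
multiple comparisons on rank sums (Nemenyi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PixelGrid
from .pipeline import TidalImage

__all__ = [
    "VentilationProfile",
    "ComparisonResult",
    "SweepResult",
    "ap_profile",
    "profile_rmse",
    "pooled_pearson",
    "bland_altman",
    "image_correlation_2d",
    "rank_settings",
    "compare_models",
]


@dataclass(frozen=True)
class VentilationProfile:
    """32-band anteroposterior ventilation distribution in percent."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < -1e-12):
            raise ValueError("profile fractions must be non-negative")
        if abs(v.sum() - 100.0) > 1e-9:
            raise ValueError("profile must sum to 100%")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return len(self.values)


def ap_profile(
    img: np.ndarray, region_mask: np.ndarray, n_regions: int = 32
) -> VentilationProfile:
    """Sum masked pixel values in equal horizontal bands, normalize to 100%.

    Accepts any resolution with at least ``n_regions`` rows (row count must
    be divisible by ``n_regions``); band 0 is the most anterior.
    """
    img = np.asarray(img, dtype=float)
    mask = np.asarray(region_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if img.shape[0] < n_regions or img.shape[0] % n_regions:
        raise ValueError(
            f"image rows {img.shape[0]} not divisible into {n_regions} bands"
        )
    rows_per_band = img.shape[0] // n_regions
    masked = np.where(mask, img, 0.0)
    bands = masked.reshape(n_regions, rows_per_band, -1).sum(axis=(1, 2))
    total = bands.sum()
    if total <= 0:
        raise ValueError("masked image has non-positive total mass")
    return VentilationProfile(values=100.0 * bands / total)


def profile_rmse(a: VentilationProfile, b: VentilationProfile) -> float:
    """Root mean square difference between two profiles, in percentage points."""
    if a.n_regions != b.n_regions:
        raise ValueError("profiles have different numbers of bands")
    return float(np.sqrt(np.mean((a.values - b.values) ** 2)))


def _retained(pairs: np.ndarray) -> np.ndarray:
    """Keep pairs where at least one of the two values is > 0."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be (n, 2)")
    return pairs[(pairs > 0).any(axis=1)]


def pooled_pearson(pairs: np.ndarray, filtered: bool = True) -> float:
    """Pearson correlation of pooled (reference, EIT) band values.

    With ``filtered`` (the primary variant), pairs where both methods report
    zero ventilation are excluded first.
    """
    p = _retained(pairs) if filtered else np.asarray(pairs, dtype=float)
    if len(p) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(p[:, 0]) == 0 or np.ptp(p[:, 1]) == 0:
        raise ValueError("correlation undefined for zero-variance margins")
    r, _ = stats.pearsonr(p[:, 0], p[:, 1])
    return float(r)


def bland_altman(pairs: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Non-parametric Bland-Altman agreement of EIT vs reference.

    Differences d = vd_eit - vd_ref over pairs where either value is
    positive; returns (median bias, (2.5th, 97.5th percentile) limits),
    quantiles by linear interpolation between order statistics.
    """
    p = _retained(pairs)
    if len(p) < 3:
        raise ValueError("fewer than 3 retained pairs")
    d = p[:, 1] - p[:, 0]
    lo, hi = np.percentile(d, [2.5, 97.5], method="linear")
    return float(np.median(d)), (float(lo), float(hi))


@dataclass
class ComparisonResult:
    """Agreement summary of one EIT profile variant against the reference."""

    rmse_per_subject: np.ndarray
    pooled_r: float
    pooled_r_unfiltered: float
    bias: float
    loa: tuple[float, float]


def image_correlation_2d(
    eit: TidalImage, ref: np.ndarray, grid: PixelGrid
) -> float:
    """Pearson correlation between an EIT tidal image and a high-resolution
    ground-truth tidal image, block-mean downsampled to the 32x32 grid.

    Both images must live on the same thorax bounding box; correlation runs
    over in-body pixels only.
    """
    ref = np.asarray(ref, dtype=float)
    nr, nc = grid.shape
    if ref.shape[0] % nr or ref.shape[1] % nc:
        raise ValueError("reference shape must be a multiple of the grid shape")
    fr, fc = ref.shape[0] // nr, ref.shape[1] // nc
    ref32 = ref.reshape(nr, fr, nc, fc).mean(axis=(1, 3))
    a = eit.pixels[grid.body_mask]
    b = ref32[grid.body_mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant image")
    r, _ = stats.pearsonr(a, b)
    return float(r)


@dataclass
class SweepResult:
    """Settings-sweep output: one row per (setting, subject) and the ranking."""

    rows: pd.DataFrame
    ranking: pd.DataFrame


def rank_settings(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank settings by 2D correlation within each subject (rank 1 = best,
    ties get average ranks), then order by mean rank across subjects.

    Failed rows (NaN correlation) receive the worst rank for that subject.
    The ranking is invariant to any monotone transform of the correlations.
    """
    if not {"setting", "subject", "correlation"} <= set(rows.columns):
        raise ValueError("rows need setting, subject and correlation columns")
    df = rows.copy()
    df["rank"] = df.groupby("subject")["correlation"].rank(
        ascending=False, method="average", na_option="bottom"
    )
    ranking = (
        df.groupby("setting", sort=False)
        .agg(mean_rank=("rank", "mean"), mean_correlation=("correlation", "mean"))
        .sort_values("mean_rank", kind="mergesort")
        .reset_index()
    )
    return ranking


def compare_models(rmse_table: pd.DataFrame) -> dict:
    """Kruskal-Wallis test across model variants plus Tukey-Kramer
    (Nemenyi) pairwise comparisons on rank sums.

    ``rmse_table``: one row per subject, one column per model variant.
    Returns H, degrees of freedom, the chi-square p-value, and a symmetric
    DataFrame of pairwise p-values.
    """
    if rmse_table.shape[1] < 2 or rmse_table.shape[0] < 3:
        raise ValueError("need >= 2 variants and >= 3 subjects")
    groups = [rmse_table[c].to_numpy(dtype=float) for c in rmse_table.columns]
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        raise ValueError("degenerate test: all values identical")
    H, p = stats.kruskal(*groups)
    k = len(groups)
    N = len(flat)
    ranks = stats.rankdata(flat)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    pair_p = pd.DataFrame(
        np.ones((k, k)), index=rmse_table.columns, columns=rmse_table.columns
    )
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(N * (N + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
            q = abs(mean_ranks[i] - mean_ranks[j]) / se * np.sqrt(2.0)
            pv = float(stats.studentized_range.sf(q, k, np.inf))
            pair_p.iat[i, j] = pair_p.iat[j, i] = pv
    return {
        "H": float(H),
        "df": k - 1,
        "p": float(p),
        "mean_ranks": dict(zip(rmse_table.columns, mean_ranks)),
        "pairwise_p": pair_p,
    }
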