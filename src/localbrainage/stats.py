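"""Group-comparison and reliability statistics for brain-PAD analyses.

Implements the downstream inferential toolkit: Welch's unequal-variance
t-test with Welch–Satterthwaite degrees of freedom, Cohen's d with the
pooled standard deviation, intraclass correlation (both the classical
Fisher pairwise form and ICC[2,1], the two-way random-effects,
absolute-agreement, single-measure coefficient), Pearson correlation,
Bonferroni correction, ROI aggregation of prediction maps, and pairwise
group comparisons at voxel, ROI or global scope.

Statistics are computed from group summaries (n, mean, unbiased variance),
so the same code path serves participant-level values and the huge pooled
voxel "populations" used at voxel scope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volume_io import ParticipantRecord, RoiAtlas

__all__ = [
    "GroupSummary",
    "summarize",
    "welch_t",
    "welch_t_from_data",
    "cohens_d",
    "icc",
    "pearson_r",
    "bonferroni",
    "roi_aggregate",
    "compare_groups",
    "welch_t_maps",
    "age_matched_subset",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: n, mean, unbiased variance."""

    n: int
    mean: float
    var: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries need n >= 2")
        if self.var < 0:
            raise ValueError("variance must be >= 0")


def summarize(values: Sequence[float]) -> GroupSummary:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    return GroupSummary(n=int(x.size), mean=float(x.mean()), var=float(x.var(ddof=1)))


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch's t, Welch–Satterthwaite df, and the two-sided p-value.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b); the degrees of
    freedom follow the Welch–Satterthwaite approximation.
    """
    va, vb = a.var / a.n, b.var / b.n
    se2 = va + vb
    if se2 == 0:
        raise ZeroDivisionError("both group variances are zero; t undefined")
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t_from_data(x, y) -> tuple[float, float, float]:
    return welch_t(summarize(x), summarize(y))


def cohens_d(a: GroupSummary, b: GroupSummary) -> float:
    """Standardised mean difference using the pooled standard deviation."""
    if a.n + b.n <= 2:
        raise ValueError("need n_a + n_b > 2 for Cohen's d")
    pooled_var = ((a.n - 1) * a.var + (b.n - 1) * b.var) / (a.n + b.n - 2)
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled standard deviation; d undefined")
    return float((a.mean - b.mean) / np.sqrt(pooled_var))


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need >= 3 pairs for a correlation")
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ZeroDivisionError("zero variance in a correlation input")
    return float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))


def bonferroni(p: float, m: int) -> float:
    """Family-wise adjusted p-value: min(1, p * m)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return float(min(1.0, p * m))


# ---------------------------------------------------------------------------
# intraclass correlation


def _icc_fisher(x: np.ndarray) -> float:
    """Fisher's classical pairwise intraclass correlation (two measurements).

    xbar = (1/2N) sum(x1 + x2);  s^2 = (1/2N) sum[(x1-xbar)^2 + (x2-xbar)^2];
    r = (1/(N s^2)) sum[(x1-xbar)(x2-xbar)].
    """
    if x.shape[1] != 2:
        raise ValueError("the Fisher formula is defined for exactly 2 measurements")
    n = x.shape[0]
    xbar = x.mean()
    s2 = ((x - xbar) ** 2).sum() / (2 * n)
    if s2 == 0:
        raise ZeroDivisionError("zero total variance; ICC undefined")
    return float(((x[:, 0] - xbar) * (x[:, 1] - xbar)).sum() / (n * s2))


def _icc21(x: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA decomposition with n participants (rows) and k
    raters/scans (columns):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sse = ((x - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ZeroDivisionError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def icc(pairs, method: str = "icc21") -> float:
    """Intraclass correlation of an ``(n_participants, k_measurements)`` table.

    ``method="fisher"`` evaluates the classical pairwise formula literally
    (k must be 2); ``method="icc21"`` computes ICC(2,1) from the ANOVA mean
    squares and supports k >= 2 raters.  Both land in [-1, 1].
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2D table with >= 2 participants and >= 2 measurements")
    if method == "fisher":
        return _icc_fisher(x)
    if method == "icc21":
        return _icc21(x)
    raise ValueError(f"unknown ICC method {method!r}")


# ---------------------------------------------------------------------------
# ROI aggregation and group comparisons


def icc_map(rater_maps: Sequence[np.ndarray], mask: np.ndarray) -> np.ndarray:
    """Voxelwise ICC(2,1) across k repeat/rescan map sets (NaN outside mask).

    ``rater_maps[r]`` stacks the n participants' maps under rater/scan r;
    the ANOVA decomposition of :func:`icc` is evaluated at every in-mask
    voxel simultaneously.
    """
    mask = np.asarray(mask).astype(bool)
    x = np.stack([np.asarray(m, dtype=float)[:, mask] for m in rater_maps], axis=1)  # (n, k, V)
    n, k, _ = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 participants and >= 2 raters")
    grand = x.mean(axis=(0, 1))
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    ssr = k * ((row - grand) ** 2).sum(axis=0)
    ssc = n * ((col - grand) ** 2).sum(axis=0)
    sse = ((x - row[:, None, :] - col[None, :, :] + grand) ** 2).sum(axis=(0, 1))
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(denom != 0, (msr - mse) / denom, np.nan)
    out = np.full(mask.shape, np.nan)
    out[mask] = vals
    return out


def roi_aggregate(
    map3d: np.ndarray,
    atlas: RoiAtlas,
    record: ParticipantRecord,
    voxel_size_mm: float = 1.5,
) -> pd.DataFrame:
    """Per-ROI brain-PAD and tissue volume for one prediction map.

    ROI brain-PAD = mean in-ROI predicted age minus chronological age; the
    ROI volume is its in-map (finite) voxel count times the voxel volume.
    """
    map3d = np.asarray(map3d, dtype=float)
    if map3d.shape != atlas.labels.shape:
        raise ValueError("atlas not aligned with the map")
    rows = []
    vox_mm3 = voxel_size_mm**3
    for label in atlas.label_ids():
        sel = (atlas.labels == label) & np.isfinite(map3d)
        if not sel.any():
            raise ValueError(f"ROI {label} lies fully outside the prediction mask")
        rows.append(
            {
                "participant_id": record.id,
                "roi_label": label,
                "roi_name": atlas.names.get(label, str(label)),
                "n_voxels": int(sel.sum()),
                "volume_mm3": float(sel.sum() * vox_mm3),
                "mean_predicted_age": float(map3d[sel].mean()),
                "brain_pad": float(map3d[sel].mean() - record.age_years),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]],
    scope: str = "global",
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """All pairwise Welch comparisons with Bonferroni-adjusted p and Cohen's d.

    ``n_comparisons`` defaults to the number of tests actually performed
    here (the group-pair count); pass the voxel or ROI count when this call
    is one of many at that scope.
    """
    groups = sorted(values_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    summaries = {g: summarize(values_by_group[g]) for g in groups}
    pairs = list(itertools.combinations(groups, 2))
    m = n_comparisons if n_comparisons is not None else len(pairs)
    rows = []
    for ga, gb in pairs:
        t, df, p = welch_t(summaries[ga], summaries[gb])
        rows.append(
            {
                "scope": scope,
                "group_a": ga,
                "group_b": gb,
                "n_a": summaries[ga].n,
                "n_b": summaries[gb].n,
                "t": t,
                "df": df,
                "p": p,
                "p_adj": bonferroni(p, m),
                "cohens_d": cohens_d(summaries[ga], summaries[gb]),
            }
        )
    return pd.DataFrame(rows)


def welch_t_maps(
    maps_a: Sequence[np.ndarray],
    maps_b: Sequence[np.ndarray],
    mask: np.ndarray,
    n_comparisons: int | None = None,
) -> dict[str, np.ndarray]:
    """Voxelwise Welch t / df / p / adjusted-p / Cohen's d maps (NaN outside).

    Each participant contributes one delta map per group; the test runs
    independently at every in-mask voxel, Bonferroni-corrected over the
    number of in-mask voxels unless ``n_comparisons`` overrides it.
    """
    mask = np.asarray(mask).astype(bool)
    a = np.asarray(maps_a, dtype=float)[:, mask]
    b = np.asarray(maps_b, dtype=float)[:, mask]
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 maps per group")
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1) / na, b.var(axis=0, ddof=1) / nb
    se2 = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
        pooled = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
            na + nb - 2
        )
        d = (ma - mb) / np.sqrt(pooled)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    m = n_comparisons if n_comparisons is not None else int(mask.sum())
    p_adj = np.minimum(1.0, p * m)

    def to_map(v):
        out = np.full(mask.shape, np.nan)
        out[mask] = v
        return out

    return {"t": to_map(t), "df": to_map(df), "p": to_map(p), "p_adj": to_map(p_adj), "d": to_map(d)}


def age_matched_subset(
    records: Sequence[ParticipantRecord], min_age: float
) -> list[ParticipantRecord]:
    """Participants strictly older than ``min_age`` (e.g. >60-year controls).

    An empty result raises a warning, not a failure.
    """
    subset = [r for r in records if r.age_years > min_age]
    if not subset:
        warnings.warn(
            f"no participants older than {min_age} years; age-matched subset is empty",
            stacklevel=2,
        )
    return subset
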