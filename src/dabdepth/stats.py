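"""Depth distributions and rank-based comparisons.

Detected DAB areas are summarized two ways: per *pixel* (every
DAB-positive pixel contributes its relative depth, so large areas weigh
proportionally to their size) and per *blob* (one mean depth per area,
removing the size weighting).  Both are kept because either choice can
bias a migration readout.

Group comparisons use the unpaired two-sample rank-sum (Mann–Whitney)
test — pixel populations from different sections are independent, so a
paired signed-rank design does not apply.  The comparison runs on the
full distribution and on three depth bands ([0,⅓), [⅓,⅔), [⅔,1]) so a
shift confined to, say, the basal third is not washed out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sstats

#: largest number of pooled-subset evaluations for exact enumeration with ties
_MAX_ENUMERATION = 200_000


@dataclass
class DepthDistribution:
    """Pooled depth values for one experimental condition."""

    condition: str
    pixel_d_rel: np.ndarray          # one value per DAB-positive pixel
    pixel_dist_epi_um: np.ndarray    # absolute distance from epidermis top
    pixel_dist_derm_um: np.ndarray
    blob_mean_d_rel: np.ndarray      # one value per blob
    replicate_of_pixel: np.ndarray   # provenance: replicate index per pixel
    replicate_of_blob: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pixel_d_rel", "blob_mean_d_rel"):
            v = getattr(self, name)
            if v.size and ((v < 0).any() or (v > 1).any()):
                raise ValueError(f"{name} outside [0, 1]")

    @property
    def n_pixels(self) -> int:
        return int(self.pixel_d_rel.size)

    @property
    def n_blobs(self) -> int:
        return int(self.blob_mean_d_rel.size)


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    alternative: str
    n_a: int
    n_b: int
    significant: bool | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.significant is None and np.isfinite(self.p_value):
            self.significant = bool(self.p_value < 0.05)


def pool_distribution(
    blobs_per_section: list[list],
    field_per_section: list,
    condition: str = "",
) -> DepthDistribution:
    """Pool blob depths over replicate sections into one distribution.

    ``blobs_per_section[i]`` are depth-annotated blobs measured on
    ``field_per_section[i]`` (same region grid).  An empty blob list
    yields a valid empty distribution.
    """
    if len(blobs_per_section) != len(field_per_section):
        raise ValueError("one depth field per section is required")
    px_vals, px_epi, px_derm, px_rep = [], [], [], []
    blob_vals, blob_rep = [], []
    for rep, (blobs, fld) in enumerate(zip(blobs_per_section, field_per_section)):
        for b in blobs:
            if b.d_rel_values is None:
                raise ValueError("blobs must be depth-annotated (attach_depths)")
            r, c = b.pixels[:, 0], b.pixels[:, 1]
            px_vals.append(b.d_rel_values)
            px_epi.append(fld.d_top_epi_um[r, c])
            px_derm.append(fld.d_top_derm_um[r, c])
            px_rep.append(np.full(b.pixels.shape[0], rep))
            blob_vals.append(b.mean_d_rel)
            blob_rep.append(rep)
    cat = lambda xs: np.concatenate(xs) if xs else np.empty(0)
    return DepthDistribution(
        condition=condition,
        pixel_d_rel=cat(px_vals),
        pixel_dist_epi_um=cat(px_epi),
        pixel_dist_derm_um=cat(px_derm),
        blob_mean_d_rel=np.asarray(blob_vals, dtype=float),
        replicate_of_pixel=cat(px_rep).astype(int),
        replicate_of_blob=np.asarray(blob_rep, dtype=int),
    )


def histogram(
    dist: DepthDistribution, n_bins: int = 50, per_pixel: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalized depth histogram and a unit-area violin density.

    Returns ``(bin_edges, bin_masses, grid, density)`` where the masses
    sum to 1 and the kernel density integrates to 1 over the grid.  Depth
    runs 0 (stratum corneum) to 1 (basal lamina); plots orient this axis
    top-to-bottom.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    values = dist.pixel_d_rel if per_pixel else dist.blob_mean_d_rel
    if values.size == 0:
        raise ValueError("no DAB-positive pixels: empty distribution")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.clip(values, 0, 1), bins=edges)
    masses = counts / counts.sum()
    grid = np.linspace(0.0, 1.0, 256)
    if values.size > 1 and values.std() > 0:
        kde = sstats.gaussian_kde(values)
        density = kde(grid)
    else:  # degenerate: all mass at one point
        density = np.zeros_like(grid)
        density[np.argmin(np.abs(grid - values[0]))] = 1.0
    area = np.trapezoid(density, grid)
    if area > 0:
        density = density / area
    return edges, masses, grid, density


def per_replicate_histograms(dist: DepthDistribution, n_bins: int = 50) -> pd.DataFrame:
    """One normalized per-pixel histogram row per replicate section.

    The bin-wise mean over replicates is the curve a mean-of-replicates
    violin would show.
    """
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for rep in np.unique(dist.replicate_of_pixel):
        vals = dist.pixel_d_rel[dist.replicate_of_pixel == rep]
        counts, _ = np.histogram(np.clip(vals, 0, 1), bins=edges)
        total = counts.sum()
        rows.append({"replicate": int(rep), "n_pixels": int(total),
                     **{f"bin_{i}": counts[i] / total for i in range(n_bins)}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-based tests

def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group b via midranks (ties supported)."""
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    r_b = ranks[a.size :].sum()
    return float(r_b - b.size * (b.size + 1) / 2.0)


def _exact_enumeration_p(a: np.ndarray, b: np.ndarray, alternative: str) -> float:
    """Permutation-exact p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    n, m = a.size, b.size
    offset = m * (m + 1) / 2.0
    u_obs = float(ranks[n:].sum() - offset)
    mu = n * m / 2.0
    count = 0
    total = comb(n + m, m)
    for idx in combinations(range(n + m), m):
        u = float(ranks[list(idx)].sum() - offset)
        if alternative == "two-sided":
            hit = abs(u - mu) >= abs(u_obs - mu) - 1e-12
        elif alternative == "greater":  # b stochastically greater
            hit = u >= u_obs - 1e-12
        else:
            hit = u <= u_obs + 1e-12
        count += hit
    return count / total


def wilcoxon_compare(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> ComparisonResult:
    """Unpaired rank-sum comparison of two value samples.

    ``alternative='greater'`` tests whether *b* is stochastically greater
    than *a*.  Small tie-free samples (n, m ≤ 50) use the exact null
    distribution; small tied samples are enumerated exactly when the
    number of group assignments is tractable; everything else falls back
    to the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    u_b = _rank_sum_u(a, b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    small = max(a.size, b.size) <= 50
    scipy_alt = {"two-sided": "two-sided", "greater": "less", "less": "greater"}[alternative]
    note = ""
    if small and not has_ties:
        res = sstats.mannwhitneyu(a, b, alternative=scipy_alt, method="exact")
        p = float(res.pvalue)
        note = "exact"
    elif small and comb(a.size + b.size, min(a.size, b.size)) <= _MAX_ENUMERATION:
        p = _exact_enumeration_p(a, b, alternative)
        note = "exact-enumeration (ties)"
    else:
        res = sstats.mannwhitneyu(a, b, alternative=scipy_alt, method="asymptotic")
        p = float(res.pvalue)
        note = "normal approximation, tie-corrected"
    return ComparisonResult(
        test="rank-sum", statistic=u_b, p_value=p, alternative=alternative,
        n_a=a.size, n_b=b.size, note=note,
    )


TERTILE_EDGES = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


def tertile_compare(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> list[ComparisonResult]:
    """Rank-sum comparison within each of three depth bands.

    Bands partition the d_rel axis: [0, ⅓), [⅓, ⅔), [⅔, 1].  A band with
    an empty group is flagged "insufficient data" rather than raising.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    results = []
    for i in range(3):
        lo, hi = TERTILE_EDGES[i], TERTILE_EDGES[i + 1]
        if i < 2:
            sel_a = a[(a >= lo) & (a < hi)]
            sel_b = b[(b >= lo) & (b < hi)]
        else:
            sel_a = a[(a >= lo) & (a <= hi)]
            sel_b = b[(b >= lo) & (b <= hi)]
        if sel_a.size == 0 or sel_b.size == 0:
            results.append(
                ComparisonResult(
                    test="rank-sum", statistic=float("nan"), p_value=float("nan"),
                    alternative=alternative, n_a=sel_a.size, n_b=sel_b.size,
                    significant=None, note=f"band {i + 1} [{lo:.2f},{hi:.2f}]: insufficient data",
                )
            )
            continue
        res = wilcoxon_compare(sel_a, sel_b, alternative)
        res.note = f"band {i + 1} [{lo:.2f},{hi:.2f}]; " + res.note
        results.append(res)
    return results


def ks_normality(values: np.ndarray) -> float:
    """One-sample KS p-value against a moment-matched normal.

    Parameters are estimated from the data, which makes the test
    conservative (true p-values are smaller than reported); it is used
    here only to justify switching to rank-based comparisons.  Constant
    samples get a tiny scale floor and reject decisively.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 5:
        raise ValueError("need at least 5 values for the normality check")
    mu = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        sd = 1e-12
    return float(sstats.kstest(values, "norm", args=(mu, sd)).pvalue)


def violin_figure(dists: dict[str, DepthDistribution], per_pixel: bool = True):
    """Violin plot of depth distributions, one per condition.

    Depth runs 0 (stratum corneum) at the top of the axis to 1 (basal
    lamina) at the bottom; each violin is scaled to unit area so shapes
    are comparable across conditions regardless of pixel counts.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.6 * max(len(dists), 2) + 1, 4.5))
    for i, (cond, dist) in enumerate(dists.items()):
        _, _, grid, density = histogram(dist, per_pixel=per_pixel)
        half = density / max(density.max(), 1e-12) * 0.4
        ax.fill_betweenx(grid, i - half, i + half, alpha=0.7)
    ax.set_xticks(range(len(dists)), list(dists.keys()))
    ax.set_ylim(1.0, 0.0)  # stratum corneum on top
    ax.set_ylabel("relative depth (0 = stratum corneum, 1 = basal lamina)")
    ax.set_title("DAB-positive pixel depth")
    fig.tight_layout()
    return fig


def results_table(results: dict[str, ComparisonResult | list[ComparisonResult]]) -> pd.DataFrame:
    """Flatten named comparison results into a tidy DataFrame."""
    rows = []
    for name, res in results.items():
        seq = res if isinstance(res, list) else [res]
        for r in seq:
            rows.append({
                "comparison": name, "test": r.test, "statistic": r.statistic,
                "p_value": r.p_value, "alternative": r.alternative,
                "n_a": r.n_a, "n_b": r.n_b, "significant": r.significant,
                "note": r.note,
            })
    return pd.DataFrame(rows)
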