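"""Two-pass genome scan for selected sites in E&R data.

Pass 1: a one-locus LR scan over all sites kept by the MAF filter, followed
by averaging the statistic in non-overlapping windows and nominating
candidate regions where the windowed mean is in the upper tail (the
original analysis nominated regions by visual inspection; an empirical
quantile rule makes the step reproducible — the threshold is a stand-in and
is configurable).

Pass 2: within each candidate region, multi-locus (3/5/7-locus) models are
refit with K-1 fixed neutral flanking SNPs placed at multiples of a
prescribed spacing (default 250 kb) from the region midpoint; each in-region
site is evaluated as the putative selected locus.  The final candidate set
is the intersection of the per-model top-k lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import gp_likelihood as gp
from . import inference as inf
from . import synthetic_data as sd

__all__ = [
    "ScanConfig",
    "CandidateRegion",
    "maf_filter",
    "window_average",
    "select_candidate_regions",
    "multilocus_refit",
    "top_k_intersection",
    "two_pass_scan",
]


@dataclass(frozen=True)
class ScanConfig:
    """Tuning of the two-pass scan."""

    maf_bounds: tuple[float, float] = (0.1, 0.9)
    window_sizes: tuple[int, ...] = (10_000,)
    flank_spacing: float = 250_000.0
    model_sizes: tuple[int, ...] = (3, 5, 7)
    top_k: int = 100
    region_quantile: float = 0.01  # fraction q of windows nominated

    def __post_init__(self):
        lo, hi = self.maf_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("need 0 < maf_lo < maf_hi < 1")
        if self.flank_spacing <= 0 or self.top_k < 1:
            raise ValueError("flank_spacing must be > 0 and top_k >= 1")


@dataclass(frozen=True)
class CandidateRegion:
    """Half-open [start, end) candidate interval nominated in pass 1."""

    start: int
    end: int
    mean_lam: float
    n_sites: int
    chrom: str = "chr"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("need start < end")


def maf_filter(
    data: sd.TrajectoryData, bounds: tuple[float, float] = (0.1, 0.9)
) -> np.ndarray:
    """Indices of sites whose observed frequency lies in the closed interval
    ``[maf_lo, maf_hi]`` at every generation and replicate.  Zero-coverage
    observations carry no frequency information and do not veto a site."""
    lo, hi = bounds
    f = data.frequencies
    ok = (f >= lo) & (f <= hi)
    if not data.infinite_coverage:
        ok |= data.coverages == 0
    else:
        ok |= ~np.isfinite(f)
    return np.nonzero(ok.all(axis=(0, 2)))[0]


def window_average(
    positions: np.ndarray,
    lams: np.ndarray,
    window_size: int,
    region_length: Optional[int] = None,
) -> pd.DataFrame:
    """Mean LR statistic in non-overlapping fixed-width windows
    ``[1 + m*w, 1 + (m+1)*w)``.  Empty windows have NaN mean (missing, not
    zero).  Sites must be position-sorted."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    positions = np.asarray(positions)
    lams = np.asarray(lams, dtype=float)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    if region_length is None:
        region_length = int(positions.max()) if positions.size else window_size
    n_win = int(np.ceil(region_length / window_size))
    idx = (positions - 1) // window_size
    sums = np.bincount(idx, weights=lams, minlength=n_win)
    counts = np.bincount(idx, minlength=n_win)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    starts = 1 + window_size * np.arange(n_win)
    return pd.DataFrame(
        {"start": starts, "end": starts + window_size, "mean_lam": means, "n_sites": counts}
    )


def select_candidate_regions(
    windows: pd.DataFrame, q: float = 0.01, chrom: str = "chr"
) -> list[CandidateRegion]:
    """Nominate windows whose mean LR lies strictly above the (1-q)
    empirical quantile of non-empty windows, merging adjacent windows into
    regions padded to window boundaries."""
    filled = windows.dropna(subset=["mean_lam"])
    if filled.empty:
        return []
    thresh = float(np.quantile(filled["mean_lam"], 1.0 - q))
    hot = windows["mean_lam"] > thresh
    regions: list[CandidateRegion] = []
    i = 0
    rows = windows.reset_index(drop=True)
    while i < len(rows):
        if not hot.iloc[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(rows) and hot.iloc[j + 1]:
            j += 1
        block = rows.iloc[i : j + 1]
        regions.append(
            CandidateRegion(
                start=int(block.iloc[0]["start"]),
                end=int(block.iloc[-1]["end"]),
                mean_lam=float(block["mean_lam"].mean()),
                n_sites=int(block["n_sites"].sum()),
                chrom=chrom,
            )
        )
        i = j + 1
    return regions


def _pick_flankers(
    panel: sd.FounderPanel,
    retained: np.ndarray,
    region: CandidateRegion,
    K: int,
    spacing: float,
) -> list[int]:
    """K-1 fixed neutral loci nearest to offsets at multiples of ``spacing``
    from the region midpoint (alternating sides), each required within
    spacing/2 of its target; falls back to the nearest available SNP with a
    warning when the map is too sparse."""
    mid = 0.5 * (region.start + region.end)
    pos = panel.positions
    outside = [j for j in retained if not (region.start <= pos[j] < region.end)]
    if len(outside) < K - 1:
        raise ValueError("not enough flanking SNPs outside the region")
    targets = []
    for m in range(1, K):
        side = 1 if m % 2 else -1
        mult = (m + 1) // 2
        targets.append(mid + side * mult * spacing)
    chosen: list[int] = []
    pool = set(outside)
    for tgt in targets:
        best = min(pool, key=lambda j: abs(pos[j] - tgt))
        if abs(pos[best] - tgt) > spacing / 2:
            warnings.warn(
                f"no flanking SNP within {spacing/2:.0f} bp of offset {tgt:.0f}; "
                "using nearest available",
                stacklevel=2,
            )
        chosen.append(best)
        pool.remove(best)
    return chosen


def multilocus_refit(
    region: CandidateRegion,
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    K: int,
    retained: Optional[np.ndarray] = None,
    spacing: float = 250_000.0,
    N_e: Optional[int] = None,
) -> pd.DataFrame:
    """Refit each retained site inside the region as the selected locus of a
    K-locus model with K-1 fixed flanking neutral SNPs; returns a table of
    per-site Lambda and s-hat.  K = 1 degenerates to the one-locus scan
    restricted to the region."""
    if retained is None:
        retained = np.arange(panel.n_sites)
    pos = panel.positions
    in_region = [j for j in retained if region.start <= pos[j] < region.end]
    if K == 1:
        res = inf.scan_1locus(data, design, panel, N_e=N_e, sites=in_region)
        return res.table
    flankers = _pick_flankers(panel, retained, region, K, spacing)
    rows = []
    for site in in_region:
        lam, s_hat = inf.lr_statistic(
            data, design, panel, site, K=K, N_e=N_e, companions=flankers
        )
        rows.append({"site": site, "position": pos[site], "lam": lam, "s_hat": s_hat})
    return pd.DataFrame(rows)


def top_k_intersection(
    model_tables: dict[int, pd.DataFrame], k: int
) -> pd.DataFrame:
    """Intersection of the per-model top-k site lists, ordered by the
    maximum Lambda across models (descending, ties by position)."""
    if not model_tables:
        raise ValueError("need at least one model table")
    top_sets = []
    for tab in model_tables.values():
        ranked = tab.sort_values(["lam", "position"], ascending=[False, True])
        top_sets.append(set(ranked.head(k)["site"]))
    common = set.intersection(*top_sets)
    merged = pd.concat(model_tables.values())
    out = (
        merged[merged.site.isin(common)]
        .groupby("site")
        .agg(position=("position", "first"), max_lam=("lam", "max"))
        .reset_index()
        .sort_values(["max_lam", "position"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def two_pass_scan(
    data: sd.TrajectoryData,
    design: sd.ExperimentDesign,
    panel: sd.FounderPanel,
    config: ScanConfig = ScanConfig(),
    N_e: Optional[int] = None,
    pass1_only: bool = False,
) -> dict:
    """Full pipeline: MAF filter, one-locus scan, window averaging, region
    nomination, multi-locus refits, and the top-k intersection.  Returns a
    dict with all intermediate tables (deterministic given data and
    config)."""
    retained = maf_filter(data, config.maf_bounds)
    if retained.size == 0:
        raise ValueError("no sites pass the MAF filter")
    pass1 = inf.scan_1locus(data, design, panel, N_e=N_e, sites=retained).table
    windows = {
        w: window_average(
            pass1["position"].to_numpy(), pass1["lam"].to_numpy(), w, panel.region_length
        )
        for w in config.window_sizes
    }
    primary = windows[config.window_sizes[0]]
    regions = select_candidate_regions(primary, q=config.region_quantile)
    out = {
        "retained": retained,
        "pass1": pass1,
        "windows": windows,
        "regions": regions,
    }
    if pass1_only:
        return out
    refits: dict[int, pd.DataFrame] = {}
    for K in config.model_sizes:
        tables = []
        for region in regions:
            tables.append(
                multilocus_refit(
                    region, data, design, panel, K,
                    retained=retained, spacing=config.flank_spacing, N_e=N_e,
                )
            )
        refits[K] = (
            pd.concat(tables, ignore_index=True) if tables else
            pd.DataFrame(columns=["site", "position", "lam", "s_hat"])
        )
    out["refits"] = refits
    nonempty = {K: t for K, t in refits.items() if len(t)}
    out["final"] = (
        top_k_intersection(nonempty, config.top_k) if nonempty else
        pd.DataFrame(columns=["site", "position", "max_lam"])
    )
    return out
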