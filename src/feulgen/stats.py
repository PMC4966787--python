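"""Descriptive and comparative statistics for image-cytometry samples.

Mirrors the reporting conventions of Feulgen DNA cytometry: per-sample
descriptive rows (n, skewness, kurtosis, mean DNA pg ± SD, mean nuclear
area ± SD, CV, SE, 95% CI), exact pooling of rows into a Total row,
nonparametric group comparison (Kruskal–Wallis with Dunn's post tests),
DNA–area correlation, fold-C histograms with a near-Gaussian flag, and
two small qPCR ΔCT helpers.

Conventions (recorded here because printed tables rarely state them):
SDs use the n−1 denominator; skewness is the adjusted Fisher–Pearson
estimator; kurtosis is excess (Fisher) kurtosis with bias correction;
the 95% CI uses the normal multiplier 1.96, not a t quantile. CV is
reported on nuclear areas (the convention the descriptive rows follow)
and DCV — the DNA content variation — is the same ratio on pg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.signal import find_peaks

CI_MULTIPLIER = 1.96


@dataclass
class SampleSummary:
    """One descriptive-statistics row for a sample of nuclei."""

    sample_id: str
    n: int
    skewness: float
    kurtosis: float  # excess (Fisher)
    mean_pg: float
    sd_pg: float
    mean_area_um2: float
    sd_area_um2: float
    cv_area_percent: float = float("nan")
    dcv_percent: float = float("nan")
    se_area_um2: float = float("nan")
    ci95_area_um2: tuple[float, float] = (float("nan"), float("nan"))
    origin: str = ""
    notes: frozenset[str] = frozenset()

    @classmethod
    def from_moments(
        cls,
        sample_id: str,
        n: int,
        mean_pg: float,
        sd_pg: float,
        mean_area_um2: float,
        sd_area_um2: float,
        skewness: float = float("nan"),
        kurtosis: float = float("nan"),
        origin: str = "",
        notes: frozenset[str] = frozenset(),
    ) -> "SampleSummary":
        """Build a row from first and second moments, deriving CV/SE/CI."""
        se = sd_area_um2 / math.sqrt(n) if n > 0 else float("nan")
        return cls(
            sample_id=sample_id,
            n=n,
            skewness=skewness,
            kurtosis=kurtosis,
            mean_pg=mean_pg,
            sd_pg=sd_pg,
            mean_area_um2=mean_area_um2,
            sd_area_um2=sd_area_um2,
            cv_area_percent=_cv(mean_area_um2, sd_area_um2),
            dcv_percent=_cv(mean_pg, sd_pg),
            se_area_um2=se,
            ci95_area_um2=(
                mean_area_um2 - CI_MULTIPLIER * se,
                mean_area_um2 + CI_MULTIPLIER * se,
            ),
            origin=origin,
            notes=notes,
        )


def _cv(mean: float, sd: float) -> float:
    if mean == 0 or not np.isfinite(mean):
        return float("nan")
    return sd / mean * 100.0


def describe_sample(
    pg: np.ndarray,
    areas_um2: np.ndarray,
    sample_id: str = "",
    origin: str = "",
) -> SampleSummary:
    """Descriptive row for raw per-nucleus DNA masses and areas.

    Degenerate inputs are reported rather than raised: n < 2 leaves the
    SD-derived fields as NaN with a note, and a constant sample (zero
    variance) reports skewness/kurtosis as 0 with a ``degenerate`` note.
    """
    pg = np.asarray(pg, dtype=float)
    areas = np.asarray(areas_um2, dtype=float)
    if pg.size != areas.size:
        raise ValueError("pg and area vectors differ in length")
    if pg.size < 1:
        raise ValueError("empty sample")
    n = pg.size
    notes: set[str] = set()
    if n < 2:
        notes.add("n_lt_2_sd_undefined")
        return SampleSummary.from_moments(
            sample_id, n, float(pg.mean()), float("nan"),
            float(areas.mean()), float("nan"),
            origin=origin, notes=frozenset(notes),
        )
    sd_pg = float(pg.std(ddof=1))
    if sd_pg == 0:
        skew = kurt = 0.0
        notes.add("degenerate_constant_sample")
    else:
        skew = float(sps.skew(pg, bias=False))
        kurt = float(sps.kurtosis(pg, fisher=True, bias=False))
    return SampleSummary.from_moments(
        sample_id, n,
        float(pg.mean()), sd_pg,
        float(areas.mean()), float(areas.std(ddof=1)),
        skewness=skew, kurtosis=kurt,
        origin=origin, notes=frozenset(notes),
    )


def pool_samples(
    summaries: list[SampleSummary], sample_id: str = "Total"
) -> SampleSummary:
    """Pool descriptive rows into a Total row, exactly.

    The pooled mean is the n-weighted mean and the pooled SD combines
    within- and between-sample sums of squares,

        s² = [Σ(nᵢ−1)sᵢ² + Σnᵢ(x̄ᵢ−x̄)²] / (N−1),

    which reproduces ``describe_sample`` on the concatenated raw data
    when the row statistics are exact. Skewness/kurtosis are not poolable
    from second moments and are reported as NaN.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to pool")
    n = np.array([s.n for s in summaries], dtype=float)

    def _pool(means: np.ndarray, sds: np.ndarray) -> tuple[float, float]:
        total = n.sum()
        mean = float((n * means).sum() / total)
        ss = ((n - 1) * sds**2).sum() + (n * (means - mean) ** 2).sum()
        return mean, float(math.sqrt(ss / (total - 1)))

    mean_area, sd_area = _pool(
        np.array([s.mean_area_um2 for s in summaries]),
        np.array([s.sd_area_um2 for s in summaries]),
    )
    mean_pg, sd_pg = _pool(
        np.array([s.mean_pg for s in summaries]),
        np.array([s.sd_pg for s in summaries]),
    )
    return SampleSummary.from_moments(
        sample_id, int(n.sum()), mean_pg, sd_pg, mean_area, sd_area,
        notes=frozenset({"pooled"}),
    )


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


@dataclass
class GroupComparison:
    """Kruskal–Wallis omnibus test plus Dunn's pairwise post tests."""

    h_statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjust: str = "none",
) -> GroupComparison:
    """Nonparametric unmatched comparison of per-sample DNA contents.

    Runs the tie-corrected Kruskal–Wallis test (chi-square p) and Dunn's
    rank-based pairwise z tests. ``adjust`` ∈ {none, bonferroni, holm}
    controls the multiplicity correction of the pairwise p values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
    pooled = np.concatenate(list(arrays.values()))
    if np.all(pooled == pooled[0]):
        # all observations tied: no evidence of any difference
        names = list(arrays)
        pairs = [
            PairwiseResult(a, b, 0.0, 1.0, 1.0)
            for i, a in enumerate(names) for b in names[i + 1 :]
        ]
        return GroupComparison(0.0, 1.0, pairs, alpha)
    h, p = sps.kruskal(*arrays.values())
    pairwise = _dunn(arrays, adjust)
    return GroupComparison(float(h), float(p), pairwise, alpha)


def _dunn(arrays: dict[str, np.ndarray], adjust: str) -> list[PairwiseResult]:
    names = list(arrays)
    sizes = {k: arrays[k].size for k in names}
    pooled = np.concatenate([arrays[k] for k in names])
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    mean_ranks = {}
    start = 0
    for k in names:
        mean_ranks[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(((counts**3) - counts).sum())
    var_term = big_n * (big_n + 1) / 12.0 - tie_sum / (12.0 * (big_n - 1))
    raw: list[tuple[str, str, float, float]] = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            denom = math.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / denom if denom > 0 else 0.0
            p = 2.0 * sps.norm.sf(abs(z))
            raw.append((a, b, z, p))
    p_adj = _adjust([r[3] for r in raw], adjust)
    return [
        PairwiseResult(a, b, z, p, pa)
        for (a, b, z, p), pa in zip(raw, p_adj)
    ]


def _adjust(pvals: list[float], method: str) -> list[float]:
    m = len(pvals)
    if method == "none" or m == 0:
        return list(pvals)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if method == "holm":
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        return adj.tolist()
    raise ValueError(f"unknown adjustment {method!r}")


def dna_area_correlation(pg, areas_um2) -> tuple[float, float, float]:
    """Pearson correlation of DNA mass against nuclear area.

    Returns (r, r², two-sided p). A strong positive relation indicates
    preserved nuclear structure: bigger nuclei carry more DNA.
    """
    pg = np.asarray(pg, dtype=float)
    areas = np.asarray(areas_um2, dtype=float)
    if pg.size != areas.size or pg.size < 3:
        raise ValueError("need at least 3 paired observations")
    if pg.std() == 0 or areas.std() == 0:
        raise ValueError("zero variance in pg or area")
    r, p = sps.pearsonr(pg, areas)
    return float(r), float(r**2), float(p)


@dataclass
class FoldHistogram:
    """Histogram of fold-C DNA values with modality diagnostics."""

    counts: np.ndarray
    bin_edges: np.ndarray
    modal_fold: float
    modes: list[float]
    skewness: float
    kurtosis: float
    near_gaussian: bool

    @property
    def unimodal(self) -> bool:
        return len(self.modes) == 1


def fold_histogram(
    folds,
    bin_width: float = 0.25,
    skew_limit: float = 2.0,
    kurtosis_limit: float = 3.0,
) -> FoldHistogram:
    """Bin fold-C values and flag a near-Gaussian (unimodal, 2C-like) shape.

    Modes are prominent local maxima of the binned counts; the
    near-Gaussian flag holds when |skewness| ≤ ``skew_limit`` and
    |excess kurtosis| ≤ ``kurtosis_limit`` (configurable working limits).
    """
    folds = np.asarray(folds, dtype=float)
    if folds.size == 0:
        raise ValueError("empty input")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(folds.min() / bin_width) * bin_width
    hi = math.ceil(folds.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(folds, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    padded = np.concatenate([[0], counts, [0]])
    peaks, _ = find_peaks(padded, prominence=max(1.0, 0.05 * counts.max()))
    modes = [float(centers[i - 1]) for i in peaks]
    modal = float(centers[int(np.argmax(counts))])
    if folds.std(ddof=0) == 0:
        skew = kurt = 0.0
    else:
        skew = float(sps.skew(folds, bias=False))
        kurt = float(sps.kurtosis(folds, fisher=True, bias=False))
    return FoldHistogram(
        counts=counts,
        bin_edges=edges,
        modal_fold=modal,
        modes=modes or [modal],
        skewness=skew,
        kurtosis=kurt,
        near_gaussian=abs(skew) <= skew_limit and abs(kurt) <= kurtosis_limit,
    )


def replicate_summary(ct_values) -> tuple[float, float]:
    """Mean and n−1 SD of qPCR threshold-cycle replicates, to 2 decimals."""
    ct = np.asarray(ct_values, dtype=float)
    if ct.size < 2:
        raise ValueError("need at least 2 replicates")
    return round(float(ct.mean()), 2), round(float(ct.std(ddof=1)), 2)


def delta_ct(mean_ct_target: float, mean_ct_reference: float) -> float:
    """ΔCT = CT(target gene) − CT(reference gene)."""
    if not (np.isfinite(mean_ct_target) and np.isfinite(mean_ct_reference)):
        raise ValueError("CT values must be finite")
    return float(mean_ct_target) - float(mean_ct_reference)


def summaries_to_frame(summaries: list[SampleSummary]):
    """Tabulate summary rows in the descriptive-table column order."""
    import pandas as pd

    return pd.DataFrame([{
        "sample_id": s.sample_id,
        "origin": s.origin,
        "n": s.n,
        "skewness": s.skewness,
        "kurtosis": s.kurtosis,
        "mean_pg": s.mean_pg,
        "sd_pg": s.sd_pg,
        "mean_area_um2": s.mean_area_um2,
        "sd_area_um2": s.sd_area_um2,
        "cv_area_percent": s.cv_area_percent,
        "dcv_percent": s.dcv_percent,
        "se_area_um2": s.se_area_um2,
        "ci95_low_um2": s.ci95_area_um2[0],
        "ci95_high_um2": s.ci95_area_um2[1],
    } for s in summaries])
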