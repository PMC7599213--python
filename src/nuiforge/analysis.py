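"""Saturation modeling, frame/genic annotation, and tissue specificity.

The saturation projection fits f(n) = a * n**b to the last ten
down-sampled points in log-log space (linear fallback when any point is
non-positive).  Tissue specificity uses Welch's unequal-variance t-test
of one tissue against all other samples pooled, on log2(count+1)
values, with Benjamini-Hochberg adjustment within each tissue; a gene is
tissue-specific when adjusted p < 0.05 and t > 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import RepresentativeNUI
from .formats import BedRecord, IntervalSet

logger = logging.getLogger(__name__)

GENIC_PRIORITY = ["coding_exon", "utr3", "utr5", "intron"]
INTERGENIC = "intergenic"

TISSUE_MIN_TOTAL_COUNT = 10
TISSUE_ALPHA = 0.05
TISSUE_MIN_T = 3.0
PROJECTION_POINTS = 10


# ---------------------------------------------------------------------------
# serialization records (CLI table rows)


@dataclass
class CurvePoint:
    n: int
    mean_count: float


@dataclass
class SampleNuiRecord:
    sample_id: str
    nui_id: str


@dataclass
class GenicAnnotation:
    nui_id: str
    genic_class: str
    regulatory: bool


# ---------------------------------------------------------------------------
# saturation / rarefaction


@dataclass
class SaturationCurve:
    n_samples: list[int]
    mean_counts: list[float]
    a: float | None = None
    b: float | None = None

    def point(self, n: int) -> float:
        return self.mean_counts[self.n_samples.index(n)]


def rarefaction(
    sample_to_ids: dict[str, set[str]], n_perm: int = 100, seed: int = 0
) -> SaturationCurve:
    """Mean cumulative distinct id count over seeded random sample orders."""
    if len(sample_to_ids) < 2:
        raise ValueError("rarefaction needs at least two samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = sorted(sample_to_ids)
    rng = np.random.default_rng(seed)
    k = len(samples)
    sums = np.zeros(k)
    for _ in range(n_perm):
        order = rng.permutation(k)
        seen: set[str] = set()
        for rank, idx in enumerate(order):
            seen |= sample_to_ids[samples[idx]]
            sums[rank] += len(seen)
    means = sums / n_perm
    return SaturationCurve(
        n_samples=list(range(1, k + 1)), mean_counts=[float(x) for x in means]
    )


def fit_power_law(ns: np.ndarray, ys: np.ndarray) -> tuple[float, float]:
    """Least squares for y = a * n**b in log-log space."""
    ln = np.log(ns)
    ly = np.log(ys)
    b, loga = np.polyfit(ln, ly, 1)
    return float(np.exp(loga)), float(b)


def project_growth(
    curve: SaturationCurve, n_points: int = PROJECTION_POINTS
) -> float:
    """Projected per-sample increment beyond the observed sample count.

    Fits the last ``n_points`` curve points to a power law; increment =
    f(N+1) - f(N).  Falls back to a linear fit when any usable point is
    non-positive.
    """
    ns = np.asarray(curve.n_samples[-n_points:], dtype=float)
    ys = np.asarray(curve.mean_counts[-n_points:], dtype=float)
    if len(ns) < 2:
        raise ValueError("need at least two points to project growth")
    big_n = float(curve.n_samples[-1])
    if np.all(ys > 0) and np.all(ns > 0):
        a, b = fit_power_law(ns, ys)
        curve.a, curve.b = a, b
        return a * (big_n + 1) ** b - a * big_n**b
    slope, _ = np.polyfit(ns, ys, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# frame and genic annotation


def frame_classify(
    nuis: list[RepresentativeNUI], size_class_max: int = 50
) -> tuple[dict[str, bool], float]:
    """In-frame (size % 3 == 0) flag per NUI, plus the in-frame fraction
    over NUIs below ``size_class_max``."""
    flags = {n.nui_id: n.insert_size % 3 == 0 for n in nuis}
    small = [n for n in nuis if n.insert_size < size_class_max]
    frac = (
        sum(1 for n in small if flags[n.nui_id]) / len(small) if small else float("nan")
    )
    return flags, frac


def annotate_genic(
    nuis: list[RepresentativeNUI],
    features: list[BedRecord],
    regulatory: list[BedRecord] | None = None,
) -> dict[str, tuple[str, bool]]:
    """Per NUI: highest-priority overlapped feature class (coding_exon >
    utr3 > utr5 > intron; none -> intergenic) plus a regulatory flag.

    Feature class is taken from the BED name column and must be one of
    the priority labels.
    """
    by_class = {
        label: IntervalSet.from_bed([f for f in features if f.name == label])
        for label in GENIC_PRIORITY
    }
    unknown = {f.name for f in features} - set(GENIC_PRIORITY)
    if unknown:
        raise ValueError(f"unknown feature classes: {sorted(unknown)}")
    reg_set = IntervalSet.from_bed(regulatory or [])
    out = {}
    for nui in nuis:
        s, e = nui.footprint
        label = INTERGENIC
        for cls in GENIC_PRIORITY:
            if by_class[cls].overlaps(nui.chrom, s, e):
                label = cls
                break
        out[nui.nui_id] = (label, reg_set.overlaps(nui.chrom, s, e))
    return out


# ---------------------------------------------------------------------------
# tissue specificity


@dataclass
class TissueCall:
    gene: str
    tissue: str
    t_stat: float
    p_raw: float
    p_adj: float
    specific: bool


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def tissue_specificity(
    counts: pd.DataFrame,
    tissue_labels: dict[str, str],
    min_total: int = TISSUE_MIN_TOTAL_COUNT,
    alpha: float = TISSUE_ALPHA,
    min_t: float = TISSUE_MIN_T,
) -> list[TissueCall]:
    """Welch-t tissue-vs-rest calls on log2-transformed counts.

    ``counts`` is genes x samples of raw counts.  Genes with fewer than
    ``min_total`` combined reads are excluded before the transform.
    Zero-variance degenerate comparisons are skipped with a log message.
    """
    samples = list(counts.columns)
    missing = [s for s in samples if s not in tissue_labels]
    if missing:
        raise ValueError(f"samples without tissue labels: {missing}")
    keep = counts.sum(axis=1) >= min_total
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d genes below the %d-read floor", n_dropped, min_total)
    filtered = counts.loc[keep]
    log_values = np.log2(filtered.to_numpy(dtype=float) + 1.0)
    genes = list(filtered.index)
    tissues = sorted(set(tissue_labels[s] for s in samples))
    calls: list[TissueCall] = []
    col_idx = np.arange(len(samples))
    for tissue in tissues:
        in_mask = np.array([tissue_labels[s] == tissue for s in samples])
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            raise ValueError(f"tissue {tissue!r} needs >= 2 samples on both sides")
        a = log_values[:, col_idx[in_mask]]
        b = log_values[:, col_idx[~in_mask]]
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        valid = np.isfinite(t) & np.isfinite(p)
        n_skipped = int((~valid).sum())
        if n_skipped:
            logger.info(
                "tissue %s: skipping %d zero-variance genes", tissue, n_skipped
            )
        p_adj = np.full(len(genes), np.nan)
        p_adj[valid] = _bh_adjust(p[valid])
        for i, gene in enumerate(genes):
            if not valid[i]:
                continue
            calls.append(
                TissueCall(
                    gene=gene,
                    tissue=tissue,
                    t_stat=float(t[i]),
                    p_raw=float(p[i]),
                    p_adj=float(p_adj[i]),
                    specific=bool(p_adj[i] < alpha and t[i] > min_t),
                )
            )
    return calls
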