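"""Test-retest and method-agreement statistics.

Connection-wise percentage change between two acquisitions, Bland-Altman
limits of agreement, Pearson correlation with Benjamini-Hochberg FDR
control across connection sets, Lin's concordance correlation
coefficient with a Fisher-z confidence interval, and bundle coverage
counting on a gray-white interface mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .apply import ScalarConnectome
from .atlas import AtlasModel

logger = logging.getLogger(__name__)


@dataclass
class ChangeMatrix:
    """Connection-wise percent change between two acquisitions."""

    codes: np.ndarray
    percent: np.ndarray
    valid: np.ndarray

    def values(self) -> np.ndarray:
        """Valid upper-triangle percent changes as a flat vector."""
        iu = np.triu_indices(len(self.codes), k=1)
        sel = self.valid[iu]
        return self.percent[iu][sel]


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    fdr_significant: bool
    n: int


@dataclass
class CoverageResult:
    """Per-voxel distinct-bundle counts on an interface mask."""

    counts: np.ndarray                       # full grid; 0 off the mask
    mask: np.ndarray
    histogram: pd.DataFrame                  # count -> voxels (overall)
    class_histograms: dict[int, pd.DataFrame]


def percent_change(c1: ScalarConnectome, c2: ScalarConnectome) -> ChangeMatrix:
    """Element-wise percent change (c2 - c1) / c1 * 100.

    Defined only where both connectomes are valid and the baseline is
    nonzero; everywhere else the entry is flagged invalid (never +-inf).
    Requires matching scale, thresholds and region set.
    """
    if c1.scale != c2.scale:
        raise ValueError("connectomes are at different scales")
    if (c1.p_thr, c1.c_thr) != (c2.p_thr, c2.c_thr):
        raise ValueError("connectomes were computed with different thresholds")
    if not np.array_equal(c1.codes, c2.codes):
        raise ValueError("connectomes have different region sets")
    valid = c1.valid & c2.valid & (c1.mean != 0)
    percent = np.zeros_like(c1.mean)
    percent[valid] = (c2.mean[valid] - c1.mean[valid]) / c1.mean[valid] * 100.0
    return ChangeMatrix(codes=c1.codes, percent=percent, valid=valid)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(y - x), limits of agreement
    bias +- 1.96 x sample SD of the differences (ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, n=x.size
    )


def lin_ccc(x, y, alpha: float = 0.05) -> CCCResult:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2) with
    population (1/n) moments.  The confidence interval uses the
    asymptotic variance of the z-transformed coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    mx, my = x.mean(), y.mean()
    sx2 = float(((x - mx) ** 2).mean())
    sy2 = float(((y - my) ** 2).mean())
    sxy = float(((x - mx) * (y - my)).mean())
    if sx2 == 0.0 or sy2 == 0.0:
        raise ValueError("zero variance in x or y")
    ccc = 2.0 * sxy / (sx2 + sy2 + (mx - my) ** 2)

    r = sxy / np.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    c = abs(ccc)
    if c >= 1.0 or r == 0.0:
        se_z = 0.0
    else:
        se_z2 = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
            + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
            - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
        se_z = float(np.sqrt(max(se_z2, 0.0)))
    z = np.arctanh(np.clip(ccc, -1 + 1e-15, 1 - 1e-15))
    q = stats.norm.ppf(1 - alpha / 2)
    lo = float(np.tanh(z - q * se_z))
    hi = float(np.tanh(z + q * se_z))
    return CCCResult(ccc=float(ccc), ci_low=min(lo, ccc), ci_high=max(hi, ccc), n=n)


def correlate_fdr(pair_sets, q: float = 0.05) -> list[CorrelationResult | None]:
    """Pearson correlation per paired set with BH-FDR control across sets.

    ``pair_sets`` is a list of (x, y) paired vectors.  A set with a
    constant vector is invalid (returned as None) and excluded from the
    correction; the remaining p-values are corrected at level ``q``
    (Benjamini-Hochberg) and flagged significant accordingly.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    results: list[CorrelationResult | None] = []
    pvals, live = [], []
    for k, (x, y) in enumerate(pair_sets):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("correlate_fdr: set %d is constant/too short; excluded", k)
            results.append(None)
            continue
        r, p = stats.pearsonr(x, y)
        results.append(CorrelationResult(r=float(r), p=float(p), fdr_significant=False, n=x.size))
        pvals.append(p)
        live.append(k)
    if pvals:
        reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
        for k, rej in zip(live, reject):
            results[k].fdr_significant = bool(rej)
    return results


def coverage_map(
    a: AtlasModel,
    interface: np.ndarray,
    voxel_classes: np.ndarray | None = None,
    p_thr: float = 0.0,
) -> CoverageResult:
    """Distinct-bundle count per voxel of a gray-white interface mask.

    For every voxel of the binary ``interface`` mask, counts the retained
    bundles whose thresholded support contains it, and histograms the
    counts overall and per optional voxel-class label (e.g. a
    gyral/sulcal split supplied as an integer label volume).
    """
    from .apply import bundle_voxel_set

    interface = np.asarray(interface).astype(bool)
    if interface.shape != tuple(a.header.dim):
        raise ValueError("interface grid does not match the atlas grid")
    counts = np.zeros(a.header.dim, dtype=np.int64)
    for pair in a.pairs:
        vox = bundle_voxel_set(a, pair, p_thr)
        if vox.shape[0]:
            counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    counts = np.where(interface, counts, 0)

    def hist(values: np.ndarray) -> pd.DataFrame:
        uniq, freq = np.unique(values, return_counts=True)
        return pd.DataFrame({"bundle_count": uniq, "voxels": freq})

    overall = hist(counts[interface])
    class_hists: dict[int, pd.DataFrame] = {}
    if voxel_classes is not None:
        voxel_classes = np.asarray(voxel_classes)
        if voxel_classes.shape != interface.shape:
            raise ValueError("voxel_classes grid does not match the atlas grid")
        for label in np.unique(voxel_classes[interface]):
            sel = interface & (voxel_classes == label)
            class_hists[int(label)] = hist(counts[sel])
    return CoverageResult(
        counts=counts, mask=interface, histogram=overall, class_histograms=class_hists
    )


# ---------------------------------------------------------------------------
# Optional plot exports (agreement and coverage figures).
# ---------------------------------------------------------------------------

def plot_bland_altman(x, y, path) -> None:
    """Scatter of differences vs means with bias and limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, y - x, s=6, alpha=0.5)
    for v, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(v, linestyle=style, color="k")
    ax.set_xlabel("mean of paired values")
    ax.set_ylabel("difference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_identity_scatter(x, y, path) -> None:
    """Scatter with the identity line (method-agreement view)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=6, alpha=0.5)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=1)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
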