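"""Empirical upper-tail selection of candidate markers.

The per-marker variance shares are treated as draws from a right-skewed
distribution.  Moment diagnostics (sample skewness and kurtosis with a
bootstrap cloud, in the style of a Cullen-Frey plot) guide the choice
between Beta and Gamma; the chosen family is fitted by maximum
likelihood and markers whose share exceeds the fitted quantile at
CDF 1 - level (default level 1e-5, the "top 0.001%") are selected.
Overlap between scenario selections is counted on genomic intervals so
a pseudo-SNP block and an NCSNP at the same locus can match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TOP_LEVEL_DEFAULT = 1e-5  # "top 0.001%" upper-tail mass


@dataclass
class MomentDiagnostics:
    skewness: float
    kurtosis: float         # plain (non-excess) kurtosis, 3 for a normal
    boot_skewness: np.ndarray
    boot_kurtosis: np.ndarray
    n: int


@dataclass
class DistributionFit:
    family: str             # "beta" or "gamma"
    params: dict
    loglik: float
    ks_stat: float          # max |empirical - fitted CDF|
    qq: np.ndarray          # (n, 2) theoretical vs empirical quantiles
    pp: np.ndarray
    scale_divisor: float    # values were divided by this before fitting


@dataclass
class TopSelection:
    level: float
    threshold: float        # on the original (percent) scale
    selected: pd.DataFrame  # marker rows with value > threshold


def moment_diagnostics(values: np.ndarray, n_boot: int = 10_000,
                       seed: int = 0) -> MomentDiagnostics:
    """Sample skewness/kurtosis with a bootstrap cloud.

    Requires at least 4 distinct values and non-zero variance.
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 4:
        raise ValueError("need at least 4 distinct values for kurtosis")
    if v.std() == 0:
        raise ValueError("zero variance")
    rng = np.random.default_rng(seed)
    sk = float(stats.skew(v))
    ku = float(stats.kurtosis(v, fisher=False))
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    bs = stats.skew(v[idx], axis=1)
    bk = stats.kurtosis(v[idx], axis=1, fisher=False)
    return MomentDiagnostics(sk, ku, bs, bk, len(v))


def _gamma_locus_kurtosis(s: float) -> float:
    # Gamma family: skew = 2/sqrt(a), kurt = 3 + 6/a  =>  kurt = 3 + 1.5 s²
    return 3.0 + 1.5 * s * s


def choose_family(diag: MomentDiagnostics) -> str:
    """Pick Beta or Gamma from the skewness-kurtosis point.

    The Gamma locus is the curve k = 3 + 1.5 s²; the Beta family
    occupies the region between the boundary k = 1 + s² and that curve,
    meeting it in the limit shape2 -> inf.  The observed point's signed
    gap below the curve is bias-corrected with the bootstrap cloud
    (sample moments of skewed data sit systematically below their
    population values); the point must fall below the curve by more
    than the bootstrap spread to select Beta, otherwise Gamma — which
    also takes exact ties, being the Beta region's limiting boundary.

    Near the boundary (Beta with a large second shape) the two families
    are statistically indistinguishable and the rule defaults to Gamma.
    """
    gap = _gamma_locus_kurtosis(diag.skewness) - diag.kurtosis  # >0: below curve
    boot_gap = _gamma_locus_kurtosis(diag.boot_skewness) - diag.boot_kurtosis
    corrected = 2.0 * gap - float(np.mean(boot_gap))  # bootstrap bias correction
    spread = float(np.std(boot_gap))
    if corrected > max(spread, 1e-12):
        return "beta"
    return "gamma"


def choose_family_likelihood(values: np.ndarray, scale_divisor: float = 100.0,
                             margin: float = 3.0) -> str:
    """Choose Beta vs Gamma by penalized maximum-likelihood comparison.

    The Beta family contains Gamma as its shape2 -> inf boundary, so a
    raw likelihood comparison always drifts toward Beta; Beta is chosen
    only when its fit beats Gamma's by more than ``margin`` nats (the
    Beta log-likelihood includes the Jacobian of the /scale_divisor
    rescale so both are on the data scale).  Near-boundary data where
    the families are indistinguishable resolve to Gamma.
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    f_g = fit_distribution(v, "gamma")
    try:
        f_b = fit_distribution(v, "beta", scale_divisor=scale_divisor)
    except (ValueError, RuntimeError):
        return "gamma"
    ll_b = f_b.loglik - v.size * np.log(f_b.scale_divisor)
    return "beta" if ll_b - f_g.loglik > margin else "gamma"


def fit_distribution(values: np.ndarray, family: str,
                     scale_divisor: float | None = None) -> DistributionFit:
    """Maximum-likelihood Beta or Gamma fit with goodness-of-fit summaries.

    Values must be positive; exact zeros are excluded upstream.  For a
    Beta fit, percent values are rescaled into (0, 1) by
    ``scale_divisor`` (default 100).
    """
    v = np.asarray(values, dtype=float)
    v = v[v > 0]
    if v.size < 2 or np.all(v == v[0]):
        raise ValueError("degenerate values: cannot fit a distribution")
    if family == "gamma":
        div = 1.0 if scale_divisor is None else scale_divisor
        x = v / div
        shape, loc, scale = stats.gamma.fit(x, floc=0)
        dist = stats.gamma(shape, loc=0, scale=scale)
        params = {"shape": shape, "rate": 1.0 / scale}
    elif family == "beta":
        div = 100.0 if scale_divisor is None else scale_divisor
        x = v / div
        if np.any(x >= 1):
            raise ValueError("beta fit needs values strictly inside (0, scale_divisor)")
        a, b, loc, scale = stats.beta.fit(x, floc=0, fscale=1)
        dist = stats.beta(a, b)
        params = {"shape1": a, "shape2": b}
    else:
        raise ValueError(f"unknown family {family!r}")
    if not all(p > 0 and np.isfinite(p) for p in params.values()):
        raise RuntimeError("non-convergent fit: parameters not positive/finite")
    xs = np.sort(x)
    n = xs.size
    emp = (np.arange(1, n + 1) - 0.5) / n
    cdf = dist.cdf(xs)
    return DistributionFit(
        family=family, params=params,
        loglik=float(np.sum(dist.logpdf(xs))),
        ks_stat=float(np.max(np.abs(emp - cdf))),
        qq=np.column_stack([dist.ppf(emp), xs]),
        pp=np.column_stack([emp, cdf]),
        scale_divisor=div,
    )


def select_top(values: np.ndarray, fit: DistributionFit,
               level: float = TOP_LEVEL_DEFAULT,
               meta: pd.DataFrame | None = None) -> TopSelection:
    """Markers above the fitted upper-``level`` quantile.

    The threshold is the fitted quantile at CDF 1 - level, mapped back
    to the original scale; strictly greater values are selected.
    """
    if fit.family == "gamma":
        dist = stats.gamma(fit.params["shape"], loc=0, scale=1.0 / fit.params["rate"])
    else:
        dist = stats.beta(fit.params["shape1"], fit.params["shape2"])
    thr = float(dist.ppf(1.0 - level)) * fit.scale_divisor
    v = np.asarray(values, dtype=float)
    mask = v > thr
    if meta is None:
        sel = pd.DataFrame({"index": np.where(mask)[0], "value": v[mask]})
    else:
        sel = meta.loc[mask].copy()
        sel["value"] = v[mask]
    return TopSelection(level=level, threshold=thr, selected=sel)


# ---------------------------------------------------------------------------
# Overlap bookkeeping
# ---------------------------------------------------------------------------

def _as_intervals(sel: pd.DataFrame) -> list[tuple[int, int, int]]:
    """(chrom, start, end) per selected marker; point markers get start=end."""
    out = []
    for _, r in sel.iterrows():
        chrom = int(r["chrom"])
        if "start" in r and "end" in r and not pd.isna(r.get("start")):
            out.append((chrom, int(r["start"]), int(r["end"])))
        else:
            p = int(r["pos"])
            out.append((chrom, p, p))
    return out


def _overlaps(a: tuple[int, int, int], b: tuple[int, int, int]) -> bool:
    return a[0] == b[0] and a[1] <= b[2] and b[1] <= a[2]


def overlap_report(selections: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Intersection cardinalities among named selections.

    For every non-empty subset of scenario names, counts the regions of
    the subset's first selection that overlap at least one region in
    every other member.  Matching is by genomic interval so pseudo-SNPs
    and NCSNPs at the same locus can coincide.
    """
    from itertools import combinations

    names = list(selections)
    ivals = {k: _as_intervals(v) for k, v in selections.items()}
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            base = ivals[combo[0]]
            count = 0
            for iv in base:
                if all(any(_overlaps(iv, jv) for jv in ivals[other])
                       for other in combo[1:]):
                    count += 1
            rows.append(("&".join(combo), r, count))
    return pd.DataFrame(rows, columns=["sets", "order", "n_common"])
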