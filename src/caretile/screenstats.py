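"""Tiling-screen scoring: guide-level null tests, sliding-window mixed
linear models, bin merging, and final element scores.

The per-bin model is a Gaussian random-intercept model: fixed intercept and
fixed day (time) effect, a random intercept per guide, fitted by full
maximum likelihood and compared with a likelihood-ratio test against the
reduced model without the time term (chi-square, df = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import bh_adjust

LOG_PSEUDOCOUNT = 0.5  # added to normalized means before log10

#: count of negative LRT statistics clipped to zero (numeric noise monitor)
negative_lrt_clips = 0


@dataclass
class WindowFit:
    """Result of one sliding-window mixed-model fit."""

    chrom: str
    start: int
    end: int
    guides_used: list[str]
    lrt_stat: float
    df: int
    p: float
    slope: float
    ll_full: float
    ll_reduced: float
    singular: bool = False
    adj_p: float = float("nan")


@dataclass
class CaRE:
    """A called element: merged significant bins plus a refit score."""

    id: str
    chrom: str
    start: int
    end: int
    direction: str
    member_guides: list[str] = field(default_factory=list)
    p: float = float("nan")
    adj_p: float = float("nan")
    score: float = float("nan")
    slope: float = float("nan")
    flagged: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# count preprocessing


def normalize_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample column."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {', '.join(map(str, zero.index))}")
    return counts / totals * 1e6


def timepoint_means(normalized: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns into one column per day (columns = days)."""
    missing = set(samples["sample"]) - set(normalized.columns)
    if missing:
        raise ValueError(f"samples missing from count table: {sorted(missing)}")
    out = {}
    for day, grp in samples.groupby("day"):
        out[float(day)] = normalized[list(grp["sample"])].mean(axis=1)
    means = pd.DataFrame(out)
    return means[sorted(means.columns)]


def guide_lfc(
    means: pd.DataFrame, first_day: float, last_day: float, pseudocount: float = 0.5
) -> pd.Series:
    """log2 fold change of each guide between the first and last timepoints."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for day in (first_day, last_day):
        if float(day) not in means.columns:
            raise ValueError(f"day {day} not present in timepoint means")
    lfc = np.log2((means[float(last_day)] + pseudocount) / (means[float(first_day)] + pseudocount))
    lfc.name = "lfc"
    return lfc


def guide_pvalues(
    lfcs: pd.Series,
    control_ids: set[str],
    two_sided: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score guides against a normal null fitted to control-guide LFCs.

    Returns a table with lfc, p, adj_p (BH) and direction
    (enriched/depleted/ns at ``alpha`` on the adjusted p-value).
    """
    ctrl = lfcs[lfcs.index.isin(control_ids)]
    ctrl = ctrl[np.isfinite(ctrl)]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control guides with finite lfc")
    mu, sd = float(ctrl.mean()), float(ctrl.std(ddof=1))
    if sd == 0:
        raise ValueError("control lfc standard deviation is zero")
    z = (lfcs - mu) / sd
    if two_sided:
        p = 2 * stats.norm.sf(np.abs(z))
    else:
        p = stats.norm.sf(z)
    adj = bh_adjust(np.asarray(p))
    direction = np.where(adj < alpha, np.where(lfcs > mu, "enriched", "depleted"), "ns")
    return pd.DataFrame(
        {"lfc": lfcs, "p": p, "adj_p": adj, "direction": direction}, index=lfcs.index
    )


# ---------------------------------------------------------------------------
# random-intercept ML


def _profiled_negll2(lam, m, XtX, Xt1, X_ty, s, yty, N):
    """-2 log-likelihood profiled over beta and sigma^2 at ratio lam.

    lam = var(random intercept) / var(residual); per-group covariance is
    sigma^2 (I + lam J) whose inverse subtracts lam/(1+lam*m) J.
    """
    c = lam / (1.0 + lam * m)  # per-group shrinkage
    A = XtX - (Xt1.T * c) @ Xt1
    b = X_ty - Xt1.T @ (c * s)
    q = yty - float(c @ (s * s))
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rss = q - float(beta @ b)
    if rss <= 0:
        return np.inf, beta, 0.0
    sigma2 = rss / N
    val = N * np.log(sigma2) + float(np.log1p(lam * m).sum()) + N * (1.0 + np.log(2 * np.pi))
    return val, beta, sigma2


def _fit_random_intercept(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML fit of y = X beta + b_group + eps with scalar random intercepts.

    The likelihood is profiled over (beta, sigma^2) and maximized over the
    variance ratio on a log grid refined by bounded 1-D optimization; the
    boundary (ratio 0, plain OLS) is always a candidate. Returns
    (loglik, beta, sigma2, tau2).
    """
    uniq, gidx = np.unique(groups, return_inverse=True)
    G, N, p = uniq.size, y.size, X.shape[1]
    m = np.bincount(gidx, minlength=G).astype(float)
    Xt1 = np.zeros((G, p))
    for j in range(p):
        Xt1[:, j] = np.bincount(gidx, weights=X[:, j], minlength=G)
    s = np.bincount(gidx, weights=y, minlength=G)
    XtX = X.T @ X
    X_ty = X.T @ y
    yty = float(y @ y)

    # balanced shortcut: equal group sizes and identical per-group design
    # rows make the GLS estimate coincide with OLS, and the variance
    # components then have a closed-form ML solution.
    if m.min() == m.max() and np.allclose(Xt1, Xt1[0]):
        mm = float(m[0])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        if rss <= 1e-10 * max(1.0, yty):  # numerically perfect fit
            return 0.0, beta, 0.0, 0.0
        rbar = np.bincount(gidx, weights=r, minlength=G) / mm
        B = mm * float(rbar @ rbar)
        W = max(rss - B, 0.0)
        if W > 1e-12 and G < N:
            sigma2 = W / (N - G)
            c = B / (G * sigma2)
            if c > 1.0:
                lam = (c - 1.0) / mm
                ll = -0.5 * (N * np.log(sigma2) + G * np.log(c) + N * (1 + np.log(2 * np.pi)))
                return ll, beta, sigma2, lam * sigma2
        # boundary or degenerate: plain OLS maximum likelihood
        sigma2 = rss / N
        if sigma2 <= 1e-300:
            return 0.0, beta, 0.0, 0.0
        ll = -0.5 * N * (np.log(2 * np.pi * sigma2) + 1.0)
        return ll, beta, sigma2, 0.0

    def obj(t):
        return _profiled_negll2(np.exp(t), m, XtX, Xt1, X_ty, s, yty, N)[0]

    # boundary candidate: lam = 0 (OLS)
    best_val, _, _ = _profiled_negll2(0.0, m, XtX, Xt1, X_ty, s, yty, N)
    best_lam = 0.0
    grid = np.linspace(-12.0, 8.0, 9)
    vals = [obj(t) for t in grid]
    k = int(np.argmin(vals))
    if vals[k] < best_val:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, grid.size - 1)]
        res = optimize.minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        cand = [(res.fun, float(np.exp(res.x))), (vals[k], float(np.exp(grid[k])))]
        cand_val, cand_lam = min(cand)
        if cand_val < best_val:
            best_val, best_lam = cand_val, cand_lam
    val, beta, sigma2 = _profiled_negll2(best_lam, m, XtX, Xt1, X_ty, s, yty, N)
    return -0.5 * val, beta, sigma2, best_lam * sigma2


def fit_window_lmm(y: np.ndarray, day: np.ndarray, guide: np.ndarray,
                   chrom: str = ".", start: int = 0, end: int = 0) -> WindowFit:
    """Likelihood-ratio test for a day effect with per-guide random intercepts.

    The full model (intercept + day + random guide intercept) and the reduced
    model (no day term) are both fitted by full ML; the LRT statistic is
    referred to chi-square with 1 df. A collapsed residual variance triggers
    the OLS fallback and flags the fit as singular.
    """
    global negative_lrt_clips
    y = np.asarray(y, dtype=float)
    day = np.asarray(day, dtype=float)
    guide = np.asarray(guide)
    if y.size != day.size or y.size != guide.size:
        raise ValueError("y, day, guide must be the same length")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.unique(guide).size < 2:
        raise ValueError("need at least 2 guides")
    if np.unique(day).size < 2:
        raise ValueError("need at least 2 distinct days")

    X_full = np.column_stack([np.ones_like(y), day])
    X_red = np.ones((y.size, 1))
    ll_full, beta, sigma2, _ = _fit_random_intercept(y, X_full, guide)
    ll_red, _, _, _ = _fit_random_intercept(y, X_red, guide)
    singular = False
    if not np.isfinite(ll_full) or not np.isfinite(ll_red) or sigma2 < 1e-12:
        # degenerate (e.g. perfectly constant response): ordinary least squares
        singular = True
        ll_full, beta = _ols_loglik(y, X_full)
        ll_red, _ = _ols_loglik(y, X_red)
    lrt = 2.0 * (ll_full - ll_red)
    if lrt < 0:
        if lrt < -1e-8:
            negative_lrt_clips += 1
            warnings.warn(f"negative LRT statistic {lrt:.3g} clipped to 0", RuntimeWarning)
        lrt = 0.0
    p = float(stats.chi2.sf(lrt, df=1)) if np.isfinite(lrt) else 1.0
    return WindowFit(
        chrom=chrom, start=start, end=end,
        guides_used=sorted(map(str, np.unique(guide))),
        lrt_stat=float(lrt), df=1, p=p, slope=float(beta[1]),
        ll_full=float(ll_full), ll_reduced=float(ll_red), singular=singular,
    )


def _ols_loglik(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = y.size
    rss = float(resid @ resid)
    if rss <= 1e-10 * max(1.0, float(y @ y)):
        return 0.0, beta  # perfect fit; LRT between two perfect fits -> 0
    sigma2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0), beta


# ---------------------------------------------------------------------------
# window scan and merging


def _log_response(means: pd.DataFrame, pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    return np.log10(means + pseudocount)


def scan_bins(
    means: pd.DataFrame,
    library: pd.DataFrame,
    region: tuple[str, int, int],
    bin_size: int = 100,
    window_bins: int = 1,
    pseudocount: float = LOG_PSEUDOCOUNT,
    col_days: np.ndarray | None = None,
) -> list[WindowFit]:
    """One mixed-model fit per bin over guides in the bin +/- ``window_bins``.

    ``means`` is a guides x columns table of normalized values; by default
    columns are timepoint means labeled by day. Passing ``col_days`` (one
    day per column) instead keeps replicate columns as observations for
    sensitivity analysis. Bins with fewer than 2 guides in the window are
    skipped (p = NaN). BH adjustment runs across tested bins only.
    """
    if window_bins < 0:
        raise ValueError("window_bins must be >= 0")
    chrom, rstart, rend = region
    logm = _log_response(means, pseudocount)
    if col_days is None:
        logm = logm[sorted(logm.columns)]
        days = np.array(sorted(logm.columns), dtype=float)
    else:
        days = np.asarray(col_days, dtype=float)
    lib = library[~library["is_control"] & (library["chrom"] == chrom)]
    pos = lib["start"].to_numpy()
    gids = lib["guide_id"].to_numpy()
    order = np.argsort(pos, kind="stable")
    pos, gids = pos[order], gids[order]
    rowpos = {g: i for i, g in enumerate(logm.index)}
    logmat = logm.to_numpy()
    rows = np.array([rowpos[g] for g in gids])

    fits: list[WindowFit] = []
    ext = window_bins * bin_size
    for bs in range(rstart, rend, bin_size):
        be = min(bs + bin_size, rend)
        lo = np.searchsorted(pos, bs - ext, side="left")
        hi = np.searchsorted(pos, be + ext, side="left")
        members = gids[lo:hi]
        if np.unique(members).size < 2:
            fits.append(WindowFit(chrom, bs, be, sorted(map(str, members)),
                                  float("nan"), 1, float("nan"), float("nan"),
                                  float("nan"), float("nan")))
            continue
        y = logmat[rows[lo:hi]].ravel()
        dd = np.tile(days, len(members))
        gg = np.repeat(np.arange(lo, hi), days.size)
        fit = fit_window_lmm(y, dd, gg, chrom=chrom, start=bs, end=be)
        fit.guides_used = sorted(map(str, members))
        fits.append(fit)

    pvec = np.array([f.p for f in fits])
    adj = bh_adjust(pvec)
    for f, a in zip(fits, adj):
        f.adj_p = float(a)
    return fits


def merge_bins(bins: list[WindowFit], max_gap: int = 500, alpha: float = 0.05) -> list[CaRE]:
    """Merge significant bins within ``max_gap`` bp into candidate elements.

    Only bins with the same slope sign merge; gap is measured end-to-start.
    Input bins must be disjoint (and on one chromosome); they are sorted
    internally.
    """
    sig = [b for b in bins if np.isfinite(b.adj_p) and b.adj_p < alpha]
    if not sig:
        return []
    chroms = {b.chrom for b in sig}
    if len(chroms) > 1:
        raise ValueError("merge_bins expects bins on a single chromosome")
    sig.sort(key=lambda b: b.start)
    for a, b in zip(sig, sig[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping bins at {a.chrom}:{a.start}-{a.end} and {b.start}-{b.end}")
    cares: list[CaRE] = []
    cur = [sig[0]]
    for b in sig[1:]:
        same_dir = np.sign(b.slope) == np.sign(cur[-1].slope)
        if b.start - cur[-1].end <= max_gap and same_dir:
            cur.append(b)
        else:
            cares.append(_bins_to_care(cur, len(cares)))
            cur = [b]
    cares.append(_bins_to_care(cur, len(cares)))
    return cares


def _bins_to_care(bins: list[WindowFit], idx: int) -> CaRE:
    guides = sorted({g for b in bins for g in b.guides_used})
    slope = float(np.mean([b.slope for b in bins]))
    return CaRE(
        id=f"care{idx:04d}",
        chrom=bins[0].chrom,
        start=bins[0].start,
        end=bins[-1].end,
        direction="depleted" if slope < 0 else "enriched",
        member_guides=guides,
        slope=slope,
    )


def score_cares(
    cares: list[CaRE],
    means: pd.DataFrame,
    library: pd.DataFrame,
    pseudocount: float = LOG_PSEUDOCOUNT,
) -> list[CaRE]:
    """Refit the mixed model on all member guides of each element.

    The final score is -log10 of the BH-adjusted p across all scored
    elements; direction comes from the refit slope sign (negative slope on
    abundance = depleted). Elements with <2 member guides are flagged and
    left unscored.
    """
    logm = _log_response(means, pseudocount)
    days = np.array(sorted(logm.columns), dtype=float)
    lib = library.set_index("guide_id")
    scored: list[CaRE] = []
    for care in cares:
        members = [g for g in care.member_guides if g in lib.index]
        if len(set(members)) < 2:
            care.flagged = True
            scored.append(care)
            continue
        sub = logm.loc[members, days]
        y = sub.to_numpy().ravel()
        dd = np.tile(days, len(members))
        gg = np.repeat(np.array(members), days.size)
        fit = fit_window_lmm(y, dd, gg, chrom=care.chrom, start=care.start, end=care.end)
        care.p = fit.p
        care.slope = fit.slope
        care.direction = "depleted" if fit.slope < 0 else "enriched"
        scored.append(care)
    ps = np.array([c.p if not c.flagged else np.nan for c in scored])
    adj = bh_adjust(ps)
    for c, a in zip(scored, adj):
        if not c.flagged:
            c.adj_p = float(a)
            c.score = float(-np.log10(max(a, 1e-300)))
    return scored


def call_cares(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    library: pd.DataFrame,
    region: tuple[str, int, int],
    bin_size: int = 100,
    window_bins: int = 1,
    alpha: float = 0.05,
    max_gap: int = 500,
    collapse_replicates: bool = True,
) -> tuple[pd.DataFrame, list[WindowFit], list[CaRE]]:
    """Full screen pipeline: CPM -> timepoint means -> guide stats -> bin
    scan -> merge -> element scores. Returns (guide table, bin fits, elements).

    ``collapse_replicates=False`` keeps replicate columns as observations in
    the mixed model instead of averaging them per day (sensitivity mode).
    """
    norm = normalize_cpm(counts)
    means = timepoint_means(norm, samples)
    days = sorted(means.columns)
    lfc = guide_lfc(means, days[0], days[-1])
    controls = set(library.loc[library["is_control"], "guide_id"])
    guide_table = guide_pvalues(lfc, controls, alpha=alpha)
    if collapse_replicates:
        fits = scan_bins(means, library, region, bin_size=bin_size, window_bins=window_bins)
    else:
        sheet = samples.set_index("sample").loc[list(norm.columns)]
        fits = scan_bins(
            norm, library, region, bin_size=bin_size, window_bins=window_bins,
            col_days=sheet["day"].to_numpy(),
        )
    cares = merge_bins(fits, max_gap=max_gap, alpha=alpha)
    cares = score_cares(cares, means, library)
    return guide_table, fits, cares


def window_fits_frame(fits: list[WindowFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [f.chrom for f in fits],
            "start": [f.start for f in fits],
            "end": [f.end for f in fits],
            "n_guides": [len(f.guides_used) for f in fits],
            "lrt_stat": [f.lrt_stat for f in fits],
            "df": [f.df for f in fits],
            "p": [f.p for f in fits],
            "adj_p": [f.adj_p for f in fits],
            "slope": [f.slope for f in fits],
            "singular": [f.singular for f in fits],
        }
    )


def cares_frame(cares: list[CaRE]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in cares],
            "chrom": [c.chrom for c in cares],
            "start": [c.start for c in cares],
            "end": [c.end for c in cares],
            "direction": [c.direction for c in cares],
            "n_guides": [len(c.member_guides) for c in cares],
            "p": [c.p for c in cares],
            "adj_p": [c.adj_p for c in cares],
            "score": [c.score for c in cares],
            "slope": [c.slope for c in cares],
            "flagged": [c.flagged for c in cares],
        }
    )
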