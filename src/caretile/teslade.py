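"""Targeted single-cell perturbation differential expression.

Guide assignment by bimodal thresholding, cell/gene filtering,
normalization with optional batch regression, and a covariate-adjusted
two-part (hurdle) test of each perturbation against a distal-guide
background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from ._glm import logistic_loglik
from ._stats import bh_adjust

log = logging.getLogger(__name__)

FALLBACK_MIN_COUNT = 2  # minimum molecules/cell when the mixture is degenerate
LFC_PSEUDOCOUNT = 0.1


@dataclass
class PerturbExpt:
    """Paired cells x genes and cells x guides count matrices.

    ``true_guides`` is simulation-only ground truth (cell -> guide ids) and
    is ignored by the analysis code.
    """

    gene_counts: pd.DataFrame
    guide_counts: pd.DataFrame
    run: pd.Series
    true_guides: dict[str, set[str]] | None = None

    def __post_init__(self):
        if not self.gene_counts.index.equals(self.guide_counts.index):
            raise ValueError("gene and guide matrices must share cell ids")
        if (self.gene_counts.to_numpy() < 0).any() or (self.guide_counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.run) != len(self.gene_counts):
            raise ValueError("run labels must cover every cell")

    @property
    def cells(self) -> pd.Index:
        return self.gene_counts.index

    @property
    def n_genes_detected(self) -> pd.Series:
        return (self.gene_counts > 0).sum(axis=1).rename("n_genes_detected")


@dataclass
class GuideAssignment:
    """Thresholded guide matrix plus the cut separating signal from noise."""

    guide_counts: pd.DataFrame  # low-mode entries zeroed
    threshold: float  # raw-count scale; values < threshold were zeroed
    method: str  # "gmm" or "fallback"

    def retained(self, cell: str) -> set[str]:
        row = self.guide_counts.loc[cell]
        return set(row.index[row > 0])


def threshold_guide_counts(guide_counts: pd.DataFrame) -> GuideAssignment:
    """Zero out the low mode of the bimodal guide-count distribution.

    A two-component Gaussian mixture is fitted to log10 of the nonzero
    counts; entries assigned to the lower component (posterior > 0.5) are
    set to zero. If the mixture is degenerate the fixed minimum of
    ``FALLBACK_MIN_COUNT`` molecules/cell applies instead.
    """
    mat = guide_counts.to_numpy()
    nz = mat[mat > 0]
    if nz.size == 0:
        raise ValueError("guide count matrix has no nonzero entries")
    logv = np.log10(nz.astype(float))
    threshold = float(FALLBACK_MIN_COUNT)
    method = "fallback"
    uniq = np.unique(logv)
    if uniq.size >= 2:
        gmm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(logv.reshape(-1, 1))
        means = gmm.means_.ravel()
        if abs(means[0] - means[1]) > 0.2:
            hi = int(np.argmax(means))
            # posterior > 0.5 for the low component defines a cut on the
            # raw-count grid: find the smallest count kept
            grid = np.unique(nz)
            post = gmm.predict_proba(np.log10(grid.astype(float)).reshape(-1, 1))[:, hi]
            kept = grid[post >= 0.5]
            if kept.size and kept.min() > grid.min():
                threshold = float(kept.min())
                method = "gmm"
    if method == "fallback":
        log.info("degenerate guide-count mixture; fixed min-count %d applied", FALLBACK_MIN_COUNT)
    out = guide_counts.where(guide_counts >= threshold, 0)
    return GuideAssignment(guide_counts=out, threshold=threshold, method=method)


def filter_cells_genes(
    expt: PerturbExpt,
    assignment: GuideAssignment,
    min_guide_signal: float = 2,
    min_gene_signal: int = 1,
) -> PerturbExpt:
    """Drop empty guides/genes and low-signal cells; idempotent.

    A cell needs a retained guide count >= ``min_guide_signal`` and at least
    ``min_gene_signal`` detected genes. Iterates to a fixed point because
    dropping genes can re-trip the cell rule.
    """
    if min_guide_signal < 0 or min_gene_signal < 0:
        raise ValueError("thresholds must be >= 0")
    genes = expt.gene_counts
    guides = assignment.guide_counts.loc[genes.index]
    run = expt.run.loc[genes.index]
    while True:
        guides = guides.loc[:, guides.sum(axis=0) > 0]
        genes = genes.loc[:, genes.sum(axis=0) > 0]
        ok = (guides.max(axis=1).reindex(genes.index, fill_value=0) >= min_guide_signal) & (
            (genes > 0).sum(axis=1) >= min_gene_signal
        )
        if ok.all() and (genes.sum(axis=0) > 0).all():
            break
        genes = genes.loc[ok]
        guides = guides.loc[ok]
        run = run.loc[ok]
        if len(genes) == 0:
            raise ValueError("all cells removed by filtering")
    if genes.shape[1] == 0 or guides.shape[1] == 0:
        raise ValueError("all genes or guides removed by filtering")
    tg = {c: s for c, s in (expt.true_guides or {}).items() if c in genes.index}
    return PerturbExpt(gene_counts=genes, guide_counts=guides, run=run,
                       true_guides=tg or None)


# ---------------------------------------------------------------------------
# normalization


def _log_normalize(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True).astype(float)
    totals[totals == 0] = 1.0
    scale = float(np.median(counts.sum(axis=1)))
    return np.log1p(counts / totals * scale)


def _pearson_nb(counts: np.ndarray) -> np.ndarray:
    """Regularized NB Pearson residuals with a depth offset.

    Per-gene dispersion is estimated by moments and smoothed against mean
    expression with a Gaussian kernel on the log scale; residuals are
    clipped at +/- sqrt(n_cells).
    """
    counts = counts.astype(float)
    n_cells, n_genes = counts.shape
    depth = counts.sum(axis=1)
    depth[depth == 0] = 1.0
    frac = counts.sum(axis=0) / depth.sum()
    mu = np.outer(depth, frac)  # expected counts per cell x gene
    gmean = counts.mean(axis=0)
    gvar = counts.var(axis=0)
    excess = np.maximum(gvar - gmean, 1e-8)
    theta_raw = np.maximum(gmean**2 / excess, 1e-3)
    # kernel-smooth log theta over log mean expression
    lx = np.log10(gmean + 1e-8)
    ly = np.log10(theta_raw)
    bw = max(0.3, (lx.max() - lx.min()) / 10 if n_genes > 1 else 0.3)
    w = np.exp(-0.5 * ((lx[:, None] - lx[None, :]) / bw) ** 2)
    theta = 10 ** (w @ ly / w.sum(axis=1))
    resid = (counts - mu) / np.sqrt(mu + mu**2 / theta[None, :] + 1e-12)
    clip = np.sqrt(n_cells)
    return np.clip(resid, -clip, clip)


def _regress_batch(values: np.ndarray, run: np.ndarray) -> np.ndarray:
    """Remove per-gene run means, keeping each gene's grand mean."""
    out = values.copy()
    grand = values.mean(axis=0)
    for r in np.unique(run):
        mask = run == r
        out[mask] -= out[mask].mean(axis=0)
    return out + grand


def normalize_expression(
    expt: PerturbExpt,
    method: str = "log_normalize",
    batch_regress: bool = True,
) -> pd.DataFrame:
    """Normalize gene counts; optionally regress out the run label per gene."""
    counts = expt.gene_counts.to_numpy()
    if method == "log_normalize":
        vals = _log_normalize(counts)
    elif method == "pearson_nb":
        vals = _pearson_nb(counts)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if batch_regress:
        runs = expt.run.to_numpy()
        if np.unique(runs).size < 2:
            warnings.warn("single run: batch regression is a no-op", RuntimeWarning)
        else:
            vals = _regress_batch(vals, runs)
    return pd.DataFrame(vals, index=expt.gene_counts.index, columns=expt.gene_counts.columns)


# ---------------------------------------------------------------------------
# background construction and the hurdle test


def build_background(
    locus: tuple[str, int],
    carrier_cells: set[str],
    assignment: GuideAssignment,
    library: pd.DataFrame,
    min_distance: int = 400_000,
) -> list[str]:
    """Cells whose every retained guide is a control or targets >= ``min_distance``
    from ``locus``; carrier cells and guide-free cells are excluded."""
    chrom, pos = locus
    lib = library.set_index("guide_id")
    mat = assignment.guide_counts
    cols = [g for g in mat.columns if g in lib.index]
    mat = mat[cols]
    gchrom = lib.loc[cols, "chrom"].to_numpy()
    gpos = lib.loc[cols, "start"].to_numpy()
    is_ctrl = lib.loc[cols, "is_control"].to_numpy().astype(bool)
    proximal = (~is_ctrl) & (gchrom == chrom) & (np.abs(gpos - pos) < min_distance)
    present = mat.to_numpy() > 0
    has_any = present.any(axis=1)
    has_proximal = present[:, proximal].any(axis=1) if proximal.any() else np.zeros(len(mat), bool)
    keep = has_any & ~has_proximal
    cells = [c for c, k in zip(mat.index, keep) if k and c not in carrier_cells]
    if not cells:
        raise ValueError(f"empty background for locus {chrom}:{pos}")
    return cells


def hurdle_test(
    values: np.ndarray,
    carrier: np.ndarray,
    covariate: np.ndarray,
) -> tuple[float, float, bool]:
    """Two-part test of carrier vs background with a per-cell covariate.

    Detection (value > 0) is modeled by logistic regression and positive
    values by a Gaussian linear model, each with a group term and the
    covariate; the combined LRT statistic is referred to chi-square df=2.
    Returns (p, log2 fold change of pseudocounted means, flagged).
    """
    values = np.asarray(values, dtype=float)
    carrier = np.asarray(carrier, dtype=bool)
    covariate = np.asarray(covariate, dtype=float)
    if carrier.sum() < 2 or (~carrier).sum() < 2:
        raise ValueError("need >= 2 carrier and >= 2 background cells")
    detected = values > 0
    m1 = max(float(values[carrier].mean()), 0.0)
    m0 = max(float(values[~carrier].mean()), 0.0)
    lfc = float(np.log2((m1 + LFC_PSEUDOCOUNT) / (m0 + LFC_PSEUDOCOUNT)))
    if not detected.any():
        return 1.0, 0.0, True

    g = carrier.astype(float)
    cov = (covariate - covariate.mean()) / (covariate.std() or 1.0)
    ones = np.ones_like(g)
    d = detected.astype(float)
    ll_full = logistic_loglik(np.column_stack([ones, cov, g]), d)
    ll_red = logistic_loglik(np.column_stack([ones, cov]), d)
    lrt = max(2.0 * (ll_full - ll_red), 0.0)

    pos = detected
    if pos.sum() >= 4 and np.unique(g[pos]).size == 2:
        yp = values[pos]
        Xf = np.column_stack([ones[pos], cov[pos], g[pos]])
        Xr = Xf[:, :2]
        rss_f = _rss(Xf, yp)
        rss_r = _rss(Xr, yp)
        if rss_f > 1e-12:
            lrt += max(pos.sum() * np.log(rss_r / rss_f), 0.0)
    p = float(stats.chi2.sf(lrt, df=2))
    return p, lfc, False


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


# ---------------------------------------------------------------------------
# driver


def run_de(
    expt: PerturbExpt,
    assignment: GuideAssignment,
    library: pd.DataFrame,
    level: str = "guide",
    cares: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_background_distance: int = 400_000,
    method: str = "log_normalize",
    batch_regress: bool = True,
) -> pd.DataFrame:
    """Hurdle tests for every (perturbation, gene), BH-adjusted jointly.

    ``level`` "guide" tests each targeting guide; "care" pools cells whose
    retained guides fall inside each element of ``cares`` (columns id,
    chrom, start, end). Perturbations with <2 carrier cells or an empty
    background are skipped and logged.
    """
    if level not in ("guide", "care"):
        raise ValueError("level must be 'guide' or 'care'")
    if level == "care" and cares is None:
        raise ValueError("care-level analysis requires a cares table")
    norm = normalize_expression(expt, method=method, batch_regress=batch_regress)
    assignment = GuideAssignment(
        assignment.guide_counts.loc[expt.cells], assignment.threshold, assignment.method
    )
    covariate = expt.n_genes_detected.to_numpy().astype(float)
    guides = assignment.guide_counts.loc[expt.cells]
    present = guides.to_numpy() > 0
    lib = library.set_index("guide_id")
    col_ids = list(guides.columns)
    gchrom = np.array([lib.at[g, "chrom"] if g in lib.index else "." for g in col_ids])
    gpos = np.array([lib.at[g, "start"] if g in lib.index else -1 for g in col_ids])
    g_ctrl = np.array(
        [bool(lib.at[g, "is_control"]) if g in lib.index else True for g in col_ids]
    )

    perturbations: list[tuple[str, np.ndarray, tuple[str, int]]] = []
    if level == "guide":
        for j, g in enumerate(col_ids):
            if g_ctrl[j]:
                continue
            perturbations.append((g, present[:, j], (gchrom[j], int(gpos[j]))))
    else:
        for rec in cares.itertuples(index=False):
            inside = (~g_ctrl) & (gchrom == rec.chrom) & (gpos >= rec.start) & (gpos < rec.end)
            if not inside.any():
                continue
            mid = (int(rec.start) + int(rec.end)) // 2
            perturbations.append((rec.id, present[:, inside].any(axis=1), (rec.chrom, mid)))

    cell_ids = np.array(expt.cells)
    rows = []
    skipped = []
    vals = norm.to_numpy()
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    for pert_id, carrier_mask, locus in perturbations:
        carriers = set(cell_ids[carrier_mask])
        if len(carriers) < 2:
            skipped.append((pert_id, "fewer than 2 carrier cells"))
            continue
        try:
            bg = build_background(locus, carriers, assignment, library,
                                  min_distance=min_background_distance)
        except ValueError:
            skipped.append((pert_id, "empty background"))
            continue
        bg = [c for c in bg if c in cell_pos]
        idx = np.array([cell_pos[c] for c in sorted(carriers)] + [cell_pos[c] for c in bg])
        flags = np.zeros(idx.size, dtype=bool)
        flags[: len(carriers)] = True
        cov = covariate[idx]
        for k, gene in enumerate(norm.columns):
            p, lfc, flagged = hurdle_test(vals[idx, k], flags, cov)
            rows.append((pert_id, gene, lfc, p, len(carriers), len(bg), level, flagged))
    for pert_id, why in skipped:
        log.info("skipped %s: %s", pert_id, why)
    out = pd.DataFrame(
        rows,
        columns=["perturbation", "gene", "lfc", "p", "n_carrier", "n_background", "level", "flagged"],
    )
    out["adj_p"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["adj_p"] < alpha
    out.attrs["skipped"] = skipped
    return out[
        ["perturbation", "gene", "lfc", "p", "adj_p", "n_carrier", "n_background",
         "level", "flagged", "significant"]
    ]
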