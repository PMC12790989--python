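"""Synthetic inputs with planted ground truth for every pipeline stage.

All generators are deterministic given a master seed; independent named
substreams mean each artifact can be regenerated on its own. Parameter
defaults (negative binomial dispersions, guide-count mixture modes, batch
effect sizes) are simulator conventions, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .teslade import PerturbExpt

# raw-scale means of the two guide-count mixture components; log10-separable
LOW_MODE_MEAN = 0.5
HIGH_MODE_MEAN = 20.0

SCREEN_DISPERSION = 50.0
SC_GENE_DISPERSION = 2.0

TRACK_FEATURES = ("ATAC", "H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3")


@dataclass(frozen=True)
class PlantedElement:
    """A genomic element with a per-day abundance slope on the log10 scale."""

    chrom: str
    start: int
    end: int
    slope: float
    direction: str  # "depleted" or "enriched"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("element end must exceed start")
        want = "depleted" if self.slope < 0 else "enriched"
        if self.slope != 0 and self.direction != want:
            raise ValueError(f"slope {self.slope} inconsistent with direction {self.direction}")


@dataclass
class ScreenTruth:
    """Planted elements and the control-guide id set of a simulated screen."""

    planted_elements: list[PlantedElement] = field(default_factory=list)
    control_guide_ids: set[str] = field(default_factory=set)


@dataclass
class TeslaTruth:
    """Planted perturbation->gene links for the single-cell simulator.

    ``links`` entries name either a guide id from the library or a key of
    ``element_intervals``; an element link applies to every guide targeting
    inside that interval.
    """

    links: list[tuple[str, str, float]] = field(default_factory=list)
    baseline_means: dict[str, float] = field(default_factory=dict)
    dispersions: dict[str, float] = field(default_factory=dict)
    batch_factors: dict[str, float] = field(default_factory=dict)
    element_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def validate(self, panel_genes: set[str]) -> None:
        for _, gene, lfc in self.links:
            if gene not in panel_genes:
                raise ValueError(f"linked gene {gene!r} not in panel")
            if not np.isfinite(lfc):
                raise ValueError(f"non-finite log2_fc for gene {gene!r}")
        for gene, theta in self.dispersions.items():
            if theta <= 0:
                raise ValueError(f"dispersion for {gene!r} must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """NB(mean, theta) with variance mean + mean^2/theta."""
    mean = np.asarray(mean, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = theta / (theta + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(theta, p)
    return np.where(mean <= 0, 0, out)


def make_guide_library(
    region: tuple[str, int, int],
    bin_size: int,
    guides_per_bin: tuple[int, int],
    n_controls: int,
    seed: int,
) -> pd.DataFrame:
    """Tile ``region`` with guides plus non-targeting controls.

    Each ``bin_size`` bin receives a uniform number of guides drawn from the
    inclusive ``guides_per_bin`` range, at uniform positions within the bin.
    Controls carry the sentinel coordinates (chrom ".", start/end -1).
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("region must have positive length")
    lo, hi = guides_per_bin
    if not (1 <= lo <= hi <= 10):
        raise ValueError("guides_per_bin range must lie within [1, 10]")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rng = substream(seed, "guide_library")
    n_bins = (end - start) // bin_size
    if n_bins == 0:
        raise ValueError("region shorter than one bin")
    counts = rng.integers(lo, hi + 1, size=n_bins)
    rows = []
    gid = 0
    for b in range(n_bins):
        bs = start + b * bin_size
        for pos in sorted(rng.integers(bs, bs + bin_size, size=counts[b])):
            rows.append((f"g{gid:06d}", chrom, int(pos), int(pos) + 1, False))
            gid += 1
    for c in range(n_controls):
        rows.append((f"ctrl{c:04d}", ".", -1, -1, True))
    lib = pd.DataFrame(rows, columns=["guide_id", "chrom", "start", "end", "is_control"])
    lib["sequence"] = "N" * 20
    return lib


def assign_guide_slopes(library: pd.DataFrame, truth: ScreenTruth) -> pd.Series:
    """Per-guide abundance slope: the slope of the planted element containing
    the guide's position, 0 elsewhere (and always 0 for controls)."""
    slopes = np.zeros(len(library))
    pos = library["start"].to_numpy()
    targeting = ~library["is_control"].to_numpy()
    for el in truth.planted_elements:
        hit = targeting & (library["chrom"].to_numpy() == el.chrom) & (pos >= el.start) & (pos < el.end)
        slopes[hit] = el.slope
    return pd.Series(slopes, index=library["guide_id"].to_numpy(), name="slope")


def simulate_screen_counts(
    library: pd.DataFrame,
    truth: ScreenTruth,
    days: list[float],
    replicates: int,
    depth: float,
    dispersion: float = SCREEN_DISPERSION,
    seed: int = 0,
    base_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate guide x sample screen counts.

    Expected relative abundance of guide g on day d is 10**(base_g +
    slope_g * d), renormalized per sample and scaled to ``depth``; counts are
    NB draws around that mean. Returns (counts, sample sheet).
    """
    if sorted(days) != list(days):
        raise ValueError("days must be ascending")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = substream(seed, "screen_counts")
    slopes = assign_guide_slopes(library, truth).to_numpy()
    base = rng.normal(0.0, base_sd, size=len(library))
    cols, counts = [], []
    samples = []
    for day in days:
        w = np.power(10.0, base + slopes * day)
        mean = w / w.sum() * depth
        for rep in range(1, replicates + 1):
            name = f"d{day:g}_r{rep}"
            cols.append(name)
            counts.append(_nb_draw(rng, mean, dispersion))
            samples.append((name, rep, float(day)))
    counts_df = pd.DataFrame(
        np.column_stack(counts), index=library["guide_id"].to_numpy(), columns=cols
    )
    counts_df.index.name = "guide_id"
    sheet = pd.DataFrame(samples, columns=["sample", "replicate", "day"])
    return counts_df, sheet


def _linked_guides(truth: TeslaTruth, library: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Resolve links to guide -> {gene: log2_fc}, expanding element links."""
    known = set(library["guide_id"])
    pos = library["start"].to_numpy()
    targeting = ~library["is_control"].to_numpy()
    out: dict[str, dict[str, float]] = {}
    for target, gene, lfc in truth.links:
        if target in known:
            gids = [target]
        elif target in truth.element_intervals:
            chrom, s, e = truth.element_intervals[target]
            hit = targeting & (library["chrom"].to_numpy() == chrom) & (pos >= s) & (pos < e)
            gids = list(library.loc[hit, "guide_id"])
        else:
            raise ValueError(f"unknown guide or element {target!r} in truth.links")
        for g in gids:
            out.setdefault(g, {})[gene] = out.setdefault(g, {}).get(gene, 0.0) + lfc
    return out


def simulate_tesla_counts(
    panel: pd.DataFrame,
    library: pd.DataFrame,
    truth: TeslaTruth,
    n_cells: int,
    moi: float = 1.0,
    ambient_guide_rate: float = 0.5,
    runs: int = 2,
    seed: int = 0,
    depth_sd: float = 0.35,
    guide_dispersion: float = 10.0,
    batch_gene_shift_sd: float = 0.1,
) -> PerturbExpt:
    """Simulate a targeted single-cell perturbation experiment.

    Cells carry Poisson(moi) true guides with counts from the high mixture
    mode and sporadic ambient guides from the low mode; panel genes are NB
    with per-cell depth and per-run batch effects, shifted by 2**log2_fc in
    carrier cells of linked guides.
    """
    if not (0 < moi <= 2):
        raise ValueError("moi must be in (0, 2]")
    if len(panel) == 0:
        raise ValueError("gene panel is empty")
    if n_cells < 1 or runs < 1:
        raise ValueError("n_cells and runs must be >= 1")
    genes = list(panel["gene"])
    truth.validate(set(genes))
    link_map = _linked_guides(truth, library)

    rng = substream(seed, "tesla_counts")
    guide_ids = list(library["guide_id"])
    n_guides = len(guide_ids)
    gidx = {g: i for i, g in enumerate(guide_ids)}

    run_labels = np.array([f"run{(i * runs) // n_cells + 1}" for i in range(n_cells)])
    cell_ids = [f"{run_labels[i]}_c{i:05d}" for i in range(n_cells)]

    guide_mat = np.zeros((n_cells, n_guides), dtype=np.int64)
    true_sets: list[np.ndarray] = []
    n_true = rng.poisson(moi, size=n_cells)
    for c in range(n_cells):
        k = min(int(n_true[c]), n_guides)
        chosen = rng.choice(n_guides, size=k, replace=False) if k else np.array([], dtype=int)
        true_sets.append(chosen)
        if k:
            guide_mat[c, chosen] = np.maximum(
                1, _nb_draw(rng, np.full(k, HIGH_MODE_MEAN), guide_dispersion)
            )
        n_amb = rng.poisson(ambient_guide_rate)
        if n_amb:
            amb = rng.choice(n_guides, size=min(n_amb, n_guides), replace=False)
            guide_mat[c, amb] += rng.poisson(LOW_MODE_MEAN, size=amb.size)

    theta = np.array([truth.dispersions.get(g, SC_GENE_DISPERSION) for g in genes])
    baseline = np.array([truth.baseline_means.get(g, 5.0) for g in genes])
    depth = np.exp(rng.normal(0.0, depth_sd, size=n_cells))
    batch_mul = np.array([truth.batch_factors.get(r, 1.0) for r in run_labels])
    uniq_runs = sorted(set(run_labels))
    gene_shift = {r: rng.normal(0.0, batch_gene_shift_sd, size=len(genes)) for r in uniq_runs}
    shift = np.vstack([gene_shift[r] for r in run_labels])

    mean = baseline[None, :] * depth[:, None] * batch_mul[:, None] * np.exp(shift)
    lfc_mat = np.zeros((n_cells, len(genes)))
    gene_pos = {g: j for j, g in enumerate(genes)}
    for c in range(n_cells):
        for gi in true_sets[c]:
            for gene, lfc in link_map.get(guide_ids[gi], {}).items():
                lfc_mat[c, gene_pos[gene]] += lfc
    mean *= np.power(2.0, lfc_mat)
    gene_mat = _nb_draw(rng, mean, theta[None, :])

    return PerturbExpt(
        gene_counts=pd.DataFrame(gene_mat, index=cell_ids, columns=genes),
        guide_counts=pd.DataFrame(guide_mat, index=cell_ids, columns=guide_ids),
        run=pd.Series(run_labels, index=cell_ids, name="run"),
        true_guides={cell_ids[c]: {guide_ids[i] for i in true_sets[c]} for c in range(n_cells)},
    )


def simulate_tracks(
    region: tuple[str, int, int],
    truth: ScreenTruth,
    enriched_fraction: float,
    seed: int,
    features: tuple[str, ...] = TRACK_FEATURES,
    bin_size: int = 100,
    background_mean: float = 10.0,
    background_sd: float = 3.0,
    effect_sds: float = 3.0,
) -> tuple[dict[str, pd.DataFrame], list[int]]:
    """bedGraph-style coverage tracks elevated at a subset of planted elements.

    Returns (feature name -> track, indices of enriched elements). Track
    values are read counts per ``bin_size`` bin; enrichment adds
    ``effect_sds`` background standard deviations to bins inside enriched
    elements.
    """
    if not 0 <= enriched_fraction <= 1:
        raise ValueError("enriched_fraction must be in [0, 1]")
    chrom, start, end = region
    rng = substream(seed, "tracks")
    n_el = len(truth.planted_elements)
    n_enriched = int(round(enriched_fraction * n_el))
    enriched = sorted(rng.choice(n_el, size=n_enriched, replace=False).tolist()) if n_enriched else []

    starts = np.arange(start, end, bin_size)
    ends = np.minimum(starts + bin_size, end)
    boost = np.zeros(starts.size)
    for i in enriched:
        el = truth.planted_elements[i]
        if el.chrom != chrom:
            continue
        hit = (ends > el.start) & (starts < el.end)
        boost[hit] = effect_sds * background_sd
    tracks = {}
    for name in features:
        vals = np.maximum(rng.normal(background_mean, background_sd, size=starts.size) + boost, 0.0)
        tracks[name] = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": ends, "value": np.round(vals, 4)}
        )
    return tracks, enriched


_SCORE_RANGES = {
    # score_kind -> ((low for background), (range for planted pairs))
    "chicago": ((0.0, 2.5), (4.0, 10.0)),
    "shaman": ((0.0, 20.0), (30.0, 80.0)),
    "epimap": ((0.0, 0.2), (0.5, 1.0)),
    "abc": ((0.0, 0.01), (0.03, 0.1)),
}


def simulate_interactions(
    pairs: pd.DataFrame,
    truth_subset: set[str],
    score_kind: str,
    seed: int,
    anchor_halfwidth: int = 1000,
) -> pd.DataFrame:
    """Region-pair score tables emulating Capture-C / Hi-C / catalog outputs.

    ``pairs`` needs columns pair_id, chromA, startA, endA, gene, chromB, tss.
    Pairs in ``truth_subset`` score above the downstream interaction
    thresholds, others below. ``abc`` tables carry gene and tissue columns
    with two tissue rows per pair.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be nonempty")
    if score_kind not in _SCORE_RANGES:
        raise ValueError(f"unknown score_kind {score_kind!r}")
    (bg_lo, bg_hi), (fg_lo, fg_hi) = _SCORE_RANGES[score_kind]
    rng = substream(seed, f"interactions_{score_kind}")
    rows = []
    for rec in pairs.itertuples(index=False):
        mid = (rec.startA + rec.endA) // 2
        a = (rec.chromA, mid - anchor_halfwidth, mid + anchor_halfwidth)
        b = (rec.chromB, rec.tss - anchor_halfwidth, rec.tss + anchor_halfwidth)
        planted = rec.pair_id in truth_subset
        if score_kind == "abc":
            hi = rng.uniform(fg_lo, fg_hi) if planted else rng.uniform(bg_lo, bg_hi)
            for tissue, score in (("tissueA", hi), ("tissueB", hi * rng.uniform(0.2, 0.8))):
                rows.append((*a, rec.gene, tissue, round(score, 6)))
        else:
            score = rng.uniform(fg_lo, fg_hi) if planted else rng.uniform(bg_lo, bg_hi)
            rows.append((*a, *b, round(score, 6)))
    if score_kind == "abc":
        cols = ["chrom", "start", "end", "gene", "tissue", "score"]
    else:
        cols = ["chromA", "startA", "endA", "chromB", "startB", "endB", "score"]
    return pd.DataFrame(rows, columns=cols)
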