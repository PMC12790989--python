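"""Attach 3D-interaction scores and regulatory-evidence classes to
element-gene pairs, plus pair geometry (linear distance, jumped genes).

Interaction squares: a score record matches a pair when each of its two
intervals, expanded by ``half_width`` on both sides, covers the
corresponding point anchor (element midpoint / gene TSS), in either order.
Intervals are half-open, so a point exactly at the expanded end is outside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CHICAGO_MIN = 3.0  # strictly greater than
SHAMAN_MIN = 25.0  # greater than or equal
CAPTURE_HALF_WIDTH = 12_500
CATALOG_HALF_WIDTH = 2_500
EVIDENCE_MAX_DIST = 250

EPIMAP_CLASS_MAP = {
    "enhancer": "enhancer",
    "promoter": "promoter",
    "dyad": "promoter",
    "DHS": "accessible",
}


def _covers(starts, ends, point, half_width):
    """Half-open containment of a point by intervals expanded by half_width."""
    return (starts - half_width <= point) & (point < ends + half_width)


def pair_square_max(
    pairs: pd.DataFrame,
    scores: pd.DataFrame,
    half_width: int,
) -> np.ndarray:
    """Max score per pair over records whose expanded interval pair covers
    the pair's (midpoint, TSS) anchors, order-insensitively; NaN if none.

    ``pairs`` needs chromA, midA, chromB, tss; ``scores`` needs
    chromA/startA/endA, chromB/startB/endB, score.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    out = np.full(len(pairs), np.nan)
    if len(scores) == 0:
        return out
    sA_chrom = scores["chromA"].to_numpy()
    sB_chrom = scores["chromB"].to_numpy()
    sA_s, sA_e = scores["startA"].to_numpy(), scores["endA"].to_numpy()
    sB_s, sB_e = scores["startB"].to_numpy(), scores["endB"].to_numpy()
    val = scores["score"].to_numpy(float)
    for i, rec in enumerate(pairs.itertuples(index=False)):
        fwd = (
            (sA_chrom == rec.chromA)
            & (sB_chrom == rec.chromB)
            & _covers(sA_s, sA_e, rec.midA, half_width)
            & _covers(sB_s, sB_e, rec.tss, half_width)
        )
        rev = (
            (sB_chrom == rec.chromA)
            & (sA_chrom == rec.chromB)
            & _covers(sB_s, sB_e, rec.midA, half_width)
            & _covers(sA_s, sA_e, rec.tss, half_width)
        )
        hit = val[fwd | rev]
        if hit.size:
            out[i] = hit.max()
    return out


def flag_interactions(chicago: float | None, shaman: float | None) -> tuple[bool, bool]:
    """Interaction flags: Capture-C strictly > 3, Hi-C >= 25; missing scores
    are not interacting."""

    def ok(v, thresh, strict):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return False
        return v > thresh if strict else v >= thresh

    return ok(chicago, CHICAGO_MIN, True), ok(shaman, SHAMAN_MIN, False)


def abc_assign(
    pairs: pd.DataFrame,
    abc: pd.DataFrame,
    half_width: int = CATALOG_HALF_WIDTH,
) -> np.ndarray:
    """Max ABC score per pair across tissues, matching by gene identity and
    the expanded-region square over the element midpoint."""
    out = np.full(len(pairs), np.nan)
    if len(abc) == 0:
        return out
    a_chrom = abc["chrom"].to_numpy()
    a_s, a_e = abc["start"].to_numpy(), abc["end"].to_numpy()
    a_gene = abc["gene"].to_numpy()
    a_val = abc["score"].to_numpy(float)
    for i, rec in enumerate(pairs.itertuples(index=False)):
        hit = (
            (a_gene == rec.gene)
            & (a_chrom == rec.chromA)
            & _covers(a_s, a_e, rec.midA, half_width)
        )
        if hit.any():
            out[i] = a_val[hit].max()
    return out


def merge_intervals(elements: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping intervals, per chromosome."""
    rows = []
    for chrom, grp in elements.groupby("chrom"):
        grp = grp.sort_values("start")
        cs, ce = None, None
        for rec in grp.itertuples(index=False):
            if cs is None:
                cs, ce = rec.start, rec.end
            elif rec.start <= ce:
                ce = max(ce, rec.end)
            else:
                rows.append((chrom, cs, ce))
                cs, ce = rec.start, rec.end
        if cs is not None:
            rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _closest_distance(care, elements: pd.DataFrame) -> float:
    """Edge-to-edge distance from a (chrom, start, end) interval to the
    closest element; 0 when overlapping, inf when none on the chromosome."""
    sub = elements[elements["chrom"] == care[0]]
    if len(sub) == 0:
        return float("inf")
    s, e = care[1], care[2]
    es = sub["start"].to_numpy()
    ee = sub["end"].to_numpy()
    gap = np.maximum(es - e, 0) + np.maximum(s - ee, 0)
    overlap = (ee > s) & (es < e)
    gap[overlap] = 0
    return float(gap.min())


def classify_evidence(
    cares: pd.DataFrame,
    nb_elements: pd.DataFrame,
    epimap_elements: pd.DataFrame,
    max_dist: int = EVIDENCE_MAX_DIST,
) -> pd.DataFrame:
    """Evidence class per element by precedence nb > other > noEF.

    An element within ``max_dist`` bp (edge-to-edge, inclusive) of the
    merged nb evidence is "nb"; else within range of an EpiMap element it is
    "other" (with the mapped EpiMap class recorded); else "noEF".
    """
    nb = merge_intervals(nb_elements) if len(nb_elements) else nb_elements
    epimap = epimap_elements.copy()
    if "class" in epimap.columns:
        epimap["class"] = epimap["class"].map(lambda c: EPIMAP_CLASS_MAP.get(c, c))
    rows = []
    for rec in cares.itertuples(index=False):
        iv = (rec.chrom, rec.start, rec.end)
        d_nb = _closest_distance(iv, nb) if len(nb) else float("inf")
        if d_nb <= max_dist:
            rows.append((rec.id, "nb", d_nb, None))
            continue
        d_ep = _closest_distance(iv, epimap) if len(epimap) else float("inf")
        if d_ep <= max_dist:
            ep_class = None
            if "class" in epimap.columns:
                sub = epimap[epimap["chrom"] == rec.chrom]
                gap = np.maximum(sub["start"].to_numpy() - rec.end, 0) + np.maximum(
                    rec.start - sub["end"].to_numpy(), 0
                )
                ov = (sub["end"].to_numpy() > rec.start) & (sub["start"].to_numpy() < rec.end)
                gap[ov] = 0
                ep_class = sub.iloc[int(np.argmin(gap))]["class"]
            rows.append((rec.id, "other", d_ep, ep_class))
        else:
            rows.append((rec.id, "noEF", min(d_nb, d_ep), None))
    return pd.DataFrame(rows, columns=["id", "evidence_class", "distance", "epimap_class"])


def pair_geometry(
    care: tuple[str, int, int],
    gene: tuple[str, int],
    annotation: pd.DataFrame,
    target_gene: str | None = None,
) -> tuple[float, int]:
    """(linear distance, jumped genes) for one element-gene pair.

    Distance is |element midpoint - TSS|; jumped genes counts annotated TSSs
    (excluding the target) strictly between the midpoint and the target TSS.
    Trans pairs return (nan, 0). Strand is ignored.
    """
    chrom, start, end = care
    gchrom, tss = gene
    if chrom != gchrom:
        log.warning("trans pair %s vs %s flagged; distance undefined", chrom, gchrom)
        return float("nan"), 0
    mid = (start + end) // 2
    lo, hi = min(mid, tss), max(mid, tss)
    ann = annotation[annotation["chrom"] == chrom]
    between = (ann["tss"] > lo) & (ann["tss"] < hi)
    if target_gene is not None:
        between &= ann["gene"] != target_gene
    return float(abs(mid - tss)), int(between.sum())


def integrate_pairs(
    de: pd.DataFrame,
    cares: pd.DataFrame,
    annotation: pd.DataFrame,
    chicago: pd.DataFrame | None = None,
    shaman: pd.DataFrame | None = None,
    epimap_links: pd.DataFrame | None = None,
    abc: pd.DataFrame | None = None,
    nb_elements: pd.DataFrame | None = None,
    epimap_elements: pd.DataFrame | None = None,
    capture_half_width: int = CAPTURE_HALF_WIDTH,
    catalog_half_width: int = CATALOG_HALF_WIDTH,
    max_dist: int = EVIDENCE_MAX_DIST,
) -> pd.DataFrame:
    """Master pair table: DE stats + geometry + interaction scores/flags +
    evidence class, one row per (element, gene) pair in ``de``."""
    care_ix = cares.set_index("id")
    ann_ix = annotation.set_index("gene")
    recs = []
    for rec in de.itertuples(index=False):
        if rec.perturbation not in care_ix.index or rec.gene not in ann_ix.index:
            continue
        c = care_ix.loc[rec.perturbation]
        g = ann_ix.loc[rec.gene]
        mid = (int(c["start"]) + int(c["end"])) // 2
        dist, jumped = pair_geometry(
            (c["chrom"], int(c["start"]), int(c["end"])),
            (g["chrom"], int(g["tss"])),
            annotation,
            target_gene=rec.gene,
        )
        recs.append(
            {
                "care": rec.perturbation,
                "gene": rec.gene,
                "chromA": c["chrom"],
                "midA": mid,
                "chromB": g["chrom"],
                "tss": int(g["tss"]),
                "lfc": rec.lfc,
                "p": rec.p,
                "adj_p": rec.adj_p,
                "distance": dist,
                "jumped_genes": jumped,
            }
        )
    out = pd.DataFrame(recs)
    if len(out) == 0:
        return out
    anchors = out[["chromA", "midA", "chromB", "tss", "gene"]]
    out["chicago_score"] = (
        pair_square_max(anchors, chicago, capture_half_width) if chicago is not None else np.nan
    )
    out["shaman_score"] = (
        pair_square_max(anchors, shaman, capture_half_width) if shaman is not None else np.nan
    )
    out["epimap_score"] = (
        pair_square_max(anchors, epimap_links, catalog_half_width)
        if epimap_links is not None
        else np.nan
    )
    out["abc_score"] = abc_assign(anchors, abc, catalog_half_width) if abc is not None else np.nan
    flags = [flag_interactions(c, s) for c, s in zip(out["chicago_score"], out["shaman_score"])]
    out["chicago_interacting"] = [f[0] for f in flags]
    out["shaman_interacting"] = [f[1] for f in flags]
    if nb_elements is not None and epimap_elements is not None:
        ev = classify_evidence(cares, nb_elements, epimap_elements, max_dist=max_dist)
        out = out.merge(
            ev[["id", "evidence_class"]], left_on="care", right_on="id", how="left"
        ).drop(columns="id")
    return out
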