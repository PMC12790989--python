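"""End-to-end driver: simulate -> screen -> tesla -> features -> integrate.

Every stage writes plain-text outputs under the run directory and the run
manifest records config, thresholds, and a checksum per file, so two runs
with the same seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, featmodels, pairintegrate, screenstats, simdata, teslade
from ._rng import substream
from .config import PipelineConfig
from .io import sha256sum, write_bed, write_bedgraph, write_mtx, write_tsv

log = logging.getLogger(__name__)

STAGES = ("simulate", "screen", "tesla", "features", "integrate")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _plant_truth(cfg: PipelineConfig) -> simdata.ScreenTruth:
    rng = substream(cfg.seed, "plant")
    chrom, start, end = cfg.region
    width = cfg.element_bins * cfg.bin_size
    n_slots = (end - start) // (3 * width)
    slots = rng.choice(n_slots, size=min(cfg.n_elements, n_slots), replace=False)
    elements = []
    for s in sorted(slots):
        es = start + int(s) * 3 * width + width
        direction = "depleted" if cfg.planted_slope < 0 else "enriched"
        elements.append(simdata.PlantedElement(chrom, es, es + width, cfg.planted_slope, direction))
    return simdata.ScreenTruth(planted_elements=elements)


def simulate_stage(cfg: PipelineConfig, outdir: Path) -> dict:
    chrom, start, end = cfg.region
    library = simdata.make_guide_library(
        cfg.region, cfg.bin_size, cfg.guides_per_bin, cfg.n_controls, cfg.seed
    )
    truth = _plant_truth(cfg)
    truth.control_guide_ids = set(library.loc[library["is_control"], "guide_id"])
    counts, samples = simdata.simulate_screen_counts(
        library, truth, list(cfg.days), cfg.replicates, cfg.depth, seed=cfg.seed
    )
    rng = substream(cfg.seed, "panel")
    tss = np.linspace(start + 1000, end - 1000, cfg.n_genes).astype(int)
    panel = pd.DataFrame(
        {
            "gene": [f"gene{i:03d}" for i in range(cfg.n_genes)],
            "chrom": chrom,
            "tss": tss,
            "strand": (["+", "-"] * (cfg.n_genes // 2 + 1))[: cfg.n_genes],
        }
    )

    elements = {f"el{i}": (e.chrom, e.start, e.end) for i, e in enumerate(truth.planted_elements)}
    link_el = rng.choice(len(elements), size=min(cfg.n_links, len(elements)), replace=False)
    link_gene = rng.choice(cfg.n_genes, size=len(link_el), replace=False)
    links = [
        (f"el{int(e)}", f"gene{int(g):03d}", cfg.link_lfc) for e, g in zip(link_el, link_gene)
    ]
    ttruth = simdata.TeslaTruth(
        links=links,
        baseline_means={g: float(m) for g, m in zip(panel["gene"], rng.uniform(3, 15, cfg.n_genes))},
        batch_factors={f"run{r + 1}": 1.0 + 0.3 * r for r in range(cfg.runs)},
        element_intervals=elements,
    )
    expt = simdata.simulate_tesla_counts(
        panel, library, ttruth, cfg.n_cells, moi=cfg.moi, runs=cfg.runs, seed=cfg.seed
    )
    tracks, enriched = simdata.simulate_tracks(cfg.region, truth, 0.7, cfg.seed)

    pairs = pd.DataFrame(
        [
            (f"el{i}|{g}", e.chrom, e.start, e.end, g, chrom, int(panel.set_index("gene").at[g, "tss"]))
            for i, e in enumerate(truth.planted_elements)
            for g in panel["gene"]
        ],
        columns=["pair_id", "chromA", "startA", "endA", "gene", "chromB", "tss"],
    )
    truth_pairs = {f"{el}|{g}" for el, g, _ in links}
    scores = {
        kind: simdata.simulate_interactions(pairs, truth_pairs, kind, cfg.seed)
        for kind in ("chicago", "shaman", "epimap", "abc")
    }
    nb_elements = pd.DataFrame(
        [(e.chrom, e.start - 50, e.end + 50) for i, e in enumerate(truth.planted_elements) if i in enriched],
        columns=["chrom", "start", "end"],
    )
    epimap_elements = pd.DataFrame(
        [
            (e.chrom, e.start, e.end, ["enhancer", "promoter", "dyad", "DHS"][i % 4])
            for i, e in enumerate(truth.planted_elements)
        ],
        columns=["chrom", "start", "end", "class"],
    )

    d = outdir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(library, d / "library.tsv", index=False)
    write_tsv(counts, d / "screen_counts.tsv")
    write_tsv(samples, d / "samples.tsv", index=False)
    write_tsv(panel, d / "panel.tsv", index=False)
    write_mtx(expt.gene_counts, d / "genes.mtx")
    write_mtx(expt.guide_counts, d / "guides.mtx")
    write_tsv(expt.run.to_frame(), d / "runs.tsv")
    for name, track in tracks.items():
        write_bedgraph(track, d / f"track_{name}.bedgraph")
    for kind, tab in scores.items():
        write_tsv(tab, d / f"scores_{kind}.tsv", index=False)
    write_bed(nb_elements, d / "nb_elements.bed")
    write_tsv(epimap_elements, d / "epimap_elements.tsv", index=False)
    write_tsv(
        pd.DataFrame(
            [(f"el{i}", e.chrom, e.start, e.end, e.slope, e.direction)
             for i, e in enumerate(truth.planted_elements)],
            columns=["id", "chrom", "start", "end", "slope", "direction"],
        ),
        d / "truth_elements.tsv", index=False,
    )
    write_tsv(pd.DataFrame(links, columns=["element", "gene", "log2_fc"]),
              d / "truth_links.tsv", index=False)
    return {
        "library": library, "truth": truth, "counts": counts, "samples": samples,
        "panel": panel, "tesla_truth": ttruth, "expt": expt, "tracks": tracks,
        "scores": scores, "nb_elements": nb_elements, "epimap_elements": epimap_elements,
    }


def screen_stage(cfg: PipelineConfig, data: dict, outdir: Path) -> dict:
    guide_table, fits, cares = screenstats.call_cares(
        data["counts"], data["samples"], data["library"], cfg.region,
        bin_size=cfg.bin_size, window_bins=cfg.window_bins,
        alpha=cfg.alpha, max_gap=cfg.max_gap,
    )
    d = outdir / "screen"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(guide_table, d / "guide_results.tsv")
    write_tsv(screenstats.window_fits_frame(fits), d / "bin_fits.tsv", index=False)
    ct = screenstats.cares_frame(cares)
    write_tsv(ct, d / "cares.tsv", index=False)
    bed = ct[["chrom", "start", "end", "id"]].copy()
    bed.columns = ["chrom", "start", "end", "name"]
    bed["score"] = np.minimum(1000, (100 * ct["score"].fillna(0)).round().astype(int))
    bed["strand"] = "."
    write_bed(bed, d / "cares.bed")
    return {"guide_table": guide_table, "fits": fits, "cares": cares, "cares_frame": ct}


def tesla_stage(cfg: PipelineConfig, data: dict, screen: dict, outdir: Path) -> dict:
    expt = data["expt"]
    assignment = teslade.threshold_guide_counts(expt.guide_counts)
    filtered = teslade.filter_cells_genes(expt, assignment)
    assignment = teslade.GuideAssignment(
        filtered.guide_counts, assignment.threshold, assignment.method
    )
    de = teslade.run_de(
        filtered, assignment, data["library"], level="care",
        cares=screen["cares_frame"], alpha=cfg.alpha,
        min_background_distance=cfg.min_background_distance,
    )
    d = outdir / "tesla"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(de, d / "de_results.tsv", index=False)
    qc = pd.DataFrame(
        {
            "n_genes_detected": filtered.n_genes_detected,
            "max_guide": filtered.guide_counts.max(axis=1),
            "run": filtered.run,
        }
    )
    write_tsv(qc, d / "cell_qc.tsv")
    return {"de": de, "assignment": assignment, "filtered": filtered,
            "threshold": assignment.threshold}


def features_stage(cfg: PipelineConfig, data: dict, screen: dict, outdir: Path) -> dict:
    chrom, start, end = cfg.region
    starts = np.arange(start, end, cfg.bin_size)
    bins = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.minimum(starts + cfg.bin_size, end)}
    )
    fm = featmodels.feature_matrix(data["tracks"], bins)
    ct = screen["cares_frame"]
    labels = np.zeros(len(bins), dtype=int)
    for rec in ct.itertuples(index=False):
        labels[(bins["end"] > rec.start) & (bins["start"] < rec.end)] = 1
    report = featmodels.fit_care_logistic(fm, labels)
    aucs = featmodels.cv_auc(fm, labels, folds=cfg.folds, repeats=cfg.repeats, seed=cfg.seed)
    d = outdir / "features"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(report.coefficients, d / "logistic_report.tsv")
    write_tsv(aucs, d / "cv_auc.tsv", index=False)
    return {"feature_matrix": fm, "labels": labels, "report": report, "aucs": aucs}


def integrate_stage(cfg: PipelineConfig, data: dict, screen: dict, tesla: dict, outdir: Path) -> dict:
    annotation = data["panel"][["gene", "chrom", "tss", "strand"]]
    table = pairintegrate.integrate_pairs(
        tesla["de"], screen["cares_frame"], annotation,
        chicago=data["scores"]["chicago"], shaman=data["scores"]["shaman"],
        epimap_links=data["scores"]["epimap"], abc=data["scores"]["abc"],
        nb_elements=data["nb_elements"], epimap_elements=data["epimap_elements"],
        capture_half_width=cfg.capture_half_width,
        catalog_half_width=cfg.catalog_half_width, max_dist=cfg.max_dist,
    )
    d = outdir / "integrate"
    d.mkdir(parents=True, exist_ok=True)
    write_tsv(table, d / "pair_records.tsv", index=False)
    return {"pairs": table}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages; returns stage results and writes a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    completed = []
    stage = "simulate"
    try:
        results["simulate"] = simulate_stage(cfg, outdir)
        completed.append(stage)
        stage = "screen"
        results["screen"] = screen_stage(cfg, results["simulate"], outdir)
        completed.append(stage)
        stage = "tesla"
        results["tesla"] = tesla_stage(cfg, results["simulate"], results["screen"], outdir)
        completed.append(stage)
        stage = "features"
        results["features"] = features_stage(cfg, results["simulate"], results["screen"], outdir)
        completed.append(stage)
        stage = "integrate"
        results["integrate"] = integrate_stage(
            cfg, results["simulate"], results["screen"], results["tesla"], outdir
        )
        completed.append(stage)
    except Exception as err:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, err) from err

    files = sorted(str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": completed,
        "config": cfg.to_dict(),
        "thresholds": {
            "alpha": cfg.alpha, "max_gap": cfg.max_gap, "window_bins": cfg.window_bins,
            "min_background_distance": cfg.min_background_distance,
            "guide_count_threshold": results["tesla"]["threshold"],
            "capture_half_width": cfg.capture_half_width,
            "catalog_half_width": cfg.catalog_half_width, "max_dist": cfg.max_dist,
        },
        "checksums": {f: sha256sum(outdir / f) for f in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    results["manifest"] = manifest
    return results
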