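"""End-to-end comparative pipeline: pairs -> balanced maps -> z-scores ->
differential / compartments / TADs / scaling / telomeres.

:class:`PipelineConfig` gathers every input path, resolution and threshold;
:func:`run_all` executes the stages that have their inputs, writes each
module's outputs under a result directory, and emits a run manifest
(config echo plus SHA-256 checksums of every output).  Stages with missing
optional inputs are skipped with a logged notice.  All randomness flows
from the single config seed through named per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .genome import ContactMap, make_binning, bin_pairs, mask_low_coverage
from .normalize import ice_balance, distance_expected, zscore_transform
from .differential import differential_score
from .compartments import call_compartments, classify_switches, expression_by_switch
from .tads import insulation, call_boundaries, derive_tads, classify_tads, classify_boundaries
from .scaling import scaling_curve, telomere_interaction, compare_telomere

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths, resolutions, thresholds and the master seed for a full run.

    ``pairs`` maps sample names (A1, A2, B1, B2) to valid-pairs TSVs.
    Optional annotation inputs gate their stages: ``genes`` for compartment
    orientation, ``expression`` for expression-by-switch, ``centromeres``
    for per-arm scaling and TAD exclusions.
    """

    chrom_sizes: str = ""
    pairs: dict[str, str] = field(default_factory=dict)
    genes: str | None = None
    peaks: str | None = None
    centromeres: str | None = None
    expression: str | None = None
    resolution_differential: int = 6_500_000
    resolution_compartments: int = 250_000
    resolution_tads: int = 40_000
    resolution_scaling: int = 1_000_000
    boundary_strength: float = 0.15
    tad_min_overlap: float = 0.90
    end_fraction: float = 0.05
    n_null: int = 500_000
    mask_fraction: float = 0.02
    de_log2fc: float = 1.0
    de_padj: float = 0.01
    small_chromosomes: list[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for name in ("resolution_differential", "resolution_compartments",
                     "resolution_tads", "resolution_scaling"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tad_min_overlap <= 1:
            raise ValueError("tad_min_overlap must be in (0, 1]")
        if not 0 < self.end_fraction < 0.5:
            raise ValueError("end_fraction must be in (0, 0.5)")
        missing = {"A1", "A2", "B1", "B2"} - set(self.pairs)
        if missing:
            raise ValueError(f"pairs missing samples: {sorted(missing)}")


SAMPLES = ("A1", "A2", "B1", "B2")


def _balanced_zscore(pairs_paths, sizes, resolution, mask_fraction):
    """Bin, mask, balance and z-transform every sample at one resolution."""
    binning = make_binning(sizes, resolution)
    iced, zmaps = {}, {}
    for name, path in pairs_paths.items():
        raw = bin_pairs(hio.read_pairs_df(path), binning)
        raw = mask_low_coverage(raw, mask_fraction)
        bal, _ = ice_balance(raw)
        iced[name] = bal
        zmaps[name] = zscore_transform(bal, distance_expected(bal))
    return binning, iced, zmaps


def _pooled(iced: dict[str, ContactMap], names) -> ContactMap:
    """Sum of per-replicate raw-equivalent balanced maps, re-balanced."""
    total = sum(iced[n].values for n in names)
    mask = np.logical_or.reduce([iced[n].mask for n in names])
    pooled = ContactMap(iced[names[0]].binning, total, mask=mask, state="raw")
    bal, _ = ice_balance(pooled)
    return bal


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage whose inputs are present; return the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sizes = hio.read_chrom_sizes(config.chrom_sizes)
    outputs: list[Path] = []
    summary: dict = {}

    def save_df(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path)
        return path

    # --- differential interactions (6.5 Mb) -------------------------------
    logger.info("stage differential at %d bp", config.resolution_differential)
    binning_d, iced_d, z_d = _balanced_zscore(config.pairs, sizes,
                                              config.resolution_differential,
                                              config.mask_fraction)
    diff = differential_score(z_d["A1"], z_d["A2"], z_d["B1"], z_d["B2"],
                              n_null=config.n_null, seed=config.seed * 10 + 1)
    path = outdir / "differential_scores.tsv"
    labels = binning_d.bin_labels()
    pd.DataFrame(diff.scores, index=labels, columns=labels).to_csv(path, sep="\t", float_format="%.5g")
    outputs.append(path)
    summary["differential"] = {"null_mean": diff.null_mean, "null_scale": diff.null_scale,
                               "n_null": diff.n_null}
    if config.small_chromosomes:
        from .differential import interchrom_set_comparison

        rest = [c for c in binning_d.chromosomes if c not in config.small_chromosomes]
        res = interchrom_set_comparison(diff, config.small_chromosomes, rest)
        summary["differential"]["small_chrom_set"] = {
            "median_within": res["median_within"],
            "median_cross": res["median_cross"],
            "p_value": res["p_value"],
        }

    # --- compartments (250 kb) --------------------------------------------
    if config.genes:
        logger.info("stage compartments at %d bp", config.resolution_compartments)
        genes = hio.read_bed(config.genes)
        binning_c, iced_c, z_c = _balanced_zscore(config.pairs, sizes,
                                                  config.resolution_compartments,
                                                  config.mask_fraction)
        prof_a = call_compartments(z_c["A1"], genes)
        prof_b = call_compartments(z_c["B1"], genes)
        hio.write_bedgraph(outdir / "compartments_A.bedgraph", binning_c, prof_a.eigenvector)
        hio.write_bedgraph(outdir / "compartments_B.bedgraph", binning_c, prof_b.eigenvector)
        outputs += [outdir / "compartments_A.bedgraph", outdir / "compartments_B.bedgraph"]
        switches = classify_switches(prof_a, prof_b)
        bins = binning_c.bins()
        bins["name"] = switches.categories
        save_df(bins[bins["name"] != ""], "compartment_switches.bed")
        summary["compartments"] = switches.counts()
        if config.expression:
            expr = pd.read_csv(config.expression, sep="\t")
            res = expression_by_switch(switches, expr)
            summary["expression_by_switch"] = {
                "medians": res["medians"],
                "p_A->B_vs_stable": res["p_A->B_vs_stable"],
                "p_B->A_vs_stable": res["p_B->A_vs_stable"],
            }
    else:
        logger.info("no gene intervals: compartment stage skipped")

    # --- TADs (40 kb) ------------------------------------------------------
    logger.info("stage TADs at %d bp", config.resolution_tads)
    binning_t, iced_t, _ = _balanced_zscore(config.pairs, sizes,
                                            config.resolution_tads,
                                            config.mask_fraction)
    pooled_a = _pooled(iced_t, ("A1", "A2"))
    pooled_b = _pooled(iced_t, ("B1", "B2"))
    exclusions = hio.read_bed(config.centromeres) if config.centromeres else None
    tracks, bounds, tads = {}, {}, {}
    for cond, pooled in (("A", pooled_a), ("B", pooled_b)):
        track = insulation(pooled)
        hio.write_bedgraph(outdir / f"insulation_{cond}.bedgraph", binning_t, track.normalized)
        outputs.append(outdir / f"insulation_{cond}.bedgraph")
        bset = call_boundaries(track, strength_threshold=config.boundary_strength)
        hio.write_bed(outdir / f"boundaries_{cond}.bed", bset.intervals())
        outputs.append(outdir / f"boundaries_{cond}.bed")
        tracks[cond], bounds[cond] = track, bset
        tads[cond] = derive_tads(bset, exclusions)
    cls = classify_boundaries(bounds["A"], bounds["B"])
    tad_a, tad_b = classify_tads(tads["A"], tads["B"], config.tad_min_overlap)
    save_df(tad_a.records, "tads_A.bed")
    save_df(tad_b.records, "tads_B.bed")
    summary["tads"] = {
        "n_boundaries_A": len(bounds["A"]), "n_boundaries_B": len(bounds["B"]),
        "n_overlapping_boundaries": cls["n_overlapping_1"],
        "n_tads_A": len(tad_a), "n_tads_B": len(tad_b),
    }

    # --- scaling and telomeres (1 Mb) --------------------------------------
    logger.info("stage scaling at %d bp", config.resolution_scaling)
    binning_s, iced_s, _ = _balanced_zscore(config.pairs, sizes,
                                            config.resolution_scaling,
                                            config.mask_fraction)
    rel = {}
    for cond, names in (("A", ("A1", "A2")), ("B", ("B1", "B2"))):
        pooled = _pooled(iced_s, names)
        rel[cond] = ContactMap(binning_s, pooled.values / pooled.total(),
                               mask=pooled.mask, state="ice")
        curve = scaling_curve(rel[cond], scope="genome")
        save_df(pd.DataFrame({"distance_bp": curve.distance_bp, "mean": curve.mean}),
                f"scaling_{cond}.tsv")
    telo_a = telomere_interaction(rel["A"], config.end_fraction)
    telo_b = telomere_interaction(rel["B"], config.end_fraction)
    telo = compare_telomere(telo_a, telo_b)
    save_df(pd.DataFrame({"chrom": telo["chromosomes"], "mean_A": telo["means_a"],
                          "mean_B": telo["means_b"], "ratio": telo["ratios"].to_numpy()}),
            "telomere.tsv")
    summary["telomere_p"] = telo["p_value"]

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": asdict(config),
        "summary": _jsonable(summary),
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
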