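"""End-to-end orchestration: synthetic inputs -> window tracks -> peaks ->
profiles -> repeat counts -> bisulfite/HPLC -> DigiWest, with a manifest.

The demo run regenerates every input from the seed, so two runs with the
same configuration produce byte-identical output directories.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import ChromSizes, write_genes_bed12, write_intervals
from .digiwest import cluster_significant, normalize_to_actin, permutation_anova2, quantify_analyte
from .methylation import HplcAreas, compare_conditions, hplc_percent_5mc
from .peaks import assign_compartments, call_peaks, reference_threshold, write_peaks
from .profiles import (
    consensus_de_sets,
    element_profile,
    genebody_profile,
    nearest_gene_within,
    promoter_mean,
    promoter_profile,
    promoter_state_stratify,
    quartile_stratify,
)
from .repeats import assign_to_repeats, combine_counts, count_by_type, normalize_repeat_counts
from .simulate import (
    SimConfig,
    default_bands,
    place_planted_regions,
    simulate_clone_matrix,
    simulate_expression,
    simulate_fraction_matrix,
    simulate_fragments,
    simulate_genome,
)
from .windows import WindowGrid, count_fragments, enriched_windows, normalize_total, subtract_input, write_track

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults are the study's printed analysis parameters."""

    seed: int = 0
    window_size: int = 200
    percentile: float = 95.0
    region_windows: int = 3
    min_qualifying: int = 2
    core_bp: int = 100
    proximal_bp: int = 1000
    distal_bp: int = 2000
    promoter_flank: int = 2000
    genebody_flank_fraction: float = 0.25
    element_flank_fraction: float = 1.0
    promoter_mean_flank: int = 1000
    nearest_max_dist: int = 10000
    de_fold: float = 2.0
    de_alpha: float = 0.05
    n_perm: int = 1000
    digiwest_alpha: float = 0.005
    # synthetic-study scale
    genome_length: int = 1_000_000
    n_genes: int = 40
    n_planted: int = 10
    planted_len: int = 2000
    planted_fold: float = 10.0
    depth: int = 100_000
    halved_condition: bool = True  # condition B keeps only half the planted territory

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name == "seed":
                continue
            if isinstance(v, (int, float)) and not isinstance(v, bool) and v <= 0:
                raise ValueError(f"pipeline parameter {name} must be positive, got {v}")


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.6f", **kw)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Run every stage on the seeded synthetic study; returns the run dir."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = SimConfig(
        seed=config.seed,
        chrom_lengths=ChromSizes({"chr1": config.genome_length}),
        n_genes=config.n_genes,
        depth_ip=config.depth,
        depth_input=config.depth,
        digiwest_effects_sd={"analyte000": (10.0, 0.0), "analyte001": (0.0, 4.0)},
    )

    log.info("stage genome: simulating annotation")
    sizes, genes, repeats, osn = simulate_genome(sim)
    sizes.write(out / "chrom.sizes")
    write_genes_bed12(genes, out / "genes.bed12")
    repeats.write_bed(out / "repeats.bed")
    write_intervals(osn, out / "osn_sites.bed")

    log.info("stage quant: fragments and window tracks")
    planted_a = place_planted_regions(sim, config.n_planted, config.planted_len, config.planted_fold)
    planted_b = planted_a[: config.n_planted // 2] if config.halved_condition else planted_a
    grid = WindowGrid(sizes, config.window_size)
    tracks = {}
    for name, planted, seed_off in (("serum", planted_a, 0), ("2i", planted_b, 100)):
        cond_sim = SimConfig(**{**sim.__dict__, "seed": sim.seed + seed_off, "planted_regions": planted})
        ip, input_ = simulate_fragments(cond_sim)
        track = subtract_input(
            normalize_total(count_fragments(grid, ip)),
            normalize_total(count_fragments(grid, input_)),
        )
        tracks[name] = track
        write_track(track, out / f"track_{name}.bedGraph")

    log.info("stage peaks: threshold from reference, 2-of-3 rule, compartments")
    thr = reference_threshold(tracks["serum"], config.percentile)
    peak_sets = {}
    for name, track in tracks.items():
        ps = call_peaks(track, thr, config.region_windows, config.min_qualifying)
        assign_compartments(ps, genes, config.core_bp, config.proximal_bp, config.distal_bp)
        peak_sets[name] = ps
        write_peaks(ps, out / f"peaks_{name}.bed")
    comp = pd.DataFrame({n: ps.compartment_counts() for n, ps in peak_sets.items()})
    _write_tsv(comp, out / "compartment_counts.tsv", index_label="compartment")

    log.info("stage profiles: metaprofiles and stratified sets")
    track = tracks["serum"]
    _write_tsv(promoter_profile(track, genes, config.promoter_flank).to_frame(), out / "profile_promoter.tsv", index=False)
    _write_tsv(
        genebody_profile(track, genes, config.genebody_flank_fraction).to_frame(),
        out / "profile_genebody.tsv",
        index=False,
    )
    _write_tsv(
        element_profile(track, osn, config.element_flank_fraction).to_frame(),
        out / "profile_element.tsv",
        index=False,
    )
    pm = promoter_mean(track, genes, config.promoter_mean_flank)
    _write_tsv(pm.to_frame(), out / "promoter_mean.tsv", index_label="gene")

    tables, de_truth = simulate_expression(sim)
    expr = pd.Series(
        {g: float(t) for g, t in zip(tables[next(iter(tables))]["gene"], tables[next(iter(tables))]["log2fc"])}
    )
    quartiles = quartile_stratify(genes, expr.reindex([g.gene_id for g in genes]).fillna(0.0))
    states = promoter_state_stratify(genes, peak_sets["serum"], config.promoter_mean_flank)
    strat = pd.DataFrame(
        [(part, gid) for part, ids in {**quartiles, **states}.items() for gid in ids],
        columns=["partition", "gene"],
    )
    _write_tsv(strat, out / "stratified_sets.tsv", index=False)
    nearest = nearest_gene_within(osn, genes, config.nearest_max_dist)
    _write_tsv(
        pd.DataFrame(
            {
                "site": [f"{s.chrom}:{s.start}-{s.end}" for s in osn],
                "gene": [g if g else "none" for g in nearest],
            }
        ),
        out / "osn_nearest_gene.tsv",
        index=False,
    )
    up, down = consensus_de_sets(tables, config.de_fold, config.de_alpha)
    _write_tsv(
        pd.DataFrame(
            [("up", g) for g in sorted(up)] + [("down", g) for g in sorted(down)],
            columns=["direction", "gene"],
        ),
        out / "consensus_de.tsv",
        index=False,
    )

    log.info("stage repeats: unique assignment and normalized counts")
    per_sample, totals = {}, {}
    for name, planted, seed_off in (("serum", planted_a, 0), ("2i", planted_b, 100)):
        cond_sim = SimConfig(**{**sim.__dict__, "seed": sim.seed + seed_off, "planted_regions": planted})
        ip, _ = simulate_fragments(cond_sim)
        per_sample[name] = count_by_type(assign_to_repeats(ip, repeats), repeats, name)
        totals[name] = ip.total_mapped
    counts = combine_counts(per_sample)
    _write_tsv(counts, out / "repeat_counts.tsv", index_label="repeat_type")
    _write_tsv(normalize_repeat_counts(counts, totals), out / "repeat_counts_rpm.tsv", index_label="repeat_type")

    log.info("stage methylation: bisulfite clone matrices and HPLC")
    m_serum = simulate_clone_matrix(sim, "serum")
    m_2i = simulate_clone_matrix(sim, "2i")
    m_serum.write_tsv(out / "clones_serum.tsv")
    m_2i.write_tsv(out / "clones_2i.tsv")
    bis = compare_conditions(m_serum, m_2i)
    hplc = {
        name: hplc_percent_5mc(HplcAreas(a_dcmp, a_5m))
        for name, (a_dcmp, a_5m) in {
            "serum": (88600.0, 3600.0),
            "2i": (88600.0, 1800.0),
        }.items()
    }
    report = pd.DataFrame(
        {
            "quantity": ["bisulfite_percent_serum", "bisulfite_percent_2i", "mwu_U", "mwu_p",
                          "hplc_percent_serum", "hplc_percent_2i"],
            "value": [bis["percent_a"], bis["percent_b"], bis["U"], bis["p"],
                       hplc["serum"], hplc["2i"]],
        }
    )
    _write_tsv(report, out / "methylation_report.tsv", index=False)

    log.info("stage digiwest: band quantification, permutation ANOVA, clustering")
    fm, dw_truth = simulate_fraction_matrix(sim)
    values = quantify_analyte(fm, default_bands(dw_truth))
    actin = values.loc["beta_actin"]
    norm = normalize_to_actin(values.drop(index="beta_actin"), actin)
    anova = permutation_anova2(
        norm, fm.design["treatment"], fm.design["celltype"], n_perm=config.n_perm, seed=config.seed
    )
    _write_tsv(anova, out / "digiwest_anova.tsv", index_label="analyte")
    order, _tree = cluster_significant(norm, anova, config.digiwest_alpha)
    (out / "digiwest_significant.txt").write_text("".join(f"{a}\n" for a in order))

    manifest = {
        "package": "epiwindow",
        "version": __version__,
        "parameters": asdict(config),
        "truth": {
            "planted_regions_serum": [[iv.chrom, iv.start, iv.end, f] for iv, f in planted_a],
            "planted_regions_2i": [[iv.chrom, iv.start, iv.end, f] for iv, f in planted_b],
            "de_up": sorted(de_truth["up"]),
            "de_down": sorted(de_truth["down"]),
            "digiwest_effects_sd": {k: list(v) for k, v in sim.digiwest_effects_sd.items()},
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out)
    return out
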