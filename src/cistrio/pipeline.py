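"""End-to-end demo pipeline on synthetic data.

Chains every analysis stage — simulate, overlap screen, combination
classification, binned densities, super-enhancer screen, knockdown
perturbation and E-code survival — and writes per-stage tables plus a
deterministic plain-text summary (same config + seed => byte-identical
summary).
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .intervals import write_bed, overlap_screen
from .signals import binned_density, mean_profile, site_signal
from .cobinding import (
    classify_combinations,
    combination_classes_as_sitesets,
    pairwise_overlap_matrix,
    nmf_binding,
)
from .superenhancer import stitch, score_regions, rank_and_cut, assign_nearest_gene
from .perturbation import classify_binding_change, peakset_diff
from .survival import encode_expression, km_by_code, logrank_test
from .simulate import (
    SimulationConfig,
    simulate_cistromes,
    simulate_tags,
    simulate_knockdown_pair,
    simulate_enhancer_signals,
    simulate_peak_loss,
    simulate_tss,
    simulate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["demo_config", "run_pipeline"]


def demo_config(seed: int = 0, n_sites: int = 2000) -> SimulationConfig:
    """A desk-scale configuration for the end-to-end demo."""
    return SimulationConfig(
        seed=seed,
        genome=(("chr1", 30_000_000), ("chr2", 25_000_000), ("chr3", 20_000_000)),
        n_latent_sites=n_sites,
        background_rate=0.02,
    )


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def run_pipeline(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run all seven stages on synthetic data; returns the summary dict.

    Writes stage outputs under ``outdir`` plus ``summary.txt`` (timestamp-
    free, reproducible) and ``manifest.json`` (run metadata including
    timings).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    ss = np.random.SeedSequence(config.seed)
    (s_cis, s_kd, s_h3k, s_factors, s_atac, s_cohort, s_tss) = ss.spawn(7)
    summary: dict = {"seed": config.seed, "n_latent_sites": config.n_latent_sites}
    lines: list[str] = [
        "cistrio demo pipeline summary",
        f"seed: {config.seed}",
        f"latent sites: {config.n_latent_sites}",
    ]
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("stage: %s", name)
        timings[name] = _time.time()
        lines.append(f"[{name}]")

    # 1 — simulate
    stage("simulate")
    sim = simulate_cistromes(config, np.random.default_rng(s_cis))
    ctrl, kd, kd_mask = simulate_knockdown_pair(config, sim, s_kd)
    h3k_mult, h3k_tail = simulate_enhancer_signals(
        config, len(sim.anchor), np.random.default_rng(s_h3k)
    )
    h3k27ac = simulate_tags(
        config, sim.anchor, h3k_mult, np.random.default_rng(s_h3k), "H3K27ac"
    )
    rng_factors = np.random.default_rng(s_factors)
    factor_tracks = {}
    for label in config.factor_labels:
        mult = np.where(sim.code_bit(label), 4.0, 1.0)
        factor_tracks[label] = simulate_tags(
            config, sim.anchor, mult, rng_factors, label
        )
    tss = simulate_tss(config, seed=np.random.default_rng(s_tss))
    write_bed(sim.anchor, outdir / "anchor.bed")
    for label, ps in sim.factor_peaks.items():
        write_bed(ps, outdir / f"{label}.bed")
    sim.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    lines.append(f"anchor peaks: {len(sim.anchor)}")
    for label, ps in sim.factor_peaks.items():
        lines.append(f"{label} peaks: {len(ps)}")

    # 2 — overlap screen
    stage("screen")
    rows = overlap_screen(sim.anchor, list(sim.factor_peaks.values()))
    pd.DataFrame(rows).to_csv(outdir / "screen.tsv", sep="\t", index=False)
    for r in rows:
        lines.append(
            f"{r.factor_label}: overlap={r.overlap_count} "
            f"coeff_anchor={_fmt(r.coefficient_anchor)} "
            f"coeff_merged={_fmt(r.coefficient_merged)}"
        )
    summary["screen"] = {r.factor_label: r.coefficient_anchor for r in rows}

    # 3 — combination classification + NMF
    stage("combos")
    table = classify_combinations(sim.anchor, list(sim.factor_peaks.values()))
    classes = combination_classes_as_sitesets(table)
    table.to_frame().to_csv(outdir / "scodes.tsv", sep="\t", index=False)
    pairwise_overlap_matrix(list(sim.factor_peaks.values())).to_csv(
        outdir / "pairwise_overlap_pct.tsv", sep="\t"
    )
    for card in sorted(table.coverage_by_cardinality):
        lines.append(
            f"bound by {card} factor(s): "
            f"{_fmt(table.coverage_by_cardinality[card])}"
        )
    lines.append(f"covered (>=1 factor): {_fmt(table.covered_fraction)}")
    summary["coverage_by_cardinality"] = table.coverage_by_cardinality
    summary["covered_fraction"] = table.covered_fraction
    nmf_matrix = np.column_stack(
        [site_signal(sim.anchor, trk) for trk in factor_tracks.values()]
    )
    nmf = nmf_binding(nmf_matrix, rank=2, seed=int(ss.entropy % (2**31)))
    np.savetxt(outdir / "nmf_coefficients.tsv", nmf.coefficients, delimiter="\t")
    lines.append(f"nmf reconstruction error: {_fmt(nmf.reconstruction_error)}")

    # 4 — binned density profiles per class
    stage("density")
    central = {}
    profiles = {}
    for code, siteset in classes.items():
        if len(siteset) == 0:
            continue
        prof = mean_profile(binned_density(siteset, ctrl))
        profiles[f"S{code}"] = prof
        central[f"S{code}"] = float(prof[len(prof) // 2])
    prof_df = pd.DataFrame(profiles)
    prof_df.insert(0, "bin_offset", np.arange(len(prof_df)) * 100 - 2000)
    prof_df.to_csv(outdir / "class_profiles.tsv", sep="\t", index=False)
    for code in sorted(central):
        lines.append(f"central anchor density {code}: {_fmt(central[code])}")
    summary["central_density_by_class"] = central

    # 5 — super-enhancer screen on the all-bound class
    stage("superenhancer")
    all_code = "1" * table.k
    cobound = classes.get(all_code)
    if cobound is not None and len(cobound) >= 3:
        regions = score_regions(
            stitch(cobound, tss_table=tss), h3k27ac
        )
        ranked = rank_and_cut(regions)
        ranked.rank_curve().to_csv(outdir / "se_rank_curve.tsv", sep="\t", index=False)
        assignments, n_genes = assign_nearest_gene(ranked.supers, tss)
        pd.DataFrame(assignments).to_csv(
            outdir / "se_gene_assignments.tsv", sep="\t", index=False
        )
        lines.append(f"stitched regions: {len(ranked.regions)}")
        lines.append(f"super-enhancers: {ranked.n_super}")
        lines.append(f"unique genes: {n_genes}")
        summary["n_stitched"] = len(ranked.regions)
        summary["n_super"] = ranked.n_super
        summary["n_unique_genes"] = n_genes
    else:
        lines.append("too few all-bound sites for the super-enhancer screen")

    # 6 — perturbation
    stage("perturb")
    change = classify_binding_change(sim.anchor, ctrl, kd)
    change.table.to_csv(outdir / "binding_change.tsv", sep="\t", index=False)
    for cls in ("weaker", "unchanged", "stronger"):
        lines.append(f"{cls}: {_fmt(change.class_fractions[cls])}")
    summary["class_fractions"] = change.class_fractions
    atac_kd, _lost = simulate_peak_loss(
        sim.anchor, 0.69, np.random.default_rng(s_atac), "atac_shKD"
    )
    diff = peakset_diff(sim.anchor, atac_kd)
    lines.append(f"peaks lost fraction: {_fmt(diff.lost_fraction)}")
    summary["lost_fraction"] = diff.lost_fraction

    # 7 — survival
    stage("survive")
    cohort, _codes = simulate_cohort(config, np.random.default_rng(s_cohort))
    cohort.data.to_csv(outdir / "cohort.tsv", sep="\t")
    coded = encode_expression(cohort, list(config.cohort_genes))
    curves = km_by_code(coded)
    curve_rows = []
    for code, curve in curves.items():
        for t, s, n in zip(curve.times, curve.survival, curve.at_risk):
            curve_rows.append((curve.group_label, t, s, n))
    pd.DataFrame(
        curve_rows, columns=["group", "time", "survival", "at_risk"]
    ).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)
    included = coded.included_codes()
    sub = coded.data[coded.data["ecode"].isin(included)]
    lr = logrank_test(
        sub["time"].to_numpy(), sub["event"].to_numpy(), sub["ecode"].to_numpy()
    )
    lines.append(f"e-code groups tested: {len(included)}")
    if coded.excluded_codes:
        lines.append("excluded small groups: " + ",".join(coded.excluded_codes))
    lines.append(f"log-rank statistic: {_fmt(lr['statistic'])}")
    lines.append(f"log-rank p: {_fmt(lr['p_value'])}")
    summary["logrank_p"] = lr["p_value"]

    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    manifest = {
        "tool": "cistrio",
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) for k, v in vars(config).items()},
        "started": t0,
        "finished": _time.time(),
        "stage_start_times": timings,
        "outputs": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
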