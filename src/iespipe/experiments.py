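"""Study-level experiments over the pipeline.

Each function runs one self-contained in-silico experiment at its study
conditions and returns plain dictionaries of measured quantities; the
acceptance checks, the analysis drivers and the reproduction script are thin
wrappers over these. All randomness derives from the single ``seed``
argument.
"""

from __future__ import annotations

import math

import numpy as np

from .enrichment import (
    enrichment_index,
    length_stats,
    matched_random_sample,
    neighbor_density,
    replicate_correlation,
    set_overlap,
)
from .pipeline import scenario_config, run_pipeline
from .scoring import (
    build_junction_library,
    count_and_score,
    estimate_retention,
    test_retention,
)
from .simulate import (
    SimulationConfig,
    assign_retention,
    generate_genome_pair,
    simulate_read_pairs,
)
from .types import SimulationTruth
from .validation import bruteforce_counts, enumerate_expected_counts

__all__ = [
    "oracle_agreement",
    "estimator_recovery",
    "null_calibration",
    "knockdown_sensitivity",
    "feature_recovery",
]


def _sub_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, n)]


def oracle_agreement(seed: int = 0, n_instances: int = 20) -> dict:
    """Exact equality of the production counter vs the brute-force scan.

    Random small instances (5 kb genome, ~1,000 read pairs each); every
    IES+/IES-/ambiguous count must match the naive substring-scan oracle
    exactly.
    """
    seeds = _sub_seeds(seed, n_instances)
    n_match = 0
    n_pairs_total = 0
    for s in seeds:
        cfg = SimulationConfig(
            replicon_length=5_000, n_ies=5, sparse_min_gap=150, rng_seed=s
        )
        mac, germ, anns = generate_genome_pair(cfg)
        truth = SimulationTruth({a.ies_id: 0.5 for a in anns}, rho=0.5)
        reads = simulate_read_pairs(mac, germ, anns, truth, coverage=40, rng_seed=s + 1)
        pairs = [(p.read1, p.read2) for p in reads.pairs]
        n_pairs_total += len(pairs)
        library = build_junction_library(mac, germ, anns)
        records = count_and_score(pairs, library)
        oracle = bruteforce_counts(pairs, mac, anns, library.min_overlap)
        ok = all(
            (r.counts.ies_plus, r.counts.ies_minus, r.counts.ambiguous,
             r.counts.pair_plus, r.counts.pair_minus) == oracle[r.ies_id]
            for r in records
        )
        n_match += ok
    return {
        "n_instances": n_instances,
        "n_match": n_match,
        "agreement_pct": 100.0 * n_match / n_instances,
        "n_pairs_total": n_pairs_total,
    }


def estimator_recovery(
    seed: int = 0,
    n_ies: int = 500,
    rho: float = 0.5,
    coverage: float = 100.0,
    read_length: int = 100,
    mean_insert: int = 300,
) -> dict:
    """Recovery of planted retention probabilities under whole-cell dilution.

    Per-IES true retention is an even grid over [0, 1]; IES loci are spaced
    farther apart than the insert so the fragment-enumeration oracle is exact
    for the simulator's generative model. Reports the RMSE of
    ``r_hat = min(1, irs/rho)`` against the planted grid and the gap between
    the empirical mean apparent score and the oracle expectation.
    """
    g_seed, r_seed = _sub_seeds(seed, 2)
    cfg = SimulationConfig(
        replicon_length=int(n_ies * 390 + 2 * 400),
        n_ies=n_ies,
        sparse_min_gap=mean_insert + 50,
        rng_seed=g_seed,
    )
    mac, germ, anns = generate_genome_pair(cfg)
    ids = sorted(a.ies_id for a in anns)
    grid = {i: (k / (len(ids) - 1) if len(ids) > 1 else 0.5) for k, i in enumerate(ids)}
    truth = SimulationTruth(grid, rho=rho)
    reads = simulate_read_pairs(
        mac, germ, anns, truth, coverage, read_length, mean_insert, rng_seed=r_seed
    )
    library = build_junction_library(mac, germ, anns, flank_k=read_length)
    records = count_and_score(reads, library)
    irs = {r.ies_id: r.irs for r in records}
    r_hat = {i: estimate_retention(irs[i], rho) for i in ids}
    defined = [i for i in ids if not math.isnan(r_hat[i])]
    rmse = float(
        np.sqrt(np.mean([(r_hat[i] - grid[i]) ** 2 for i in defined]))
    )
    genome_len = sum(len(s) for s in mac.values())
    n_frag = int(round(coverage * genome_len / (2 * read_length)))
    expected = enumerate_expected_counts(
        mac, anns, truth, n_frag, read_length, mean_insert, library.min_overlap
    )
    mean_irs = float(np.mean([irs[i] for i in defined]))
    oracle_mean = float(np.mean([expected[i].expected_irs for i in defined]))
    return {
        "n_ies": len(ids),
        "n_defined": len(defined),
        "n_pairs": len(reads),
        "rmse": rmse,
        "mean_irs": mean_irs,
        "oracle_mean_irs": oracle_mean,
        "mean_irs_gap": mean_irs - oracle_mean,
    }


def null_calibration(
    seed: int = 0,
    n_replicates: int = 20,
    n_ies: int = 500,
    r: float = 0.2,
    rho: float = 0.5,
    coverage: float = 30.0,
    alpha: float = 0.05,
) -> dict:
    """False-discovery behaviour when case and control share the same truth.

    One genome and one truth (uniform retention), ``n_replicates``
    independent case/control read-pair simulations; every significant call is
    by construction a false discovery, so the per-replicate false-discovery
    proportion is 1 if anything is called and 0 otherwise.
    """
    seeds = _sub_seeds(seed, 1 + 2 * n_replicates)
    cfg = SimulationConfig(replicon_length=130_000, n_ies=n_ies, rng_seed=seeds[0])
    mac, germ, anns = generate_genome_pair(cfg)
    dens = neighbor_density(anns)
    truth = assign_retention(anns, dens, "uniform", 0, r=r, rho=rho)
    library = build_junction_library(mac, germ, anns)
    fdps = []
    n_sig_total = 0
    for k in range(n_replicates):
        case = count_and_score(
            simulate_read_pairs(mac, germ, anns, truth, coverage, rng_seed=seeds[1 + 2 * k]),
            library, "case",
        )
        ctrl = count_and_score(
            simulate_read_pairs(mac, germ, anns, truth, coverage, rng_seed=seeds[2 + 2 * k]),
            library, "control",
        )
        tested = test_retention(case, ctrl, alpha=alpha)
        n_sig = sum(rec.significant for rec in tested)
        n_sig_total += n_sig
        fdps.append(1.0 if n_sig > 0 else 0.0)  # all truths equal: any call is false
    return {
        "n_replicates": n_replicates,
        "n_ies": n_ies,
        "alpha": alpha,
        "mean_fdp": float(np.mean(fdps)),
        "n_significant_total": n_sig_total,
    }


def knockdown_sensitivity(
    seed: int = 0,
    n_ies: int = 500,
    rho: float = 0.5,
    coverage: float = 30.0,
    alpha: float = 0.05,
) -> dict:
    """Power against a genome-wide excision failure.

    All IESs retained in the case, none in the control; reports the fraction
    of adequately covered (tested) IESs called significantly retained.
    """
    seeds = _sub_seeds(seed, 3)
    cfg = SimulationConfig(replicon_length=130_000, n_ies=n_ies, rng_seed=seeds[0])
    mac, germ, anns = generate_genome_pair(cfg)
    dens = neighbor_density(anns)
    library = build_junction_library(mac, germ, anns)
    case_truth = assign_retention(anns, dens, "all_retained", rho=rho)
    ctrl_truth = assign_retention(anns, dens, "none_retained", rho=rho)
    case = count_and_score(
        simulate_read_pairs(mac, germ, anns, case_truth, coverage, rng_seed=seeds[1]),
        library, "kd",
    )
    ctrl = count_and_score(
        simulate_read_pairs(mac, germ, anns, ctrl_truth, coverage, rng_seed=seeds[2]),
        library, "control",
    )
    tested = test_retention(case, ctrl, alpha=alpha)
    n_tested = sum(r.tested for r in tested)
    n_sig = sum(r.significant for r in tested)
    mean_irs_case = float(np.nanmean([r.irs for r in case]))
    mean_irs_ctrl = float(np.nanmean([r.irs for r in ctrl]))
    return {
        "n_ies": n_ies,
        "n_tested": n_tested,
        "n_significant": n_sig,
        "sensitivity": n_sig / n_tested if n_tested else math.nan,
        "mean_irs_case": mean_irs_case,
        "mean_irs_control": mean_irs_ctrl,
    }


def feature_recovery(seed: int = 0, outdir: str | None = None, n_sample_seeds: int = 20) -> dict:
    """Retained-IES feature structure under length/density-biased retention.

    Runs the feature scenario end to end, then characterizes the
    significantly retained set of replicate 1: density-class enrichment
    indexes, first-peak fractions, and the two matched random-sampling
    controls (averaged over ``n_sample_seeds`` draws: a density-matched
    sample's mean length, and a length-matched sample's top-class enrichment).
    """
    import tempfile

    if outdir is None:
        outdir = tempfile.mkdtemp(prefix="iespipe_feature_")
    cfg = scenario_config("feature", seed=seed, outdir=outdir)
    summary = run_pipeline(cfg)

    # recompute the retained set and universe in memory for the controls
    import dataclasses

    from .pipeline import _stage_seeds

    sim = dataclasses.replace(cfg.sim, rng_seed=_stage_seeds(cfg.seed, 1)[0])
    mac, germ, anns = generate_genome_pair(sim)
    from .io import read_tsv

    frame = read_tsv(f"{outdir}/scores_{cfg.case_label}_r1.tsv")
    retained = [str(r.ies_id) for r in frame.itertuples() if bool(r.significant)]
    dens = neighbor_density(anns, cfg.window)
    ann_by = {a.ies_id: a for a in anns}

    ei = enrichment_index(retained, anns, dens, cfg.max_density_class)
    top = ei[
        (ei.n_universe > 0)
        & (ei.density_class.isin([str(c) for c in range(5, cfg.max_density_class)]
                                 + [f"{cfg.max_density_class}+"]))
    ]
    uni_peak, _ = length_stats([a.length for a in anns], cfg.first_peak)
    ret_peak, _ = length_stats([ann_by[i].length for i in retained], cfg.first_peak)
    uni_mean_len = float(np.mean([a.length for a in anns]))

    sample_seeds = _sub_seeds(seed + 10_000, n_sample_seeds)
    dens_matched_lens = []
    len_matched_top_ei = []
    for s in sample_seeds:
        dm = matched_random_sample(anns, retained, "density", dens, rng_seed=s,
                                   max_class=cfg.max_density_class)
        dens_matched_lens.append(np.mean([ann_by[i].length for i in dm.ids]))
        lm = matched_random_sample(anns, retained, "length", rng_seed=s + 1)
        ei_lm = enrichment_index(lm.ids, anns, dens, cfg.max_density_class)
        len_matched_top_ei.append(float(ei_lm.iloc[-1]["ei"]))

    frame2 = read_tsv(f"{outdir}/scores_{cfg.case_label}_r2.tsv")
    retained2 = [str(r.ies_id) for r in frame2.itertuples() if bool(r.significant)]
    overlap = set_overlap(retained, retained2)
    from .io import scores_from_frame

    spearman, n_shared = replicate_correlation(
        scores_from_frame(frame), scores_from_frame(frame2)
    )
    return {
        "summary": summary,
        "n_retained": len(retained),
        "universe_size": len(anns),
        "ei_table": ei,
        "top_class_ei": {
            str(row.density_class): float(row.ei) for row in top.itertuples()
        },
        "retained_first_peak": ret_peak,
        "universe_first_peak": uni_peak,
        "universe_mean_length": uni_mean_len,
        "density_matched_mean_length": float(np.mean(dens_matched_lens)),
        "length_matched_top_ei": float(np.nanmean(len_matched_top_ei)),
        "retained_top_ei": float(ei.iloc[-1]["ei"]),
        "replicate_overlap": overlap,
        "replicate_spearman": spearman,
        "n_shared_scores": n_shared,
    }
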