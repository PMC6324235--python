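"""Shared fixtures: simulated scenarios run once per session.

Each fixture executes the real pipeline path (simulate -> hits -> blocks ->
Ks -> classification -> profiling) on a fixed-seed scenario and exposes the
intermediate objects so module tests and acceptance tests can assert
against the same computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ploidyscan import correction, ksdist, pipeline, ploidy, simulate


def run_depth_flow(scenario_name: str, reference: str, target: str, seed: int = 1,
                   n_genes: int = 200, **overrides) -> dict:
    """simulate -> blocks -> Ks -> Ks-classification -> depth profile."""
    cfg = pipeline.PipelineConfig(
        outdir="unused", scenario=scenario_name, seed=seed,
        scenario_overrides={"n_ancestral_genes": n_genes, **overrides},
        render_dotplots=False)
    genomes, sequences, hit_cache, truth = pipeline.load_inputs(cfg)
    blocks = pipeline.blocks_between(genomes, hit_cache, reference, target, cfg)
    cache = pipeline.block_ks(blocks, sequences)
    labeled = ploidy.classify_blocks_by_ks(blocks, *simulate.SCENARIO_KS_THRESHOLDS)
    profile = ploidy.depth_profile(genomes[reference], labeled, target)
    return {"genomes": genomes, "sequences": sequences, "hit_cache": hit_cache,
            "truth": truth, "blocks": labeled, "ks_cache": cache,
            "profile": profile, "config": cfg}


def truth_label_blocks(blocks, truth) -> list:
    """Label blocks by the majority true relation of their gene pairs.

    Used where a test targets downstream depth/table logic rather than the
    Ks classifier, so no sequence evolution is needed.
    """
    for b in blocks:
        votes = {}
        for q, s in b.pairs:
            rel = truth.relation(q, s)
            votes[rel] = votes.get(rel, 0) + 1
        top = max(votes, key=votes.get)
        if top == "ortholog":
            b.label = ploidy.ORTHOLOG
        elif top and top.endswith("outparalog"):
            b.label = ploidy.OUTPARALOG
        else:
            b.label = ploidy.AMBIGUOUS
    return blocks


@pytest.fixture(scope="session")
def ech_dsh_run():
    """Shared hexaploidization + durian triplication, no loss, grape vs durian."""
    return run_depth_flow("ech_dsh", "grape", "durian", seed=1)


@pytest.fixture(scope="session")
def ech_wgd_run():
    """Shared hexaploidization + durian WGD, no loss, grape vs durian."""
    return run_depth_flow("ech_wgd", "grape", "durian", seed=1)


@pytest.fixture(scope="session")
def ech_only_run():
    """Shared hexaploidization only, no loss, grape vs durian."""
    return run_depth_flow("ech_only", "grape", "durian", seed=1)


@pytest.fixture(scope="session")
def durian_cotton_run():
    """Full independent-events model, durian reference vs cotton."""
    return run_depth_flow("ech_dsh_gsd", "durian", "cotton", seed=1)


@pytest.fixture(scope="session")
def rate_recovery_run():
    """Two-step rate-correction exercise on the elevated-cotton scenario.

    Returns the per-sample mixture fits plus the corrected peaks and dates
    computed exactly as the correction stage does.
    """
    cfg = pipeline.PipelineConfig(
        outdir="unused", scenario="rate_recovery", seed=5,
        scenario_overrides={"n_ancestral_genes": 150}, render_dotplots=False)
    genomes, sequences, hit_cache, truth = pipeline.load_inputs(cfg)

    blocks, ks_cache = {}, {}
    for pair in [("grape", "grape"), ("cacao", "cacao"), ("durian", "durian"),
                 ("cotton", "cotton"), ("durian", "cacao"), ("cotton", "cacao")]:
        b = pipeline.blocks_between(genomes, hit_cache, *pair, cfg)
        pipeline.block_ks(b, sequences, ks_cache)
        if pair[0] != pair[1]:
            ploidy.classify_blocks_by_ks(b, *simulate.SCENARIO_KS_THRESHOLDS)
        blocks[pair] = b

    samples = {
        "grape": pipeline.ks_sample(blocks[("grape", "grape")], ks_cache),
        "cacao": pipeline.ks_sample(blocks[("cacao", "cacao")], ks_cache),
        "durian": pipeline.ks_sample(blocks[("durian", "durian")], ks_cache),
        "cotton": pipeline.ks_sample(blocks[("cotton", "cotton")], ks_cache),
        "durian-cacao": pipeline.ks_sample(blocks[("durian", "cacao")], ks_cache,
                                           ploidy.ORTHOLOG),
        "cotton-cacao": pipeline.ks_sample(blocks[("cotton", "cacao")], ks_cache,
                                           ploidy.ORTHOLOG),
    }
    fits = {k: ksdist.fit_ks_distribution(v) for k, v in samples.items()}

    ech_peaks = {t: pipeline.ech_component(fits[t]).mean
                 for t in ("grape", "cacao", "durian", "cotton")}
    model = correction.build_correction_model(ech_peaks)

    recovered, refits = {}, {}
    for taxon in ("durian", "cotton"):
        sample = correction.apply_correction(samples[taxon], model.step1[taxon])
        if taxon == "cotton":
            mu_cc = correction.correct_between(
                [fits["cotton-cacao"].principal_mean],
                model.step1["cotton"], model.step1["cacao"])[0]
            mu_dc = correction.correct_between(
                [fits["durian-cacao"].principal_mean],
                model.step1["durian"], model.step1["cacao"])[0]
            model.step2 = correction.step2_coefficient(mu_dc, mu_cc)
            sample = correction.apply_correction(sample, model.step2)
        refit = ksdist.fit_ks_distribution(sample)
        refits[taxon] = refit
        recovered[taxon] = pipeline.recent_component(refit).mean

    dates = {
        "DSH": correction.date_event(recovered["durian"], ech_peaks["grape"],
                                     event="DSH"),
        "GSD": correction.date_event(recovered["cotton"], ech_peaks["grape"],
                                     event="GSD"),
    }
    return {"genomes": genomes, "sequences": sequences, "truth": truth,
            "blocks": blocks, "ks_cache": ks_cache, "samples": samples,
            "fits": fits, "refits": refits, "model": model,
            "ech_peaks": ech_peaks, "recovered": recovered, "dates": dates}
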