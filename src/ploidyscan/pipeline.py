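"""End-to-end orchestration: simulate/load -> blocks -> Ks -> fits ->
correction & dating -> ploidy profiling -> fractionation -> trees.

Every stage is a thin call into the corresponding module; results are
written as TSV/JSON (plus SVG/PNG dotplots and Newick trees) under the
output directory, together with a run manifest.  Stage failures abort with
the stage name attached.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import colinearity, correction, fractionation, ksdist, ploidy, simulate, trees
from .genome import GenomeTable, read_fasta

log = logging.getLogger("ploidyscan")

TAXA = simulate.TAXA


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    scenario: str | None = None          # simulator scenario name, or
    input_dir: str | None = None         # directory of real inputs
    seed: int = 0
    scenario_overrides: dict = dataclasses.field(default_factory=dict)
    reference: str = "grape"
    evalue_max: float = 1e-5
    max_gap: int = 50
    min_pairs: int = 4
    bandwidth: float = 0.05
    r2_min: float = 0.95
    ortholog_max: float = simulate.SCENARIO_KS_THRESHOLDS[0]
    outparalog_min: float = simulate.SCENARIO_KS_THRESHOLDS[1]
    window: int = 20
    bootstrap_n: int = 100
    support_min: float = 70.0
    calibration: tuple[float, float] = (115.0, 130.0)
    max_tree_groups: int = 50
    min_fit_n: int = 50
    render_dotplots: bool = True

    def validate(self) -> None:
        if (self.scenario is None) == (self.input_dir is None):
            raise ValueError("exactly one of scenario / input_dir must be set")
        for name in ("evalue_max", "max_gap", "min_pairs", "bandwidth", "r2_min",
                     "ortholog_max", "outparalog_min", "window", "support_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# ---------------------------------------------------------------- stage steps


def load_inputs(cfg: PipelineConfig):
    """Simulate a scenario, or read BED + FASTA + hit tables from a directory."""
    if cfg.scenario is not None:
        config = simulate.scenario(cfg.scenario, seed=cfg.seed, **cfg.scenario_overrides)
        genomes, truth, sequences = simulate.simulate_all(config)
        hit_cache: dict[tuple[str, str], list] = {}
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
        import itertools as it
        for a, b in it.combinations_with_replacement(sorted(genomes), 2):
            hit_cache[(a, b)] = [
                colinearity.HomologHit(q, s, pid, ev, bits)
                for q, s, pid, ln, ev, bits in simulate.hit_rows(truth, config, a, b, rng)
            ]
        return genomes, sequences, hit_cache, truth
    indir = Path(cfg.input_dir)
    genomes = {}
    sequences = {}
    hit_cache = {}
    for bed in sorted(indir.glob("*.bed")):
        taxon = bed.stem
        genomes[taxon] = GenomeTable.read_bed(taxon, bed)
        fasta = indir / f"{taxon}.cds.fasta"
        if fasta.exists():
            sequences.update(read_fasta(fasta))
    for hits_path in sorted(indir.glob("hits.*.tsv")):
        a, b = hits_path.stem.split(".", 1)[1].split("-")
        hit_cache[(a, b)] = colinearity.read_blast_tab(hits_path)
    return genomes, sequences, hit_cache, None


def hits_between(hit_cache: Mapping, a: str, b: str):
    if (a, b) in hit_cache:
        return hit_cache[(a, b)], False
    if (b, a) in hit_cache:
        return hit_cache[(b, a)], True
    raise KeyError(f"no hit table for {a}-{b}")


def blocks_between(genomes, hit_cache, a: str, b: str, cfg: PipelineConfig):
    """Detect blocks with taxon ``a`` on the A side."""
    hits, swapped = hits_between(hit_cache, a, b)
    if swapped:
        hits = [colinearity.HomologHit(h.subject, h.query, h.identity, h.evalue,
                                       h.bitscore) for h in hits]
    ta, tb = genomes[a], (genomes[a] if a == b else genomes[b])
    blocks = colinearity.detect_blocks(hits, ta, tb, cfg.max_gap, cfg.min_pairs,
                                       cfg.evalue_max)
    colinearity.score_all_blocks(blocks, ta, tb, hits, cfg.max_gap)
    return blocks


def block_ks(blocks: Sequence, sequences: Mapping[str, str],
             cache: dict[tuple[str, str], ksdist.KsEstimate] | None = None
             ) -> dict[tuple[str, str], ksdist.KsEstimate]:
    """Ks per gene pair of every block; fills block.median_ks in place."""
    cache = cache if cache is not None else {}
    for b in blocks:
        ests = []
        for q, s in b.pairs:
            key = (q, s) if q <= s else (s, q)
            if key not in cache:
                cache[key] = ksdist.pair_ks(sequences[q], sequences[s], q, s)
            ests.append(cache[key])
        b.median_ks = ksdist.block_median_ks(ests)
    return cache


def ks_sample(blocks: Sequence, cache: Mapping, label: str | None = None) -> list[float]:
    """Finite pairwise Ks values of (optionally label-filtered) blocks."""
    out = []
    for b in blocks:
        if label is not None and b.label != label:
            continue
        for q, s in b.pairs:
            key = (q, s) if q <= s else (s, q)
            est = cache.get(key)
            if est is not None and est.defined:
                out.append(est.ks)
    return out


def ech_component(fit: ksdist.KsPeakFit, weight_min: float = 0.05):
    """The shared-hexaploidization component: largest mean with real weight."""
    cands = [c for c in fit.components if c.weight >= weight_min] or fit.components
    return max(cands, key=lambda c: c.mean)


def recent_component(fit: ksdist.KsPeakFit, weight_min: float = 0.05):
    """The youngest substantive component, or None if the fit is unimodal."""
    cands = [c for c in fit.components if c.weight >= weight_min] or fit.components
    if len(cands) < 2:
        return None
    return min(cands, key=lambda c: c.mean)


# ---------------------------------------------------------------- full run


def run_pipeline(cfg: PipelineConfig) -> dict:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "seed": cfg.seed,
                      "stages": []}
    import ploidyscan
    manifest["version"] = getattr(ploidyscan, "__version__", "unknown")

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                fn()
                manifest["stages"].append(name)
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc
        return deco

    state: dict = {}

    @stage("inputs")
    def _inputs():
        genomes, sequences, hit_cache, truth = load_inputs(cfg)
        state.update(genomes=genomes, sequences=sequences, hit_cache=hit_cache,
                     truth=truth)

    genomes = state["genomes"]
    sequences = state["sequences"]
    hit_cache = state["hit_cache"]
    taxa = [t for t in TAXA if t in genomes]
    ref = cfg.reference
    targets = [t for t in taxa if t != ref]

    all_blocks: dict[tuple[str, str], list] = {}
    ks_cache: dict = {}

    @stage("colinearity")
    def _blocks():
        for t in taxa:
            all_blocks[(t, t)] = blocks_between(genomes, hit_cache, t, t, cfg)
        for t in targets:
            all_blocks[(ref, t)] = blocks_between(genomes, hit_cache, ref, t, cfg)
        for a, b in (("durian", "cacao"), ("cotton", "cacao"), ("durian", "cotton")):
            if a in taxa and b in taxa and (a, b) not in all_blocks:
                all_blocks[(a, b)] = blocks_between(genomes, hit_cache, a, b, cfg)
        for pair, blocks in all_blocks.items():
            colinearity.write_blocks_tsv(
                blocks, outdir / f"blocks.{pair[0]}-{pair[1]}.tsv")

    @stage("ks")
    def _ks():
        for blocks in all_blocks.values():
            block_ks(blocks, sequences, ks_cache)
        rows = [{"gene_a": k[0], "gene_b": k[1], "ks": e.ks, "ka": e.ka,
                 "s_sites": e.s_sites, "n_sites": e.n_sites}
                for k, e in sorted(ks_cache.items())]
        pd.DataFrame(rows).to_csv(outdir / "ks_pairs.tsv", sep="\t", index=False)

    labeled: dict[tuple[str, str], list] = {}

    @stage("classification")
    def _classify():
        for pair, blocks in all_blocks.items():
            if pair[0] == pair[1]:
                continue
            labeled[pair] = ploidy.classify_blocks_by_ks(
                blocks, cfg.ortholog_max, cfg.outparalog_min)
            colinearity.write_blocks_tsv(
                blocks, outdir / f"blocks.{pair[0]}-{pair[1]}.tsv")

    fits: dict[str, ksdist.KsPeakFit] = {}

    @stage("fitting")
    def _fits():
        for t in taxa:
            sample = ks_sample(all_blocks[(t, t)], ks_cache)
            if len(sample) >= cfg.min_fit_n:
                fits[t] = ksdist.fit_ks_distribution(
                    sample, cfg.bandwidth, cfg.r2_min, min_n=cfg.min_fit_n)
        for pair in (("durian", "cacao"), ("cotton", "cacao"), ("durian", "cotton")):
            if pair in labeled:
                sample = ks_sample(labeled[pair], ks_cache, ploidy.ORTHOLOG)
                if len(sample) >= cfg.min_fit_n:
                    fits[f"{pair[0]}-{pair[1]}"] = ksdist.fit_ks_distribution(
                        sample, cfg.bandwidth, cfg.r2_min, min_n=cfg.min_fit_n)
        summary = {
            name: [dataclasses.asdict(c) for c in fit.components]
            for name, fit in fits.items()
        }
        (outdir / "ks_fits.json").write_text(json.dumps(summary, indent=2))

    dating_rows: list[dict] = []

    @stage("correction_dating")
    def _correct():
        if "grape" not in fits:
            log.info("no grape paralog fit; skipping correction")
            return
        ech_peaks = {t: ech_component(fits[t]).mean for t in taxa if t in fits}
        model = correction.build_correction_model(ech_peaks, reference="grape")
        ech_cal = ech_peaks["grape"]

        def ortho_peak(fit: ksdist.KsPeakFit) -> float:
            return fit.principal_mean

        def corrected_recent(taxon: str) -> float | None:
            fit = fits.get(taxon)
            comp = recent_component(fit) if fit else None
            if comp is None:
                return None
            sample = np.asarray(ks_sample(all_blocks[(taxon, taxon)], ks_cache))
            sample = correction.apply_correction(sample, model.step1[taxon])
            if taxon == "cotton" and "cotton-cacao" in fits and "durian-cacao" in fits:
                mu_cc = correction.correct_between(
                    [ortho_peak(fits["cotton-cacao"])],
                    model.step1["cotton"], model.step1["cacao"])[0]
                mu_dc = correction.correct_between(
                    [ortho_peak(fits["durian-cacao"])],
                    model.step1["durian"], model.step1["cacao"])[0]
                model.step2 = correction.step2_coefficient(mu_dc, mu_cc)
                sample = correction.apply_correction(sample, model.step2)
            refit = ksdist.fit_ks_distribution(sample, cfg.bandwidth, cfg.r2_min,
                                               min_n=cfg.min_fit_n)
            comp2 = recent_component(refit)
            return comp2.mean if comp2 else None

        for taxon, event in (("durian", "recent-durian"), ("cotton", "recent-cotton")):
            if taxon not in fits:
                continue
            peak = corrected_recent(taxon)
            if peak is None:
                log.info("no post-ECH event peak for %s", taxon)
                continue
            date = correction.date_event(peak, ech_cal, *cfg.calibration, event=event)
            dating_rows.append({
                "event": event, "corrected_peak": peak, "calibration_peak": ech_cal,
                "date_lo_mya": date.date_range[0], "date_hi_mya": date.date_range[1],
            })
        (outdir / "correction.json").write_text(json.dumps({
            "step1": model.step1, "step2": model.step2,
            "ech_calibration_peak": ech_cal}, indent=2))
        pd.DataFrame(dating_rows).to_csv(outdir / "dates.tsv", sep="\t", index=False)

    profiles: dict[str, ploidy.DepthProfile] = {}

    @stage("ploidy")
    def _ploidy():
        for t in targets:
            prof = ploidy.depth_profile(genomes[ref], labeled[(ref, t)], t, cfg.window)
            profiles[t] = prof
            prof.table.to_csv(outdir / f"depth.{ref}-{t}.tsv", sep="\t", index=False)
            if cfg.render_dotplots:
                hits, swapped = hits_between(hit_cache, ref, t)
                if swapped:
                    hits = [colinearity.HomologHit(h.subject, h.query, h.identity,
                                                   h.evalue, h.bitscore) for h in hits]
                ploidy.render_dotplot(hits, genomes[ref], genomes[t],
                                      labeled[(ref, t)], outdir / f"dotplot.{ref}-{t}")
        pd.DataFrame([
            {"target": t, "orthology": p.orthology_ratio,
             "outparalogy": p.outparalogy_ratio}
            for t, p in profiles.items()
        ]).to_csv(outdir / "ploidy_ratios.tsv", sep="\t", index=False)

    table_holder: dict = {}

    @stage("fractionation")
    def _fraction():
        table = fractionation.build_alignment_table(
            genomes[ref], {t: labeled[(ref, t)] for t in targets})
        table_holder["table"] = table
        fractionation.write_alignment_tsv(table, outdir / "alignment_table.tsv")
        stats = {t: fractionation.count_missing(table, t) for t in targets}
        summary: dict = {"missing_fraction": stats}
        if "durian" in targets and "cotton" in targets:
            sim = fractionation.similarity_matrix(table, "durian", "cotton")
            sim.matrix.to_csv(outdir / "similarity.durian-cotton.tsv", sep="\t")
            summary["similarity"] = {"best_match_mean": sim.best_match_mean,
                                     "margin_mean": sim.margin_mean}
        (outdir / "fractionation.json").write_text(json.dumps(summary, indent=2))

    @stage("trees")
    def _trees():
        table = table_holder.get("table")
        needed = {"cacao", "cotton", "durian"}
        if table is None or not needed <= set(table.columns_by_target):
            log.info("tree stage needs cacao+cotton+durian columns; skipping")
            return
        groups = trees.extract_groups(
            table.frame, sequences,
            table.columns_by_target["cacao"],
            table.columns_by_target["cotton"],
            table.columns_by_target["durian"])[:cfg.max_tree_groups]
        rows = []
        with open(outdir / "trees.nwk", "w") as fh:
            for i, g in enumerate(groups):
                res = trees.build_tree(g, "nj", cfg.bootstrap_n, seed=cfg.seed + i)
                fh.write(res.newick + "\n")
                rows.append({
                    "group": g.group_id,
                    "type": trees.classify_topology(res.tree),
                    "pattern": trees.cluster_pattern(res.tree, cfg.support_min),
                })
        frame = pd.DataFrame(rows)
        frame.to_csv(outdir / "tree_topologies.tsv", sep="\t", index=False)
        if len(frame):
            frac = (frame["type"] != "A").mean()
            manifest["distorted_fraction"] = float(frac)

    manifest["n_genes"] = {t: len(genomes[t]) for t in taxa}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "manifest": manifest, "genomes": genomes, "blocks": all_blocks,
        "labeled": labeled, "fits": fits, "profiles": profiles,
        "dates": dating_rows, "outdir": outdir,
    }
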