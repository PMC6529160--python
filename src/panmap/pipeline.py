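"""End-to-end orchestration of the analysis stages on one config.

The pipeline runs the synthetic generators (or consumes user files where
paths are given), then the enabled analysis stages in dependency order:
TE flagging before CNV and pan-genome classification, RBH before SV-block
calling.  Every text output starts with a provenance header (version,
config hash, seed) and a ``manifest.json`` records the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coverage, genome_stats, io_formats, linkage, pangenome
from . import rbh_synteny, simulate, te_overlap


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All thresholds and stage toggles of one pipeline run."""

    seed: int = 0
    out_dir: str = "panmap_out"
    # stage toggles
    stages: tuple[str, ...] = ("simulate", "te", "cnv", "pangenome", "rbh",
                               "anchor", "svdist", "gapstats")
    # thresholds (documented defaults)
    cnv_low: float = 0.5
    cnv_high: float = 1.5
    pangenome_low: float = 0.1
    min_accessions: int = 100
    min_avg_depth: float = 10.0
    te_score_frac: float = 0.9
    te_overlap_frac: float = 0.8
    min_run: int = 3
    window: int = 5
    tolerance: int = 20
    r_max: float = 0.25
    gap_length: int = 100
    flank: int = 30_000
    sv_min_len: int = 1000
    sv_window: int = 1_000_000
    min_contig_length: int = 50_000
    # synthetic-stage sizes
    sim: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    panel_accessions: int = 300
    panel_dispensable: int = 40
    panel_depth: float = 15.0
    f2_plants: int = 500
    f2_missing_rate: float = 0.05
    n_svs: int = 200
    # optional external inputs (paths); when absent, synthetic data is used
    inputs: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)   # the hash covers the scientific config only
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.sim = simulate.SimulationConfig(**sim_d) if isinstance(sim_d, dict) \
            else sim_d
        if "stages" in d:
            cfg.stages = tuple(d["stages"])
        return cfg


_STAGE_DEPS = {
    "cnv": ("simulate", "te"),
    "pangenome": ("simulate", "te"),
    "te": ("simulate",),
    "rbh": ("simulate",),
    "anchor": ("simulate",),
    "svdist": ("simulate",),
    "gapstats": (),
}


def _header(config: RunConfig) -> str:
    return (f"# panmap {__version__}\n"
            f"# config_hash={config.config_hash()}\n"
            f"# seed={config.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns a result bundle of paths/objects."""
    enabled = set(config.stages)
    for stage in enabled:
        if stage not in _STAGE_DEPS and stage != "simulate":
            raise ConfigError(f"unknown stage {stage!r}")
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled and not config.inputs.get(dep):
                raise ConfigError(
                    f"stage {stage!r} requires {dep!r} (enable it or provide input)")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    results: dict = {"out_dir": str(out)}

    config.sim.seed = config.seed
    pair = simulate.simulate_genome_pair(config.sim, rng)
    results["truth"] = pair.truth
    if "simulate" in enabled:
        assembly = io_formats.filter_contigs_by_length(
            pair.assembly, min_length=min(config.min_contig_length,
                                          min(map(len, pair.assembly.values()))))
        with open(out / "assembly.fasta", "w") as fh:
            io_formats.write_fasta(assembly, fh)
        with open(out / "genes.gff3", "w") as fh:
            io_formats.write_gene_models(pair.genes, fh)

    seq_lengths = {sid: len(s) for sid, s in pair.assembly.items()}

    te_flags: dict[str, bool] = {}
    if "te" in enabled:
        te_hits, top_scores = simulate.make_te_hit_table(pair.te_intervals, rng)
        placements = te_overlap.select_te_placements(
            te_hits, top_scores, min_frac=config.te_score_frac)
        flags = te_overlap.flag_te_genes(pair.genes, placements,
                                         min_frac=config.te_overlap_frac)
        te_flags = {f.gene_id: f.flagged for f in flags}
        _write_tsv(pd.DataFrame([dataclasses.asdict(f) for f in flags]),
                   out / "te_flags.tsv", config)
        results["te_flags"] = te_flags

    if "cnv" in enabled:
        track_r = simulate.simulate_depth_track(
            seq_lengths, pair.genes, pair.copy_map_r, config.sim.mean_depth,
            config.sim.bias_spread, rng, accession_id="R")
        track_q = simulate.simulate_depth_track(
            seq_lengths, pair.genes, pair.copy_map_q, config.sim.mean_depth,
            config.sim.bias_spread, rng, accession_id="Q")
        vals_r = coverage.gene_relative_coverage(track_r, pair.genes)
        vals_q = coverage.gene_relative_coverage(track_q, pair.genes)
        calls = coverage.classify_duplications(vals_r, vals_q,
                                               low=config.cnv_low,
                                               high=config.cnv_high)
        calls = coverage.filter_te_calls(calls, te_flags)
        df = pd.DataFrame([{"gene_id": c.gene_id, "v_R": c.v_r, "v_Q": c.v_q,
                            "ratio": c.ratio, "call": c.call} for c in calls])
        _write_tsv(df, out / "duplication_calls.tsv", config)
        results["duplication_calls"] = calls

    if "pangenome" in enabled:
        gene_ids = [g.gene_id for g in pair.genes]
        acc_ids = [f"acc{i:04d}" for i in range(config.panel_accessions)]
        disp = simulate.simulate_dispensable_truth(
            gene_ids, acc_ids, config.panel_dispensable, rng)
        matrix, avg_depth = simulate.simulate_accession_panel(
            gene_ids, config.panel_accessions, disp, config.panel_depth, rng)
        kept = pangenome.filter_accessions(matrix, avg_depth,
                                           min_avg_depth=config.min_avg_depth)
        min_acc = config.min_accessions
        if min_acc >= kept.shape[1]:   # small synthetic panels: scale the cutoff
            min_acc = int(0.1 * kept.shape[1])
        classes = pangenome.classify_genes(kept, te_flags,
                                           low=config.pangenome_low,
                                           min_accessions=min_acc)
        _write_tsv(pd.DataFrame([dataclasses.asdict(c) for c in classes]),
                   out / "gene_classes.tsv", config)
        results["gene_classes"] = classes
        results["dispensable_truth"] = disp

    if "rbh" in enabled:
        tables = simulate.make_rbh_hit_tables(pair.genes, pair.truth, rng)
        map_rq, tied = rbh_synteny.best_hits_with_ties(tables.hits_rq)
        map_qr = rbh_synteny.best_hits(tables.hits_qr)
        pairs = rbh_synteny.reciprocal_best_hits(map_rq, map_qr, pair.genes,
                                                 tables.genes_q, tied_a=tied)
        flags = rbh_synteny.detect_synteny_outliers(pairs, window=config.window,
                                                    tolerance=config.tolerance)
        blocks = rbh_synteny.call_sv_blocks(pairs, flags, min_run=config.min_run)
        _write_tsv(pd.DataFrame([{
            "gene_a": p.gene_a, "gene_b": p.gene_b, "rank_a": p.rank_a,
            "rank_b": p.rank_b, "outlier": f} for p, f in zip(pairs, flags)]),
            out / "rbh_pairs.tsv", config)
        _write_tsv(pd.DataFrame([{
            "sv_type": b.sv_type, "n_genes": b.n_genes,
            "rank_a_start": b.span_a()[0], "rank_a_end": b.span_a()[1]}
            for b in blocks]), out / "sv_blocks.tsv", config)
        results["rbh_pairs"], results["sv_blocks"] = pairs, blocks

    if "anchor" in enabled:
        map_truth = simulate.simulate_marker_map(rng=rng)
        gm, f2_truth = simulate.simulate_f2_population(
            map_truth.markers, config.f2_plants, config.f2_missing_rate, rng)
        placements, unplaced, rf = linkage.anchor_contigs(gm, r_max=config.r_max)
        contig_seqs = {cid: simulate.random_sequence(2000, rng)
                       for cid in map_truth.contig_lengths}
        fasta, agp = linkage.build_pseudochromosomes(
            placements, contig_seqs, gap_length=config.gap_length)
        with open(out / "pseudochromosomes.fasta", "w") as fh:
            io_formats.write_fasta(fasta, fh)
        with open(out / "pseudochromosomes.agp", "w") as fh:
            fh.write(_header(config))
            io_formats.write_agp(agp, fh)
        _write_tsv(pd.DataFrame([dataclasses.asdict(p) for p in placements]),
                   out / "placements.tsv", config)
        _write_tsv(rf, out / "rf_matrix.tsv", config, index=True)
        results["placements"] = placements
        results["map_truth"] = map_truth
        results["f2_truth"] = f2_truth

    if "svdist" in enabled:
        centromeres = {sid: n // 2 for sid, n in seq_lengths.items()}
        # keep >= ~10 windows per sequence on small synthetic genomes
        win = min(config.sv_window, max(config.sv_min_len,
                                        min(seq_lengths.values()) // 10))
        svs = simulate.simulate_clustered_svs(seq_lengths, centromeres,
                                              config.n_svs, rng,
                                              decay_scale=min(seq_lengths.values()) / 5,
                                              min_len=config.sv_min_len,
                                              max_len=max(2 * config.sv_min_len, win // 4))
        table = genome_stats.window_sv_counts(svs, seq_lengths, centromeres,
                                              window=win,
                                              min_len=config.sv_min_len)
        # pool windows across sequences for the rank correlation
        rho, p = genome_stats.spearman(table["centromere_distance"],
                                       table["count"])
        _write_tsv(table, out / "sv_windows.tsv", config)
        results["sv_spearman"] = (rho, p)

    if "gapstats" in enabled:
        scenario = simulate.simulate_gap_scenario(rng=rng, enrich_factor=3.0)
        ref = scenario.reference["ref1"]
        gaps = {f"gap{i}": ("ref1", s, e)
                for i, (s, e) in enumerate(genome_stats.find_assembly_gaps(ref))}
        homologs, rejected = genome_stats.extract_gap_homologs(
            gaps, scenario.flank_hits, scenario.target)
        freqs = [genome_stats.homotetramer_frequency(h.sequence)
                 for h in homologs]
        exclude = {"tig1": [(h.target_start, h.target_end) for h in homologs]}
        controls = genome_stats.sample_control_sequences(
            scenario.target, [len(h.sequence) for h in homologs], rng,
            exclude=exclude)
        control_freqs = [genome_stats.homotetramer_frequency(c) for c in controls]
        u, p = genome_stats.mann_whitney_u(freqs, control_freqs)
        _write_tsv(pd.DataFrame({
            "group": ["gap_homolog"] * len(freqs) + ["control"] * len(control_freqs),
            "homotetramers_per_kbp": freqs + control_freqs}),
            out / "gap_homotetramers.tsv", config)
        results["gap_mwu"] = (u, p)
        results["gap_rejected"] = rejected

    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config.config_hash(),
                "stages": sorted(enabled)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results
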