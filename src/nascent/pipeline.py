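"""File-based pipeline stages and their orchestration.

Each stage reads its inputs from a run directory, writes its outputs there,
and is deterministic given (config, seed). ``run_pipeline`` chains
simulate -> correct -> segment -> kinetics -> diffexpr -> pair -> motifs and
writes a machine-readable summary with per-stage timing and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, io, kinetics, motifs, pairing, segment, simgen, tracks

log = logging.getLogger("nascent")

DEFAULTS = dict(
    seed=1,
    bin_size=200,
    pseudo_count=1.0,
    min_sense=100.0,
    rpk_candidates=[0.5, 1, 2, 4, 8, 16, 32, 64],
    labeling_duration=5.0,
    fc_cutoff=2.0,
    padj_cutoff=0.05,
    exclusion_bp=1000,
    proximal_bp=10_000,
    mrna_prefix_bp=2200,
    n_perm=1000,
    motif_frac=0.8,
    hmm_max_iter=25,
    sim_preset="small",
    plant_rate_pos=0.4,
    plant_rate_neg=0.05,
)


class ConfigError(ValueError):
    pass


class DataError(RuntimeError):
    pass


def load_config(path=None, **overrides) -> dict:
    cfg = dict(DEFAULTS)
    if path is not None:
        import yaml

        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path} is not a mapping")
        cfg.update(user)
    cfg.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("fc_cutoff", "padj_cutoff", "exclusion_bp", "proximal_bp",
                "mrna_prefix_bp", "n_perm", "bin_size"):
        if cfg[key] <= 0:
            raise ConfigError(f"config value {key} must be positive")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# the AP-1 consensus TGACTCA as a sharp count matrix, plus decoys
def default_pfms() -> dict:
    def consensus_pfm(cons, n=100):
        mat = np.ones((4, len(cons)))
        for j, b in enumerate(cons):
            mat["ACGT".index(b), j] = n
        return mat

    return {
        "AP1": consensus_pfm("TGACTCA"),
        "DECOY_CCGCGG": consensus_pfm("CCGCGG"),
        "DECOY_ATTAAT": consensus_pfm("ATTAAT"),
    }


def _track_paths(outdir: Path, sid: str):
    return outdir / f"{sid}.plus.bedgraph", outdir / f"{sid}.minus.bedgraph"


def stage_simulate(cfg: dict, rundir: Path) -> None:
    out = rundir / "sim"
    out.mkdir(parents=True, exist_ok=True)
    preset = cfg.get("sim_preset", "small")
    sim_cfg = (simgen.SimConfig.small() if preset == "small"
               else simgen.SimConfig())
    world = simgen.simulate_world(sim_cfg, seed=cfg["seed"])
    sc = simgen.simulate_counts(world, seed=cfg["seed"] + 1)
    io.write_json({"genome": world.genome}, out / "genome.json")
    io.write_gtf(world.genes, world.exons, out / "reference.gtf")
    io.write_bed(world.enhancer_states, out / "enhancer_states.bed")
    nb = world.neighborhoods.reset_index().rename(columns={"id": "name"})
    io.write_bed(nb, out / "neighborhoods.bed")
    sc.samples.to_csv(out / "samples.tsv", sep="\t")
    io.write_spikein_table(sc.spikeins, out / "spikeins.tsv")
    io.write_count_matrix(sc.counts, sc.lengths, out / "true_counts.tsv")
    for sid, tr in sc.tracks.items():
        io.write_bedgraph(tr, *_track_paths(out, sid))
    pwms = default_pfms()
    io.write_pfms(pwms, out / "pwms.pfm")
    seqs, labels = simgen.simulate_sequences(
        world, pwms["AP1"], cfg["plant_rate_pos"], cfg["plant_rate_neg"],
        seed=cfg["seed"] + 2)
    io.write_fasta({k: v for k, v in seqs.items() if labels[k] == "pos"},
                   out / "sequences_pos.fasta")
    io.write_fasta({k: v for k, v in seqs.items() if labels[k] == "neg"},
                   out / "sequences_neg.fasta")
    truth = dict(
        transcripts=world.truth.transcripts.reset_index().to_dict("records"),
        pairs=world.truth.pairs.to_dict("records"),
        antisense_c=world.truth.antisense_c,
    )
    io.write_json(truth, out / "truth.json")


def _read_world_files(rundir: Path):
    sim = rundir / "sim"
    if not sim.exists():
        raise DataError(f"missing simulate outputs under {sim}")
    genome = {k: int(v) for k, v in io.read_json(sim / "genome.json")["genome"].items()}
    samples = pd.read_csv(sim / "samples.tsv", sep="\t", index_col="sample_id")
    return genome, samples


def stage_correct(cfg: dict, rundir: Path) -> None:
    genome, samples = _read_world_files(rundir)
    sim, out = rundir / "sim", rundir / "correct"
    out.mkdir(exist_ok=True)
    genes, _ = io.read_gtf(sim / "reference.gtf")
    rows = []
    for sid in samples.index:
        tr = io.read_bedgraph(*_track_paths(sim, sid), genome=genome,
                              bin_size=cfg["bin_size"], sample_id=sid)
        try:
            bias = tracks.estimate_antisense_bias(
                tr, genes, min_sense=cfg["min_sense"],
                pseudo_count=cfg["pseudo_count"])
            c = bias.c
            n_used = bias.n_positions_used
        except tracks.CoverageError:
            c, n_used = 0.0, 0
        corrected = tracks.correct_track(tr, c)
        io.write_bedgraph(corrected, *_track_paths(out, sid))
        rows.append(dict(sample_id=sid, c=c, n_positions_used=n_used))
    pd.DataFrame(rows).set_index("sample_id").to_csv(out / "bias.tsv", sep="\t")


def _load_corrected_tracks(cfg, rundir, samples, genome, subset=None):
    out = {}
    for sid in (subset if subset is not None else samples.index):
        out[sid] = io.read_bedgraph(*_track_paths(rundir / "correct", sid),
                                    genome=genome, bin_size=cfg["bin_size"],
                                    sample_id=sid)
    return out


def stage_segment(cfg: dict, rundir: Path) -> None:
    genome, samples = _read_world_files(rundir)
    out = rundir / "segment"
    out.mkdir(exist_ok=True)
    tt_ids = samples.index[samples["assay"] == "TT"]
    tts = _load_corrected_tracks(cfg, rundir, samples, genome, tt_ids)
    track_list = [tts[sid] for sid in tt_ids]
    keys, seqs = segment.tracks_to_sequences(track_list,
                                             pseudo_count=cfg["pseudo_count"])
    params = segment.fit_hmm(seqs, max_iter=cfg["hmm_max_iter"],
                             seed=cfg["seed"])
    decoded = segment.decode_transcribed(params, keys, seqs, cfg["bin_size"],
                                         genome)
    rows = []
    i = 0
    for (chrom, strand), ivals in decoded.items():
        for s, e in ivals:
            rows.append(dict(id=f"tu_{i:05d}", chrom=chrom, start=int(s),
                             end=int(e), strand=strand))
            i += 1
    if not rows:
        raise DataError("segmentation produced no transcribed intervals")
    tus = pd.DataFrame(rows).set_index("id")
    # mean RPK over TT samples (corrected counts)
    cm = tracks.count_matrix(tts, tus)
    lengths = (tus["end"] - tus["start"]).astype(float)
    tus["rpk"] = tracks.rpk(cm.mean(axis=1), lengths)
    theta, scan = segment.optimize_rpk_threshold(
        tus, _reference_intervals(rundir), cfg["rpk_candidates"])
    scan.to_csv(out / "rpk_scan.tsv", sep="\t", index=False)
    tus = tus[tus["rpk"] >= theta]
    # refine boundaries on per-bp expansion of the mean corrected TT coverage
    bs = cfg["bin_size"]
    refined = []
    for strand in ("+", "-"):
        per_bp = {}
        for chrom, length in genome.items():
            binned = np.mean([tts[sid].data[(chrom, strand)] for sid in tt_ids],
                             axis=0)
            per_bp[chrom] = np.repeat(binned / bs, bs)[:length]
        sub = tus[tus["strand"] == strand]
        for tid, r in sub.iterrows():
            s, e = segment.refine_boundaries(r, per_bp)
            refined.append((tid, s, e))
    for tid, s, e in refined:
        tus.loc[tid, ["start", "end"]] = [s, e]
    genes, exons = io.read_gtf(rundir / "sim" / "reference.gtf")
    classified = segment.classify_tus(tus, genes, exons)
    classified.index.name = "id"
    classified.to_csv(out / "tu.tsv", sep="\t")
    bed = classified.reset_index(names="name")
    bed["score"] = 0
    io.write_bed(bed[["chrom", "start", "end", "name", "score", "strand"]],
                 out / "tu.bed")
    io.write_json(dict(rpk_threshold=theta,
                       loglik_path=params.loglik_path), out / "segment.json")


def _reference_intervals(rundir: Path) -> dict:
    genes, _ = io.read_gtf(rundir / "sim" / "reference.gtf")
    out = {}
    for (chrom, strand), grp in genes.groupby(["chrom", "strand"]):
        out[(chrom, strand)] = grp[["start", "end"]].to_numpy()
    return out


def _tu_features(rundir: Path) -> pd.DataFrame:
    tu = pd.read_csv(rundir / "segment" / "tu.tsv", sep="\t", index_col="id")
    return tu


def stage_kinetics(cfg: dict, rundir: Path) -> None:
    genome, samples = _read_world_files(rundir)
    out = rundir / "kinetics"
    out.mkdir(exist_ok=True)
    tu = _tu_features(rundir)
    all_tracks = _load_corrected_tracks(cfg, rundir, samples, genome)
    counts = tracks.count_matrix(all_tracks, tu).round()
    lengths = (tu["end"] - tu["start"]).astype(float)
    io.write_count_matrix(counts, lengths, out / "counts.tsv")
    spike = io.read_spikein_table(rundir / "sim" / "spikeins.tsv")
    cals = kinetics.calibrate(spike, samples["assay"].to_dict())
    t0 = samples["time"].min()
    rates = kinetics.estimate_rates_table(
        counts, lengths, samples, cals, t=cfg["labeling_duration"],
        time_point=t0)
    rates["cls"] = tu["cls"].reindex(rates.index)
    rates.to_csv(out / "rates.tsv", sep="\t")
    pd.DataFrame([dict(sample_id=s.sample_id, sigma=s.sigma,
                       epsilon=s.epsilon, scale=s.scale, assay=s.assay)
                  for s in cals.values()]).set_index("sample_id").to_csv(
        out / "calibration.tsv", sep="\t")


def stage_diffexpr(cfg: dict, rundir: Path) -> None:
    genome, samples = _read_world_files(rundir)
    out = rundir / "diffexpr"
    out.mkdir(exist_ok=True)
    counts, _ = io.read_count_matrix(rundir / "kinetics" / "counts.tsv")
    tu = _tu_features(rundir)
    tt = samples[samples["assay"] == "TT"]
    sub = counts[tt.index]
    pc_ids = tu.index[tu["cls"] == "mRNA"]
    sf = diffexpr.size_factors(sub, pc_ids)
    design = pd.DataFrame({"condition": tt["time"]}, index=tt.index)
    de = diffexpr.test_differential(sub, design, sf)
    de = diffexpr.classify_changes(de, cfg["fc_cutoff"], cfg["padj_cutoff"])
    de.to_csv(out / "de.tsv", sep="\t", index=False)
    sf.to_csv(out / "size_factors.tsv", sep="\t")


def stage_pair(cfg: dict, rundir: Path) -> None:
    genome, samples = _read_world_files(rundir)
    out = rundir / "pair"
    out.mkdir(exist_ok=True)
    tu = _tu_features(rundir)
    enh = io.read_bed(rundir / "sim" / "enhancer_states.bed")
    nb = io.read_bed(rundir / "sim" / "neighborhoods.bed").set_index("name")
    ncrnas = tu[tu["cls"] == "ncRNA"]
    is_erna = pairing.classify_ernas(ncrnas, enh)
    ernas = ncrnas[is_erna]
    mrnas = tu[tu["cls"] == "mRNA"]
    pairs = pairing.pair_within_neighborhoods(ernas, mrnas, nb,
                                              cfg["exclusion_bp"])
    counts, _ = io.read_count_matrix(rundir / "kinetics" / "counts.tsv")
    sf = pd.read_csv(rundir / "diffexpr" / "size_factors.tsv", sep="\t",
                     index_col=0).iloc[:, 0]
    ts = pairing.replicate_averaged(counts, samples, assay="TT", sf=sf)
    pairs = pairing.pair_correlations(pairs, ts)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    report = {}
    if len(pairs) >= 2:
        obs, null, p = pairing.permutation_test(pairs, ts, cfg["n_perm"],
                                                seed=cfg["seed"])
        report = dict(observed=obs, p=p, n_perm=cfg["n_perm"],
                      null_mean=float(np.mean(null)),
                      null_sd=float(np.std(null)))
    closest, diag = pairing.closest_pairing(ernas, mrnas, nb, ts)
    closest.to_csv(out / "closest_pairs.tsv", sep="\t", index=False)
    report["closest_diagnostics"] = diag
    report["summary"] = pairing.pairing_summary(pairs)
    io.write_json(report, out / "permutation.json")


def stage_motifs(cfg: dict, rundir: Path) -> None:
    out = rundir / "motifs"
    out.mkdir(exist_ok=True)
    sim = rundir / "sim"
    pos = io.read_fasta(sim / "sequences_pos.fasta")
    neg = io.read_fasta(sim / "sequences_neg.fasta")
    pwms = io.read_pfms(sim / "pwms.pfm")
    table = motifs.enrichment_table(pos, neg, pwms, frac=cfg["motif_frac"])
    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)


STAGES = [
    ("simulate", stage_simulate),
    ("correct", stage_correct),
    ("segment", stage_segment),
    ("kinetics", stage_kinetics),
    ("diffexpr", stage_diffexpr),
    ("pair", stage_pair),
    ("motifs", stage_motifs),
]


def run_pipeline(cfg: dict, rundir) -> dict:
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    summary = dict(config_hash=config_hash(cfg), stages={})
    for name, fn in STAGES:
        t0 = time.time()
        log.info("stage %s starting", name)
        try:
            fn(cfg, rundir)
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise DataError(f"stage {name} failed: {exc}") from exc
        dt = time.time() - t0
        summary["stages"][name] = dict(seconds=round(dt, 3))
        log.info("stage %s done in %.1fs", name, dt)
    io.write_json(summary, rundir / "summary.json")
    return summary
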