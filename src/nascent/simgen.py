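"""Synthetic worlds with known ground truth for every downstream stage.

A :class:`SimWorld` bundles a toy genome, a reference annotation restricted to
protein-coding/lincRNA genes (the planted ncRNAs/eRNAs are deliberately absent
from the reference, mirroring how unannotated transcription units are called),
enhancer-state and insulated-neighborhood intervals, the experimental design,
and a :class:`SimTruth` with per-transcript kinetic parameters, per-time-point
fold changes and the planted enhancer-promoter pairs.

:func:`simulate_counts` then inverts the downstream observation model: the
expected count of feature i in sample j is ``L_i*(sigma_j*alpha_ij +
epsilon_j*beta_ij)`` with labeled amount ``alpha = mu*(1-exp(-lambda*t))/
lambda`` under first-order kinetics and piecewise-constant synthesis, drawn
Poisson per bin, spread uniformly over the feature's bins, and finally mixed
across strands with the antisense bleed rate ``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .tracks import StrandedCoverageTrack

CLASSES = ("mRNA", "lincRNA", "ncRNA", "eRNA")


class CapacityError(ValueError):
    """Requested transcripts do not fit on the configured genome."""


@dataclass(frozen=True)
class ExperimentDesign:
    time_points: tuple = (0, 5, 10, 15)
    replicates: int = 2
    labeling_duration: float = 5.0
    assays: tuple = ("TT", "RNA")

    def __post_init__(self):
        if self.labeling_duration <= 0:
            raise ValueError("labeling duration must be > 0")
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValueError("time points must be strictly increasing")

    def samples(self) -> pd.DataFrame:
        rows = []
        for assay in self.assays:
            for tp in self.time_points:
                for rep in range(1, self.replicates + 1):
                    rows.append(dict(sample_id=f"{assay}_t{tp}_r{rep}",
                                     assay=assay, time=tp, replicate=rep))
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class SimConfig:
    chromosomes: tuple = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_per_class: tuple = ((("mRNA"), 120), (("lincRNA"), 20), (("ncRNA"), 80),
                          (("eRNA"), 80))
    length_ranges: tuple = ((("mRNA"), (5_000, 30_000)),
                            (("lincRNA"), (2_000, 10_000)),
                            (("ncRNA"), (600, 3_000)),
                            (("eRNA"), (600, 3_000)))
    half_life_ranges: tuple = ((("mRNA"), (30.0, 200.0)),
                               (("lincRNA"), (20.0, 100.0)),
                               (("ncRNA"), (5.0, 60.0)),
                               (("eRNA"), (2.0, 15.0)))
    mu0_log_mean: float = math.log(0.5)
    mu0_log_sd: float = 1.0
    min_gap: int = 2_000
    max_gap: int = 20_000
    n_neighborhoods: int = 40
    neighborhood_size: tuple = (100_000, 400_000)
    neighborhood_gap: int = 10_000
    n_decoy_enhancers: int = 10
    # pairing / regulation truth
    pair_rho: float = 0.8
    distance_decay: float | None = None  # bp; None = constant rho
    frac_pairs_up: float = 0.4
    frac_pairs_down: float = 0.3
    fc_up: float = 4.0
    fc_down: float = 0.25
    traj_noise_sd: float = 0.4  # log2 sd of per-time-point trajectory noise
    frac_unpaired_changed: float = 0.2
    # observation model
    sigma_tt: float = 0.05
    epsilon_tt: float = 5e-4
    sigma_rna: float = 0.01
    depth_jitter_sd: float = 0.1
    antisense_c: float = 0.05
    background_rate: float = 0.05  # Poisson rate per bin per strand
    extra_noise_sd: float = 0.0  # log-normal extra-Poisson noise, log sd
    bin_size: int = 200
    # spike-ins
    n_spike_labeled: int = 8
    n_spike_unlabeled: int = 8
    spike_length_range: tuple = (1_000, 4_000)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)

    def as_dicts(self):
        return (dict(self.n_per_class), dict(self.length_ranges),
                dict(self.half_life_ranges))

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """Desk-scale config for fast tests (1 chromosome, ~90 transcripts)."""
        base = dict(
            chromosomes=(("chr1", 2_500_000),),
            n_per_class=(("mRNA", 35), ("lincRNA", 5), ("ncRNA", 25),
                         ("eRNA", 25)),
            length_ranges=(("mRNA", (4_000, 15_000)),
                           ("lincRNA", (2_000, 8_000)),
                           ("ncRNA", (600, 2_500)),
                           ("eRNA", (600, 2_500))),
            n_neighborhoods=12,
            neighborhood_size=(80_000, 250_000),
            max_gap=10_000,
            n_decoy_enhancers=4,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SimTruth:
    transcripts: pd.DataFrame  # per transcript: coords, class, kinetics, fcs
    pairs: pd.DataFrame  # erna_id, mrna_id, neighborhood_id, rho, pattern, ...
    antisense_c: dict  # sample_id -> c
    spike_amounts: pd.DataFrame
    sample_depths: pd.DataFrame | None = None  # sigma/epsilon truth per sample


@dataclass
class SimWorld:
    genome: dict
    genes: pd.DataFrame  # reference annotation (mRNA + lincRNA only)
    exons: pd.DataFrame
    enhancer_states: pd.DataFrame
    neighborhoods: pd.DataFrame
    truth: SimTruth
    design: ExperimentDesign
    config: SimConfig

    @property
    def features(self) -> pd.DataFrame:
        """All planted transcripts as a chrom/start/end/strand frame."""
        t = self.truth.transcripts
        return t[["chrom", "start", "end", "strand"]].copy()


def _tss(row) -> int:
    return int(row["start"]) if row["strand"] == "+" else int(row["end"]) - 1


def _upstream_interval(row, length=1000):
    if row["strand"] == "+":
        return max(0, int(row["start"]) - length), int(row["start"])
    return int(row["end"]), int(row["end"]) + length


def simulate_world(config: SimConfig = SimConfig(), seed: int = 0) -> SimWorld:
    """Generate a deterministic synthetic world for the given config/seed."""
    rng = np.random.default_rng(seed)
    n_per_class, length_ranges, hl_ranges = config.as_dicts()

    # --- transcript placement -------------------------------------------------
    pool = [cls for cls, n in n_per_class.items() for _ in range(n)]
    rng.shuffle(pool)
    needed = sum(length_ranges[c][1] + config.min_gap for c in pool)
    genome = dict(config.chromosomes)
    if needed > 0.95 * sum(genome.values()):
        raise CapacityError(
            f"~{needed} bp required for {len(pool)} transcripts but genome is "
            f"only {sum(genome.values())} bp")
    rows = []
    counters = {c: 0 for c in CLASSES}
    chrom_iter = iter(genome.items())
    chrom, clen = next(chrom_iter)
    pos = int(rng.integers(config.min_gap, config.max_gap))
    for cls in pool:
        lo, hi = length_ranges[cls]
        length = int(rng.integers(lo, hi + 1))
        while pos + length + config.min_gap > clen:
            try:
                chrom, clen = next(chrom_iter)
            except StopIteration:
                raise CapacityError(
                    "ran out of genome while placing transcripts; reduce "
                    "counts or enlarge chromosomes") from None
            pos = int(rng.integers(config.min_gap, config.max_gap))
        strand = "+" if rng.random() < 0.5 else "-"
        counters[cls] += 1
        rows.append(dict(id=f"{cls.lower()}_{counters[cls]:04d}", cls=cls,
                         chrom=chrom, start=pos, end=pos + length,
                         strand=strand, length=length))
        pos += length + int(rng.integers(config.min_gap, config.max_gap + 1))
    tx = pd.DataFrame(rows).set_index("id")

    # --- kinetics truth -------------------------------------------------------
    hl = np.empty(len(tx))
    for cls, (lo, hi) in hl_ranges.items():
        m = (tx["cls"] == cls).to_numpy()
        hl[m] = np.exp(rng.uniform(math.log(lo), math.log(hi), m.sum()))
    tx["half_life"] = hl
    tx["lam"] = math.log(2) / tx["half_life"]
    tx["mu0"] = np.exp(rng.normal(config.mu0_log_mean, config.mu0_log_sd,
                                  len(tx)))

    # --- neighborhoods --------------------------------------------------------
    nb_rows = []
    per_chrom = max(1, config.n_neighborhoods // max(1, len(genome)))
    i = 0
    for chrom, clen in genome.items():
        pos = int(rng.integers(0, 50_000))
        for _ in range(per_chrom):
            size = int(rng.integers(*config.neighborhood_size))
            if pos + size > clen or i >= config.n_neighborhoods:
                break
            nb_rows.append(dict(id=f"nb_{i:03d}", chrom=chrom, start=pos,
                                end=pos + size))
            pos += size + config.neighborhood_gap
            i += 1
    neighborhoods = pd.DataFrame(nb_rows).set_index("id")

    # --- enhancer states ------------------------------------------------------
    enh_rows = []
    for tid, row in tx[tx["cls"] == "eRNA"].iterrows():
        t = _tss(row)
        enh_rows.append(dict(chrom=row["chrom"], start=max(0, t - 500),
                             end=t + 500, name=f"state_{tid}"))
    # decoys in transcript-free gaps, away from any planted ncRNA/eRNA
    occupied = tx[["chrom", "start", "end"]].copy()
    for _ in range(config.n_decoy_enhancers):
        chrom = list(genome)[int(rng.integers(len(genome)))]
        clen = genome[chrom]
        for _ in range(50):
            p = int(rng.integers(0, clen - 1000))
            near = occupied[(occupied["chrom"] == chrom)
                            & (occupied["start"] - 3_000 < p + 1000)
                            & (occupied["end"] + 3_000 > p)]
            if len(near) == 0:
                enh_rows.append(dict(chrom=chrom, start=p, end=p + 1000,
                                     name="decoy"))
                break
    enhancer_states = pd.DataFrame(enh_rows)

    # --- pairing truth --------------------------------------------------------
    tx["pattern"] = "flat"
    tx["paired"] = False
    pair_rows = []
    ernas = tx[tx["cls"] == "eRNA"]
    mrnas = tx[tx["cls"] == "mRNA"]
    for nbid, nb in neighborhoods.iterrows():
        e_in = [tid for tid, r in ernas.iterrows()
                if r["chrom"] == nb["chrom"] and nb["start"] <= _tss(r) < nb["end"]]
        m_in = [tid for tid, r in mrnas.iterrows()
                if r["chrom"] == nb["chrom"] and nb["start"] <= _tss(r) < nb["end"]]
        if not e_in or not m_in:
            continue
        free = list(m_in)
        for eid in e_in:
            if not free:
                break
            # half the pairs target the closest free promoter so that the
            # planted distance distribution includes proximal (<10 kb) pairs
            if rng.random() < 0.5:
                et = _tss(ernas.loc[eid])
                j = int(np.argmin([abs(_tss(mrnas.loc[m]) - et) for m in free]))
                mid = free.pop(j)
            else:
                mid = free.pop(int(rng.integers(len(free))))
            d = abs(_tss(ernas.loc[eid]) - _tss(mrnas.loc[mid]))
            if d <= 1000:
                continue
            u = rng.random()
            pattern = ("up" if u < config.frac_pairs_up else
                       "down" if u < config.frac_pairs_up + config.frac_pairs_down
                       else "flat")
            rho = config.pair_rho
            if config.distance_decay:
                rho = config.pair_rho * math.exp(-d / config.distance_decay)
            pair_rows.append(dict(erna_id=eid, mrna_id=mid,
                                  neighborhood_id=nbid, distance=d,
                                  rho=rho, pattern=pattern))
            tx.loc[eid, ["pattern", "paired"]] = [pattern, True]
            tx.loc[mid, ["pattern", "paired"]] = [pattern, True]
    pairs = pd.DataFrame(pair_rows,
                         columns=["erna_id", "mrna_id", "neighborhood_id",
                                  "distance", "rho", "pattern"])

    # unpaired transcripts: a fraction also changes (independently)
    unpaired = tx.index[~tx["paired"]]
    flips = rng.random(len(unpaired)) < config.frac_unpaired_changed
    for tid, flip in zip(unpaired, flips):
        if flip:
            tx.loc[tid, "pattern"] = "up" if rng.random() < 0.5 else "down"

    # --- per-time-point fold changes -----------------------------------------
    tps = [t for t in config.design.time_points if t != config.design.time_points[0]]
    shift = {"up": math.log2(config.fc_up), "down": math.log2(config.fc_down),
             "flat": 0.0}
    log2fc = {tid: np.zeros(len(tps)) for tid in tx.index}
    tau = config.traj_noise_sd
    for _, p in pairs.iterrows():
        z = rng.normal(0.0, tau, len(tps))
        rho = min(max(p["rho"], 0.0), 1.0)
        for tid in (p["erna_id"], p["mrna_id"]):
            eta = rng.normal(0.0, tau, len(tps))
            log2fc[tid] = (shift[tx.loc[tid, "pattern"]]
                           + math.sqrt(rho) * z + math.sqrt(1 - rho) * eta)
    for tid in unpaired:
        log2fc[tid] = (shift[tx.loc[tid, "pattern"]]
                       + rng.normal(0.0, tau, len(tps)))
    for j, tp in enumerate(tps):
        tx[f"f{tp}"] = [2.0 ** log2fc[tid][j] for tid in tx.index]
    tx["readthrough"] = False

    # --- reference annotation (mRNA + lincRNA only, single exon) -------------
    ref = tx[tx["cls"].isin(["mRNA", "lincRNA"])]
    genes = pd.DataFrame({
        "chrom": ref["chrom"], "start": ref["start"], "end": ref["end"],
        "strand": ref["strand"],
        "biotype": ref["cls"].map({"mRNA": "protein_coding",
                                   "lincRNA": "lincRNA"}),
    })
    genes.index = [tid.replace("mrna_", "gene_m").replace("lincgene_m", "gene_l")
                   if tid.startswith("mrna_") else tid.replace("lincrna_", "gene_l")
                   for tid in ref.index]
    genes.index.name = "gene_id"
    exons = pd.DataFrame({
        "gene_id": genes.index,
        "transcript_id": [g + ".t1" for g in genes.index],
        "chrom": genes["chrom"].to_numpy(),
        "start": genes["start"].to_numpy(),
        "end": genes["end"].to_numpy(),
        "strand": genes["strand"].to_numpy(),
    }).reset_index(drop=True)

    # --- spike-ins ------------------------------------------------------------
    ns_l, ns_u = config.n_spike_labeled, config.n_spike_unlabeled
    spike = pd.DataFrame({
        "length_bp": rng.integers(config.spike_length_range[0],
                                  config.spike_length_range[1] + 1,
                                  ns_l + ns_u),
        "labeled": [1] * ns_l + [0] * ns_u,
    }, index=[f"spike_l{i}" for i in range(ns_l)]
        + [f"spike_u{i}" for i in range(ns_u)])

    design = config.design
    samples = design.samples()
    truth = SimTruth(
        transcripts=tx,
        pairs=pairs,
        antisense_c={sid: config.antisense_c for sid in samples.index},
        spike_amounts=spike,
    )
    world = SimWorld(genome=genome, genes=genes, exons=exons,
                     enhancer_states=enhancer_states,
                     neighborhoods=neighborhoods, truth=truth, design=design,
                     config=config)
    _check_world(world)
    return world


def _check_world(world: SimWorld) -> None:
    tx = world.truth.transcripts
    for tid, r in tx.iterrows():
        if not (0 <= r["start"] < r["end"] <= world.genome[r["chrom"]]):
            raise AssertionError(f"transcript {tid} outside chromosome bounds")
    nb = world.neighborhoods.sort_values(["chrom", "start"])
    for chrom, grp in nb.groupby("chrom"):
        ends = grp["end"].to_numpy()
        starts = grp["start"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise AssertionError("neighborhoods are nested/overlapping")


def true_amounts(world: SimWorld) -> dict:
    """Per-time-point labeled/unlabeled amounts (alpha, beta) for every feature.

    Synthesis is piecewise constant per inter-time-point interval: the rate in
    force during (T_prev, T_k] is mu0 * f(T_k); labeling always covers the
    final ``labeling_duration`` minutes of each interval. At the first time
    point the system is at steady state with rate mu0.

    Returns {time_point: DataFrame(alpha, beta, total) indexed by feature}.
    """
    tx = world.truth.transcripts
    design = world.design
    t_label = design.labeling_duration
    tps = list(design.time_points)
    lam = tx["lam"].to_numpy()
    mu0 = tx["mu0"].to_numpy()
    out = {}
    A = mu0 / lam  # steady state at first time point
    alpha = mu0 * (1 - np.exp(-lam * t_label)) / lam
    out[tps[0]] = pd.DataFrame({"alpha": alpha, "beta": A - alpha,
                                "total": A}, index=tx.index)
    for prev, tp in zip(tps[:-1], tps[1:]):
        dt = tp - prev
        mu_k = mu0 * tx[f"f{tp}"].to_numpy()
        A = mu_k / lam + (A - mu_k / lam) * np.exp(-lam * dt)
        alpha = mu_k * (1 - np.exp(-lam * t_label)) / lam
        # the labeled part of A synthesized in the last t_label minutes
        alpha = np.minimum(alpha, A)
        out[tp] = pd.DataFrame({"alpha": alpha, "beta": A - alpha,
                                "total": A}, index=tx.index)
    return out


@dataclass
class SimCounts:
    tracks: dict  # sample_id -> StrandedCoverageTrack (after antisense bleed)
    counts: pd.DataFrame  # true-strand feature counts (pre-bleed)
    lengths: pd.Series
    spikeins: pd.DataFrame
    samples: pd.DataFrame
    calibration_truth: pd.DataFrame  # sigma/epsilon per sample
    amounts: dict  # time point -> DataFrame(alpha, beta, total)


def _feature_bins(start, end, bin_size, nbins_total):
    b_lo = max(int(np.ceil((start - bin_size / 2) / bin_size)), 0)
    b_hi = min(int(np.ceil((end - bin_size / 2) / bin_size)), nbins_total)
    return b_lo, b_hi


def simulate_counts(world: SimWorld, seed: int = 0, *, noise: bool = True,
                    antisense_c: float | None = None) -> SimCounts:
    """Draw coverage tracks, feature counts and spike-in counts for a world.

    With ``noise=False`` all Poisson draws are replaced by their means, the
    background is switched off and depths are not jittered, so track bin sums
    over a feature equal ``L_i*(sigma_j*alpha_ij + epsilon_j*beta_ij)``
    exactly (before strand mixing).
    """
    cfg = world.config
    if world.design.labeling_duration <= 0:
        raise ValueError("labeling duration must be > 0")
    rng = np.random.default_rng(seed)
    c = cfg.antisense_c if antisense_c is None else antisense_c
    samples = world.design.samples()
    amounts = true_amounts(world)
    tx = world.truth.transcripts
    bs = cfg.bin_size

    cal_rows = []
    for sid, s in samples.iterrows():
        jit = math.exp(rng.normal(0, cfg.depth_jitter_sd)) if noise else 1.0
        if s["assay"] == "TT":
            sigma, eps = cfg.sigma_tt * jit, cfg.epsilon_tt * jit
        else:
            sigma = eps = cfg.sigma_rna * jit
        cal_rows.append(dict(sample_id=sid, sigma=sigma, epsilon=eps,
                             assay=s["assay"], time=s["time"]))
    cal = pd.DataFrame(cal_rows).set_index("sample_id")

    tracks = {}
    counts = pd.DataFrame(index=tx.index, columns=samples.index, dtype=float)
    for sid, s in samples.iterrows():
        track = StrandedCoverageTrack(bin_size=bs, genome=world.genome,
                                      sample_id=sid)
        am = amounts[s["time"]]
        sigma, eps = cal.loc[sid, "sigma"], cal.loc[sid, "epsilon"]
        for tid, r in tx.iterrows():
            mean = r["length"] * (sigma * am.loc[tid, "alpha"]
                                  + eps * am.loc[tid, "beta"])
            if noise and cfg.extra_noise_sd > 0:
                mean *= math.exp(rng.normal(0, cfg.extra_noise_sd))
            vec = track.data[(r["chrom"], r["strand"])]
            b_lo, b_hi = _feature_bins(r["start"], r["end"], bs, len(vec))
            nb = max(b_hi - b_lo, 1)
            per_bin = mean / nb
            if noise:
                draws = rng.poisson(per_bin, nb).astype(float)
            else:
                draws = np.full(nb, per_bin)
            vec[b_lo:b_hi] += draws
            counts.loc[tid, sid] = draws.sum()
        if noise and cfg.background_rate > 0:
            for key, vec in track.data.items():
                vec += rng.poisson(cfg.background_rate, len(vec))
        # antisense bleed: obs_s = real_s + c * real_a
        if c > 0:
            for chrom in world.genome:
                plus = track.data[(chrom, "+")].copy()
                minus = track.data[(chrom, "-")].copy()
                track.data[(chrom, "+")] = plus + c * minus
                track.data[(chrom, "-")] = minus + c * plus
        tracks[sid] = track

    spike = world.truth.spike_amounts.copy()
    for sid in samples.index:
        sigma, eps = cal.loc[sid, "sigma"], cal.loc[sid, "epsilon"]
        rate = np.where(spike["labeled"] == 1, sigma, eps)
        mean = spike["length_bp"].to_numpy() * rate
        spike[sid] = rng.poisson(mean) if noise else mean
    lengths = tx["length"].astype(float).rename("length_bp")
    return SimCounts(tracks=tracks, counts=counts, lengths=lengths,
                     spikeins=spike, samples=samples, calibration_truth=cal,
                     amounts=amounts)


def simulate_sequences(world: SimWorld, pwm: np.ndarray,
                       plant_rate_pos: float, plant_rate_neg: float,
                       seed: int = 0, *, window: int = 250):
    """Upstream promoter-window sequences with a motif planted at known rates.

    Positive set = planted eRNAs, negative set = other ncRNAs; each sequence
    is ``window`` bp of uniform background, with the PWM's consensus planted
    at a uniform position with the given per-set probability.

    Returns ``(seqs, labels)``: id -> sequence and id -> "pos" | "neg".
    """
    for r in (plant_rate_pos, plant_rate_neg):
        if not (0 <= r <= 1):
            raise ValueError("plant rates must be in [0, 1]")
    mat = np.asarray(pwm, dtype=float)
    w = mat.shape[1]
    if window < w:
        raise ValueError(f"window ({window}) shorter than motif ({w})")
    consensus = "".join("ACGT"[i] for i in mat.argmax(axis=0))
    rng = np.random.default_rng(seed)
    tx = world.truth.transcripts
    pos_ids = list(tx.index[tx["cls"] == "eRNA"])
    neg_ids = list(tx.index[tx["cls"] == "ncRNA"])
    seqs, labels = {}, {}
    for ids, rate, label in ((pos_ids, plant_rate_pos, "pos"),
                             (neg_ids, plant_rate_neg, "neg")):
        for tid in ids:
            s = rng.choice(list("ACGT"), window)
            if rng.random() < rate:
                p = int(rng.integers(0, window - w + 1))
                s[p:p + w] = list(consensus)
            seqs[tid] = "".join(s)
            labels[tid] = label
    return seqs, labels


def simulate_trajectory_cohort(n_pairs: int, n_unpaired: int, rho: float,
                               seed: int = 0, *,
                               time_points=(0, 5, 10, 15), replicates: int = 2,
                               base_count: float = 500.0,
                               noise_sd: float = 0.5,
                               poisson: bool = True):
    """Replicate-averaged count trajectories with correlated planted pairs.

    For each true pair, the two members' per-time-point log2 fold changes
    share a latent component so that their correlation is ``rho``; unpaired
    features fluctuate independently. Used to exercise the pairing
    permutation test without a full world simulation.

    Returns ``(ts_counts, pairs)``: a feature x time-point frame of
    replicate-averaged counts and a pair table (erna_id, mrna_id).
    """
    rng = np.random.default_rng(seed)
    tps = list(time_points)
    ntp = len(tps)
    rows = {}

    def trajectory(logfc):
        means = base_count * 2.0 ** logfc
        reps = (rng.poisson(means, (replicates, ntp)) if poisson
                else np.tile(means, (replicates, 1)))
        return reps.mean(axis=0)

    pair_rows = []
    for k in range(n_pairs):
        z = rng.normal(0, noise_sd, ntp)
        for role in ("erna", "mrna"):
            eta = rng.normal(0, noise_sd, ntp)
            logfc = math.sqrt(rho) * z + math.sqrt(1 - rho) * eta
            rows[f"{role}_{k:04d}"] = trajectory(logfc)
        pair_rows.append(dict(erna_id=f"erna_{k:04d}", mrna_id=f"mrna_{k:04d}"))
    for k in range(n_unpaired):
        rows[f"bg_{k:04d}"] = trajectory(rng.normal(0, noise_sd, ntp))
    ts_counts = pd.DataFrame.from_dict(rows, orient="index", columns=tps)
    return ts_counts, pd.DataFrame(pair_rows)
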