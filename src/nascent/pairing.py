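"""Enhancer-RNA calling, enhancer-promoter pairing and temporal correlation.

An ncRNA becomes an eRNA when its body or the 1 kb strand-aware upstream
region overlaps an enhancer-state interval (readthrough-flagged ncRNAs are
excluded). eRNAs and mRNAs are paired in all combinations whose TSSs fall in
the same insulated neighborhood, excluding eRNA TSSs within +/-1 kb of the
mRNA TSS. Pair co-regulation is summarized by the Pearson correlation of
replicate-averaged counts across time points; the null is built by random
re-pairing ignoring neighborhoods.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr, spearmanr

from .tracks import count_features


def tss(features: pd.DataFrame) -> pd.Series:
    """Strand-aware 5' position (0-based) for each feature."""
    return pd.Series(
        np.where(features["strand"] == "+", features["start"],
                 features["end"] - 1),
        index=features.index, name="tss")


def upstream_window(features: pd.DataFrame, length: int = 1000) -> pd.DataFrame:
    """The ``length``-bp strand-aware upstream interval of each feature."""
    plus = features["strand"] == "+"
    start = np.where(plus, features["start"] - length, features["end"])
    end = np.where(plus, features["start"], features["end"] + length)
    out = features.copy()
    out["start"] = np.clip(start, 0, None)
    out["end"] = end
    return out


def classify_ernas(ncrnas: pd.DataFrame, enhancer_states: pd.DataFrame,
                   upstream_bp: int = 1000) -> pd.Series:
    """Boolean eRNA flag per ncRNA (body or 1 kb upstream touches a state).

    ncRNAs with a truthy ``readthrough`` column are never eRNAs.
    """
    ups = upstream_window(ncrnas, upstream_bp)
    flags = []
    for tid, r in ncrnas.iterrows():
        if bool(r.get("readthrough", False)):
            flags.append(False)
            continue
        st = enhancer_states[enhancer_states["chrom"] == r["chrom"]]
        u = ups.loc[tid]
        hit = ((st["start"] < r["end"]) & (st["end"] > r["start"])).any() or \
              ((st["start"] < u["end"]) & (st["end"] > u["start"])).any()
        flags.append(bool(hit))
    return pd.Series(flags, index=ncrnas.index, name="is_erna")


def pair_within_neighborhoods(ernas: pd.DataFrame, mrnas: pd.DataFrame,
                              neighborhoods: pd.DataFrame,
                              exclusion_bp: int = 1000) -> pd.DataFrame:
    """All (eRNA, mRNA) pairs with both TSSs in one insulated neighborhood.

    Signed distance is eRNA TSS minus mRNA TSS in the mRNA's orientation
    (negative = upstream of the promoter). Pairs whose eRNA TSS lies within
    +/-``exclusion_bp`` of the mRNA TSS are dropped. With overlapping
    neighborhoods a pair may qualify several times; it is reported once (the
    first qualifying neighborhood id).
    """
    e_tss = tss(ernas)
    m_tss = tss(mrnas)
    rows = {}
    for nbid, nb in neighborhoods.iterrows():
        e_in = e_tss[(ernas["chrom"] == nb["chrom"])
                     & (e_tss >= nb["start"]) & (e_tss < nb["end"])]
        m_in = m_tss[(mrnas["chrom"] == nb["chrom"])
                     & (m_tss >= nb["start"]) & (m_tss < nb["end"])]
        for eid, et in e_in.items():
            for mid, mt in m_in.items():
                if abs(et - mt) <= exclusion_bp:
                    continue
                key = (eid, mid)
                if key in rows:
                    continue
                sign = 1 if mrnas.loc[mid, "strand"] == "+" else -1
                rows[key] = dict(erna_id=eid, mrna_id=mid,
                                 neighborhood_id=nbid,
                                 tss_distance=int(sign * (et - mt)))
    out = pd.DataFrame(list(rows.values()),
                       columns=["erna_id", "mrna_id", "neighborhood_id",
                                "tss_distance"])
    out["proximal"] = out["tss_distance"].abs() < 10_000
    return out


def pairing_summary(pairs: pd.DataFrame) -> dict:
    """Pairs per enhancer / per promoter / per neighborhood."""
    return dict(
        n_pairs=int(len(pairs)),
        mrnas_per_erna=pairs.groupby("erna_id")["mrna_id"].nunique().describe().to_dict(),
        ernas_per_mrna=pairs.groupby("mrna_id")["erna_id"].nunique().describe().to_dict(),
        pairs_per_neighborhood=pairs.groupby("neighborhood_id").size().describe().to_dict(),
    )


def replicate_averaged(counts: pd.DataFrame, samples: pd.DataFrame,
                       assay: str = "TT",
                       sf: pd.Series | None = None) -> pd.DataFrame:
    """Feature x time-point frame of (optionally size-factor-normalized)
    counts averaged over replicates of one assay."""
    sel = samples[samples["assay"] == assay]
    norm = counts[sel.index]
    if sf is not None:
        norm = norm.div(sf.reindex(sel.index), axis=1)
    out = {}
    for tp, grp in sel.groupby("time"):
        out[tp] = norm[grp.index].mean(axis=1)
    return pd.DataFrame(out)


def pair_correlations(pairs: pd.DataFrame, ts_counts: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between the members' time trajectories, per pair.

    ``ts_counts`` is a feature x time-point frame (replicate-averaged).
    Constant trajectories give r = NaN with a ``constant`` flag.
    """
    if ts_counts.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    out = pairs.copy()
    rs, flags = [], []
    for _, p in pairs.iterrows():
        x = ts_counts.loc[p["erna_id"]].to_numpy(dtype=float)
        y = ts_counts.loc[p["mrna_id"]].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(np.nan)
            flags.append("constant")
        else:
            rs.append(pearsonr(x, y).statistic)
            flags.append("")
    out["r"] = rs
    out["flags"] = flags
    return out


def permutation_test(pairs: pd.DataFrame, ts_counts: pd.DataFrame,
                     n_perm: int = 1000, seed: int = 0,
                     statistic: str = "mean"):
    """Null distribution of the pair-correlation statistic by re-pairing.

    eRNAs are re-paired to mRNAs uniformly at random (a random permutation of
    the mRNA column), ignoring neighborhoods, ``n_perm`` times. Returns
    ``(observed, null, p)`` with the add-one empirical p-value
    ``(#{null >= observed} + 1) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    agg = np.mean if statistic == "mean" else np.median
    rng = np.random.default_rng(seed)
    mat = ts_counts.to_numpy(dtype=float)
    idx = {fid: i for i, fid in enumerate(ts_counts.index)}
    e_idx = np.array([idx[e] for e in pairs["erna_id"]])
    m_idx = np.array([idx[m] for m in pairs["mrna_id"]])
    # center rows once; constant rows excluded like in pair_correlations.
    # observed and null share one code path so that exchangeable inputs give
    # p ~ 1 instead of tie-breaking on float rounding.
    X = mat - mat.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)

    def stat(m_indices):
        xe, xm = X[e_idx], X[m_indices]
        se, sm = sd[e_idx], sd[m_indices]
        ok = (se > 0) & (sm > 0)
        r = (xe[ok] * xm[ok]).mean(axis=1) / (se[ok] * sm[ok])
        return float(agg(r))

    observed = stat(m_idx)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = stat(rng.permutation(m_idx))
    p = (np.sum(null >= observed) + 1) / (n_perm + 1)
    return observed, null, float(p)


def closest_pairing(ernas: pd.DataFrame, mrnas: pd.DataFrame,
                    neighborhoods: pd.DataFrame,
                    ts_counts: pd.DataFrame | None = None) -> tuple:
    """Pair every promoter with its closest eRNA TSS genome-wide.

    Ties break to the smaller eRNA TSS coordinate. Returns (pairs frame,
    diagnostics dict); with ``ts_counts`` the diagnostics include the Spearman
    correlation of |distance| vs r and a two-sided rank-sum comparison of r
    between same- and different-neighborhood pairs.
    """
    if len(ernas) == 0:
        warnings.warn("no eRNAs: closest pairing is empty")
        return pd.DataFrame(columns=["erna_id", "mrna_id", "distance",
                                     "same_neighborhood"]), {}
    e_tss = tss(ernas)
    m_tss = tss(mrnas)

    def nb_of(chrom, pos):
        hit = neighborhoods[(neighborhoods["chrom"] == chrom)
                            & (neighborhoods["start"] <= pos)
                            & (neighborhoods["end"] > pos)]
        return hit.index[0] if len(hit) else None

    rows = []
    for mid, mt in m_tss.items():
        chrom = mrnas.loc[mid, "chrom"]
        cand = e_tss[ernas["chrom"] == chrom]
        if len(cand) == 0:
            continue
        d = (cand - mt).abs()
        dmin = d.min()
        best = sorted(cand[d == dmin].index, key=lambda e: e_tss[e])[0]
        rows.append(dict(erna_id=best, mrna_id=mid, distance=int(dmin),
                         same_neighborhood=(
                             nb_of(chrom, mt) is not None
                             and nb_of(chrom, mt) == nb_of(chrom, e_tss[best]))))
    out = pd.DataFrame(rows)
    diag = {}
    if ts_counts is not None and len(out):
        rr = pair_correlations(out, ts_counts)
        out["r"] = rr["r"]
        ok = out["r"].notna()
        if ok.sum() >= 3:
            diag["spearman_distance_vs_r"] = float(
                spearmanr(out.loc[ok, "distance"], out.loc[ok, "r"]).statistic)
        same = out.loc[ok & out["same_neighborhood"], "r"]
        diff = out.loc[ok & ~out["same_neighborhood"], "r"]
        if len(same) and len(diff):
            stat = mannwhitneyu(same, diff, alternative="two-sided")
            diag["same_vs_diff_neighborhood_p"] = float(stat.pvalue)
            diag["median_r_same"] = float(same.median())
            diag["median_r_diff"] = float(diff.median())
    return out, diag


def mrna_prefix_features(mrnas: pd.DataFrame, prefix_bp: int = 2200) -> pd.DataFrame:
    """Strand-aware first ``prefix_bp`` of each mRNA (whole mRNA if shorter)."""
    out = mrnas.copy()
    short = (out["end"] - out["start"]) <= prefix_bp
    plus = out["strand"] == "+"
    out["prefix_flagged"] = short
    new_end = np.where(plus & ~short, out["start"] + prefix_bp, out["end"])
    new_start = np.where(~plus & ~short, out["end"] - prefix_bp, out["start"])
    out["start"], out["end"] = new_start, new_end
    return out


def temporal_profiles(pairs: pd.DataFrame, tracks: dict,
                      features: pd.DataFrame, samples: pd.DataFrame,
                      sf: pd.Series, *, assay: str = "TT",
                      mrna_prefix: int = 2200) -> pd.DataFrame:
    """Median/quartile trajectories for paired eRNAs and mRNA 5' prefixes.

    Counts the whole eRNA and the first ``mrna_prefix`` bp of the paired mRNA
    in every sample of ``assay``, normalizes by size factor, averages
    replicates and reports per-time-point median and quartiles over pairs,
    scaled to each pair member's own time-course mean (so trajectories are
    comparable across expression levels).
    """
    e_feats = features.loc[pairs["erna_id"].unique()]
    m_feats = mrna_prefix_features(features.loc[pairs["mrna_id"].unique()],
                                   mrna_prefix)
    sel = samples[samples["assay"] == assay]
    counts = {}
    for sid in sel.index:
        ce = count_features(tracks[sid], e_feats)
        cm = count_features(tracks[sid], m_feats)
        counts[sid] = pd.concat([ce, cm]) / float(sf.loc[sid])
    cdf = pd.DataFrame(counts)
    avg = {tp: cdf[grp.index].mean(axis=1) for tp, grp in sel.groupby("time")}
    avg = pd.DataFrame(avg)
    rel = avg.div(avg.mean(axis=1).replace(0, np.nan), axis=0)
    rows = []
    for role, ids in (("eRNA", pairs["erna_id"]), ("mRNA", pairs["mrna_id"])):
        sub = rel.loc[ids.unique()].dropna()
        for tp in avg.columns:
            q1, med, q3 = np.percentile(sub[tp], [25, 50, 75])
            rows.append(dict(role=role, time=tp, q1=q1, median=med, q3=q3,
                             n=len(sub)))
    return pd.DataFrame(rows)


def tss_metaprofile(signal: dict, tss_df: pd.DataFrame, window: int) -> np.ndarray:
    """Strand-oriented average signal around a TSS set.

    ``signal`` maps chromosome -> per-position array (any fixed resolution in
    bp units of array index); returns a length-2*window array covering
    [-window, window) relative to the TSS, with minus-strand profiles
    reversed. Positions falling off a chromosome are ignored via NaN-mean.
    """
    if len(tss_df) == 0:
        raise ValueError("empty TSS set")
    pos = tss(tss_df)
    acc = np.full((len(tss_df), 2 * window), np.nan)
    for i, (tid, p) in enumerate(pos.items()):
        arr = signal[tss_df.loc[tid, "chrom"]]
        lo, hi = p - window, p + window
        s_lo, s_hi = max(lo, 0), min(hi, len(arr))
        if s_hi <= s_lo:
            continue
        row = np.full(2 * window, np.nan)
        row[s_lo - lo: s_hi - lo] = arr[s_lo:s_hi]
        if tss_df.loc[tid, "strand"] == "-":
            row = row[::-1]
        acc[i] = row
    return np.nanmean(acc, axis=0)
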