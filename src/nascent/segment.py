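"""Two-state HMM genome segmentation and transcription-unit annotation.

The segmentation model has states "untranscribed" (0) and "transcribed" (1)
with a Poisson-log-normal emission per state and input track: the bin count is
Poisson with rate ``exp(m + s*Z)``, ``Z ~ N(0,1)``. The marginal likelihood is
evaluated by Gauss-Hermite quadrature. Fitting is Baum-Welch EM; the emission
M-step maximizes the expected log-likelihood numerically per state/track,
warm-started at the current parameters so the data log-likelihood is
non-decreasing.

Downstream of decoding: an RPK threshold chosen by maximizing the nucleotide
Jaccard index against a reference annotation, boundary refinement by a
two-segment piecewise-constant least-squares fit in a +/-200 bp window, and
rule-based classification of transcription units against the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from . import intervals

jaccard = intervals.jaccard  # nucleotide Jaccard of interval sets


class DegenerateFitError(RuntimeError):
    pass


@dataclass
class HMMParams:
    transition: np.ndarray  # 2x2, rows sum to 1
    start_prob: np.ndarray  # length 2
    means: np.ndarray  # (2, n_tracks) log-scale locations m
    sds: np.ndarray  # (2, n_tracks) log-scale sds s
    loglik_path: list = field(default_factory=list)
    degenerate: bool = False
    n_quad: int = 30

    @property
    def state_means(self) -> np.ndarray:
        """Expected emission rate per state (summed over tracks)."""
        return np.exp(self.means + 0.5 * self.sds**2).sum(axis=1)


def _gh_nodes(n_quad: int):
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    return z, np.log(w) - 0.5 * np.log(np.pi)


def pln_logpmf(k, m, s, n_quad: int = 30):
    """log P(K = k) for the Poisson-log-normal, via Gauss-Hermite quadrature."""
    z, logw = _gh_nodes(n_quad)
    k = np.atleast_1d(np.asarray(k, dtype=float))
    log_rate = m + np.sqrt(2.0) * s * z  # (Q,)
    # Poisson logpmf at each node: k*log(rate) - rate - lgamma(k+1)
    ll = (k[:, None] * log_rate[None, :] - np.exp(log_rate)[None, :]
          - gammaln(k + 1)[:, None])
    return logsumexp(ll + logw[None, :], axis=1)


def tracks_to_sequences(tracks, pseudo_count: float = 1.0):
    """Stack per-sample tracks into per-(chrom, strand) count matrices.

    Returns ``(keys, sequences)`` where each sequence is an int array of shape
    (n_bins, n_tracks) with the pseudo-count added (bins are rounded, the
    emission is a count distribution).
    """
    t0 = tracks[0]
    keys = sorted(t0.data.keys())
    seqs = []
    for key in keys:
        mat = np.stack([np.rint(tr.data[key] + pseudo_count) for tr in tracks],
                       axis=1)
        seqs.append(mat.astype(np.int64))
    return keys, seqs


def _emission_logprob(seq: np.ndarray, params: HMMParams) -> np.ndarray:
    """(n_bins, 2) joint log emission across tracks, via unique-value tables."""
    n, T = seq.shape
    out = np.zeros((n, 2))
    for t in range(T):
        u, inv = np.unique(seq[:, t], return_inverse=True)
        for s in range(2):
            table = pln_logpmf(u, params.means[s, t], params.sds[s, t],
                               params.n_quad)
            out[:, s] += table[inv]
    return out


def _forward_backward(logB: np.ndarray, trans: np.ndarray, start: np.ndarray):
    """Scaled forward-backward; returns (gamma, xi_sum, loglik)."""
    n = len(logB)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    alpha = np.zeros((n, 2))
    scale = np.zeros(n)
    a = start * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, n):
        a = (alpha[i - 1] @ trans) * B[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]
    beta = np.zeros((n, 2))
    beta[-1] = 1.0
    xi = np.zeros((2, 2))
    for i in range(n - 2, -1, -1):
        b = trans @ (B[i + 1] * beta[i + 1])
        beta[i] = b / scale[i + 1]
        xi += (alpha[i][:, None] * trans
               * (B[i + 1] * beta[i + 1])[None, :]) / scale[i + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(scale)) + np.sum(logB.max(axis=1)))
    return gamma, xi, loglik


def _weighted_pln_nll(params_vec, values, weights, n_quad):
    m, log_s = params_vec
    s = np.exp(log_s)
    return -float(np.dot(weights, pln_logpmf(values, m, s, n_quad)))


def fit_hmm(sequences, max_iter: int = 50, tol: float = 1e-3, seed: int = 0,
            n_quad: int = 30, pseudo_count: float | None = None) -> HMMParams:
    """Baum-Welch EM fit of the two-state Poisson-log-normal HMM.

    ``sequences`` is a list of (n_bins, n_tracks) count arrays (or a single
    such array), already pseudo-counted. Initialization splits bins at the
    90th percentile of the per-bin track sum.
    """
    if isinstance(sequences, np.ndarray):
        sequences = [sequences]
    sequences = [np.asarray(s) for s in sequences]
    if not sequences:
        raise ValueError("need at least one sequence")
    sequences = [s.reshape(len(s), -1) for s in sequences]
    T = sequences[0].shape[1]
    allbins = np.concatenate(sequences, axis=0)
    totals = allbins.sum(axis=1)
    if np.all(allbins == allbins[0]):
        warnings.warn("degenerate all-equal input; returning single-state fit")
        m = float(np.log(max(allbins[0].mean(), 0.5)))
        return HMMParams(
            transition=np.array([[0.5, 0.5], [0.5, 0.5]]),
            start_prob=np.array([0.5, 0.5]),
            means=np.full((2, T), m), sds=np.full((2, T), 0.1),
            degenerate=True, n_quad=n_quad)

    cut = np.percentile(totals, 90)
    hi = totals > cut
    if hi.sum() == 0 or (~hi).sum() == 0:
        hi = totals > np.median(totals)
    means = np.zeros((2, T))
    sds = np.zeros((2, T))
    for s_idx, mask in enumerate((~hi, hi)):
        logk = np.log(allbins[mask] + 0.5)
        means[s_idx] = logk.mean(axis=0)
        sds[s_idx] = np.clip(logk.std(axis=0), 0.1, None)
    params = HMMParams(
        transition=np.array([[0.99, 0.01], [0.05, 0.95]]),
        start_prob=np.array([0.9, 0.1]),
        means=means, sds=sds, n_quad=n_quad)

    prev_ll = -np.inf
    for _ in range(max_iter):
        gammas, xi_sum, ll = [], np.zeros((2, 2)), 0.0
        start_acc = np.zeros(2)
        for seq in sequences:
            logB = _emission_logprob(seq, params)
            g, xi, l = _forward_backward(logB, params.transition,
                                         params.start_prob)
            gammas.append(g)
            xi_sum += xi
            start_acc += g[0]
            ll += l
        params.loglik_path.append(ll)
        # M-step: transitions / start
        trans = xi_sum / xi_sum.sum(axis=1, keepdims=True)
        start = start_acc / start_acc.sum()
        gamma_all = np.concatenate(gammas, axis=0)
        new_means = params.means.copy()
        new_sds = params.sds.copy()
        for t in range(T):
            u, inv = np.unique(allbins[:, t], return_inverse=True)
            for s_idx in range(2):
                w = np.bincount(inv, weights=gamma_all[:, s_idx],
                                minlength=len(u))
                x0 = np.array([params.means[s_idx, t],
                               np.log(params.sds[s_idx, t])])
                res = minimize(_weighted_pln_nll, x0,
                               args=(u, w, n_quad), method="Nelder-Mead",
                               options=dict(xatol=1e-4, fatol=1e-6,
                                            maxiter=200))
                if res.fun <= _weighted_pln_nll(x0, u, w, n_quad):
                    new_means[s_idx, t] = res.x[0]
                    new_sds[s_idx, t] = float(np.exp(res.x[1]))
        params.transition = trans
        params.start_prob = start
        params.means = new_means
        params.sds = new_sds
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    # order states: index 1 = transcribed (higher expected rate)
    if params.state_means[0] > params.state_means[1]:
        params.means = params.means[::-1].copy()
        params.sds = params.sds[::-1].copy()
        params.transition = params.transition[::-1, ::-1].copy()
        params.start_prob = params.start_prob[::-1].copy()
    return params


def posterior_transcribed(seq: np.ndarray, params: HMMParams) -> np.ndarray:
    logB = _emission_logprob(np.asarray(seq).reshape(len(seq), -1), params)
    g, _, _ = _forward_backward(logB, params.transition, params.start_prob)
    return g[:, 1]


def decode_transcribed(params: HMMParams, keys, sequences, bin_size: int,
                       genome: dict, threshold: float = 0.5) -> dict:
    """Posterior-decode each sequence into transcribed intervals (bp).

    Returns {(chrom, strand): Nx2 array of 0-based half-open intervals}.
    """
    out = {}
    for key, seq in zip(keys, sequences):
        chrom = key[0] if isinstance(key, tuple) else key
        post = posterior_transcribed(seq, params)
        on = post > threshold
        ivals = []
        i = 0
        n = len(on)
        while i < n:
            if on[i]:
                j = i
                while j < n and on[j]:
                    j += 1
                ivals.append((i * bin_size,
                              min(j * bin_size, genome[chrom])))
                i = j
            else:
                i += 1
        out[key] = np.asarray(ivals, dtype=np.int64).reshape(-1, 2)
    return out


# ---------------------------------------------------------------------------
# RPK threshold optimization


def optimize_rpk_threshold(tus: pd.DataFrame, reference: dict,
                           candidates) -> tuple[float, pd.DataFrame]:
    """argmax over candidate thresholds of Jaccard(TUs with RPK >= theta, ref).

    ``tus`` needs chrom/start/end/strand/rpk; ``reference`` maps
    (chrom, strand) -> Nx2 intervals. Ties resolve to the smallest theta.
    Returns (theta, scan frame with columns threshold/jaccard).
    """
    cands = sorted(set(float(c) for c in candidates))
    if not cands:
        raise ValueError("empty candidate threshold list")
    rows = []
    best = (-1.0, None)
    for theta in cands:
        kept = tus[tus["rpk"] >= theta]
        ivals = {}
        for (chrom, strand), grp in kept.groupby(["chrom", "strand"]):
            ivals[(chrom, strand)] = grp[["start", "end"]].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j = intervals.jaccard(ivals, reference)
        rows.append(dict(threshold=theta, jaccard=j))
        if j > best[0]:
            best = (j, theta)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# boundary refinement


def _best_breakpoint(x: np.ndarray) -> tuple[int, float]:
    """Breakpoint b in [1, n-1] minimizing the RSS of a two-constant fit."""
    n = len(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x.astype(float) ** 2)])

    def rss(lo, hi):  # [lo, hi)
        m = hi - lo
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / m

    best_b, best_r = 1, np.inf
    for b in range(1, n):
        r = rss(0, b) + rss(b, n)
        if r < best_r - 1e-12:
            best_r, best_b = r, b
    return best_b, best_r


def refine_boundary(profile: np.ndarray, orig_offset: int) -> int:
    """New boundary offset within a coverage window around a TU border.

    Fits a piecewise-constant two-segment curve to the window by exhaustive
    breakpoint search; returns the RSS-minimizing breakpoint. When the fit is
    flat (no breakpoint strictly better than splitting at the original
    offset), the original offset is kept.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) < 2:
        return orig_offset
    b, r = _best_breakpoint(x)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    csq = np.concatenate([[0.0], np.cumsum(x ** 2)])

    def rss(lo, hi):
        m = hi - lo
        if m <= 0:
            return 0.0
        s = csum[hi] - csum[lo]
        return (csq[hi] - csq[lo]) - s * s / m

    orig = min(max(orig_offset, 1), len(x) - 1)
    r_orig = rss(0, orig) + rss(orig, len(x))
    if r >= r_orig - 1e-9:
        return orig_offset
    return b


def refine_boundaries(tu_row, coverage: dict, window: int = 200):
    """Adjust TU start/end with per-bp coverage within +/-``window`` bp.

    ``coverage`` maps chromosome -> per-bp float array. Windows are clipped to
    the chromosome (with a warning). The boundary moves at most ``window`` bp.
    """
    chrom = tu_row["chrom"]
    cov = coverage[chrom]
    out = {}
    for which, pos in (("start", int(tu_row["start"])),
                       ("end", int(tu_row["end"]))):
        lo, hi = pos - window, pos + window
        if lo < 0 or hi > len(cov):
            warnings.warn(f"refinement window at {chrom}:{pos} clipped")
            lo, hi = max(lo, 0), min(hi, len(cov))
        if hi - lo < 2:
            out[which] = pos
            continue
        b = refine_boundary(cov[lo:hi], pos - lo)
        out[which] = lo + b
    if out["start"] >= out["end"]:
        return int(tu_row["start"]), int(tu_row["end"])
    return out["start"], out["end"]


# ---------------------------------------------------------------------------
# classification


def _overlap_len(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_tus(tus: pd.DataFrame, genes: pd.DataFrame, exons: pd.DataFrame,
                 *, min_gene_frac: float = 0.2, ncrna_merge_gap: int = 200,
                 ambiguous_gene_frac: float = 0.75,
                 ambiguous_tu_frac: float = 0.2,
                 short_mrna_bp: int = 5_000, short_mrna_frac: float = 0.1,
                 readthrough_bp: int = 1_000) -> pd.DataFrame:
    """Classify transcription units against a reference annotation.

    In order: (1) TUs overlapping >= 20% of their length with a sense
    protein-coding/lincRNA gene *and* touching one of its exons become
    mRNA/lincRNA, the rest ncRNA; (2) TUs linked to the same gene are
    combined; (3) ncRNAs <= 200 bp apart are merged; (4) TUs covering
    multiple protein-coding genes (>= 75% of the gene and >= 20% of the TU)
    are removed as ambiguous; (5) mRNAs shorter than 5 kb with < 10% overlap
    with any protein-coding gene are downgraded to ncRNA; (6) ncRNAs starting
    within 1 kb downstream of a protein-coding gene on the sense strand are
    flagged as readthrough.

    Raises if a linked gene has no exon records.
    """
    gene_list = genes.reset_index().rename(columns={genes.index.name or "index":
                                                    "gene_id"})
    recs = []
    for tid, tu in tus.iterrows():
        tu_len = tu["end"] - tu["start"]
        best = (0, None, None)
        for _, g in gene_list.iterrows():
            if (g["chrom"] != tu["chrom"] or g["strand"] != tu["strand"]
                    or g["biotype"] not in ("protein_coding", "lincRNA")):
                continue
            ov = _overlap_len(tu["start"], tu["end"], g["start"], g["end"])
            if ov == 0 or ov / tu_len < min_gene_frac:
                continue
            gex = exons[exons["gene_id"] == g["gene_id"]]
            if len(gex) == 0:
                raise ValueError(f"gene {g['gene_id']} has no exon records")
            touches = any(_overlap_len(tu["start"], tu["end"], e["start"],
                                       e["end"]) > 0
                          for _, e in gex.iterrows())
            if touches and ov > best[0]:
                best = (ov, g["gene_id"], g["biotype"])
        cls = ("mRNA" if best[2] == "protein_coding"
               else "lincRNA" if best[2] == "lincRNA" else "ncRNA")
        recs.append(dict(id=tid, chrom=tu["chrom"], start=int(tu["start"]),
                         end=int(tu["end"]), strand=tu["strand"], cls=cls,
                         linked_gene_id=best[1],
                         rpk=float(tu.get("rpk", np.nan))))
    df = pd.DataFrame(recs).set_index("id")

    # (2) combine TUs linked to the same gene
    combined = []
    for (gid,), grp in df[df["linked_gene_id"].notna()].groupby(
            ["linked_gene_id"]):
        row = grp.iloc[0].copy()
        row["start"] = int(grp["start"].min())
        row["end"] = int(grp["end"].max())
        lens = (grp["end"] - grp["start"]).to_numpy(dtype=float)
        row["rpk"] = float(np.average(grp["rpk"], weights=lens)) \
            if np.isfinite(grp["rpk"]).all() else np.nan
        row.name = grp.index[0]
        combined.append(row)
    linked = pd.DataFrame(combined) if combined else df.iloc[0:0]
    df = pd.concat([linked, df[df["linked_gene_id"].isna()]])

    # (3) merge nearby ncRNAs (same chrom/strand, gap <= ncrna_merge_gap)
    nc = df[df["cls"] == "ncRNA"].sort_values(["chrom", "strand", "start"])
    keep_rows = []
    for (chrom, strand), grp in nc.groupby(["chrom", "strand"]):
        cur = None
        for tid, r in grp.iterrows():
            if cur is None:
                cur = r.copy()
                continue
            if r["start"] - cur["end"] <= ncrna_merge_gap:
                w1, w2 = cur["end"] - cur["start"], r["end"] - r["start"]
                cur["rpk"] = (cur["rpk"] * w1 + r["rpk"] * w2) / (w1 + w2) \
                    if np.isfinite([cur["rpk"], r["rpk"]]).all() else np.nan
                cur["end"] = max(cur["end"], r["end"])
            else:
                keep_rows.append(cur)
                cur = r.copy()
        if cur is not None:
            keep_rows.append(cur)
    nc_merged = pd.DataFrame(keep_rows) if keep_rows else nc
    df = pd.concat([df[df["cls"] != "ncRNA"], nc_merged])

    # (4) remove TUs ambiguously covering multiple protein-coding genes
    pc = gene_list[gene_list["biotype"] == "protein_coding"]
    drop = []
    for tid, tu in df.iterrows():
        tu_len = tu["end"] - tu["start"]
        n_cov = 0
        for _, g in pc.iterrows():
            if g["chrom"] != tu["chrom"] or g["strand"] != tu["strand"]:
                continue
            ov = _overlap_len(tu["start"], tu["end"], g["start"], g["end"])
            if (ov >= ambiguous_gene_frac * (g["end"] - g["start"])
                    and ov >= ambiguous_tu_frac * tu_len):
                n_cov += 1
        if n_cov >= 2:
            drop.append(tid)
    df = df.drop(index=drop)

    # (5) short weak mRNAs downgraded to ncRNA
    for tid, tu in df[df["cls"] == "mRNA"].iterrows():
        tu_len = tu["end"] - tu["start"]
        if tu_len >= short_mrna_bp:
            continue
        max_frac = 0.0
        for _, g in pc.iterrows():
            if g["chrom"] != tu["chrom"] or g["strand"] != tu["strand"]:
                continue
            ov = _overlap_len(tu["start"], tu["end"], g["start"], g["end"])
            max_frac = max(max_frac, ov / tu_len)
        if max_frac < short_mrna_frac:
            df.loc[tid, ["cls", "linked_gene_id"]] = ["ncRNA", None]

    # (6) flag sense readthrough ncRNAs
    df["readthrough"] = False
    for tid, tu in df[df["cls"] == "ncRNA"].iterrows():
        for _, g in pc.iterrows():
            if g["chrom"] != tu["chrom"] or g["strand"] != tu["strand"]:
                continue
            if g["strand"] == "+":
                ds = tu["start"] - g["end"]  # bp downstream of gene end
            else:
                ds = g["start"] - tu["end"]
            if 0 <= ds <= readthrough_bp:
                df.loc[tid, "readthrough"] = True
                break
    return df.sort_values(["chrom", "start"])


def constitutive_exons(exons: pd.DataFrame) -> pd.DataFrame:
    """Per gene, the intersection of exonic intervals across all isoforms.

    Returns a frame with gene_id/chrom/strand/start/end rows (possibly several
    per gene) plus an ``empty`` flag row-less genes are reported through the
    returned frame's attrs["empty_genes"].
    """
    rows = []
    empty = []
    for gid, grp in exons.groupby("gene_id"):
        txs = grp.groupby("transcript_id")
        if len(txs) == 0:
            raise ValueError(f"gene {gid} has no isoforms")
        common = None
        chrom = grp["chrom"].iloc[0]
        strand = grp["strand"].iloc[0]
        for _, tgrp in txs:
            ivals = intervals.merge(tgrp[["start", "end"]].to_numpy())
            common = ivals if common is None else intervals.intersect(common,
                                                                      ivals)
        if len(common) == 0:
            empty.append(gid)
            continue
        for s, e in common:
            rows.append(dict(gene_id=gid, chrom=chrom, strand=strand,
                             start=int(s), end=int(e)))
    out = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start",
                                      "end"])
    out.attrs["empty_genes"] = empty
    return out
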