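"""RNA synthesis/degradation kinetics from labeled (TT) and total (RNA) counts.

Observation model: the expected count of feature i in sample j is

    E[k_ij] = L_i * (sigma_j * alpha_ij + epsilon_j * beta_ij)

with L_i the feature length, alpha/beta the labeled/unlabeled RNA amounts,
sigma_j the sequencing depth and epsilon_j the cross-contamination rate of
sample j. sigma/epsilon are calibrated from spike-ins (alpha=1, beta=0 for
labeled spike-ins; alpha=0, beta=1 for unlabeled); total-RNA samples are
rescaled so that epsilon_j == 1. Under first-order kinetics with labeling
duration t,

    lambda_i = -(1/t) * log(beta_i / (alpha_i + beta_i))
    mu_i     = (alpha_i + beta_i) * lambda_i
    half-life = ln(2) / lambda_i
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize


class CalibrationError(ValueError):
    pass


@dataclass
class SampleCalibration:
    sample_id: str
    sigma: float
    epsilon: float
    assay: str  # "TT" or "RNA"
    scale: float = 1.0  # divisor applied by the epsilon==1 rescale convention

    def __post_init__(self):
        if self.sigma <= 0:
            raise CalibrationError(f"{self.sample_id}: sigma must be > 0")
        if self.epsilon < 0:
            raise CalibrationError(f"{self.sample_id}: epsilon must be >= 0")


def calibrate(spikeins: pd.DataFrame, sample_assays: dict) -> dict:
    """Per-sample depth/contamination from a spike-in count table.

    ``spikeins`` has columns ``length_bp``, ``labeled`` (0/1) and one count
    column per sample. ``sample_assays`` maps sample id -> "TT" | "RNA".
    Returns {sample_id: SampleCalibration}; RNA samples are rescaled so that
    epsilon == 1 (sigma divided by the same factor).
    """
    lab = spikeins[spikeins["labeled"] == 1]
    unlab = spikeins[spikeins["labeled"] == 0]
    if len(lab) == 0 or len(unlab) == 0:
        raise CalibrationError("need at least one labeled and one unlabeled spike-in")
    out = {}
    for sid, assay in sample_assays.items():
        if sid not in spikeins.columns:
            raise CalibrationError(f"no spike-in counts for sample {sid!r}")
        sigma = float(np.median(lab[sid] / lab["length_bp"]))
        eps = float(np.median(unlab[sid] / unlab["length_bp"]))
        if sigma <= 0:
            raise CalibrationError(f"{sid}: labeled spike-ins yield sigma <= 0")
        scale = 1.0
        if assay == "RNA":
            if eps <= 0:
                raise CalibrationError(f"{sid}: cannot rescale, epsilon <= 0")
            scale = eps
            sigma, eps = sigma / eps, 1.0
        out[sid] = SampleCalibration(sample_id=sid, sigma=sigma, epsilon=eps,
                                     assay=assay, scale=scale)
    return out


def fit_amounts(k_tt, k_rna, length_bp, cal_tt: SampleCalibration,
                cal_rna: SampleCalibration):
    """Labeled/unlabeled amounts (alpha, beta) from one TT/RNA pair of counts.

    Solves the 2x2 linear system exactly (which coincides with the Poisson
    MLE for one observation per assay); negative solutions are clamped to 0
    and flagged. Vectorized over features.

    When the RNA calibration was rescaled to epsilon == 1 (``scale`` != 1),
    the TT calibration is expressed in the same unit system, so the returned
    amounts are in RNA-equivalent units and lambda stays invariant.

    Returns ``(alpha, beta, clamped)`` arrays.
    """
    sT, eT = cal_tt.sigma / cal_rna.scale, cal_tt.epsilon / cal_rna.scale
    sR, eR = cal_rna.sigma, cal_rna.epsilon
    det = sT * eR - sR * eT
    if abs(det) < 1e-12 * max(sT * eR, sR * eT, 1e-300):
        raise CalibrationError("calibration matrix is singular; alpha/beta not identifiable")
    L = np.asarray(length_bp, dtype=float)
    yT = np.asarray(k_tt, dtype=float) / L
    yR = np.asarray(k_rna, dtype=float) / L
    alpha = (eR * yT - eT * yR) / det
    beta = (sT * yR - sR * yT) / det
    clamped = (alpha < 0) | (beta < 0)
    alpha = np.clip(alpha, 0.0, None)
    beta = np.clip(beta, 0.0, None)
    return alpha, beta, clamped


def fit_amounts_replicates(k_tt: np.ndarray, k_rna: np.ndarray, length_bp,
                           cals_tt, cals_rna):
    """Poisson-ML (alpha, beta) from replicate TT/RNA counts of one feature.

    ``k_tt``/``k_rna`` are 1-D arrays over replicates, ``cals_*`` matching
    lists of calibrations. Non-negative optimization of the Poisson deviance;
    with a single replicate per assay this equals :func:`fit_amounts`.
    """
    L = float(length_bp)
    cals_tt, cals_rna = list(cals_tt), list(cals_rna)
    # homogeneous calibrations per assay: the Poisson MLE over replicates is
    # the exact 2x2 solution on the replicate means (sum of Poissons)
    if (len({(c.sigma, c.epsilon, c.scale) for c in cals_tt}) == 1
            and len({(c.sigma, c.epsilon, c.scale) for c in cals_rna}) == 1):
        a, b, clamped = fit_amounts(np.mean(k_tt), np.mean(k_rna), L,
                                    cals_tt[0], cals_rna[0])
        return float(a), float(b), bool(clamped)
    ks = np.concatenate([np.asarray(k_tt, float), np.asarray(k_rna, float)])
    # common unit system: mean rescale factor over the RNA replicates
    s_bar = float(np.mean([c.scale for c in cals_rna]))
    sig = np.array([c.sigma * c.scale / s_bar if c.assay == "RNA"
                    else c.sigma / s_bar for c in list(cals_tt) + list(cals_rna)])
    eps = np.array([c.epsilon * c.scale / s_bar if c.assay == "RNA"
                    else c.epsilon / s_bar for c in list(cals_tt) + list(cals_rna)])

    def nll(x):
        a, b = x
        mu = L * (sig * a + eps * b)
        mu = np.clip(mu, 1e-12, None)
        return float(np.sum(mu - ks * np.log(mu)))

    a0, b0, _ = fit_amounts(np.mean(k_tt), np.mean(k_rna), L,
                            cals_tt[0], cals_rna[0])
    x0 = np.array([max(float(a0), 1e-8), max(float(b0), 1e-8)])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(0.0, None), (0.0, None)])
    a, b = res.x
    return float(a), float(b), bool((a <= 0) or (b <= 0))


@dataclass
class KineticEstimate:
    feature_id: str
    alpha: float
    beta: float
    lam: float  # degradation rate, 1/min
    mu: float  # synthesis rate, amount/min
    half_life: float  # min
    flags: str = ""


def rates(alpha, beta, t: float):
    """(lambda, mu, half_life, flags) from labeled/unlabeled amounts.

    Vectorized; boundary cases are flagged rather than raised:
    beta == 0 -> lambda undefined (inf), mu reported as alpha/t;
    alpha == 0 -> no labeling, lambda = mu = 0.
    alpha + beta == 0 raises.
    """
    if t <= 0:
        raise ValueError("labeling duration t must be > 0")
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    scalar = a.ndim == 0
    a, b = np.atleast_1d(a), np.atleast_1d(b)
    if np.any((a + b) == 0) and not np.all((a + b) > 0):
        bad = np.where((a + b) == 0)[0]
        raise ValueError(f"alpha + beta == 0 for {len(bad)} feature(s); rate undefined")
    lam = np.empty_like(a)
    mu = np.empty_like(a)
    flags = np.full(a.shape, "", dtype=object)
    with np.errstate(divide="ignore"):
        frac = b / (a + b)
        ok = (a > 0) & (b > 0)
        lam[ok] = -(1.0 / t) * np.log(frac[ok])
        mu[ok] = (a[ok] + b[ok]) * lam[ok]
        no_label = a == 0
        lam[no_label] = 0.0
        mu[no_label] = 0.0
        flags[no_label] = "no_labeling"
        all_label = (b == 0) & (a > 0)
        lam[all_label] = np.inf
        mu[all_label] = a[all_label] / t
        flags[all_label] = "unstable"
    with np.errstate(divide="ignore"):
        half_life = np.where(lam > 0, math.log(2) / np.where(lam > 0, lam, 1.0),
                             np.inf)
    half_life = np.where(np.isinf(lam), 0.0, half_life)
    if scalar:
        return float(lam[0]), float(mu[0]), float(half_life[0]), str(flags[0])
    return lam, mu, half_life, flags


def estimate_rates_table(counts: pd.DataFrame, lengths: pd.Series,
                         samples: pd.DataFrame, calibrations: dict,
                         t: float = 5.0, time_point=None) -> pd.DataFrame:
    """Per-feature kinetic estimates for one time point.

    ``samples`` has columns assay/time/replicate indexed by sample id; counts
    for replicates of each assay are fitted jointly by Poisson ML (single
    replicate reduces to the exact 2x2 solution).
    """
    sel = samples if time_point is None else samples[samples["time"] == time_point]
    tt_ids = list(sel.index[sel["assay"] == "TT"])
    rna_ids = list(sel.index[sel["assay"] == "RNA"])
    if not tt_ids or not rna_ids:
        raise CalibrationError("need at least one TT and one RNA sample")
    cals_tt = [calibrations[s] for s in tt_ids]
    cals_rna = [calibrations[s] for s in rna_ids]
    rows = []
    for fid in counts.index:
        k_tt = counts.loc[fid, tt_ids].to_numpy(dtype=float)
        k_rna = counts.loc[fid, rna_ids].to_numpy(dtype=float)
        L = float(lengths.loc[fid])
        if k_tt.sum() == 0 and k_rna.sum() == 0:
            rows.append(dict(feature_id=fid, alpha=0.0, beta=0.0,
                             lambda_per_min=np.nan, mu_per_min=0.0,
                             half_life_min=np.nan, flags="all_zero"))
            continue
        if len(tt_ids) == 1 and len(rna_ids) == 1:
            a, b, clamped = fit_amounts(k_tt[0], k_rna[0], L,
                                        cals_tt[0], cals_rna[0])
            a, b, clamped = float(a), float(b), bool(clamped)
        else:
            a, b, clamped = fit_amounts_replicates(k_tt, k_rna, L,
                                                   cals_tt, cals_rna)
        if a + b == 0:
            rows.append(dict(feature_id=fid, alpha=a, beta=b,
                             lambda_per_min=np.nan, mu_per_min=0.0,
                             half_life_min=np.nan, flags="degenerate"))
            continue
        lam, mu, hl, flag = rates(a, b, t)
        if clamped:
            flag = (flag + ",clamped").strip(",")
        rows.append(dict(feature_id=fid, alpha=a, beta=b, lambda_per_min=lam,
                         mu_per_min=mu, half_life_min=hl, flags=flag))
    return pd.DataFrame(rows).set_index("feature_id")
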