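"""Differential synthesis between time points, with a negative-binomial test.

Size factors use the median-of-ratios estimator restricted to a reference
feature set (protein-coding units). The per-contrast test is a documented
stand-in for a shrinkage-based NB framework: a Wald test on the log fold
change of normalized condition means, with a method-of-moments dispersion
pooled across conditions and smoothed across features by a trended (binned
median) estimate, and Benjamini-Hochberg adjustment within each contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


def size_factors(counts: pd.DataFrame, reference_ids=None) -> pd.Series:
    """Median-of-ratios size factor per sample.

    ``reference_ids`` restricts the estimator to a feature subset (features
    with any zero count are excluded, as the geometric mean is degenerate).
    A single-sample matrix returns factor 1.
    """
    sub = counts.loc[reference_ids] if reference_ids is not None else counts
    sub = sub[(sub > 0).all(axis=1)]
    if len(sub) == 0:
        raise ValueError("no reference feature with nonzero counts in all samples")
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    log_gm = np.log(sub).mean(axis=1)
    ratios = np.log(sub).sub(log_gm, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _trended_dispersion(mean_counts: np.ndarray, disp_raw: np.ndarray,
                        n_bins: int = 20) -> np.ndarray:
    """Smooth per-feature dispersions by binned means over the expression mean.

    The per-feature moment estimator is clipped at zero and heavily skewed
    with few replicates; its bin *mean* is close to unbiased while the bin
    median is biased low (which would make the Wald test anti-conservative).
    """
    ok = mean_counts > 0
    if ok.sum() < 10:
        med = np.mean(disp_raw[ok]) if ok.any() else 0.0
        return np.full_like(disp_raw, max(med, 1e-8))
    order = np.log(mean_counts[ok])
    qs = np.quantile(order, np.linspace(0, 1, n_bins + 1))
    qs[-1] += 1e-9
    out = np.full_like(disp_raw, np.nan)
    idx = np.where(ok)[0]
    binned = np.digitize(order, qs[1:-1])
    for b in range(n_bins):
        sel = idx[binned == b]
        if len(sel):
            out[sel] = max(float(np.mean(disp_raw[sel])), 1e-8)
    # fill gaps (all-zero features, empty bins) with the global mean
    fill = np.nanmean(out)
    if not np.isfinite(fill):
        fill = 1e-8
    out[~np.isfinite(out)] = fill
    return out


def test_differential(counts: pd.DataFrame, design: pd.DataFrame,
                      sf: pd.Series, *, reference_level=None) -> pd.DataFrame:
    """NB Wald test of each condition against the reference condition.

    ``design`` maps samples (index) to a ``condition`` column; the reference
    defaults to the smallest condition value (time point 0). Returns a long
    frame: feature_id, contrast, log2fc, pvalue, padj, flags.
    """
    conds = design["condition"]
    levels = sorted(conds.unique())
    ref = levels[0] if reference_level is None else reference_level
    others = [c for c in levels if c != ref]
    norm_counts = counts.div(sf, axis=1)

    # per-condition replicate means/vars on normalized counts
    cond_means, cond_vars, cond_n = {}, {}, {}
    for lvl in levels:
        ids = conds.index[conds == lvl]
        sub = norm_counts[ids]
        cond_means[lvl] = sub.mean(axis=1).to_numpy()
        cond_vars[lvl] = sub.var(axis=1, ddof=1).to_numpy() if len(ids) > 1 \
            else np.zeros(len(sub))
        cond_n[lvl] = len(ids)

    pooled_fallback = all(n < 2 for n in cond_n.values())
    # method-of-moments dispersion pooled across conditions:
    # Var(norm count) ~ mu/s_eff + phi * mu^2
    s_eff = float(np.mean(sf.to_numpy()))
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for lvl in levels:
        if cond_n[lvl] < 2:
            continue
        w = cond_n[lvl] - 1
        num += w * (cond_vars[lvl] - cond_means[lvl] / s_eff)
        den += w * cond_means[lvl] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_raw = np.where(den > 0, np.clip(num / den, 0.0, None), 0.0)
    all_mean = norm_counts.mean(axis=1).to_numpy()
    disp = _trended_dispersion(all_mean, disp_raw)

    rows = []
    for lvl in others:
        m1, m0 = cond_means[lvl], cond_means[ref]
        n1, n0 = cond_n[lvl], cond_n[ref]
        zero = (m1 == 0) & (m0 == 0)
        # moderated means to keep logs finite for one-sided zeros
        m1s = np.where(m1 > 0, m1, 0.5)
        m0s = np.where(m0 > 0, m0, 0.5)
        log2fc = np.log2(m1s / m0s)
        if pooled_fallback:
            var_log = (1 / np.clip(m1s, 1e-8, None) / max(n1, 1)
                       + 1 / np.clip(m0s, 1e-8, None) / max(n0, 1))
            flag = "poisson_fallback"
        else:
            var_log = ((1 / np.clip(m1s, 1e-8, None) + disp) / max(n1, 1)
                       + (1 / np.clip(m0s, 1e-8, None) + disp) / max(n0, 1))
            flag = ""
        z = np.log(m1s / m0s) / np.sqrt(var_log)
        p = 2 * norm.sf(np.abs(z))
        log2fc = np.where(zero, 0.0, log2fc)
        p = np.where(zero, 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
        for i, fid in enumerate(counts.index):
            rows.append(dict(feature_id=fid, contrast=f"{lvl}_vs_{ref}",
                             condition=lvl, log2fc=float(log2fc[i]),
                             pvalue=float(p[i]), padj=float(padj[i]),
                             flags="all_zero" if zero[i] else flag))
    return pd.DataFrame(rows)


def classify_changes(de: pd.DataFrame, fc_cutoff: float = 2.0,
                     padj_cutoff: float = 0.05, *,
                     inclusive: bool = True) -> pd.DataFrame:
    """Direction labels per contrast plus an any-contrast "changed" flag.

    A feature is up in a contrast when its fold change is at least
    ``fc_cutoff`` and its adjusted p-value at most ``padj_cutoff`` (boundary
    inclusive by default; set ``inclusive=False`` for strict cutoffs); down
    symmetrically.
    """
    de = de.copy()
    lfc = np.log2(fc_cutoff)

    def ok_fc(x, cut):
        return x >= cut if inclusive else x > cut

    def ok_p(p):
        return p <= padj_cutoff if inclusive else p < padj_cutoff

    direction = np.where(ok_fc(de["log2fc"], lfc) & ok_p(de["padj"]), "up",
                         np.where(ok_fc(-de["log2fc"], lfc) & ok_p(de["padj"]),
                                  "down", "unchanged"))
    de["direction"] = direction
    changed = (de[de["direction"] != "unchanged"]
               .groupby("feature_id").size().index)
    de["changed_any"] = de["feature_id"].isin(changed)
    return de
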