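"""PWM scanning with an 80%-of-max score cutoff and set-level enrichment.

PWMs are position count matrices converted to log2-odds against a uniform
background after adding a small pseudo-weight. A window is a hit when its
score reaches ``frac`` (default 0.8) of the matrix's maximal achievable
score; scanning covers both strands by default. Enrichment between a positive
and a negative sequence set is an odds ratio with a two-sided Fisher exact
test and Benjamini-Hochberg adjustment across matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    id: str
    matrix: np.ndarray  # 4 x w log2-odds weights

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must be 4 x w (rows A,C,G,T)")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.id + "_rc", self.matrix[::-1, ::-1])


def pwm_from_counts(counts: np.ndarray, id: str = "pwm",
                    pseudo_weight: float = 0.01) -> PWM:
    """Log2-odds PWM vs uniform background from a 4 x w count matrix."""
    c = np.asarray(counts, dtype=float) + pseudo_weight
    p = c / c.sum(axis=0, keepdims=True)
    return PWM(id=id, matrix=np.log2(p / 0.25))


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int8)


def _scores_one_strand(enc: np.ndarray, pwm: PWM) -> np.ndarray:
    w = pwm.width
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    # N scores as the position's minimum
    lut = np.vstack([pwm.matrix, pwm.matrix.min(axis=0)])
    scores = np.zeros(n)
    for j in range(w):
        scores += lut[enc[j:j + n], j]
    return scores


def scan_sequence(seq: str, pwm: PWM, frac: float = 0.8,
                  both_strands: bool = True) -> list:
    """0-based window start positions scoring >= frac * max_score.

    Reverse-strand hits are reported at their forward-coordinate window start.
    Sequences shorter than the motif yield an empty list.
    """
    enc = _encode(seq)
    cutoff = frac * pwm.max_score
    hits = set(np.nonzero(_scores_one_strand(enc, pwm) >= cutoff)[0].tolist())
    if both_strands:
        rc = pwm.reverse_complement()
        hits |= set(np.nonzero(_scores_one_strand(enc, rc) >= cutoff)[0].tolist())
    return sorted(hits)


def consensus_scan(seq: str, consensus: str = "TGACTCA",
                   window: tuple = (-500, -100), tss_offset: int | None = None,
                   both_strands: bool = True) -> bool:
    """Exact-substring consensus occurrence within a TSS-relative window.

    ``seq`` is oriented 5'->3' with the TSS at ``tss_offset`` (defaults to the
    sequence end, i.e. an upstream extract). The window is given relative to
    the TSS; out-of-sequence parts are clipped.
    """
    if tss_offset is None:
        tss_offset = len(seq)
    lo = max(0, tss_offset + window[0])
    hi = min(len(seq), tss_offset + window[1])
    if hi <= lo:
        return False
    sub = seq[lo:hi].upper()
    if consensus.upper() in sub:
        return True
    if both_strands:
        rc = consensus.upper().translate(_COMPLEMENT)[::-1]
        return rc in sub
    return False


@dataclass
class EnrichmentResult:
    pwm_id: str
    a: int  # hits in positive set
    A: int  # positive set size
    b: int  # hits in negative set
    B: int  # negative set size
    odds_ratio: float
    pvalue: float
    padj: float = np.nan
    flags: str = ""


def enrichment(pos_flags, neg_flags, pwm_id: str = "pwm") -> EnrichmentResult:
    """Odds ratio + two-sided Fisher exact test for one motif.

    OR = (a/(A-a)) / (b/(B-b)); the Haldane-Anscombe +0.5 correction is
    applied (and flagged) when any cell of the 2x2 table is zero.
    """
    pos = np.asarray(pos_flags, dtype=bool)
    neg = np.asarray(neg_flags, dtype=bool)
    A, B = len(pos), len(neg)
    if A == 0 or B == 0:
        raise ValueError("both sequence sets must be non-empty")
    a, b = int(pos.sum()), int(neg.sum())
    table = np.array([[a, A - a], [b, B - b]], dtype=float)
    flags = ""
    if (table == 0).any():
        table = table + 0.5
        flags = "haldane"
    odds = (table[0, 0] / table[0, 1]) / (table[1, 0] / table[1, 1])
    p = fisher_exact([[a, A - a], [b, B - b]], alternative="two-sided")[1]
    return EnrichmentResult(pwm_id=pwm_id, a=a, A=A, b=b, B=B,
                            odds_ratio=float(odds), pvalue=float(p),
                            flags=flags)


def enrichment_table(pos_seqs: dict, neg_seqs: dict, pwms: dict,
                     frac: float = 0.8, both_strands: bool = True,
                     pseudo_weight: float = 0.01) -> pd.DataFrame:
    """Scan every PWM against both sets; BH-adjust p-values across PWMs.

    ``pwms`` maps id -> 4 x w count matrix (or PWM instance).
    """
    rows = []
    for pid, mat in pwms.items():
        pwm = mat if isinstance(mat, PWM) else pwm_from_counts(
            mat, id=pid, pseudo_weight=pseudo_weight)
        pos_flags = [len(scan_sequence(s, pwm, frac, both_strands)) > 0
                     for s in pos_seqs.values()]
        neg_flags = [len(scan_sequence(s, pwm, frac, both_strands)) > 0
                     for s in neg_seqs.values()]
        res = enrichment(pos_flags, neg_flags, pwm_id=pid)
        rows.append(vars(res))
    df = pd.DataFrame(rows)
    df["padj"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df
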