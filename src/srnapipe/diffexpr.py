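"""Two-library differential expression for small-RNA tag counts.

Single library per condition, so significance comes from an exact
count-based test in the Audic–Claverie family rather than a dispersion
model.  Given x tags of a miRNA in the treated library (total clean tags
N1) and y in the control library (total N2), the control count is modelled
conditionally on the treated count as negative binomial:

    p(y | x) = r^y (x + y)! / (x! y! (1 + r)^(x + y + 1)),   r = N2 / N1

which sums to 1 over y >= 0 and reduces to the classic equal-depth
Audic–Claverie probability at r = 1.  Tail probabilities

    p_lower = sum_{y = 0..y_obs} p(y|x)
    p_upper = sum_{y >= y_obs}  p(y|x)  =  1 - p_lower + p(y_obs|x)

are both inclusive of the observed count; the two-sided p-value is
min(1, 2 * min(p_lower, p_upper)).

Expression is normalized to tags per million (TPM = count / total * 1e6).
A miRNA absent from exactly one library gets TPM 0.01 there, so the
log2 fold-change log2(TPM_control / TPM_treated) is always defined;
miRNAs below 1 TPM in both libraries are filtered before testing.
Calls are two-tier: |log2 FC| >= 0.6 with 0.01 <= p < 0.05 is
"differentially expressed" (DE); |log2 FC| >= 0.6 with p < 0.01 is
"significant".  Positive fold-change means lower expression under
treatment (down-regulated in hypoxia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "LibraryTotals",
    "PValueResult",
    "normalize",
    "tpm_with_substitution",
    "filter_low",
    "fold_change",
    "exact_count_pvalue",
    "classify",
    "differential_expression",
    "ZERO_SUBSTITUTE_TPM",
    "MIN_TPM",
    "FC_THRESHOLD",
    "P_DE",
    "P_SIGNIFICANT",
]

#: TPM assigned to a miRNA detected in only one of the two libraries.
ZERO_SUBSTITUTE_TPM = 0.01
#: retention rule: keep a miRNA iff TPM >= MIN_TPM in at least one library.
MIN_TPM = 1.0
#: |log2 fold-change| required for either DE tier (1.516-fold linear).
FC_THRESHOLD = 0.6
#: p-value bands for the two tiers.
P_DE = 0.05
P_SIGNIFICANT = 0.01


@dataclass(frozen=True)
class LibraryTotals:
    """Total clean-tag counts: n1 = treated (hypoxia), n2 = control."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")

    @property
    def ratio(self) -> float:
        """r = N2/N1, the library-size correction of the exact test."""
        return self.n2 / self.n1


@dataclass(frozen=True)
class PValueResult:
    p_point: float
    p_lower: float
    p_upper: float
    p_two_sided: float


def normalize(raw_count: int, total: int) -> float:
    """Tags-per-million normalization: raw / total * 1e6."""
    if total <= 0:
        raise ValueError("total clean-read count must be positive")
    if raw_count < 0:
        raise ValueError("raw count must be non-negative")
    return raw_count / total * 1_000_000


def tpm_with_substitution(
    raw_ck: int, raw_hypoxia: int, total_ck: int, total_hypoxia: int
) -> tuple[float, float]:
    """Per-library TPMs with the single-library-zero substitution.

    A miRNA not expressed in exactly one library gets ZERO_SUBSTITUTE_TPM
    there so its fold-change is defined.  Zero in both libraries is left
    at (0, 0); such records are dropped upstream.
    """
    tpm_ck = normalize(raw_ck, total_ck)
    tpm_hyp = normalize(raw_hypoxia, total_hypoxia)
    if raw_ck == 0 and raw_hypoxia > 0:
        tpm_ck = ZERO_SUBSTITUTE_TPM
    elif raw_hypoxia == 0 and raw_ck > 0:
        tpm_hyp = ZERO_SUBSTITUTE_TPM
    return tpm_ck, tpm_hyp


def filter_low(records: pd.DataFrame, min_tpm: float = MIN_TPM) -> pd.DataFrame:
    """Keep records with TPM >= min_tpm in at least one library (inclusive)."""
    keep = (records["tpm_ck"] >= min_tpm) | (records["tpm_hypoxia"] >= min_tpm)
    return records.loc[keep].reset_index(drop=True)


def fold_change(tpm_ck: float, tpm_hypoxia: float) -> float:
    """log2(control TPM / treated TPM); positive = lower under treatment."""
    if tpm_ck <= 0 or tpm_hypoxia <= 0:
        raise ValueError(
            "fold change needs positive TPMs; apply the zero substitution first"
        )
    return math.log2(tpm_ck / tpm_hypoxia)


def _log_pmf_array(x: int, y_max: int, r: float) -> np.ndarray:
    """log p(y|x) for y = 0..y_max via the stable ratio recurrence.

    p(0|x) = (1+r)^-(x+1) and p(y+1)/p(y) = r (x+y+1) / [(y+1)(1+r)],
    accumulated entirely in log space.
    """
    y = np.arange(1, y_max + 1, dtype=np.float64)
    steps = np.log(r) + np.log(x + y) - np.log(y) - np.log1p(r)
    logs = np.empty(y_max + 1)
    logs[0] = -(x + 1) * np.log1p(r)
    if y_max:
        np.cumsum(steps, out=logs[1:])
        logs[1:] += logs[0]
    return logs


def exact_count_pvalue(x: int, y_obs: int, totals: LibraryTotals) -> PValueResult:
    """Exact two-library test of the observed control count y_obs given x.

    Both tails are inclusive of y_obs; they overlap in exactly the point
    probability, so p_lower + p_upper - p_point = 1.
    """
    if x < 0 or y_obs < 0:
        raise ValueError("counts must be non-negative integers")
    if x != int(x) or y_obs != int(y_obs):
        raise ValueError("counts must be integers")
    r = totals.ratio
    # extend the evaluation grid far enough past the distribution bulk
    # that the upper tail is summed directly (no 1 - lower cancellation).
    mean = r * (x + 1)
    sd = math.sqrt(r * (1 + r) * (x + 1))
    y_max = int(max(y_obs, math.ceil(mean + 20 * sd + 50)))
    logs = _log_pmf_array(int(x), y_max, r)

    tiny = 5e-324  # deep tails can underflow float64; keep probabilities > 0
    p_point = max(float(np.exp(logs[y_obs])), tiny)
    p_lower = float(np.exp(logsumexp(logs[: y_obs + 1])))
    p_upper = float(np.exp(logsumexp(logs[y_obs:])))
    # the grid truncates mass beyond y_max (< 1e-16 of total by construction)
    p_lower = min(max(p_lower, tiny), 1.0)
    p_upper = min(max(p_upper, tiny), 1.0)
    p_two = min(1.0, 2.0 * min(p_lower, p_upper))
    return PValueResult(p_point, p_lower, p_upper, p_two)


def classify(fc: float, p: float) -> str:
    """Two-tier call from |log2 FC| and the (two-sided) p-value."""
    if abs(fc) >= FC_THRESHOLD:
        if p < P_SIGNIFICANT:
            return "significant"
        if p < P_DE:
            return "DE"
    return "not_DE"


def _direction(fc: float) -> str:
    if fc > 0:
        return "down_in_hypoxia"
    if fc < 0:
        return "up_in_hypoxia"
    return "unchanged"


def differential_expression(
    counts: pd.DataFrame, totals: LibraryTotals, min_tpm: float = MIN_TPM
) -> pd.DataFrame:
    """Full DE table from per-miRNA raw counts.

    Parameters
    ----------
    counts
        Columns ``mirna_id``, ``count_ck``, ``count_hypoxia`` (raw tag
        counts; rows zero in both libraries are dropped).
    totals
        Clean-tag totals; note n1 = hypoxia = x-library, n2 = control.

    Returns the per-miRNA table with TPMs (after substitution), linear
    abundance ratio, log2 fold-change, all p-value fields, tier and
    direction, sorted by |fold-change| descending then id.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        x = int(rec.count_hypoxia)
        y = int(rec.count_ck)
        if x == 0 and y == 0:
            continue
        tpm_ck, tpm_hyp = tpm_with_substitution(y, x, totals.n2, totals.n1)
        fc = fold_change(tpm_ck, tpm_hyp)
        pv = exact_count_pvalue(x, y, totals)
        lo, hi = sorted((tpm_ck, tpm_hyp))
        rows.append(
            {
                "mirna_id": rec.mirna_id,
                "count_ck": y,
                "count_hypoxia": x,
                "tpm_ck": tpm_ck,
                "tpm_hypoxia": tpm_hyp,
                "abundance_ratio": round(hi / lo, 2),
                "fold_change": fc,
                "p_point": pv.p_point,
                "p_lower": pv.p_lower,
                "p_upper": pv.p_upper,
                "p_two_sided": pv.p_two_sided,
                "tier": classify(fc, pv.p_two_sided),
                "direction": _direction(fc),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "count_ck",
            "count_hypoxia",
            "tpm_ck",
            "tpm_hypoxia",
            "abundance_ratio",
            "fold_change",
            "p_point",
            "p_lower",
            "p_upper",
            "p_two_sided",
            "tier",
            "direction",
        ],
    )
    if df.empty:
        return df
    df = filter_low(df, min_tpm=min_tpm)
    df = df.sort_values(
        by=["fold_change", "mirna_id"],
        key=lambda s: -s.abs() if s.name == "fold_change" else s,
        kind="stable",
    )
    return df.reset_index(drop=True)
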