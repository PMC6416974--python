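"""Stem-loop qRT-PCR relative quantification (2^-ddCt).

Each Ct table row is one technical/biological replicate of one target in
one sample, paired with the internal-control (reference gene, e.g. U6)
Ct from the same well group.  For each (sample, target):

    dCt   = mean(Ct_target) - mean(Ct_reference)
    ddCt  = dCt_treated - dCt_control
    RQ    = 2 ** -ddCt          (calibrator sample RQ == 1 by definition)

assuming perfect per-cycle doubling.  A two-sided Welch t test on the
replicate dCt values provides the usual significance asterisks
(* P < 0.05, ** P < 0.01).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["read_ct_table", "relative_expression"]

_REQUIRED = ["sample", "target", "reference", "ct_target", "ct_reference", "replicate"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def _validate(table: pd.DataFrame) -> None:
    missing = set(_REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    cts = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if np.isnan(cts).any():
        bad = table.loc[np.isnan(cts).any(axis=1), ["sample", "target"]]
        pair = tuple(bad.iloc[0])
        raise ValueError(f"missing reference/target Ct for (sample, target) = {pair}")
    if ((cts <= 0) | (cts >= 45)).any():
        raise ValueError("Ct values must lie in (0, 45)")


def relative_expression(
    table: pd.DataFrame,
    control_sample: str = "CK",
    treated_sample: str | None = None,
) -> pd.DataFrame:
    """Per-target relative expression of the treated sample vs. control.

    Returns one row per target: dCt per sample, ddCt, rq (= 2^-ddCt),
    per-replicate RQ dispersion (rq_sd, on the linear scale), Welch
    t-test p-value on replicate dCts and its significance stars.
    """
    _validate(table)
    samples = sorted(table["sample"].unique())
    if control_sample not in samples:
        raise ValueError(f"control sample {control_sample!r} not in table")
    if treated_sample is None:
        others = [s for s in samples if s != control_sample]
        if len(others) != 1:
            raise ValueError(f"ambiguous treated sample among {others}")
        treated_sample = others[0]

    rows = []
    for target, sub in table.groupby("target", sort=True):
        dct = {}
        reps = {}
        for sample in (control_sample, treated_sample):
            grp = sub[sub["sample"] == sample]
            if grp.empty:
                raise ValueError(
                    f"no reference measurement for (sample, target) = "
                    f"({sample!r}, {target!r})"
                )
            per_rep = grp["ct_target"].to_numpy() - grp["ct_reference"].to_numpy()
            reps[sample] = per_rep
            dct[sample] = grp["ct_target"].mean() - grp["ct_reference"].mean()
        ddct = dct[treated_sample] - dct[control_sample]
        rq = 2.0 ** -ddct
        # per-replicate RQs (vs. the control-sample mean dCt) for dispersion
        rep_rq = 2.0 ** -(reps[treated_sample] - dct[control_sample])
        degenerate = (
            np.var(reps[treated_sample]) == 0 and np.var(reps[control_sample]) == 0
        )
        if degenerate:
            p = float("nan")  # no replicate scatter: the t statistic is undefined
        elif len(reps[treated_sample]) > 1 and len(reps[control_sample]) > 1:
            p = float(
                stats.ttest_ind(
                    reps[treated_sample], reps[control_sample], equal_var=False
                ).pvalue
            )
        else:
            p = float("nan")
        stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
        rows.append(
            {
                "target": target,
                "reference": sub["reference"].iloc[0],
                "dct_control": dct[control_sample],
                "dct_treated": dct[treated_sample],
                "ddct": ddct,
                "rq": rq,
                "rq_sd": float(np.std(rep_rq, ddof=1)) if len(rep_rq) > 1 else 0.0,
                "p_value": p,
                "significance": stars,
            }
        )
    return pd.DataFrame(rows)
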