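"""Report-layer arithmetic and table shaping.

These are the published-table computations: category frequencies as
percentages of clean reads, the mapped-read percentage, the share of DE
calls that are down-regulated, and the linear abundance-ratio table
(control TPM over treated TPM shown as "numerator/denominator" strings,
sorted by effect size within direction).  All percentages and ratios are
rounded half-up to 2 decimals, exactly as printed; full precision stays
in the upstream tables.
"""

from __future__ import annotations

import pandas as pd

from ._util import round_half_up

__all__ = [
    "frequency_percent",
    "mapped_percent",
    "down_regulated_percent",
    "linear_ratio",
    "ratio_report",
    "summary_json",
]


def frequency_percent(category_reads: int, total_clean: int, ndigits: int = 2) -> float:
    """Category frequency as a percentage of clean reads."""
    if total_clean <= 0:
        raise ValueError("total clean reads must be positive")
    return round_half_up(100 * category_reads / total_clean, ndigits)


def mapped_percent(mapped_reads: int, total_clean: int, ndigits: int = 2) -> float:
    """Genome-mapped reads as a percentage of clean reads."""
    return frequency_percent(mapped_reads, total_clean, ndigits)


def down_regulated_percent(n_down: int, n_de: int, ndigits: int = 2) -> float:
    """Share of DE miRNAs that are down-regulated under treatment."""
    if n_de <= 0:
        raise ValueError("no DE miRNAs")
    return round_half_up(100 * n_down / n_de, ndigits)


def linear_ratio(numerator_tpm: float, denominator_tpm: float, ndigits: int = 2) -> float:
    """Linear abundance ratio, rounded as displayed on ratio charts."""
    if denominator_tpm <= 0:
        raise ValueError("denominator TPM must be positive")
    return round_half_up(numerator_tpm / denominator_tpm, ndigits)


def ratio_report(de_results: pd.DataFrame) -> pd.DataFrame:
    """Abundance-ratio chart data for the DE set.

    One row per miRNA with the "control/treated" TPM label, the linear
    ratio in the direction of change, tier and direction; sorted by
    |log2 FC| descending within direction, ties broken by miRNA id.
    """
    cols = ["mirna_id", "abundance_label", "ratio", "fold_change", "tier", "direction"]
    if de_results.empty:
        return pd.DataFrame(columns=cols)
    df = de_results.copy()
    df["abundance_label"] = [
        f"{round_half_up(ck, 2)}/{round_half_up(hy, 2)}"
        for ck, hy in zip(df["tpm_ck"], df["tpm_hypoxia"])
    ]
    df["ratio"] = [
        linear_ratio(max(ck, hy), min(ck, hy))
        for ck, hy in zip(df["tpm_ck"], df["tpm_hypoxia"])
    ]
    df["_absfc"] = df["fold_change"].abs()
    df = df.sort_values(
        ["direction", "_absfc", "mirna_id"], ascending=[True, False, True]
    )
    return df[cols].reset_index(drop=True)


def summary_json(de_results: pd.DataFrame) -> dict:
    """Tier/direction counts for the run summary."""
    out = {
        "n_mirnas_tested": int(len(de_results)),
        "n_de": int((de_results["tier"] == "DE").sum()) if len(de_results) else 0,
        "n_significant": (
            int((de_results["tier"] == "significant").sum()) if len(de_results) else 0
        ),
    }
    called = de_results[de_results["tier"] != "not_DE"] if len(de_results) else de_results
    out["n_called"] = int(len(called))
    out["n_down_in_hypoxia"] = (
        int((called["direction"] == "down_in_hypoxia").sum()) if len(called) else 0
    )
    out["n_up_in_hypoxia"] = (
        int((called["direction"] == "up_in_hypoxia").sum()) if len(called) else 0
    )
    if out["n_called"]:
        out["down_regulated_percent"] = down_regulated_percent(
            out["n_down_in_hypoxia"], out["n_called"]
        )
    return out
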