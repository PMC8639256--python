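"""Fall vs. nonfall group comparison of sway features.

Each populated feature code is compared between the two groups with a
two-sided Welch (unequal-variance) t-test at significance level
``alpha`` (default 0.05, uncorrected — a Benjamini-Hochberg option is
available but off by default).  Missing feature values are excluded
pairwise.  By default every trial is one observation; an optional mode
averages the trials of a subject (within the condition view) first,
which restores the independence the t-test assumes when subjects
contribute several correlated trials.

Significant-code counts are summarised by signal origin (raw vs.
EMD-derived), by IMF level, and by feature domain (time = RMSD;
frequency = median frequency, total power; nonlinear = ApEn, SampEn).
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import META_COLUMNS, parse_code, DOMAINS

__all__ = [
    "welch_ttest",
    "compare_groups",
    "summarize_significance",
    "significance_matrix",
    "SUMMARY_ROWS",
]

#: row order of the significance-count summary table
SUMMARY_ROWS = (
    "all",
    "raw",
    "emd_derived",
    "imf1",
    "imf2",
    "imf3",
    "imf4",
    "imf5",
    "imf6",
    "time",
    "frequency",
    "nonlinear",
)


def welch_ttest(sample_a, sample_b):
    """Two-sided unequal-variance t-test.

    Returns ``(t, p)`` or ``None`` when the comparison is not testable
    (fewer than 2 finite values in either sample, or zero variance in
    both).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return None
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return None
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _average_trials(table: pd.DataFrame) -> pd.DataFrame:
    codes = [c for c in table.columns if c not in META_COLUMNS]
    grouped = (
        table.groupby(["subject_id", "group", "condition"], as_index=False)[codes]
        .mean()
    )
    grouped["trial"] = 1
    return grouped


def compare_groups(
    table: pd.DataFrame,
    alpha: float = 0.05,
    average_trials: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-code group means/SDs and Welch test with a significance flag.

    Returns a DataFrame with one row per feature code and columns
    ``code, n_fall, n_nonfall, mean_fall, sd_fall, mean_nonfall,
    sd_nonfall, t, p, testable, significant``.  ``fdr=True`` applies a
    Benjamini-Hochberg correction to the p-values before flagging.
    """
    groups = set(table["group"].unique())
    if not {"fall", "nonfall"} <= groups:
        raise ValueError(f"need both group labels, table has {sorted(groups)}")
    if average_trials:
        table = _average_trials(table)
    codes = [c for c in table.columns if c not in META_COLUMNS]
    fall = table[table["group"] == "fall"]
    nonfall = table[table["group"] == "nonfall"]
    rows = []
    for code in codes:
        va = fall[code].to_numpy(float)
        vb = nonfall[code].to_numpy(float)
        va = va[np.isfinite(va)]
        vb = vb[np.isfinite(vb)]
        res = welch_ttest(va, vb)
        rows.append(
            dict(
                code=code,
                n_fall=len(va),
                n_nonfall=len(vb),
                mean_fall=va.mean() if len(va) else np.nan,
                sd_fall=va.std(ddof=1) if len(va) > 1 else np.nan,
                mean_nonfall=vb.mean() if len(vb) else np.nan,
                sd_nonfall=vb.std(ddof=1) if len(vb) > 1 else np.nan,
                t=res[0] if res else np.nan,
                p=res[1] if res else np.nan,
                testable=res is not None,
            )
        )
    out = pd.DataFrame(rows)
    pvals = out["p"].to_numpy()
    if fdr:
        adjusted = pvals.copy()
        mask = np.isfinite(pvals)
        if mask.any():
            adjusted[mask] = sps.false_discovery_control(pvals[mask])
        out["p_adjusted"] = adjusted
        flag_p = adjusted
    else:
        flag_p = pvals
    out["significant"] = out["testable"] & (flag_p < alpha)
    return out


def _count(codes) -> dict:
    counts = {row: 0 for row in SUMMARY_ROWS}
    for code in codes:
        _, level, fid = parse_code(code)
        counts["all"] += 1
        if level == 0:
            counts["raw"] += 1
        else:
            counts["emd_derived"] += 1
            counts[f"imf{level}"] += 1
        for domain, fids in DOMAINS.items():
            if fid in fids:
                counts[domain] += 1
    return counts


def summarize_significance(comparisons: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Significant-code counts per condition view.

    ``comparisons`` maps a condition view (C4, CR, OR, CF, OF) to the
    output of :func:`compare_groups`.  Returns a table with the
    :data:`SUMMARY_ROWS` categories as rows and one column per view.
    The identities raw + EMD-derived = all, sum over IMF levels =
    EMD-derived and sum over domains = all hold by construction and are
    asserted.
    """
    data = {}
    for view, comp in comparisons.items():
        sig = comp.loc[comp["significant"], "code"]
        counts = _count(sig)
        assert counts["raw"] + counts["emd_derived"] == counts["all"]
        assert sum(counts[f"imf{k}"] for k in range(1, 7)) == counts["emd_derived"]
        assert sum(counts[d] for d in DOMAINS) == counts["all"]
        data[view] = [counts[row] for row in SUMMARY_ROWS]
    return pd.DataFrame(data, index=list(SUMMARY_ROWS))


def significance_matrix(comparisons: Dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Code x condition-view boolean flag matrix (rows limited to codes
    significant in at least one view)."""
    flags = {}
    for view, comp in comparisons.items():
        flags[view] = comp.set_index("code")["significant"]
    mat = pd.DataFrame(flags).fillna(False)
    return mat.loc[mat.any(axis=1)]
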