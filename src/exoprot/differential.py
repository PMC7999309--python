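"""Per-protein case/control testing and pi-score ranking.

Each protein is compared between groups with a two-sided Welch t-test
(unequal variances, Welch-Satterthwaite degrees of freedom) on normalized
abundances.  Effect size is the log2 ratio of group arithmetic means.  The
two are combined into the signed pi-score

    pi = log2FC * (-log10 p)

which ranks proteins by joint significance and effect size; proteins with
``pi > threshold`` (default 1, strict) are called case-associated and those
with ``pi < -threshold`` control-associated.  No multiple-testing correction
enters the classification — a Benjamini-Hochberg q-value column is emitted
for reference only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "welch_t",
    "log2_fold_change",
    "pi_score",
    "differential_table",
    "classify_proteins",
    "volcano_table",
    "volcano_figure",
    "CASE_ASSOCIATED",
    "CONTROL_ASSOCIATED",
    "NOT_SIGNIFICANT",
]

CASE_ASSOCIATED = "case_associated"
CONTROL_ASSOCIATED = "control_associated"
NOT_SIGNIFICANT = "not_significant"

_TINY_P = float(np.finfo(float).tiny)

#: fixed column order of the exported differential table
TABLE_COLUMNS = ["mean_case", "mean_control", "log2fc", "p_value", "bh_q", "pi_score", "class_label"]


def welch_t(case_values, control_values) -> tuple[float, float]:
    """Two-sided Welch t-test; requires >= 2 values per group.

    Degenerate inputs are resolved explicitly: two constant, equal groups
    give (0, 1); two constant, unequal groups give an infinite statistic and
    the smallest representable positive p, with a warning.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("both groups constant but unequal; p clamped to the smallest positive float")
        return float(np.sign(a.mean() - b.mean()) * np.inf), _TINY_P
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def log2_fold_change(case_values, control_values, pseudocount: float = 0.0) -> float:
    """log2 of the ratio of group arithmetic means (plus optional pseudocount)."""
    mc = float(np.mean(np.asarray(case_values, dtype=float))) + pseudocount
    mk = float(np.mean(np.asarray(control_values, dtype=float))) + pseudocount
    if mc < 0 or mk < 0:
        raise ValueError("group means plus pseudocount must be nonnegative")
    if mc == 0.0 and mk == 0.0:
        raise ValueError("fold change undefined: both group means are zero (pseudocount 0)")
    if mk == 0.0:
        warnings.warn("control mean is zero; log2 fold change is +inf")
        return float(np.inf)
    if mc == 0.0:
        warnings.warn("case mean is zero; log2 fold change is -inf")
        return float(-np.inf)
    return float(np.log2(mc / mk))


def pi_score(p_value: float, log2fc: float) -> float:
    """Signed significance score: log2 fold change times -log10 p."""
    if p_value > 1.0:
        raise ValueError("p_value must lie in (0, 1]")
    if p_value <= 0.0:
        warnings.warn("p-value <= 0 clamped to the smallest positive float")
        p_value = _TINY_P
    return float(log2fc * (-np.log10(p_value)))


def classify_proteins(table: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Assign class labels by strict pi-score threshold (|pi| > threshold)."""
    out = table.copy()
    pi = out["pi_score"]
    out["class_label"] = np.select(
        [pi > threshold, pi < -threshold],
        [CASE_ASSOCIATED, CONTROL_ASSOCIATED],
        default=NOT_SIGNIFICANT,
    )
    return out


def differential_table(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    case_label: str = "case",
    pseudocount: float = 0.0,
    pi_threshold: float = 1.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Run the full per-protein comparison over a proteins x samples matrix.

    ``metadata['group']`` must be binary; samples whose label equals
    ``case_label`` form the case group.  Proteins with fewer than two present
    values in either group cannot be tested and are returned separately as a
    skipped list.

    Returns
    -------
    (table, skipped)
        ``table`` has the fixed column order mean_case, mean_control, log2fc,
        p_value, bh_q, pi_score, class_label and is indexed by protein id.
    """
    groups = metadata.loc[list(matrix.columns), "group"]
    labels = groups.unique().tolist()
    if len(labels) != 2 or case_label not in labels:
        raise ValueError(f"need exactly two group labels including {case_label!r}, got {labels}")
    case_cols = groups.index[groups == case_label]
    ctrl_cols = groups.index[groups != case_label]

    rows: dict[str, list[float]] = {}
    skipped: list[str] = []
    for pid, row in matrix.iterrows():
        a = row[case_cols].dropna().to_numpy(dtype=float)
        b = row[ctrl_cols].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            skipped.append(pid)
            continue
        t, p = welch_t(a, b)
        fc = log2_fold_change(a, b, pseudocount=pseudocount)
        rows[pid] = [float(a.mean()), float(b.mean()), fc, p, pi_score(p, fc)]

    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_case", "mean_control", "log2fc", "p_value", "pi_score"]
    )
    table.index.name = "protein_id"
    if len(table):
        table["bh_q"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        table["bh_q"] = pd.Series(dtype=float)
    table = classify_proteins(table, threshold=pi_threshold)
    return table[TABLE_COLUMNS], skipped


def _rank_order(table: pd.DataFrame) -> pd.Index:
    """Protein order by decreasing |pi|; ties by smaller p, then identifier."""
    key = pd.DataFrame(
        {"abs_pi": table["pi_score"].abs(), "p": table["p_value"], "pid": table.index.astype(str)},
        index=table.index,
    )
    return key.sort_values(["abs_pi", "p", "pid"], ascending=[False, True, True]).index


def volcano_table(table: pd.DataFrame, top_k: int = 10) -> pd.DataFrame:
    """Volcano-plot export: -log10 p plus per-class top-k flags ranked by |pi|."""
    out = table.copy()
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out["top_case"] = False
    out["top_control"] = False
    for label, col in ((CASE_ASSOCIATED, "top_case"), (CONTROL_ASSOCIATED, "top_control")):
        sub = out[out["class_label"] == label]
        if len(sub):
            flagged = _rank_order(sub)[:top_k]
            out.loc[flagged, col] = True
    return out


def volcano_figure(volcano: pd.DataFrame, path, pi_threshold: float = 1.0) -> None:
    """Optional rendering of the volcano table to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = volcano["class_label"].map(
        {CASE_ASSOCIATED: "tab:red", CONTROL_ASSOCIATED: "tab:blue", NOT_SIGNIFICANT: "0.7"}
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(volcano["log2fc"], volcano["neg_log10_p"], s=12, c=colors, alpha=0.8, linewidths=0)
    for pid in volcano.index[volcano["top_case"] | volcano["top_control"]]:
        ax.annotate(str(pid), (volcano.at[pid, "log2fc"], volcano.at[pid, "neg_log10_p"]), fontsize=6)
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"|pi| > {pi_threshold:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
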