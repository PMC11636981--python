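"""Condition-associated candidate genes via the GS/MM/DE triple filter.

A condition variable (sulfide, oxygen, nitrate or hydrogen) is coded 1 for
samples whose treatment was replete in that substrate and 0 when it was
limiting or absent.  The two modules with the highest mean |GS| for the
condition are searched, and genes pass if |GS| > 0.2 with P <= 0.05,
|MM| > 0.8 against their own module eigengene, and at least one of the
named pairwise DE comparisons for that condition is significant; the mean
and SD of log2FC over the significant comparisons are reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .simulate import STATES, SUBSTRATES

#: Pairwise DE comparisons per condition under the default synthetic design:
#: five sulfide and two oxygen limitation comparisons.
DEFAULT_COMPARISONS: dict[str, list[str]] = {
    "sulfide": [
        "replete_a_vs_sulfide_limiting",
        "replete_a_vs_no_sulfide",
        "replete_b_vs_sulfide_limiting",
        "replete_b_vs_no_sulfide",
        "replete_h2_vs_sulfide_limiting",
    ],
    "oxygen": [
        "replete_a_vs_oxygen_limiting",
        "replete_a_vs_no_oxygen",
    ],
}


def encode_condition(samples: pd.DataFrame, condition: str) -> pd.Series:
    """Binary condition vector: replete -> 1, limiting/absent -> 0."""
    if condition not in SUBSTRATES:
        raise ValueError(f"unknown condition {condition!r}; expected one of {SUBSTRATES}")
    states = samples[condition]
    bad = set(states) - set(STATES)
    if bad:
        raise ValueError(
            f"unknown substrate state(s) {sorted(bad)}; allowed: {STATES}"
        )
    vec = (states == "replete").astype(float)
    vec.index = samples["sample"]
    vec.name = condition
    if vec.nunique() < 2:
        raise ValueError(
            f"condition {condition!r} is constant across samples (all "
            f"{'replete' if vec.iloc[0] else 'limiting/absent'})"
        )
    return vec


def rank_modules_by_gs(
    gs: pd.DataFrame, labels: pd.Series, k: int = 2
) -> list[str]:
    """Modules ordered by mean |GS| of their member genes; top k, grey excluded."""
    if k == 0:
        return []
    means = (
        gs["gs"].abs().groupby(labels).mean().drop(index="grey", errors="ignore")
    )
    ranked = means.sort_values(ascending=False).index.tolist()
    if len(ranked) < k:
        warnings.warn(
            f"only {len(ranked)} modules available for top-{k} ranking", stacklevel=2
        )
    return ranked[:k]


def select_candidates(
    gs: pd.DataFrame,
    mm: pd.DataFrame,
    labels: pd.Series,
    de_table: pd.DataFrame,
    modules: list[str],
    comparisons: list[str],
    gs_min: float = 0.2,
    p_max: float = 0.05,
    mm_min: float = 0.8,
    de_fdr: float = 0.05,
) -> pd.DataFrame:
    """Candidate genes passing |GS| > gs_min, P <= p_max, |MM| > mm_min and DE.

    ``mm`` is the gene x module MM matrix ("ME<module>" columns); each gene
    is evaluated against its own module's eigengene.  DE significance is
    padj <= de_fdr in at least one of the named comparisons; log2FC
    mean/SD are taken over the significant comparisons only.  The direction
    label reflects the sign of the mean log2FC ("increase" when expression
    rises with the comparisons' reference, i.e. repletion).
    """
    if not comparisons:
        raise ValueError("empty comparisons list")
    missing = set(comparisons) - set(de_table["contrast"].unique())
    if missing:
        raise ValueError(f"comparisons not present in DE table: {sorted(missing)}")

    de = de_table[de_table["contrast"].isin(comparisons)]
    rows = []
    for gene in labels.index:
        module = labels[gene]
        if module not in modules:
            continue
        g, p = gs.loc[gene, "gs"], gs.loc[gene, "p"]
        if not (abs(g) > gs_min and p <= p_max):
            continue
        me_col = f"ME{module}"
        if me_col not in mm.columns:
            continue
        m = mm.loc[gene, me_col]
        if not abs(m) > mm_min:
            continue
        gd = de[de["gene"] == gene]
        sig = gd[gd["padj"] <= de_fdr]
        if sig.empty:
            continue
        lfc = sig["log2fc"].to_numpy()
        rows.append(
            {
                "gene": gene,
                "module": module,
                "gs": g,
                "gs_p": p,
                "mm": m,
                "mean_log2fc": float(lfc.mean()),
                "sd_log2fc": float(lfc.std(ddof=1)) if len(lfc) > 1 else 0.0,
                "n_comparisons": int(len(lfc)),
                "direction": "increase" if lfc.mean() > 0 else "decrease",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "module", "gs", "gs_p", "mm",
            "mean_log2fc", "sd_log2fc", "n_comparisons", "direction",
        ],
    )
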