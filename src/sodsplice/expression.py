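"""RT-qPCR analysis: Livak 2^-ddCt quantification, Fisher's LSD letters,
and Pearson correlations with developmental karyogamy efficiency.

The Livak statistic assumes amplification efficiency of exactly 2 and a
reference gene measured in every sample: dCt = target Ct - reference Ct
per replicate, ddCt = mean dCt - mean dCt of the calibrator condition,
relative expression = 2^-ddCt.  By construction the calibrator's fold is
exactly 1 for any noise realization.  Standard errors of fold changes are
delta-method transforms of the dCt standard error onto the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, EvidenceError, InputError

ALPHA_DEFAULT = 0.05

# Stage-wise percentage of basidia having completed karyogamy
# (egg stage at 3 h, elongation at 9 h, maturation at 7 h).
KARYOGAMY_TABLE = pd.DataFrame(
    {"stage": ["egg", "elongation", "maturation"],
     "karyogamy_pct": [37.5, 30.0, 0.1]})


def ddct_fold_change(ct_table: pd.DataFrame, reference_gene: str,
                     calibrator: str) -> pd.DataFrame:
    """Relative expression per gene and condition by the 2^-ddCt method.

    ``ct_table`` needs columns condition, gene, replicate, ct (a sample
    column is accepted and ignored for the computation).  Returns one row
    per (gene, condition) with columns dct_mean, dct_se, ddct, fold,
    fold_se, n.  Raises when the reference gene is missing from a sample.
    """
    required = {"condition", "gene", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise InputError(f"Ct table lacks columns {sorted(missing)}")
    genes = [g for g in ct_table["gene"].unique() if g != reference_gene]
    if reference_gene not in set(ct_table["gene"]):
        raise EvidenceError(f"reference gene {reference_gene!r} absent")
    if calibrator not in set(ct_table["condition"]):
        raise InputError(f"calibrator condition {calibrator!r} absent")

    ref = (ct_table[ct_table["gene"] == reference_gene]
           .set_index(["condition", "replicate"])["ct"])
    rows = []
    dct_by_gene_cond: dict[tuple[str, str], np.ndarray] = {}
    for gene in genes:
        sub = ct_table[ct_table["gene"] == gene]
        for cond, grp in sub.groupby("condition", sort=False):
            dcts = []
            for _, row in grp.iterrows():
                key = (cond, row["replicate"])
                if key not in ref.index:
                    raise EvidenceError(
                        f"sample {cond!r} replicate {row['replicate']} has no "
                        f"{reference_gene!r} measurement")
                dcts.append(row["ct"] - ref.loc[key])
            dct_by_gene_cond[(gene, cond)] = np.asarray(dcts, dtype=float)
    for gene in genes:
        cal = dct_by_gene_cond.get((gene, calibrator))
        if cal is None:
            raise InputError(f"gene {gene!r} not measured in the calibrator")
        cal_mean = cal.mean()
        for cond in ct_table[ct_table["gene"] == gene]["condition"].unique():
            dct = dct_by_gene_cond[(gene, cond)]
            n = dct.size
            dct_se = float(dct.std(ddof=1) / sqrt(n)) if n > 1 else float("nan")
            ddct = float(dct.mean() - cal_mean)
            fold = float(2.0 ** (-ddct))
            fold_se = fold * log(2.0) * dct_se if n > 1 else float("nan")
            rows.append((gene, cond, float(dct.mean()), dct_se, ddct, fold,
                         fold_se, n))
    return pd.DataFrame(rows, columns=["gene", "condition", "dct_mean",
                                       "dct_se", "ddct", "fold", "fold_se",
                                       "n"])


def lsd_letters(groups: Mapping[str, Sequence[float]],
                alpha: float = ALPHA_DEFAULT) -> tuple[dict[str, str], dict]:
    """Fisher's LSD compact letter display after one-way ANOVA.

    Pairwise t tests use the pooled ANOVA error term; letters are
    assigned by insert-and-absorb so that two groups share a letter iff
    they are not significantly different at ``alpha``.  Returns (letters,
    summary) where summary carries the ANOVA table and the pairwise
    p-value matrix.
    """
    if len(groups) < 2:
        raise InputError("LSD lettering needs >= 2 groups")
    names = list(groups)
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in data.items():
        if v.size < 2:
            raise InputError(f"group {g!r} has fewer than 2 replicates")
    k = len(names)
    N = sum(v.size for v in data.values())
    grand = np.concatenate(list(data.values())).mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_b, df_w = k - 1, N - k
    if ss_within <= 0:
        raise InputError(
            "zero within-group variance everywhere; LSD is degenerate")
    mse = ss_within / df_w
    f_stat = (ss_between / df_b) / mse
    anova_p = float(stats.f.sf(f_stat, df_b, df_w))

    pvals = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = data[a], data[b]
            t = (va.mean() - vb.mean()) / sqrt(mse * (1 / va.size + 1 / vb.size))
            p = float(2 * stats.t.sf(abs(t), df_w))
            pvals.loc[a, b] = pvals.loc[b, a] = p

    # insert-and-absorb over groups sorted by mean (descending, ties by name)
    order = sorted(names, key=lambda g: (-data[g].mean(), g))
    columns: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            if pvals.loc[a, b] >= alpha:
                continue
            split = []
            for col in columns:
                if a in col and b in col:
                    split.append(col - {a})
                    split.append(col - {b})
                else:
                    split.append(col)
            uniq: list[set[str]] = []
            for col in split:
                if col and col not in uniq:
                    uniq.append(col)
            columns = [c for c in uniq if not any(c < other for other in uniq)]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in names}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for g in order:
            if g in col:
                letters[g] += letter
    summary = {"f": float(f_stat), "p": anova_p, "df": (df_b, df_w),
               "mse": float(mse), "pairwise_p": pvals}
    return letters, summary


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on unequal lengths, fewer than
    three points, or zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y have different lengths")
    if x.size < 3:
        raise InputError("correlation needs at least 3 points")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise InputError("undefined correlation: an argument has zero variance")
    return float(stats.pearsonr(x, y)[0])


def karyogamy_correlation(expression_by_stage: Mapping[str, Mapping[str, float]],
                          karyogamy_table: pd.DataFrame = KARYOGAMY_TABLE,
                          ) -> dict[str, float]:
    """Pearson r between stage-wise expression and karyogamy efficiency.

    ``expression_by_stage`` maps gene -> {stage: expression}; stages must
    match the karyogamy table exactly (order-insensitive).
    """
    stages = list(karyogamy_table["stage"])
    pct = karyogamy_table.set_index("stage")["karyogamy_pct"]
    out = {}
    for gene, expr in expression_by_stage.items():
        if set(expr) != set(stages):
            raise InputError(
                f"gene {gene!r}: stages {sorted(expr)} do not match "
                f"karyogamy stages {sorted(stages)}")
        x = [expr[s] for s in stages]
        y = [float(pct[s]) for s in stages]
        out[gene] = pearson_correlation(x, y)
    return out
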