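"""Length/GC summaries, two-way ANOVA with Tukey HSD, insertion-site logos,
and the feature bubble matrix.

Intron length and GC content are compared across intron lineages
(IIA-RT/M, IIB-RT/M, IIB-LHE, IIB-like) and organellar compartments
(mt, cp) with a two-way fixed-effects ANOVA using Type-II sums of squares
(the cohorts are unbalanced), followed by Tukey-Kramer HSD on the crossed
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "gc_content",
    "at_content",
    "AnovaResult",
    "two_way_anova_tukey",
    "LogoProfile",
    "insertion_site_logo",
    "bubble_matrix",
    "gc_vs_host_test",
]


def gc_content(sequence: str) -> float:
    """GC percentage of a nucleotide sequence; N excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGUT"}
    denom = sum(counts.values())
    if denom == 0:
        warnings.warn("sequence contains no unambiguous nucleotides; GC undefined")
        return float("nan")
    return 100.0 * (counts["G"] + counts["C"]) / denom


def at_content(sequence: str) -> float:
    s = sequence.upper()
    counts = {b: s.count(b) for b in "ACGUT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return 100.0 * (counts["A"] + counts["U"] + counts["T"]) / denom


@dataclass
class AnovaResult:
    anova: pd.DataFrame  # effect, df, sum_sq, F, p
    tukey: pd.DataFrame | None
    cells: pd.DataFrame  # per-cell n and mean
    reduced_to_one_way: bool = False


def two_way_anova_tukey(values, factor_a, factor_b, with_tukey: bool = True) -> AnovaResult:
    """Two-way fixed-effects ANOVA (Type-II SS) + Tukey-Kramer HSD.

    ``factor_a`` is the intron-lineage-like factor, ``factor_b`` the
    organelle-like factor. If a factor has a single level the analysis
    reduces to a one-way ANOVA with a warning. Tukey HSD is computed on the
    crossed cells (A:B groups); pass ``with_tukey=False`` to skip the post
    hoc step (e.g. in calibration loops).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float),
         "A": pd.Categorical(factor_a), "B": pd.Categorical(factor_b)}
    )
    if df["A"].nunique() < 2 and df["B"].nunique() < 2:
        raise ValueError("need at least one factor with >= 2 levels")
    reduced = False
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        warnings.warn("a factor has a single level; reducing to one-way ANOVA")
        reduced = True
        fac = "A" if df["A"].nunique() >= 2 else "B"
        model = smf.ols(f"y ~ C({fac})", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    else:
        model = smf.ols("y ~ C(A) * C(B)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename_axis("effect").reset_index()

    cells = (
        df.assign(cell=df["A"].astype(str) + ":" + df["B"].astype(str))
        .groupby("cell", observed=True)["y"]
        .agg(n="size", mean="mean")
        .reset_index()
    )
    tukey = None
    groups = df["A"].astype(str) + ":" + df["B"].astype(str)
    if with_tukey and groups.nunique() >= 2 and (groups.value_counts() >= 2).all():
        res = pairwise_tukeyhsd(df["y"].values, groups.values)
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return AnovaResult(anova=anova, tukey=tukey, cells=cells, reduced_to_one_way=reduced)


@dataclass
class LogoProfile:
    """Per-position base frequencies and information content around a junction."""

    positions: list  # e.g. -20..-1, +1..+20 with 0 = junction boundary omitted
    frequencies: pd.DataFrame  # rows = positions, columns = A,C,G,U
    information: np.ndarray  # bits per position
    n: int


def insertion_site_logo(windows: list[str], small_sample_correction: bool = False) -> LogoProfile:
    """Sequence-logo profile of aligned insertion-site windows.

    Information content per position is ``2 - H`` (Shannon entropy, log2)
    over {A,C,G,U}; the optional small-sample correction subtracts
    ``e(n) = 3/(2 ln2 n)``.
    """
    if not windows:
        raise ValueError("no windows supplied")
    L = len(windows[0])
    if any(len(w) != L for w in windows):
        raise ValueError("windows differ in length")
    n = len(windows)
    half = L // 2
    positions = [p - half if p < half else p - half + 1 for p in range(L)]
    freq = np.zeros((L, 4))
    bases = "ACGU"
    for w in windows:
        w = w.upper().replace("T", "U")
        for i, c in enumerate(w):
            if c in bases:
                freq[i, bases.index(c)] += 1
    totals = freq.sum(axis=1)
    totals[totals == 0] = 1.0
    freq = freq / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -np.nansum(np.where(freq > 0, freq * np.log2(freq), 0.0), axis=1)
    info = 2.0 - H
    if small_sample_correction:
        info = info - 3.0 / (2.0 * np.log(2) * n)
    info = np.clip(info, 0.0, 2.0)
    return LogoProfile(
        positions=positions,
        frequencies=pd.DataFrame(freq, index=positions, columns=list(bases)),
        information=info,
        n=n,
    )


def bubble_matrix(feature_table: pd.DataFrame, feature_columns: list[str],
                  family_column: str = "family") -> pd.DataFrame:
    """Per-family percentages of members carrying each feature.

    ``feature_table`` holds one row per intron with boolean (or 0/1/NaN)
    feature columns; NaN cells are excluded from that feature's denominator
    and reported in ``<feature>_n`` alongside. Percentages are rounded to
    one decimal, as in the family-by-feature bubble matrix display.
    """
    missing = [c for c in feature_columns + [family_column] if c not in feature_table]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    out = {}
    grouped = feature_table.groupby(family_column)
    out["n_members"] = grouped.size()
    for col in feature_columns:
        vals = feature_table[[family_column, col]].copy()
        ok = vals[col].notna()
        pct = (
            vals[ok]
            .assign(v=vals.loc[ok, col].astype(float))
            .groupby(family_column)["v"]
            .mean()
            * 100.0
        )
        out[col] = pct.round(1)
        out[f"{col}_n"] = vals[ok].groupby(family_column).size()
    res = pd.DataFrame(out)
    res.index.name = "family"
    return res


def gc_vs_host_test(member_gc: list[float], host_gc: float) -> dict:
    """Is a family's GC content shifted relative to its host genome?

    One-sample t-test of member GC values against the host-genome GC, with a
    Wilcoxon signed-rank fallback when normality is doubtful (n < 8 or zero
    variance handled explicitly).
    """
    from scipy import stats as sps

    x = np.asarray(member_gc, dtype=float)
    if x.size < 2 or np.allclose(x.var(), 0):
        return {"test": "none", "p": float("nan"), "mean_diff": float(x.mean() - host_gc) if x.size else float("nan")}
    t, p = sps.ttest_1samp(x, host_gc)
    out = {"test": "t", "stat": float(t), "p": float(p), "mean_diff": float(x.mean() - host_gc)}
    if x.size < 8:
        try:
            w, pw = sps.wilcoxon(x - host_gc)
            out.update({"test": "wilcoxon", "stat": float(w), "p": float(pw)})
        except ValueError:
            pass
    return out
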