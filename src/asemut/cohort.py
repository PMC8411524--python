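"""Cohort-level summaries and hypothesis tests.

Covers expressed tumor mutational burden, gene-wise mutation-expression
frequency, DNA-MAF group contrasts, delta-MAF stratified by mutation type x
gene category x allelic balance, imbalance enrichment in cancer-critical
genes, and mutant-dose versus drug-sensitivity correlations.  All p-values
are two-sided; no multiple-testing correction is applied unless requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ase_records_to_frame
from .types import AseRecord, MutationClass, Status, TRUNCATING, SPLICE_SITE

#: Mutation-type groups for delta-MAF stratification.  Truncating pools the
#: premature-stop classes (nonsense SNVs + frameshift indels); splice-site
#: SNVs and indels are pooled by default.
MUTATION_GROUPS: dict[str, frozenset[MutationClass]] = {
    "synonymous": frozenset({MutationClass.SYNONYMOUS_SNV}),
    "missense": frozenset({MutationClass.MISSENSE_SNV}),
    "truncating": TRUNCATING,
    "splice_site": SPLICE_SITE,
    "stoploss": frozenset({MutationClass.STOPLOSS_SNV}),
    "inframe": frozenset({MutationClass.INFRAME_INDEL}),
}

#: Minimum stratum size reported.
MIN_STRATUM_N = 10

REFERENCE_GROUP = "synonymous"


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return ase_records_to_frame(records)


def mutation_group(mutation_class: MutationClass | str) -> str:
    mc = MutationClass(mutation_class)
    for name, members in MUTATION_GROUPS.items():
        if mc in members:
            return name
    raise ValueError(f"unmapped mutation class {mc}")


# ---------------------------------------------------------------------------
# expressed TMB


def expressed_tmb(records, capture_size_mb: float = 50.0) -> dict:
    """Tumor mutational burden of one sample, total and expressed.

    ``tmb`` counts amino-acid-changing mutations passing DNA filters (the
    input records are post-filter); ``expressed_tmb`` those classified
    MUT_EXPRESSED.  The proportion expressed is computed over evaluable
    (non-UNEVALUABLE) amino-acid-changing mutations and is NaN when there
    are none.
    """
    df = _as_frame(records)
    aa = df[df["amino_acid_changing"]] if len(df) else df
    tmb = int(len(aa))
    expressed = int((aa["status"] == Status.MUT_EXPRESSED.value).sum()) if tmb else 0
    evaluable = int((aa["status"] != Status.UNEVALUABLE.value).sum()) if tmb else 0
    return {
        "tmb": tmb,
        "expressed_tmb": expressed,
        "tmb_per_mb": tmb / capture_size_mb,
        "expressed_tmb_per_mb": expressed / capture_size_mb,
        "n_evaluable": evaluable,
        "proportion_expressed": expressed / evaluable if evaluable else math.nan,
    }


def per_sample_tmb(records, capture_size_mb: float = 50.0) -> pd.DataFrame:
    """Expressed-TMB summary per sample, one row per sample."""
    df = _as_frame(records)
    rows = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        row = {"sample_id": sample_id}
        row.update(expressed_tmb(sub, capture_size_mb))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene-wise mutation-expression frequency


def gene_expression_frequency(collapsed_records) -> pd.DataFrame:
    """Per-gene proportion of mutated tumors expressing the mutation.

    Input must already be gene-collapsed (one mutated gene per sample,
    expressed records preferred) and is restricted here to
    amino-acid-changing classes.  The denominator counts evaluable tumors
    only; genes mutated exclusively in unevaluable tumors get frequency NA.
    Tumors, not mutations, are the unit: several retained expressed records
    of one gene in one sample still count that tumor once.
    """
    df = _as_frame(collapsed_records)
    df = df[df["amino_acid_changing"]]
    columns = [
        "gene", "role", "cancer_critical", "n_mutated_tumors",
        "n_evaluable_tumors", "n_expressed_tumors", "frequency",
    ]
    if not len(df):
        return pd.DataFrame(columns=columns)
    per_tumor = (
        df.assign(
            _expr=df["status"] == Status.MUT_EXPRESSED.value,
            _eval=df["status"] != Status.UNEVALUABLE.value,
        )
        .groupby(["gene", "sample_id"], sort=True)
        .agg(
            _expr=("_expr", "any"),
            _eval=("_eval", "any"),
            role=("role", "first"),
            cancer_critical=("cancer_critical", "first"),
        )
        .reset_index()
    )
    out = (
        per_tumor.groupby("gene", sort=True)
        .agg(
            role=("role", "first"),
            cancer_critical=("cancer_critical", "first"),
            n_mutated_tumors=("sample_id", "size"),
            n_evaluable_tumors=("_eval", "sum"),
            n_expressed_tumors=("_expr", "sum"),
        )
        .reset_index()
    )
    out["frequency"] = out["n_expressed_tumors"] / out["n_evaluable_tumors"].where(
        out["n_evaluable_tumors"] > 0
    )
    return out[columns]


def gene_frequency_by_role(freq: pd.DataFrame) -> pd.DataFrame:
    """Mean gene-wise expression frequency per gene-role group."""
    valid = freq.dropna(subset=["frequency"])
    rows = []
    for critical, sub in valid.groupby("cancer_critical"):
        mean = float(sub["frequency"].mean())
        ci = _mean_ci(sub["frequency"].to_numpy())
        rows.append(
            {
                "cancer_critical": bool(critical),
                "n_genes": int(len(sub)),
                "mean_frequency": mean,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group contrasts


def _mean_ci(values: np.ndarray, confidence: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        return (math.nan, math.nan)
    sem = stats.sem(values)
    half = sem * stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    mean = float(values.mean())
    return (mean - half, mean + half)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided t-test; (statistic, p). NaN when a group has < 2 values."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        return (math.nan, math.nan)
    res = stats.ttest_ind(a, b, equal_var=False)
    return (float(res.statistic), float(res.pvalue))


def paired_t(diffs_a: Sequence[float], diffs_b: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided t-test on matched per-sample values."""
    a, b = np.asarray(diffs_a, float), np.asarray(diffs_b, float)
    if a.size < 2:
        return (math.nan, math.nan)
    res = stats.ttest_rel(a, b)
    return (float(res.statistic), float(res.pvalue))


def _sample_means(df: pd.DataFrame, value: str) -> pd.Series:
    return df.groupby("sample_id")[value].mean()


def maf_group_contrast(
    records,
    group_col: str,
    value_col: str = "dna_maf",
    balanced_only: bool = False,
) -> dict:
    """Contrast *value_col* between the two levels of a boolean/binary column.

    Record-level Welch t-test plus a sample-wise paired t-test on per-sample
    group means over samples containing both groups (complete pairs).  With
    ``balanced_only`` the records are first restricted to copy-number
    balanced loci.
    """
    df = _as_frame(records).dropna(subset=[value_col, group_col])
    if balanced_only:
        df = df[df["balanced"] == True]  # noqa: E712 — column may hold None
    levels = sorted(df[group_col].unique())
    if len(levels) != 2:
        raise ValueError(f"expected 2 levels of {group_col}, got {levels}")
    a = df.loc[df[group_col] == levels[0], value_col].to_numpy(float)
    b = df.loc[df[group_col] == levels[1], value_col].to_numpy(float)
    t, p = welch_t(a, b)
    means_a = _sample_means(df[df[group_col] == levels[0]], value_col)
    means_b = _sample_means(df[df[group_col] == levels[1]], value_col)
    common = means_a.index.intersection(means_b.index)
    if len(common) >= 2:
        pt, pp = paired_t(means_a.loc[common].to_numpy(), means_b.loc[common].to_numpy())
        paired_diff = float((means_a.loc[common] - means_b.loc[common]).mean())
    else:
        pt, pp, paired_diff = math.nan, math.nan, math.nan
    return {
        "levels": levels,
        "n": [int(a.size), int(b.size)],
        "means": [float(a.mean()) if a.size else math.nan,
                  float(b.mean()) if b.size else math.nan],
        "mean_difference": (float(a.mean() - b.mean()) if a.size and b.size else math.nan),
        "welch_t": t,
        "welch_p": p,
        "n_paired_samples": int(len(common)),
        "paired_mean_difference": paired_diff,
        "paired_t": pt,
        "paired_p": pp,
    }


# ---------------------------------------------------------------------------
# delta-MAF stratification


@dataclass(frozen=True)
class StratumSummary:
    """Mean delta-MAF of one mutation-type x gene-role stratum."""

    mutation_group: str
    cancer_critical: bool
    balance: str  # "all", "balanced" or "imbalanced"
    n: int
    mean_delta: float
    ci_low: float
    ci_high: float
    welch_p: float  # vs synonymous SNVs of the same role group
    paired_p: float  # sample-wise paired t vs synonymous, complete pairs


def _residualize_on_purity(df: pd.DataFrame, value: str) -> pd.Series:
    """Residuals of *value* after a linear fit on tumor purity."""
    sub = df.dropna(subset=[value, "purity"])
    out = df[value].copy()
    if len(sub) < 3 or sub["purity"].nunique() < 2:
        return out
    slope, intercept = np.polyfit(sub["purity"].astype(float), sub[value].astype(float), 1)
    fitted = intercept + slope * df["purity"].astype(float)
    return df[value] - (fitted - df[value].mean())


def stratified_delta(
    records,
    value_col: str = "delta_maf",
    balance: str = "all",
    min_n: int = MIN_STRATUM_N,
    purity_adjust: bool = False,
) -> list[StratumSummary]:
    """Mean delta-MAF per (mutation-type group x cancer-critical) stratum.

    Only records with a defined delta-MAF (expressed mutations of QC-passing
    samples) enter.  Each stratum is tested against synonymous SNVs of the
    same gene-role group (record-level Welch t and a sample-wise paired t on
    complete pairs).  ``balance`` restricts to copy-number balanced or
    imbalanced loci.  Strata below *min_n* are omitted.
    """
    df = _as_frame(records).dropna(subset=[value_col])
    if balance == "balanced":
        df = df[df["balanced"] == True]  # noqa: E712
    elif balance == "imbalanced":
        df = df[df["balanced"] == False]  # noqa: E712
    elif balance != "all":
        raise ValueError(f"balance must be all/balanced/imbalanced, got {balance!r}")
    if purity_adjust and len(df):
        df = df.assign(**{value_col: _residualize_on_purity(df, value_col)})
    df = df.assign(mutation_group=df["mutation_class"].map(mutation_group))

    out: list[StratumSummary] = []
    for critical in (True, False):
        role_df = df[df["cancer_critical"] == critical]
        ref = role_df[role_df["mutation_group"] == REFERENCE_GROUP]
        ref_values = ref[value_col].to_numpy(float)
        ref_sample_means = _sample_means(ref, value_col)
        for name in MUTATION_GROUPS:
            sub = role_df[role_df["mutation_group"] == name]
            if len(sub) < min_n:
                continue
            values = sub[value_col].to_numpy(float)
            ci = _mean_ci(values)
            if name == REFERENCE_GROUP:
                wp, pp = math.nan, math.nan
            else:
                _, wp = welch_t(values, ref_values)
                sm = _sample_means(sub, value_col)
                common = sm.index.intersection(ref_sample_means.index)
                if len(common) >= 2:
                    _, pp = paired_t(sm.loc[common].to_numpy(),
                                     ref_sample_means.loc[common].to_numpy())
                else:
                    pp = math.nan
            out.append(
                StratumSummary(
                    mutation_group=name, cancer_critical=critical, balance=balance,
                    n=int(len(sub)), mean_delta=float(values.mean()),
                    ci_low=ci[0], ci_high=ci[1], welch_p=wp, paired_p=pp,
                )
            )
    return out


def strata_to_frame(strata: Iterable[StratumSummary],
                    bh_correct: bool = False) -> pd.DataFrame:
    """Tabulate strata; optional Benjamini-Hochberg correction of Welch p."""
    df = pd.DataFrame([asdict(s) for s in strata])
    if bh_correct and len(df):
        from statsmodels.stats.multitest import multipletests

        mask = df["welch_p"].notna()
        adj = np.full(len(df), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                df.loc[mask, "welch_p"], method="fdr_bh"
            )[1]
        df["welch_p_bh"] = adj
    return df


# ---------------------------------------------------------------------------
# allelic imbalance enrichment


def balance_enrichment(records) -> dict:
    """Enrichment of allelic imbalance at cancer-critical loci.

    2x2 table of (cancer-critical vs other) x (imbalanced vs balanced) with
    the odds ratio and two-sided Fisher exact p.  A zero margin yields OR
    NaN; a zero cell yields an infinite or zero sample OR (noted), the exact
    p is still valid.
    """
    df = _as_frame(records).dropna(subset=["balanced"])
    cc = df["cancer_critical"].astype(bool)
    imb = ~df["balanced"].astype(bool)
    table = np.array(
        [
            [int((cc & imb).sum()), int((cc & ~imb).sum())],
            [int((~cc & imb).sum()), int((~cc & ~imb).sum())],
        ]
    )
    res = {"table": table.tolist()}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        res.update(odds_ratio=math.nan, fisher_p=math.nan, note="zero margin")
        return res
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    res.update(odds_ratio=float(odds), fisher_p=float(p))
    if (table == 0).any():
        res["note"] = "zero cell: sample odds ratio degenerate (Haldane continuity not applied)"
    return res


# ---------------------------------------------------------------------------
# drug sensitivity


def dose_drug_correlation(
    normalized_counts: Mapping[str, float],
    dss: Mapping[str, float],
) -> dict:
    """Spearman correlation of mutant-allele dose with drug-sensitivity score.

    Keys are model identifiers; only models present in both tables enter.
    Needs at least 3 shared models; a constant vector yields NaN.
    """
    common = sorted(set(normalized_counts) & set(dss))
    x = np.array([normalized_counts[m] for m in common], dtype=float)
    y = np.array([dss[m] for m in common], dtype=float)
    if len(common) < 3:
        return {"n": len(common), "rho": math.nan, "p": math.nan}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"n": len(common), "rho": math.nan, "p": math.nan}
    rho, p = stats.spearmanr(x, y)
    return {"n": len(common), "rho": float(rho), "p": float(p)}


def gene_drug_correlations(
    dose_table: pd.DataFrame, dss_table: pd.DataFrame
) -> pd.DataFrame:
    """Correlate every (gene, drug) pair.

    *dose_table* columns: model_id, gene, normalized_mut_count; *dss_table*
    columns: model_id, drug, dss.
    """
    rows = []
    for gene, gsub in dose_table.groupby("gene", sort=True):
        doses = dict(zip(gsub["model_id"], gsub["normalized_mut_count"]))
        for drug, dsub in dss_table.groupby("drug", sort=True):
            scores = dict(zip(dsub["model_id"], dsub["dss"]))
            res = dose_drug_correlation(doses, scores)
            rows.append({"gene": gene, "drug": drug, **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional (5' vs 3') contrast and double-mutation flags


def positional_contrast(
    records,
    relative_position: Mapping[tuple, float],
    breakpoint: float = 0.5,
    value_col: str = "delta_maf",
) -> dict:
    """Delta-MAF contrast between mutations 5' and 3' of a CDS breakpoint.

    *relative_position* maps record keys (sample, chrom, pos, ref, alt) to
    the mutation's relative coding-sequence position in [0, 1].
    """
    df = _as_frame(records).dropna(subset=[value_col])
    keys = list(zip(df["sample_id"], df["chrom"], df["pos"], df["ref_allele"], df["alt_allele"]))
    rel = np.array([relative_position.get(k, np.nan) for k in keys])
    df = df.assign(_rel=rel).dropna(subset=["_rel"])
    df = df.assign(_threeprime=df["_rel"] >= breakpoint)
    if df["_threeprime"].nunique() < 2:
        return {"n": [0, 0], "means": [math.nan, math.nan], "welch_p": math.nan}
    return maf_group_contrast(df, "_threeprime", value_col)


def double_mutation_flags(records) -> dict[tuple[str, str], bool]:
    """True for (sample, gene) pairs carrying more than one mutation."""
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.sample_id, rec.gene) if isinstance(rec, AseRecord) else (rec[0], rec[1])
        counts[key] = counts.get(key, 0) + 1
    return {key: n > 1 for key, n in counts.items()}
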