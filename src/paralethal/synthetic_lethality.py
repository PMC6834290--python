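"""Expression-stratified synthetic-lethality calling between paralogs.

For each focal gene A1 that is sometimes (but not broadly) essential in at
least 1% of cell lines, the expression of a paralog A2 is compared between
the lines where A1 is essential and the lines where it is not. A pair is a
putative synthetic-lethal (SL) when the BH q-value of the two-sided t test
falls under the FDR level *and* mean A2 expression is lower in the
A1-essential lines. Two modes define the test family: ``closest`` (each A1
against its most sequence-similar expressed paralog) and ``all`` (each A1
against every expressed paralog).

Follow-ups on flagged pairs ask whether the expression drop is mirrored in
A2 copy number (same stratified t test) or explained by A2 nonsense
mutations (one-sided Fisher enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_core import (
    ContingencyTable2x2,
    bh_fdr,
    fisher_exact_or,
    two_sample_t,
)

MIN_ESSENTIAL_FRACTION = 0.01


@dataclass
class SLTestResult:
    A1: str
    A2: str
    n_lines_A1_essential: int
    n_lines_A1_nonessential: int
    mean_expr_A2_essential: float
    mean_expr_A2_nonessential: float
    t: float
    p: float
    q: float = np.nan
    is_putative_SL: bool = False
    is_closest_pair: bool = False
    cn_p: float = np.nan
    cn_q: float = np.nan
    cn_driven: bool = False
    nonsense_p: float = np.nan
    nonsense_q: float = np.nan
    nonsense_driven: bool = False


def select_testable_pairs(
    gene_summaries: pd.DataFrame,
    pairs: pd.DataFrame,
    expressed_genes: set[str],
    mode: str = "closest",
) -> tuple[pd.DataFrame, int]:
    """Pairs (A1, A2) eligible for the SL expression test.

    A1 must be sometimes essential with fraction_essential >= 1%. In
    ``closest`` mode each A1 contributes the expressed partner with the
    highest identity of A1's sequence (ties: smallest symbol); in ``all``
    mode, every expressed partner. Returns the testable pairs and the count
    of qualifying A1 genes with no expressed paralog.
    """
    if mode not in ("closest", "all"):
        raise ValueError("mode must be 'closest' or 'all'")
    qualifying = gene_summaries[
        (gene_summaries["category"] == "sometimes")
        & (gene_summaries["fraction_essential"] >= MIN_ESSENTIAL_FRACTION)
    ]["gene"]
    fwd = pairs.rename(columns={"identity_A1_in_A2": "identity_A1"})[
        ["A1", "A2", "identity_A1"]
    ]
    rev = pairs.rename(
        columns={"A1": "A2", "A2": "A1", "identity_A2_in_A1": "identity_A1"}
    )[["A1", "A2", "identity_A1"]]
    directional = pd.concat([fwd, rev], ignore_index=True).drop_duplicates(
        ["A1", "A2"]
    )
    cand = directional[
        directional["A1"].isin(set(qualifying))
        & directional["A2"].isin(expressed_genes)
    ].copy()
    n_without = int(len(set(qualifying) - set(cand["A1"])))
    # mark the closest expressed partner for every A1
    cand = cand.sort_values(
        ["A1", "identity_A1", "A2"], ascending=[True, False, True], kind="mergesort"
    )
    cand["is_closest_pair"] = ~cand.duplicated("A1", keep="first")
    if mode == "closest":
        cand = cand[cand["is_closest_pair"]]
    return cand.reset_index(drop=True), n_without


def sl_expression_test(
    a1: str,
    a2: str,
    essentiality_row: pd.Series,
    expression_row: pd.Series,
    is_closest: bool = False,
) -> SLTestResult | None:
    """Stratified t test of A2 expression by A1 essentiality; None if a
    stratum has fewer than 2 usable lines."""
    lines = essentiality_row.dropna().index.intersection(
        expression_row.dropna().index
    )
    ess_lines = [l for l in lines if essentiality_row[l] == 1]
    non_lines = [l for l in lines if essentiality_row[l] == 0]
    if len(ess_lines) < 2 or len(non_lines) < 2:
        return None
    x = expression_row[ess_lines].to_numpy(dtype=float)
    y = expression_row[non_lines].to_numpy(dtype=float)
    res = two_sample_t(x, y)
    return SLTestResult(
        A1=a1,
        A2=a2,
        n_lines_A1_essential=len(ess_lines),
        n_lines_A1_nonessential=len(non_lines),
        mean_expr_A2_essential=float(x.mean()),
        mean_expr_A2_nonessential=float(y.mean()),
        t=res.statistic,
        p=res.p_value,
        is_closest_pair=is_closest,
    )


def call_sl(
    results: list[SLTestResult], fdr_level: float = 0.10
) -> pd.DataFrame:
    """BH-FDR over one mode's tests; flag q < level with the right direction."""
    if not results:
        raise ValueError("no testable pairs")
    df = pd.DataFrame([vars(r) for r in results])
    df["q"] = bh_fdr(df["p"].to_numpy())
    df["is_putative_SL"] = (df["q"] < fdr_level) & (
        df["mean_expr_A2_essential"] < df["mean_expr_A2_nonessential"]
    )
    return df


def cn_followup(
    calls: pd.DataFrame,
    copy_number: pd.DataFrame,
    binary: pd.DataFrame,
    p_cutoff: float = 0.05,
    fdr_level: float = 0.10,
) -> pd.DataFrame:
    """Stratified t test of A2 copy number for the flagged pairs.

    The BH family is the evaluable flagged pairs only. A pair is CN-driven
    when p < 0.05, q < 0.10 and A2 copy number is lower in the A1-essential
    lines.
    """
    out = calls.copy()
    flagged = out.index[out["is_putative_SL"]]
    stats = {}
    for i in flagged:
        a1, a2 = out.at[i, "A1"], out.at[i, "A2"]
        if a2 not in copy_number.index or a1 not in binary.index:
            continue
        res = sl_expression_test(a1, a2, binary.loc[a1], copy_number.loc[a2])
        if res is None:
            continue
        stats[i] = (res.p, res.mean_expr_A2_essential < res.mean_expr_A2_nonessential)
    if stats:
        idx = list(stats)
        ps = np.array([stats[i][0] for i in idx])
        qs = bh_fdr(ps)
        for i, p, q in zip(idx, ps, qs):
            out.at[i, "cn_p"] = p
            out.at[i, "cn_q"] = q
            out.at[i, "cn_driven"] = bool(
                p < p_cutoff and q < fdr_level and stats[i][1]
            )
    return out


def nonsense_followup(
    calls: pd.DataFrame,
    mutations: pd.DataFrame,
    binary: pd.DataFrame,
    p_cutoff: float = 0.05,
    fdr_level: float = 0.10,
) -> tuple[pd.DataFrame, int]:
    """Fisher enrichment of A2 nonsense mutations in A1-essential lines.

    Restricted to flagged pairs whose A2 carries a nonsense mutation in at
    least one line; returns the annotated table and the count of flagged
    pairs excluded for lack of any A2 nonsense mutation.
    """
    nonsense = mutations[
        mutations["Variant_Classification"] == "Nonsense_Mutation"
    ]
    mutated_lines = nonsense.groupby("gene")["cell_line"].apply(set)
    out = calls.copy()
    flagged = out.index[out["is_putative_SL"]]
    n_excluded = 0
    stats = {}
    for i in flagged:
        a1, a2 = out.at[i, "A1"], out.at[i, "A2"]
        mut = mutated_lines.get(a2, set())
        if not mut or a1 not in binary.index:
            n_excluded += 1
            continue
        row = binary.loc[a1].dropna()
        ess = set(row.index[row == 1])
        non = set(row.index[row == 0])
        table = ContingencyTable2x2(
            a=len(ess & mut), b=len(ess - mut),
            c=len(non & mut), d=len(non - mut),
        )
        res = fisher_exact_or(table, alternative="greater")
        stats[i] = res.p_value
    if stats:
        idx = list(stats)
        ps = np.array([stats[i] for i in idx])
        qs = bh_fdr(ps)
        for i, p, q in zip(idx, ps, qs):
            out.at[i, "nonsense_p"] = p
            out.at[i, "nonsense_q"] = q
            out.at[i, "nonsense_driven"] = bool(p < p_cutoff and q < fdr_level)
    return out, n_excluded


def _or_test(flags: pd.Series, group: pd.Series) -> dict:
    t = ContingencyTable2x2(
        a=int((flags & group).sum()),
        b=int((~flags & group).sum()),
        c=int((flags & ~group).sum()),
        d=int((~flags & ~group).sum()),
    )
    res = fisher_exact_or(t)
    return {"or": res.statistic, "p": res.p_value,
            "rate_in_group": t.a / (t.a + t.b) if t.a + t.b else np.nan,
            "rate_out_group": t.c / (t.c + t.d) if t.c + t.d else np.nan}


def sl_enrichment(annotated_calls: pd.DataFrame) -> dict:
    """Fisher/t battery relating SL flags to pair annotations.

    Requires columns is_putative_SL, duplication_mode, either_in_complex,
    same_complex, and the two directional identities. The pair identity used
    for the t comparisons is the mean of the two directions.
    """
    df = annotated_calls.copy()
    sl = df["is_putative_SL"].astype(bool)
    wgd = df["duplication_mode"] == "WGD"
    either = df["either_in_complex"].astype(bool)
    same = df["same_complex"].astype(bool)
    report = {
        "sl_vs_wgd": _or_test(sl, wgd),
        "sl_vs_either_in_complex": _or_test(sl, either),
        "sl_vs_same_complex": _or_test(sl, same),
    }
    in_complex = df[either]
    if len(in_complex) and in_complex["is_putative_SL"].nunique() >= 1:
        report["wgd_within_complex_pairs"] = _or_test(
            in_complex["is_putative_SL"].astype(bool),
            in_complex["duplication_mode"] == "WGD",
        )
    wgd_pairs = df[wgd]
    if len(wgd_pairs):
        report["complex_within_wgd_pairs"] = _or_test(
            wgd_pairs["is_putative_SL"].astype(bool),
            wgd_pairs["either_in_complex"].astype(bool),
        )
    df["pair_identity"] = (
        df["identity_A1_in_A2"] + df["identity_A2_in_A1"]
    ) / 2.0
    identity = {}
    subsets = {
        "overall": pd.Series(True, index=df.index),
        "wgd": wgd,
        "ssd": ~wgd,
        "either_in_complex": either,
    }
    for name, mask in subsets.items():
        x = df.loc[mask & sl, "pair_identity"].to_numpy()
        y = df.loc[mask & ~sl, "pair_identity"].to_numpy()
        if len(x) >= 2 and len(y) >= 2:
            res = two_sample_t(x, y)
            identity[name] = {
                "t": res.statistic, "p": res.p_value,
                "mean_sl": float(x.mean()), "mean_non_sl": float(y.mean()),
            }
    report["identity_comparisons"] = identity
    report["identity_convention"] = "mean of the two directional identities"
    return report
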