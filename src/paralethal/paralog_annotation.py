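"""Paralog-pair filtering, per-gene paralogy summaries and pair annotation.

The pair table is directional: each unordered pair appears once per
direction with the two bidirectional protein-sequence identities swapped.
Pairs are kept when both identities are >= 20% and both genes are
protein-coding. A gene's "closest" paralog is the partner in which the
largest percent of the gene's own protein sequence is matched (ties broken
by the lexicographically smallest partner symbol) — this directional
convention is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLOSEST_CONVENTION = "identity of focal gene's sequence matched in partner"


def expand_directional(pairs: pd.DataFrame) -> pd.DataFrame:
    """One row per direction: (A1,A2) plus (A2,A1) with identities swapped."""
    fwd = pairs.copy()
    rev = pairs.rename(
        columns={
            "A1": "A2", "A2": "A1",
            "identity_A1_in_A2": "identity_A2_in_A1",
            "identity_A2_in_A1": "identity_A1_in_A2",
        }
    )
    both = pd.concat([fwd, rev], ignore_index=True)
    return both[fwd.columns.tolist()].sort_values(["A1", "A2"]).reset_index(drop=True)


def filter_paralog_pairs(
    raw_pairs: pd.DataFrame,
    coding_genes: set[str],
    min_identity: float = 20.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep pairs with both identities >= min_identity and both genes coding.

    Returns the filtered table and per-rule removal counts.
    """
    df = raw_pairs.copy()
    removed = {}
    missing = df["identity_A1_in_A2"].isna() | df["identity_A2_in_A1"].isna()
    removed["missing identity"] = int(missing.sum())
    df = df[~missing]
    low = (
        (df["identity_A1_in_A2"] < min_identity)
        | (df["identity_A2_in_A1"] < min_identity)
    )
    removed["below identity floor"] = int(low.sum())
    df = df[~low]
    noncoding = ~(df["A1"].isin(coding_genes) & df["A2"].isin(coding_genes))
    removed["non-coding gene"] = int(noncoding.sum())
    df = df[~noncoding]
    return df.reset_index(drop=True), removed


@dataclass
class GeneParalogySummary:
    gene: str
    n_paralogs: int
    closest_paralog: str | None
    max_identity: float | None
    is_singleton: bool
    duplication_mode: str  # WGD / SSD / none


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def summarize_paralogy(
    gene: str, pairs: pd.DataFrame, gene_modes: dict[str, str] | None = None
) -> GeneParalogySummary:
    """Summary for one gene from the filtered (unordered-row) pair table."""
    fwd = pairs[pairs["A1"] == gene][["A2", "identity_A1_in_A2"]].rename(
        columns={"A2": "partner", "identity_A1_in_A2": "identity"}
    )
    rev = pairs[pairs["A2"] == gene][["A1", "identity_A2_in_A1"]].rename(
        columns={"A1": "partner", "identity_A2_in_A1": "identity"}
    )
    partners = pd.concat([fwd, rev], ignore_index=True).drop_duplicates("partner")
    if partners.empty:
        return GeneParalogySummary(gene, 0, None, None, True, "none")
    # max identity of the focal gene's sequence in any partner; ties -> smallest symbol
    partners = partners.sort_values(
        ["identity", "partner"], ascending=[False, True], kind="mergesort"
    )
    best = partners.iloc[0]
    mode = (gene_modes or {}).get(gene, "none")
    return GeneParalogySummary(
        gene=gene,
        n_paralogs=len(partners),
        closest_paralog=str(best["partner"]),
        max_identity=float(best["identity"]),
        is_singleton=False,
        duplication_mode=mode,
    )


def summarize_all_genes(
    universe: list[str], pairs: pd.DataFrame, gene_modes: dict[str, str] | None = None
) -> pd.DataFrame:
    rows = [summarize_paralogy(g, pairs, gene_modes) for g in universe]
    df = pd.DataFrame([vars(r) for r in rows])
    df["paralog_bin"] = np.where(
        df["n_paralogs"] >= 4, "4+", df["n_paralogs"].astype(str)
    )
    return df


def classify_duplication(
    pairs: pd.DataFrame,
    wgd_list_a: list[tuple[str, str]],
    wgd_list_b: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """WGD/SSD labels per pair, and per gene.

    A pair is WGD if its unordered symbols appear on either input list; a
    gene is WGD if it belongs to any WGD pair, regardless of also belonging
    to SSD pairs.
    """
    wgd_set = {_pair_key(*p) for p in wgd_list_a}
    if wgd_list_b:
        wgd_set |= {_pair_key(*p) for p in wgd_list_b}
    out = pairs.copy()
    out["duplication_mode"] = [
        "WGD" if _pair_key(a, b) in wgd_set else "SSD"
        for a, b in zip(out["A1"], out["A2"])
    ]
    gene_modes: dict[str, str] = {}
    for row in out.itertuples():
        for g in (row.A1, row.A2):
            if row.duplication_mode == "WGD":
                gene_modes[g] = "WGD"
            else:
                gene_modes.setdefault(g, "SSD")
    return out, gene_modes


def annotate_complexes(
    pairs: pd.DataFrame, complexes: pd.DataFrame
) -> pd.DataFrame:
    """Flag pairs by protein-complex membership of their genes."""
    members_by_complex = complexes.groupby("complex_id")["gene"].apply(set)
    complexes_by_gene: dict[str, set[str]] = {}
    for cid, members in members_by_complex.items():
        for g in members:
            complexes_by_gene.setdefault(g, set()).add(cid)
    out = pairs.copy()
    either, same = [], []
    for a, b in zip(out["A1"], out["A2"]):
        ca = complexes_by_gene.get(a, set())
        cb = complexes_by_gene.get(b, set())
        either.append(bool(ca or cb))
        same.append(bool(ca & cb))
    out["either_in_complex"] = either
    out["same_complex"] = same
    return out
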