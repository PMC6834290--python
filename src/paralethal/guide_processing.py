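"""sgRNA multi-target detection, library filtering and gene-level scoring.

Alignment is exhaustive: every 20-nt window at every offset on both strands
is compared against the protospacer, keeping hits with at most two
mismatches whose adjacent PAM (the 3 nt immediately 3' of the protospacer
on the hit strand) matches NGG. On toy genomes this is tractable and serves
as its own specification — there is no index to disagree with.

Mismatch positions are indexed 1..20 from the PAM-distal end, so "the two
most PAM-distal nucleotides" are positions {1, 2}. A guide is flagged
multi-targeting if it has (a) two or more perfect hits, (b) a perfect hit
plus any one-mismatch hit, or (c) a perfect hit plus a two-mismatch hit
whose mismatches both sit at positions {1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGT", "TGCA")

DROP_MULTI = "multi-target"
DROP_UNALIGNABLE = "unalignable"
DROP_NO_PERFECT = "no perfect hit"
DROP_MULTI_GENE = "multi-gene locus"
DROP_INTERGENIC = "intergenic"


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    protospacer: str
    intended_gene: str = ""

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20 or set(self.protospacer) - set("ACGT"):
            raise ValueError(
                f"{self.guide_id}: protospacer must be a 20-nt ACGT string"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic occurrence of a protospacer (forward-strand coordinates)."""

    chromosome: str
    strand: str
    start: int
    end: int
    n_mismatches: int
    mismatch_positions: frozenset[int]
    pam: str
    pam_canonical: bool

    def __post_init__(self) -> None:
        assert self.end - self.start == 20
        assert self.n_mismatches == len(self.mismatch_positions)
        assert self.mismatch_positions <= frozenset(range(1, 21))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_guide(
    protospacer: str,
    genome: Mapping[str, str],
    max_mismatches: int = 2,
) -> list[AlignmentHit]:
    """Every <=2-mismatch, NGG-PAM genomic occurrence of a protospacer.

    Hits whose PAM window would run past the contig end are discarded, as
    are hits with a non-NGG PAM ("N" matches any base). Coordinates are
    0-based half-open on the forward strand.
    """
    if len(protospacer) != 20 or set(protospacer) - set("ACGT"):
        raise ValueError("protospacer must be a 20-nt ACGT string")
    guide_fwd = _encode(protospacer)
    guide_rev = _encode(_revcomp(protospacer))
    hits: list[AlignmentHit] = []
    for chrom, seq in genome.items():
        enc = _encode(seq)
        L = len(enc)
        if L < 20:
            continue
        n_win = L - 19
        # mismatch count per window, per strand, via 20 shifted comparisons
        mm_fwd = np.zeros(n_win, dtype=np.int16)
        mm_rev = np.zeros(n_win, dtype=np.int16)
        for k in range(20):
            col = enc[k:k + n_win]
            mm_fwd += col != guide_fwd[k]
            mm_rev += col != guide_rev[k]
        for strand, mm, genc in (("+", mm_fwd, guide_fwd), ("-", mm_rev, guide_rev)):
            for start in np.nonzero(mm <= max_mismatches)[0]:
                start = int(start)
                end = start + 20
                if strand == "+":
                    if end + 3 > L:
                        continue  # PAM window off the contig end
                    pam = seq[end:end + 3]
                    window = seq[start:end]
                    mism = {
                        i + 1
                        for i in range(20)
                        if window[i] != protospacer[i]
                    }
                else:
                    if start - 3 < 0:
                        continue
                    pam = _revcomp(seq[start - 3:start])
                    window = _revcomp(seq[start:end])
                    mism = {
                        i + 1
                        for i in range(20)
                        if window[i] != protospacer[i]
                    }
                canonical = pam[1:3] == "GG"
                if not canonical:
                    continue
                hits.append(
                    AlignmentHit(
                        chromosome=chrom,
                        strand=strand,
                        start=start,
                        end=end,
                        n_mismatches=len(mism),
                        mismatch_positions=frozenset(mism),
                        pam=pam,
                        pam_canonical=True,
                    )
                )
    return hits


def classify_multi_targeting(hits: Sequence[AlignmentHit]) -> tuple[bool, str]:
    """Apply the three multi-target rules to a guide's canonical-PAM hits."""
    if not hits:
        return False, DROP_UNALIGNABLE
    perfect = [h for h in hits if h.n_mismatches == 0]
    one_mm = [h for h in hits if h.n_mismatches == 1]
    two_mm_distal = [
        h
        for h in hits
        if h.n_mismatches == 2 and h.mismatch_positions <= {1, 2}
    ]
    if len(perfect) >= 2:
        return True, "multiple perfect"
    if perfect and one_mm:
        return True, "single mismatch"
    if perfect and two_mm_distal:
        return True, "double mismatch PAM-distal"
    return False, ""


@dataclass
class GuideGeneMap:
    """Per-guide verdicts: retained guides map to exactly one gene."""

    table: pd.DataFrame  # columns: sgRNA, gene, retained, reason

    def retained(self) -> pd.DataFrame:
        return self.table[self.table["retained"]]

    def genes_per_guide(self) -> Mapping[str, str]:
        r = self.retained()
        return dict(zip(r["sgRNA"], r["gene"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _overlapping_genes(hit: AlignmentHit, genes: pd.DataFrame) -> list[str]:
    sel = (
        (genes["chrom"] == hit.chromosome)
        & (genes["start"] < hit.end)
        & (genes["end"] > hit.start)
    )
    return sorted(genes.loc[sel, "name"])


def build_guide_gene_map(
    guides: pd.DataFrame,
    hit_lists: Mapping[str, Sequence[AlignmentHit]],
    genes: pd.DataFrame,
) -> GuideGeneMap:
    """Assign each guide to a gene, or a drop reason.

    Guides flagged multi-targeting are dropped; so are guides with no
    perfect hit, guides whose single locus overlaps zero genes, and guides
    whose locus overlaps two or more genes (read-through-style loci).
    """
    rows = []
    for rec in guides.itertuples():
        hits = list(hit_lists.get(rec.guide_id, []))
        is_multi, reason = classify_multi_targeting(hits)
        if not hits:
            rows.append((rec.guide_id, "", False, DROP_UNALIGNABLE))
            continue
        if is_multi:
            rows.append((rec.guide_id, "", False, DROP_MULTI))
            continue
        perfect = [h for h in hits if h.n_mismatches == 0]
        if not perfect:
            rows.append((rec.guide_id, "", False, DROP_NO_PERFECT))
            continue
        overlapping = _overlapping_genes(perfect[0], genes)
        if len(overlapping) == 0:
            rows.append((rec.guide_id, "", False, DROP_INTERGENIC))
        elif len(overlapping) > 1:
            rows.append((rec.guide_id, "", False, DROP_MULTI_GENE))
        else:
            rows.append((rec.guide_id, overlapping[0], True, ""))
    return GuideGeneMap(
        pd.DataFrame(rows, columns=["sgRNA", "gene", "retained", "reason"])
    )


def gate_genes_by_guide_count(
    guide_map: GuideGeneMap, min_guides: int = 3
) -> tuple[list[str], pd.DataFrame]:
    """Split genes into scorable and dropped by retained-guide count."""
    counts = guide_map.retained().groupby("gene").size()
    all_genes = guide_map.table.loc[guide_map.table["gene"] != "", "gene"].unique()
    retained = sorted(counts.index[counts >= min_guides])
    dropped_rows = [
        {"gene": g, "n_guides": int(counts.get(g, 0)),
         "reason": "no guides" if counts.get(g, 0) == 0 else "too few guides"}
        for g in sorted(set(all_genes) - set(retained))
    ]
    return retained, pd.DataFrame(dropped_rows, columns=["gene", "n_guides", "reason"])


def score_genes(
    lfc: pd.DataFrame,
    guide_map: GuideGeneMap,
    retained_genes: Iterable[str],
    min_guides: int = 3,
) -> pd.DataFrame:
    """Simplified guide-aggregation scorer: per-line mean of retained guides.

    This is deliberately *not* a CERES re-implementation — no copy-number
    correction or guide-efficacy modelling — just the arithmetic mean of a
    gene's retained guides' log-fold changes in each line. A gene's score in
    a line is missing if fewer than ``min_guides`` of its guides have an LFC
    there.
    """
    retained_genes = list(retained_genes)
    mapping = guide_map.retained()
    mapping = mapping[mapping["gene"].isin(retained_genes)]
    present = mapping[mapping["sgRNA"].isin(lfc.index)]
    sub = lfc.loc[present["sgRNA"]]
    sub.index = present["gene"].to_numpy()
    scores = sub.groupby(level=0).mean()
    informative = sub.notna().groupby(level=0).sum()
    scores = scores.where(informative >= min_guides)
    return scores.reindex(retained_genes)


def precision_recall_qc(
    scores: pd.DataFrame,
    essential_ref: set[str],
    nonessential_ref: set[str],
) -> tuple[pd.Series, float]:
    """Per-line average precision for recovering reference essential genes.

    Genes are restricted to the labelled reference sets present in the score
    matrix and ranked by ascending score (most negative first); the AUC is
    the average of precision-at-rank over the positive (essential) genes.
    """
    if essential_ref & nonessential_ref:
        raise ValueError("reference sets must be disjoint")
    labelled = (essential_ref | nonessential_ref) & set(scores.index)
    pos = essential_ref & labelled
    if not pos or not (nonessential_ref & labelled):
        raise ValueError("reference sets do not intersect the scored genes")
    per_line = {}
    for line in scores.columns:
        col = scores.loc[sorted(labelled), line].dropna()
        ranked = col.sort_values(kind="mergesort").index
        hits = 0
        precisions = []
        for rank, gene in enumerate(ranked, start=1):
            if gene in pos:
                hits += 1
                precisions.append(hits / rank)
        per_line[line] = float(np.mean(precisions)) if precisions else np.nan
    series = pd.Series(per_line, name="auc")
    return series, float(series.mean())
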