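"""Synthetic fixture cohort with planted ground truth.

Generates an internally consistent bundle — toy genome with planted gene
duplications, an sgRNA library, screen log-fold changes, expression, copy
number, nonsense-mutation calls, and paralog/WGD/complex annotations — so
that every downstream analysis stage can be exercised and audited without
external downloads.

Model, in brief. Every gene carries a latent per-cell-line fitness state:

* ``never`` genes are tolerated in every line;
* ``broadly`` genes are essential in every line;
* ``sometimes`` genes are essential in an exact per-gene fraction
  f ~ U(0.05, 0.6) of lines and cause a moderate fitness defect elsewhere;
* a planted synthetic-lethal A1 is essential exactly in the lines where its
  partner A2 sits in its low-expression state, and tolerated elsewhere.

The observed score of a gene in a line is a draw from the Gaussian component
matching its state (defaults N(-1, 0.2^2) / N(-0.5, 0.15^2) / N(0, 0.15^2)),
and a guide's log-fold change adds i.i.d. guide noise on top. Expression is
generated on a log2(TPM+1)-like scale as Gaussian high/low states; planted
A2 genes are bimodal across lines. Copy number is flat except for the
configured fraction of planted pairs whose A2 loses copies in exactly the
low-expression lines.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))

CATEGORY_NEVER = "never"
CATEGORY_SOMETIMES = "sometimes"
CATEGORY_BROADLY = "broadly"


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class GenomeConfig:
    """Layout of the toy genome."""

    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_genes: int = 40
    gene_length: int = 1_000
    n_duplicate_pairs: int = 4
    duplication_mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_chromosomes < 2 or self.chromosome_length < 20_000:
            raise ValueError("need >=2 chromosomes of >=20 kb")
        if not 0.0 <= self.duplication_mutation_rate <= 1.0:
            raise ValueError("mutation rate must be in [0, 1]")
        if 2 * self.n_duplicate_pairs > self.n_genes:
            raise ValueError("too many duplicate pairs for the gene count")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the composition of the real screen panel: ~61% of genes
    have a paralog, ~64% of paralog pairs arise from whole-genome
    duplication, and the never/sometimes/broadly split is 48/46/6.
    """

    n_cell_lines: int = 60
    n_genes: int = 600
    frac_paralog: float = 0.61
    family_size_weights: tuple[tuple[int, float], ...] = (
        (2, 0.70), (3, 0.15), (4, 0.10), (5, 0.05),
    )
    frac_wgd_pairs: float = 0.64
    frac_never: float = 0.48
    frac_sometimes: float = 0.46
    frac_broadly: float = 0.06
    n_planted_sl_pairs: int = 40
    essential_mean: float = -1.0
    essential_sd: float = 0.2
    moderate_mean: float = -0.5
    moderate_sd: float = 0.15
    tolerated_mean: float = 0.0
    tolerated_sd: float = 0.15
    expr_high_mean: float = 6.0
    expr_low_mean: float = 3.0
    expr_sd: float = 1.0
    frac_low_expression_lines: float = 0.30
    frac_sl_cn_driven: float = 0.5
    nonsense_rate: float = 0.002
    plant_nonsense_pair: bool = False
    sl_wgd_odds_ratio: float = 2.3
    complex_wgd_odds_ratio: float = 2.3
    frac_unexpressed_genes: float = 0.0
    guide_noise_sd: float = 0.1
    guides_per_gene: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_paralog": self.frac_paralog,
            "frac_wgd_pairs": self.frac_wgd_pairs,
            "frac_never": self.frac_never,
            "frac_sometimes": self.frac_sometimes,
            "frac_broadly": self.frac_broadly,
            "frac_low_expression_lines": self.frac_low_expression_lines,
            "frac_sl_cn_driven": self.frac_sl_cn_driven,
            "frac_unexpressed_genes": self.frac_unexpressed_genes,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        total = self.frac_never + self.frac_sometimes + self.frac_broadly
        if abs(total - 1.0) > 1e-9:
            raise ValueError("category fractions must sum to 1")
        if self.frac_sometimes <= 0:
            raise ValueError("frac_sometimes must be positive")
        if not self.essential_mean < self.moderate_mean < self.tolerated_mean:
            raise ValueError("component means must be ordered essential < moderate < tolerated")
        if abs(sum(w for _, w in self.family_size_weights) - 1.0) > 1e-9:
            raise ValueError("family size weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth for auditing downstream stages."""

    categories: dict[str, str]
    sl_pairs: list[tuple[str, str]]
    cn_driven: dict[str, bool]  # keyed "A1|A2"
    low_lines: dict[str, list[str]]  # keyed "A1|A2"
    multi_target_guides: list[str]
    mixture_means: list[float]
    mixture_sds: list[float]
    mixture_weights: list[float]  # realized state occupancy (essential, moderate, tolerated)
    true_scores: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k != "true_scores"
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, sharing gene/line indices."""

    lfc: pd.DataFrame                # guides x lines
    guide_map: pd.DataFrame          # sgRNA, gene
    expression: pd.DataFrame         # genes x lines (some genes may be absent)
    copy_number: pd.DataFrame        # genes x lines
    mutations: pd.DataFrame          # long: gene, cell_line, Variant_Classification
    paralogs: pd.DataFrame           # A1, A2, identity_A1_in_A2, identity_A2_in_A1, wgd_flag
    complexes: pd.DataFrame          # complex_id, gene
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.lfc.to_csv(outdir / "logfold_change.csv")
        self.guide_map.to_csv(outdir / "guide_gene_map.csv", index=False)
        self.expression.to_csv(outdir / "expression.csv")
        self.copy_number.to_csv(outdir / "copy_number.csv")
        self.mutations.to_csv(outdir / "mutations.csv", index=False)
        self.paralogs.to_csv(outdir / "paralogs.csv", index=False)
        self.complexes.to_csv(outdir / "complexes.csv", index=False)
        self.truth.to_json(outdir / "ground_truth.json")


# ---------------------------------------------------------------------------
# toy genome


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_toy_genome(
    config: GenomeConfig, seed: int
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Random-base chromosomes with non-overlapping genes and planted duplications.

    Returns the genome as ``{chromosome: sequence}``, a BED-style gene table
    (0-based half-open), and a duplication map listing which gene's sequence
    was copied (with per-base mutations) into which other gene.
    """
    rng = np.random.default_rng(seed)
    chroms = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=config.chromosome_length))
        for i in range(config.n_chromosomes)
    }

    # spread genes across chromosomes; error out if they cannot be placed
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chromosomes)
    min_gap = 50
    records = []
    for chrom, idx in zip(chroms, per_chrom):
        needed = len(idx) * (config.gene_length + min_gap)
        if needed > config.chromosome_length:
            raise ValueError(
                f"{len(idx)} genes of {config.gene_length} bp do not fit on "
                f"{chrom} ({config.chromosome_length} bp)"
            )
        slack = config.chromosome_length - needed
        gaps = rng.multinomial(slack, np.ones(len(idx) + 1) / (len(idx) + 1))
        pos = 0
        for k, g in enumerate(idx):
            pos += gaps[k] + min_gap
            records.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + config.gene_length,
                    "name": f"G{g + 1:04d}",
                    "score": 0,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
            pos += config.gene_length
    genes = pd.DataFrame(records)

    # plant duplications: copy one gene's sequence into another, mutated
    order = rng.permutation(config.n_genes)
    dup_rows = []
    arrays = {c: np.array(list(s)) for c, s in chroms.items()}
    for k in range(config.n_duplicate_pairs):
        src = genes.iloc[order[2 * k]]
        dst = genes.iloc[order[2 * k + 1]]
        src_seq = arrays[src.chrom][src.start:src.end].copy()
        mutate = rng.random(len(src_seq)) < config.duplication_mutation_rate
        if mutate.any():
            # substitute with a uniformly different base
            shift = rng.integers(1, 4, size=int(mutate.sum()))
            codes = np.searchsorted(BASES, src_seq[mutate])
            src_seq[mutate] = BASES[(codes + shift) % 4]
        if src.strand != dst.strand:
            src_seq = np.array(list(_revcomp("".join(src_seq))))
        arrays[dst.chrom][dst.start:dst.end] = src_seq
        dup_rows.append(
            {
                "source_gene": src["name"],
                "target_gene": dst["name"],
                "mutation_rate": config.duplication_mutation_rate,
            }
        )
    genome = {c: "".join(a) for c, a in arrays.items()}
    duplication_map = pd.DataFrame(
        dup_rows, columns=["source_gene", "target_gene", "mutation_rate"]
    )
    return genome, genes, duplication_map


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(genes: pd.DataFrame, path: str | Path) -> None:
    genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# guide library


def generate_guide_library(
    genome: dict[str, str],
    genes: pd.DataFrame,
    guides_per_gene: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Pick NGG-adjacent 20-mers inside each gene on its annotated strand.

    Returns the guide table (guide_id, protospacer, intended_gene) and a list
    of warnings for genes with fewer usable PAM sites than requested.
    """
    rng = np.random.default_rng(seed)
    rows = []
    warnings: list[str] = []
    for rec in genes.itertuples():
        seq = genome[rec.chrom][rec.start:rec.end]
        if rec.strand == "-":
            seq = _revcomp(seq)
        candidates = [
            i
            for i in range(len(seq) - 22)
            if seq[i + 21] == "G" and seq[i + 22] == "G"
        ]
        if len(candidates) < guides_per_gene:
            warnings.append(
                f"{rec.name}: only {len(candidates)} PAM sites for "
                f"{guides_per_gene} requested guides"
            )
        chosen = sorted(
            rng.choice(candidates, size=min(guides_per_gene, len(candidates)),
                       replace=False)
        ) if candidates else []
        for j, pos in enumerate(chosen):
            rows.append(
                {
                    "guide_id": f"{rec.name}_sg{j + 1}",
                    "protospacer": seq[pos:pos + 20],
                    "intended_gene": rec.name,
                }
            )
    return pd.DataFrame(rows, columns=["guide_id", "protospacer", "intended_gene"]), warnings


def _true_multi_target_flags(
    guides: pd.DataFrame, genome: dict[str, str]
) -> list[str]:
    """Guides whose protospacer occurs perfectly at >=2 NGG-adjacent loci.

    Plain string search on both strands — deliberately independent of the
    alignment module, so it can serve as planted truth for its tests.
    """
    flagged = []
    for row in guides.itertuples():
        count = 0
        for seq in genome.values():
            for s in (seq, _revcomp(seq)):
                start = 0
                while True:
                    i = s.find(row.protospacer, start)
                    if i < 0:
                        break
                    if i + 22 < len(s) and s[i + 21:i + 23] == "GG":
                        count += 1
                    start = i + 1
        if count >= 2:
            flagged.append(row.guide_id)
    return flagged


# ---------------------------------------------------------------------------
# cohort


def _partition_families(n_paralog_genes: int, weights, rng) -> list[int]:
    sizes, probs = zip(*weights)
    out = []
    remaining = n_paralog_genes
    while remaining >= 2:
        s = int(rng.choice(sizes, p=probs))
        s = min(s, remaining)
        if s < 2:
            break
        out.append(s)
        remaining -= s
    return out


def _weighted_or_probability(base_p: float, odds_ratio: float) -> float:
    """Probability whose odds are ``odds_ratio`` times those of ``base_p``."""
    odds = base_p / (1 - base_p) * odds_ratio
    return odds / (1 + odds)


def _stratified_sl_indices(
    pairs: pd.DataFrame,
    eligible: np.ndarray,
    n_planted: int,
    wgd_odds_ratio: float,
    rng,
) -> np.ndarray:
    """Choose planted SL pairs so that P(SL|WGD) vs P(SL|SSD) realizes the
    configured odds ratio as closely as integer counts allow."""
    if n_planted == 0:
        return np.array([], dtype=int)
    wgd_mask = pairs.loc[eligible, "wgd_flag"].to_numpy()
    wgd_idx = eligible[wgd_mask]
    ssd_idx = eligible[~wgd_mask]
    if len(wgd_idx) == 0 or len(ssd_idx) == 0:
        return rng.choice(eligible, size=n_planted, replace=False)

    def planted_total(p_ssd: float) -> float:
        odds = p_ssd / (1 - p_ssd) * wgd_odds_ratio
        p_wgd = odds / (1 + odds)
        return len(wgd_idx) * p_wgd + len(ssd_idx) * p_ssd

    lo, hi = 1e-9, 1 - 1e-9
    for _ in range(200):
        mid = (lo + hi) / 2
        if planted_total(mid) < n_planted:
            lo = mid
        else:
            hi = mid
    p_ssd = (lo + hi) / 2
    odds = p_ssd / (1 - p_ssd) * wgd_odds_ratio
    p_wgd = odds / (1 + odds)
    n_wgd = min(int(round(len(wgd_idx) * p_wgd)), len(wgd_idx), n_planted)
    n_ssd = min(n_planted - n_wgd, len(ssd_idx))
    n_wgd = n_planted - n_ssd
    return np.concatenate([
        rng.choice(wgd_idx, size=n_wgd, replace=False),
        rng.choice(ssd_idx, size=n_ssd, replace=False),
    ])


def generate_cohort(
    config: CohortConfig,
    guide_table: pd.DataFrame | None = None,
    genome: dict[str, str] | None = None,
) -> CohortBundle:
    """Generate every table of the synthetic cohort plus its ground truth.

    ``guide_table`` (guide_id, protospacer, intended_gene) may come from
    :func:`generate_guide_library`; if omitted, a sequence-free library of
    ``guides_per_gene`` guides per gene is fabricated so the screen tables
    can be produced without a genome.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    lines = [f"CL{j + 1:03d}" for j in range(config.n_cell_lines)]
    n_lines = config.n_cell_lines

    # ---- paralog families and pairs
    n_paralog = int(round(config.frac_paralog * config.n_genes))
    paralog_genes = list(rng.choice(genes, size=n_paralog, replace=False))
    family_sizes = _partition_families(len(paralog_genes), config.family_size_weights, rng)
    families: list[list[str]] = []
    cursor = 0
    for s in family_sizes:
        families.append(paralog_genes[cursor:cursor + s])
        cursor += s
    paralog_genes = paralog_genes[:cursor]  # genes actually placed in a family

    pair_rows = []
    for fam in families:
        for g1, g2 in itertools.combinations(sorted(fam), 2):
            pair_rows.append({"A1": g1, "A2": g2})
    pairs = pd.DataFrame(pair_rows, columns=["A1", "A2"])
    pairs["wgd_flag"] = rng.random(len(pairs)) < config.frac_wgd_pairs

    # ---- plant SL pairs in size-2 families, biased toward WGD pairs
    two_gene_families = {tuple(sorted(f)) for f in families if len(f) == 2}
    eligible = pairs.index[
        pairs.apply(lambda r: (r.A1, r.A2) in two_gene_families, axis=1)
    ].to_numpy() if len(pairs) else np.array([], dtype=int)
    if config.n_planted_sl_pairs > len(eligible):
        raise ValueError(
            f"cannot plant {config.n_planted_sl_pairs} SL pairs: only "
            f"{len(eligible)} two-gene families available"
        )
    sl_idx = _stratified_sl_indices(
        pairs, eligible, config.n_planted_sl_pairs,
        config.sl_wgd_odds_ratio, rng,
    )
    sl_pairs = [(pairs.at[i, "A1"], pairs.at[i, "A2"]) for i in sl_idx]
    # orient each pair: A1 is the sometimes-essential focal gene
    sl_pairs = [
        (a, b) if rng.random() < 0.5 else (b, a) for a, b in sl_pairs
    ]

    # ---- identities: uniform [20,100], planted SL pairs [60,100]
    sl_unordered = {frozenset(p) for p in sl_pairs}
    lo = np.where(
        pairs.apply(lambda r: frozenset((r.A1, r.A2)) in sl_unordered, axis=1)
        if len(pairs) else np.array([], dtype=bool),
        60.0, 20.0,
    )
    pairs["identity_A1_in_A2"] = np.round(rng.uniform(lo, 100.0), 2)
    pairs["identity_A2_in_A1"] = np.round(rng.uniform(lo, 100.0), 2)

    # ---- essentiality categories
    sl_a1 = [a for a, _ in sl_pairs]
    sl_a2 = [b for _, b in sl_pairs]
    n_broadly = int(round(config.frac_broadly * config.n_genes))
    n_never = int(round(config.frac_never * config.n_genes))
    n_sometimes = config.n_genes - n_broadly - n_never
    if len(sl_a1) > n_sometimes:
        raise ValueError("more planted SL A1 genes than the sometimes quota")
    categories = {}
    for g in sl_a1:
        categories[g] = CATEGORY_SOMETIMES
    for g in sl_a2:
        categories[g] = CATEGORY_NEVER
    pool = [g for g in genes if g not in categories]
    rng.shuffle(pool)
    quota = {
        CATEGORY_SOMETIMES: n_sometimes - len(sl_a1),
        CATEGORY_NEVER: max(n_never - len(sl_a2), 0),
        CATEGORY_BROADLY: n_broadly,
    }
    it = iter(pool)
    for cat, n_cat in quota.items():
        for _ in range(n_cat):
            try:
                categories[next(it)] = cat
            except StopIteration:
                break
    for g in it:  # remainder (rounding slack) -> never
        categories[g] = CATEGORY_NEVER

    # ---- latent per-line essential state
    essential_state = pd.DataFrame(False, index=genes, columns=lines)
    n_low = max(int(round(config.frac_low_expression_lines * n_lines)), 2)
    low_lines: dict[str, list[str]] = {}
    for a1, a2 in sl_pairs:
        chosen = sorted(rng.choice(lines, size=n_low, replace=False))
        low_lines[f"{a1}|{a2}"] = chosen
        essential_state.loc[a1, chosen] = True
    sl_a1_set = set(sl_a1)
    moderate_state = pd.DataFrame(False, index=genes, columns=lines)
    for g in genes:
        cat = categories[g]
        if cat == CATEGORY_BROADLY:
            essential_state.loc[g, :] = True
        elif cat == CATEGORY_SOMETIMES and g not in sl_a1_set:
            f = rng.uniform(0.05, 0.6)
            k = max(int(round(f * n_lines)), 1)
            ess = rng.choice(lines, size=k, replace=False)
            essential_state.loc[g, ess] = True
            moderate_state.loc[g, :] = ~essential_state.loc[g, :]

    # ---- scores and LFCs
    ess = essential_state.to_numpy()
    mod = moderate_state.to_numpy()
    true_scores = rng.normal(config.tolerated_mean, config.tolerated_sd, ess.shape)
    true_scores[mod] = rng.normal(config.moderate_mean, config.moderate_sd, int(mod.sum()))
    true_scores[ess] = rng.normal(config.essential_mean, config.essential_sd, int(ess.sum()))
    true_scores = pd.DataFrame(true_scores, index=genes, columns=lines)

    if guide_table is None:
        guide_table = pd.DataFrame(
            {
                "guide_id": [
                    f"{g}_sg{j + 1}"
                    for g in genes
                    for j in range(config.guides_per_gene)
                ],
                "intended_gene": [
                    g for g in genes for _ in range(config.guides_per_gene)
                ],
            }
        )
    guide_table = guide_table.reset_index(drop=True)
    covered = guide_table["intended_gene"].isin(true_scores.index)
    gt = guide_table.loc[covered]
    lfc = (
        true_scores.loc[gt["intended_gene"]].to_numpy()
        + rng.normal(0.0, config.guide_noise_sd, (len(gt), n_lines))
    )
    lfc = pd.DataFrame(lfc, index=pd.Index(gt["guide_id"], name="sgRNA"), columns=lines)
    guide_map = gt[["guide_id", "intended_gene"]].rename(
        columns={"guide_id": "sgRNA", "intended_gene": "gene"}
    )

    # ---- expression
    expr = rng.normal(config.expr_high_mean, config.expr_sd, (config.n_genes, n_lines))
    expr = pd.DataFrame(expr, index=genes, columns=lines)
    for key, lows in low_lines.items():
        a2 = key.split("|")[1]
        expr.loc[a2, lows] = rng.normal(
            config.expr_low_mean, config.expr_sd, len(lows)
        )
    if config.frac_unexpressed_genes > 0:
        protected = set(sl_a2)
        droppable = [g for g in genes if g not in protected]
        n_drop = int(round(config.frac_unexpressed_genes * config.n_genes))
        drop = rng.choice(droppable, size=min(n_drop, len(droppable)), replace=False)
        expr = expr.drop(index=list(drop))

    # ---- copy number (log2 relative scale, ~1 at neutral ploidy)
    cn = pd.DataFrame(
        rng.normal(1.0, 0.1, (config.n_genes, n_lines)), index=genes, columns=lines
    )
    n_cn_driven = int(round(config.frac_sl_cn_driven * len(sl_pairs)))
    cn_driven = {}
    for k, (a1, a2) in enumerate(sl_pairs):
        driven = k < n_cn_driven
        cn_driven[f"{a1}|{a2}"] = driven
        if driven:
            lows = low_lines[f"{a1}|{a2}"]
            cn.loc[a2, lows] = rng.normal(0.5, 0.1, len(lows))

    # ---- nonsense mutations
    hits = rng.random((config.n_genes, n_lines)) < config.nonsense_rate
    mut_rows = [
        {"gene": genes[i], "cell_line": lines[j],
         "Variant_Classification": "Nonsense_Mutation"}
        for i, j in zip(*np.nonzero(hits))
    ]
    if config.plant_nonsense_pair and sl_pairs:
        a1, a2 = sl_pairs[0]
        for line in low_lines[f"{a1}|{a2}"]:
            mut_rows.append(
                {"gene": a2, "cell_line": line,
                 "Variant_Classification": "Nonsense_Mutation"}
            )
    mutations = pd.DataFrame(
        mut_rows, columns=["gene", "cell_line", "Variant_Classification"]
    ).drop_duplicates().reset_index(drop=True)

    # ---- protein complexes: WGD pairs enriched at the configured odds ratio
    base_p = 0.25
    p_wgd = _weighted_or_probability(base_p, config.complex_wgd_odds_ratio)
    complex_rows = []
    cid = 0
    for row in pairs.itertuples():
        p_member = p_wgd if row.wgd_flag else base_p
        if rng.random() < p_member:
            cid += 1
            name = f"CPX{cid:03d}"
            complex_rows.append({"complex_id": name, "gene": row.A1})
            if rng.random() < 0.5:
                complex_rows.append({"complex_id": name, "gene": row.A2})
    # one housekeeping complex of broadly essential genes, for enrichment tests
    broadly = [g for g, c in categories.items() if c == CATEGORY_BROADLY]
    for g in broadly[: min(10, len(broadly))]:
        complex_rows.append({"complex_id": "CPX_CORE", "gene": g})
    complexes = pd.DataFrame(complex_rows, columns=["complex_id", "gene"])

    state_total = ess.size
    weights_real = [
        float(ess.sum()) / state_total,
        float(mod.sum()) / state_total,
        float(state_total - ess.sum() - mod.sum()) / state_total,
    ]
    truth = GroundTruth(
        categories=categories,
        sl_pairs=sl_pairs,
        cn_driven=cn_driven,
        low_lines=low_lines,
        multi_target_guides=(
            _true_multi_target_flags(guide_table, genome)
            if genome is not None and "protospacer" in guide_table
            else []
        ),
        mixture_means=[config.essential_mean, config.moderate_mean, config.tolerated_mean],
        mixture_sds=[config.essential_sd, config.moderate_sd, config.tolerated_sd],
        mixture_weights=weights_real,
        true_scores=true_scores,
    )
    return CohortBundle(
        lfc=lfc,
        guide_map=guide_map.reset_index(drop=True),
        expression=expr,
        copy_number=cn,
        mutations=mutations,
        paralogs=pairs[
            ["A1", "A2", "identity_A1_in_A2", "identity_A2_in_A1", "wgd_flag"]
        ].copy(),
        complexes=complexes,
        truth=truth,
    )


def expected_state_occupancy(config: CohortConfig) -> tuple[float, float, float]:
    """Analytic expected (essential, moderate, tolerated) cell fractions.

    Sometimes genes occupy the essential state in E[f] = 0.325 of lines and
    the moderate state elsewhere; planted SL focal genes swap moderate for
    tolerated; broadly genes are always essential and never genes always
    tolerated.
    """
    n = config.n_genes
    frac_sl = config.n_planted_sl_pairs / n
    frac_sometimes_free = config.frac_sometimes - frac_sl
    mean_f = (0.05 + 0.6) / 2
    p_ess = (
        config.frac_broadly
        + frac_sometimes_free * mean_f
        + frac_sl * config.frac_low_expression_lines
    )
    p_mod = frac_sometimes_free * (1 - mean_f)
    return p_ess, p_mod, 1.0 - p_ess - p_mod
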