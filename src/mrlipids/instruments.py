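"""Instrument screening and the unweighted allele score.

Candidate SNPs are checked against the instrumental-variable
assumptions in three ordered screens:

1. linkage disequilibrium with known lipid-associated loci
   (r² > 0.2 fails — a pleiotropy proxy),
2. Pearson correlation with potentially genetically determined
   confounders: smoking, BMI, waist-to-hip ratio, diabetes
   (|r| > 0.1 fails),
3. pairwise LD among the survivors (r² > 0.7): within each high-LD
   clique only the variant with the most functional impact (exonic/
   splicing first), then the largest source sample size, then the
   lexicographically smallest id, is kept.

Survivors are allele-oriented so each dosage counts the
alcohol-raising allele, then summed into an unweighted score.  LD is
computed on unphased dosages (composite r²), the estimator the screens
were applied with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference

DEFAULT_THRESHOLDS = (0.2, 0.1, 0.7)  # lipid-locus r², confounder |r|, pairwise r²
CONFOUNDER_COLUMNS = ("smoking", "bmi", "whr", "diabetes")
FUNCTIONAL_RANK = {"exonic": 0, "splicing": 0, "intronic": 1, "utr": 1, "intergenic": 2,
                   "other": 2}
MIN_PAIRWISE_OVERLAP = 50


@dataclass
class VariantRecord:
    """Candidate instrument metadata."""

    snp_id: str
    gene: str = ""
    maf: float = 0.25
    raising_allele: str = ""
    functional_class: str = "other"
    source_sample_size: int = 0
    alcohol_beta: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside (0, 0.5]")
        if self.functional_class not in FUNCTIONAL_RANK:
            raise ValueError(f"unknown functional class {self.functional_class!r}")


@dataclass
class ScreeningDecision:
    snp_id: str
    reason: str  # pass | fail_ld_lipid_locus | fail_confounder_corr | pruned_pairwise
    statistic: float = float("nan")
    detail: str = ""


@dataclass
class ScreeningReport:
    decisions: list = field(default_factory=list)

    @property
    def passed(self) -> list:
        return [d.snp_id for d in self.decisions if d.reason == "pass"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(d.snp_id, d.reason, d.statistic, d.detail) for d in self.decisions],
            columns=["snp_id", "reason", "statistic", "detail"],
        )


@dataclass
class GeneticScore:
    """Per-individual unweighted raising-allele count."""

    values: pd.Series
    snp_ids: list
    confounder_corr: dict = field(default_factory=dict)
    lipid_locus_r2: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def max_value(self) -> int:
        return 2 * len(self.snp_ids)


def default_roster() -> list:
    """VariantRecords for the five default instrument SNPs."""
    return [
        VariantRecord(
            snp_id=s["snp_id"], gene=s["gene"], maf=s["maf"],
            raising_allele=s["raising_allele"], functional_class=s["functional_class"],
            source_sample_size=s["source_sample_size"], alcohol_beta=s["alcohol_beta"],
        )
        for s in reference.INSTRUMENT_SNPS
    ]


def roster_to_frame(roster) -> pd.DataFrame:
    return pd.DataFrame([vars(v) for v in roster])


def roster_from_frame(df: pd.DataFrame) -> list:
    return [VariantRecord(**{k: row[k] for k in (
        "snp_id", "gene", "maf", "raising_allele", "functional_class",
        "source_sample_size", "alcohol_beta") if k in df.columns})
        for _, row in df.iterrows()]


def _pairwise_complete(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def per_snp_alcohol_beta(dosage, log_alcohol) -> float:
    """Univariate OLS slope of log-alcohol on dosage (cov/var)."""
    g, y = _pairwise_complete(dosage, log_alcohol)
    if len(g) != len(y):
        raise ValueError("length mismatch")
    vg = np.var(g)
    if vg == 0:
        raise ValueError("degenerate regressor: dosage is constant")
    return float(np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1))


def orient_alleles(variant: VariantRecord, dosage, log_alcohol):
    """Flip dosage to 2−G (and swap the recorded raising allele) when
    the fitted alcohol slope is negative; returns (dosage, record)."""
    slope = per_snp_alcohol_beta(dosage, log_alcohol)
    dosage = np.asarray(dosage, dtype=float)
    if slope < 0:
        flipped = 2.0 - dosage
        new = VariantRecord(
            snp_id=variant.snp_id, gene=variant.gene, maf=variant.maf,
            raising_allele=f"flip({variant.raising_allele})" if variant.raising_allele else "",
            functional_class=variant.functional_class,
            source_sample_size=variant.source_sample_size,
            alcohol_beta=-slope if np.isnan(variant.alcohol_beta) else variant.alcohol_beta,
        )
        return flipped, new
    return dosage, variant


def _pearson(a, b, min_overlap: int = MIN_PAIRWISE_OVERLAP):
    a, b = _pairwise_complete(a, b)
    if len(a) < min_overlap:
        return float("nan")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate vector: zero variance")
    return float(np.corrcoef(a, b)[0, 1])


def ld_r2(dosage_a, dosage_b) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors."""
    r = _pearson(dosage_a, dosage_b, min_overlap=2)
    return r * r


def _numeric_confounders(confounder_table: pd.DataFrame) -> pd.DataFrame:
    df = confounder_table.copy()
    if df["smoking"].dtype == object:
        df["smoking"] = df["smoking"].map({"never": 0, "former": 1, "current": 2})
    return df.astype(float)


def screen_candidates(
    candidates,
    dosages: pd.DataFrame,
    lipid_locus_dosages: pd.DataFrame | None,
    confounder_table: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    strict: bool = True,
):
    """Apply the three IV screens in order; returns
    (ScreeningReport, surviving VariantRecords).

    Pairwise pruning resolves each connected component of the
    r² > threshold graph deterministically: best functional class,
    then largest source sample size, then smallest snp_id — so the
    surviving set is invariant to candidate order.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    lipid_r2, conf_r, pair_r2 = thresholds
    for col in CONFOUNDER_COLUMNS:
        if col not in confounder_table.columns:
            raise KeyError(f"confounder table missing column {col!r}")
    conf = _numeric_confounders(confounder_table[list(CONFOUNDER_COLUMNS)])
    by_id = {v.snp_id: v for v in candidates}
    if len(by_id) != len(candidates):
        raise ValueError("duplicate snp_id among candidates")

    report = ScreeningReport()
    decided: dict[str, ScreeningDecision] = {}

    # screen 1: LD with lipid-associated loci
    stage2 = []
    for v in candidates:
        g = dosages[v.snp_id]
        worst, worst_id = -1.0, ""
        if lipid_locus_dosages is not None:
            for locus in lipid_locus_dosages.columns:
                r2 = ld_r2(g, lipid_locus_dosages[locus])
                if np.isnan(r2):
                    r2 = float("inf") if strict else 0.0
                if r2 > worst:
                    worst, worst_id = r2, locus
        if worst > lipid_r2:
            decided[v.snp_id] = ScreeningDecision(
                v.snp_id, "fail_ld_lipid_locus", worst, f"locus={worst_id}")
        else:
            stage2.append(v)

    # screen 2: correlation with potential confounders
    stage3 = []
    for v in stage2:
        worst, worst_col = -1.0, ""
        for col in CONFOUNDER_COLUMNS:
            r = _pearson(dosages[v.snp_id], conf[col])
            r = abs(r) if not np.isnan(r) else (float("inf") if strict else 0.0)
            if r > worst:
                worst, worst_col = r, col
        if worst > conf_r:
            decided[v.snp_id] = ScreeningDecision(
                v.snp_id, "fail_confounder_corr", worst, f"confounder={worst_col}")
        else:
            stage3.append(v)

    # screen 3: pairwise LD pruning on connected components
    ids = sorted(v.snp_id for v in stage3)
    adj = {i: set() for i in ids}
    pair_stat = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r2 = ld_r2(dosages[a], dosages[b])
            if np.isnan(r2):
                if strict:
                    r2 = float("inf")
                else:
                    continue
            if r2 > pair_r2:
                adj[a].add(b)
                adj[b].add(a)
                pair_stat[(a, b)] = pair_stat[(b, a)] = r2

    def sort_key(snp_id):
        v = by_id[snp_id]
        return (FUNCTIONAL_RANK[v.functional_class], -v.source_sample_size, v.snp_id)

    seen = set()
    for start in ids:
        if start in seen:
            continue
        comp = []
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node] - seen)
        comp.sort(key=sort_key)
        keeper = comp[0]
        decided[keeper] = ScreeningDecision(keeper, "pass")
        for loser in comp[1:]:
            decided[loser] = ScreeningDecision(
                loser, "pruned_pairwise",
                pair_stat.get((loser, keeper), max(
                    (pair_stat[(loser, o)] for o in comp if (loser, o) in pair_stat),
                    default=float("nan"))),
                f"kept={keeper}")

    for v in candidates:  # report in candidate order, every candidate exactly once
        report.decisions.append(decided[v.snp_id])
    survivors = [by_id[i] for i in sorted(report.passed, key=lambda s: list(by_id).index(s))]
    return report, survivors


def build_score(
    oriented_dosages: pd.DataFrame,
    survivors,
    confounder_table: pd.DataFrame | None = None,
    lipid_locus_dosages: pd.DataFrame | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    strict: bool = False,
) -> GeneticScore:
    """Sum oriented dosages over the surviving SNPs (unweighted score).

    The score itself is re-checked against the confounder and
    lipid-locus screens; breaches are recorded as flags (a hard error
    only in strict mode).  Individuals with any missing dosage get a
    missing score — unweighted sums are biased by per-individual
    missingness, so there is no imputation.
    """
    if not survivors:
        raise ValueError("no surviving SNPs to combine")
    snp_ids = [v.snp_id for v in survivors]
    sub = oriented_dosages[snp_ids]
    score = sub.sum(axis=1, skipna=False)
    out = GeneticScore(values=score, snp_ids=snp_ids)
    lipid_r2_t, conf_r_t, _ = thresholds
    if confounder_table is not None:
        conf = _numeric_confounders(confounder_table[list(CONFOUNDER_COLUMNS)])
        for col in CONFOUNDER_COLUMNS:
            r = _pearson(score, conf[col])
            out.confounder_corr[col] = r
            if not np.isnan(r) and abs(r) > conf_r_t:
                out.flags.append(f"score_confounder_corr:{col}:{r:.3f}")
    if lipid_locus_dosages is not None:
        for locus in lipid_locus_dosages.columns:
            r2 = ld_r2(score, lipid_locus_dosages[locus])
            out.lipid_locus_r2[locus] = r2
            if not np.isnan(r2) and r2 > lipid_r2_t:
                out.flags.append(f"score_lipid_locus_ld:{locus}:{r2:.3f}")
    if strict and out.flags:
        raise ValueError("genetic score failed validation: " + "; ".join(out.flags))
    return out
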