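"""Synthetic cohort generator.

Draws cohorts with the statistical structure the Mendelian-randomization
analysis assumes: Hardy–Weinberg genotypes at the five instrument SNPs,
a weak polygenic effect of the alcohol-raising alleles on consumption,
a latent confounder U that drives both drinking and lipids (and the
observed confounders smoking/BMI/WHR/diabetes), never/former/current
drinking statuses, and per-lipid causal curves that may be null, linear
or peaked in the recorded log exposure.

The causal curve operates on the *recorded* exposure ln(g/wk + 1)
(zero for abstainers and for current drinkers under one drink/week),
i.e. the same quantity the downstream estimator uses, so linear-effect
parameter recovery is exact rather than attenuated.

Default parameters are calibrated so the unweighted five-SNP score
explains roughly 0.1% of exposure variance at n ≈ 10⁴ — the
weak-instrument regime the study design operates in.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .phenotypes import GRAMS_PER_BEER

CURVE_KINDS = ("null", "linear", "peaked")

#: exposure-model constants, tuned once by simulation so the default
#: score's first-stage partial R² sits in the ~0.1% regime while the
#: drinker-category mix stays close to the reference cohort
DEFAULT_EXPOSURE_INTERCEPT = 2.9
DEFAULT_EXPOSURE_NOISE_SD = 1.15

#: default trough/peak location of the peaked causal curves on the
#: recorded ln(g/wk+1) scale; ~59 g/wk, i.e. the largest effect sits
#: at moderate regular intake
DEFAULT_PEAK_LOCATION = 4.1

MEASURED_LIPIDS = ("tg", "total_chol", "hdl", "hdl3", "lpa", "sdldl", "apob")
#: lipids a causal curve may target (hdl is emitted as hdl2 + hdl3;
#: ldl is Friedewald-derived downstream, so neither takes its own curve)
CURVE_TARGETS = ("tg", "total_chol", "hdl2", "hdl3", "sdldl", "apob", "lpa")
VISIT4_LIPIDS = ("sdldl", "apob")


@dataclass(frozen=True)
class CausalCurve:
    """Mean effect of recorded log-alcohol x on one lipid.

    kind="null": 0 everywhere.  kind="linear": beta·x.  kind="peaked":
    piecewise-linear, slope `rise` up to `peak_location` then slope
    `decline` beyond it, so the effect magnitude peaks near
    x = peak_location (signs of rise/decline set the direction).
    """

    kind: str = "null"
    beta: float = 0.0
    rise: float = 0.0
    peak_location: float = 0.0
    decline: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown causal curve kind {self.kind!r}")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "null":
            return np.zeros_like(x)
        if self.kind == "linear":
            return self.beta * x
        return self.rise * np.minimum(x, self.peak_location) + self.decline * np.maximum(
            x - self.peak_location, 0.0
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CausalCurve":
        return cls(**dict(d))


def default_causal_curves(peak: float = DEFAULT_PEAK_LOCATION) -> dict:
    """Peaked curves mirroring the study's qualitative findings:
    TG, total cholesterol, sdLDL-c and apoB fall with a trough near the
    third predicted-exposure quartile; HDL2-c rises with a peak there;
    HDL3-c and Lp(a) are causally null."""
    return {
        "tg": CausalCurve("peaked", rise=-0.15, peak_location=peak, decline=0.22),
        "total_chol": CausalCurve("peaked", rise=-8.0, peak_location=peak, decline=12.0),
        "hdl2": CausalCurve("peaked", rise=0.12, peak_location=peak, decline=-0.18),
        "hdl3": CausalCurve("null"),
        "sdldl": CausalCurve("peaked", rise=-0.10, peak_location=peak, decline=0.0),
        "apob": CausalCurve("peaked", rise=-0.05, peak_location=peak, decline=0.075),
        "lpa": CausalCurve("null"),
    }


def null_causal_curves() -> dict:
    return {name: CausalCurve("null") for name in CURVE_TARGETS}


# per-lipid measurement model: scale ("log" draws a lognormal around a
# median, "raw" a normal around a mean), baseline, residual SD on the
# draw scale, additive sex (female) and per-year age effects, and the
# default effect of the latent confounder U
LIPID_MODEL = {
    "tg": {"scale": "log", "baseline": 112.0, "sd": 0.50, "female": -0.10,
           "age": 0.004, "confounder": 0.12},
    "total_chol": {"scale": "raw", "baseline": 212.0, "sd": 38.0, "female": 2.0,
                   "age": 0.5, "confounder": 4.0},
    "hdl3": {"scale": "raw", "baseline": 35.0, "sd": 10.0, "female": 3.5,
             "age": 0.02, "confounder": -1.5},
    "hdl2": {"scale": "log", "baseline": 11.5, "sd": 0.55, "female": 0.25,
             "age": 0.002, "confounder": -0.06},
    "sdldl": {"scale": "log", "baseline": 41.0, "sd": 0.45, "female": -0.08,
              "age": 0.003, "confounder": 0.08},
    "apob": {"scale": "log", "baseline": 97.0, "sd": 0.25, "female": -0.02,
             "age": 0.003, "confounder": 0.05},
    "lpa": {"scale": "log", "baseline": 6.2, "sd": 1.05, "female": 0.05,
            "age": 0.0, "confounder": 0.0},
}


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic cohort draw."""

    n_individuals: int = 10893
    snp_ids: tuple = reference.INSTRUMENT_SNP_IDS
    snp_mafs: tuple = reference.INSTRUMENT_MAFS
    snp_betas: tuple = reference.INSTRUMENT_BETAS
    sex_effect: float = 0.9          # additive male effect on latent log-alcohol
    age_effect: float = -0.01        # per year, centred at the reference mean age
    confounder_effect_exposure: float = 0.4
    exposure_intercept: float = DEFAULT_EXPOSURE_INTERCEPT
    exposure_noise_sd: float = DEFAULT_EXPOSURE_NOISE_SD
    status_probs: tuple = (0.181, 0.170, 0.649)   # never / former / current
    abstention_confounded: bool = False
    abstention_confounder_strength: float = 0.6
    causal_curves: dict = field(default_factory=default_causal_curves)
    confounder_effect_outcome: dict = field(
        default_factory=lambda: {k: v["confounder"] for k, v in LIPID_MODEL.items()}
    )
    outcome_noise_sd: dict = field(
        default_factory=lambda: {k: v["sd"] for k, v in LIPID_MODEL.items()}
    )
    female_prob: float = 0.531
    age_mean: float = 54.3
    age_sd: float = 5.7
    lipid_missing_rate: float = 0.05
    visit4_attendance: float = 0.78
    min_carrier_warn: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if len(self.snp_mafs) != len(self.snp_betas) or len(self.snp_ids) != len(self.snp_mafs):
            raise ValueError("snp_ids, snp_mafs and snp_betas must have equal length")
        for maf in self.snp_mafs:
            if not 0.0 < maf <= 0.5:
                raise ValueError(f"MAF {maf} outside (0, 0.5]")
        if len(self.status_probs) != 3 or any(p < 0 for p in self.status_probs):
            raise ValueError("status_probs must be three non-negative probabilities")
        if abs(sum(self.status_probs) - 1.0) > 1e-9:
            raise ValueError("status_probs must sum to 1")
        if self.exposure_noise_sd <= 0:
            raise ValueError("exposure_noise_sd must be positive")
        for name, sd in self.outcome_noise_sd.items():
            if sd <= 0:
                raise ValueError(f"outcome noise SD for {name} must be positive")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must be in [0, 1]")
        for name in self.causal_curves:
            if name not in CURVE_TARGETS:
                raise ValueError(f"causal curve for unknown lipid {name!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["causal_curves"] = {k: v.to_dict() for k, v in self.causal_curves.items()}
        for key in ("snp_ids", "snp_mafs", "snp_betas", "status_probs"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "causal_curves" in d:
            d["causal_curves"] = {
                k: v if isinstance(v, CausalCurve) else CausalCurve.from_dict(v)
                for k, v in d["causal_curves"].items()
            }
        for key in ("snp_ids", "snp_mafs", "snp_betas", "status_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrueParameters:
    """The realized generating parameters of a draw — the recovery
    target for simulation studies.  Round-trips losslessly with the
    SimulationConfig it came from."""

    config: SimulationConfig

    @property
    def snp_betas(self):
        return self.config.snp_betas

    @property
    def causal_curves(self):
        return self.config.causal_curves

    @property
    def confounder_effect_exposure(self):
        return self.config.confounder_effect_exposure

    def to_config(self) -> SimulationConfig:
        return self.config

    def to_json(self) -> str:
        return json.dumps(self.config.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrueParameters":
        return cls(SimulationConfig.from_dict(json.loads(text)))


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def simulate_genotypes(mafs: Sequence[float], n: int, seed) -> np.ndarray:
    """Independent Hardy–Weinberg dosages, one Binomial(2, maf) column
    per SNP, counting the alcohol-raising allele."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for maf in mafs:
        if not 0.0 < maf <= 0.5:
            raise ValueError(f"MAF {maf} outside (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, np.asarray(mafs, dtype=float), size=(n, len(mafs)))


def _assign_status(u: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Never/former/current labels; optionally coupled to U so that
    poor-health individuals abstain (reverse-causation stress mode)."""
    p = np.tile(np.asarray(config.status_probs, dtype=float), (len(u), 1))
    if config.abstention_confounded:
        s = config.abstention_confounder_strength
        w = np.column_stack([
            np.exp(0.5 * s * u), np.exp(0.5 * s * u), np.exp(-0.5 * s * u)
        ])
        p = p * w
        p /= p.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    draw = rng.random(len(u))[:, None]
    idx = (draw > cum).sum(axis=1)
    return np.array(["never", "former", "current"], dtype=object)[idx]


def simulate_exposure(
    genotypes: np.ndarray,
    sex_male: np.ndarray,
    age: np.ndarray,
    u: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Drinking status, grams/week and the recorded log exposure.

    Latent log-consumption for current drinkers is linear in the
    raising-allele dosages, sex, age and the confounder, truncated at
    zero.  Current drinkers under one (beer-equivalent) drink per week
    are recorded as 0 g/wk, matching the analysis convention.
    """
    n = len(sex_male)
    if genotypes.shape[0] != n or len(age) != n or len(u) != n:
        raise ValueError("genotypes, sex, age and confounder lengths disagree")
    if genotypes.shape[1] != len(config.snp_betas):
        raise ValueError("genotype columns do not match snp_betas")
    status = _assign_status(u, config, rng)
    latent = (
        config.exposure_intercept
        + genotypes @ np.asarray(config.snp_betas, dtype=float)
        + config.sex_effect * sex_male
        + config.age_effect * (np.asarray(age, dtype=float) - config.age_mean)
        + config.confounder_effect_exposure * u
        + rng.normal(0.0, config.exposure_noise_sd, n)
    )
    latent = np.maximum(latent, 0.0)
    current = status == "current"
    g_wk = np.where(current, np.expm1(latent), 0.0)
    drinks = g_wk / GRAMS_PER_BEER
    recorded = np.where(current & (drinks >= 1.0), g_wk, 0.0)
    return pd.DataFrame({
        "drinking_status": status,
        "alcohol_g_wk": g_wk,
        "drinks_per_wk": drinks,
        "log_alcohol": np.log1p(recorded),
    })


def simulate_lipids(
    log_alcohol: np.ndarray,
    u: np.ndarray,
    sex_male: np.ndarray,
    age: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Measured lipid panel given the recorded log exposure.

    Skewed lipids are drawn on the log scale and exponentiated; total
    cholesterol and HDL3-c are drawn on the measurement scale.  HDL-c
    is emitted as the sum of the latent HDL2-c and HDL3-c so that the
    downstream subfraction subtraction recovers the causal HDL2-c
    signal.  Values are floored just above zero (no negative lipids).
    """
    x = np.asarray(log_alcohol, dtype=float)
    n = len(x)
    female = 1.0 - np.asarray(sex_male, dtype=float)
    age_c = np.asarray(age, dtype=float) - config.age_mean
    curves = config.causal_curves
    parts = {}
    for name, model in LIPID_MODEL.items():
        curve = curves.get(name, CausalCurve("null"))
        mean = (
            curve(x)
            + config.confounder_effect_outcome.get(name, 0.0) * u
            + model["female"] * female
            + model["age"] * age_c
        )
        noise = rng.normal(0.0, config.outcome_noise_sd[name], n)
        if model["scale"] == "log":
            parts[name] = model["baseline"] * np.exp(mean + noise)
        else:
            parts[name] = np.maximum(model["baseline"] + mean + noise, 1.0)
    out = pd.DataFrame({
        "tg": parts["tg"],
        "total_chol": parts["total_chol"],
        "hdl": parts["hdl2"] + parts["hdl3"],
        "hdl3": parts["hdl3"],
        "lpa": parts["lpa"],
        "sdldl": parts["sdldl"],
        "apob": parts["apob"],
    })
    return out


def generate_cohort(config: SimulationConfig | None = None):
    """Draw a complete cohort table plus its generating parameters.

    Returns ``(cohort, truth)`` where the cohort has one row per
    individual: demographics, drinking variables, raising-allele
    dosages (one column per SNP id), two ancestry PCs, observed
    confounders and the measured lipid panel (with visit-4 attrition
    for sdLDL-c/apoB and a small missing rate elsewhere).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    sex_male = (rng.random(n) >= config.female_prob).astype(float)
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 44.0, 66.0)
    u = rng.normal(0.0, 1.0, n)
    genotypes = simulate_genotypes(config.snp_mafs, n, rng)
    carriers = (genotypes > 0).sum(axis=0)
    import logging
    for snp, c in zip(config.snp_ids, carriers):
        if c < config.min_carrier_warn:
            logging.getLogger(__name__).warning(
                "SNP %s has only %d carriers at n=%d", snp, int(c), n
            )
    expo = simulate_exposure(genotypes, sex_male, age, u, config, rng)
    lipids = simulate_lipids(expo["log_alcohol"].to_numpy(), u, sex_male, age, config, rng)

    # visit-4 attrition and sporadic baseline missingness
    if config.visit4_attendance < 1.0:
        absent = rng.random(n) >= config.visit4_attendance
        lipids.loc[absent, list(VISIT4_LIPIDS)] = np.nan
    if config.lipid_missing_rate > 0.0:
        for col in ("tg", "total_chol", "hdl", "hdl3", "lpa"):
            miss = rng.random(n) < config.lipid_missing_rate
            lipids.loc[miss, col] = np.nan

    # observed confounders as noisy functions of U
    z = 0.6 * u + 0.8 * rng.normal(0.0, 1.0, n)
    smoking = np.digitize(z, [-0.245, 0.697])
    bmi = 27.0 + 1.5 * u + rng.normal(0.0, 4.66, n)
    whr = 0.90 + 0.02 * u + 0.03 * sex_male + rng.normal(0.0, 0.095, n)
    diabetes = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-2.75 + 0.8 * u)))).astype(int)

    cohort = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "sex": np.where(sex_male == 1.0, "M", "F"),
        "age": age,
        "age_v4": age + 9.0,
    })
    cohort = pd.concat([cohort, expo], axis=1)
    for j, snp in enumerate(config.snp_ids):
        cohort[snp] = genotypes[:, j]
    cohort["PC1"] = rng.normal(0.0, 1.0, n)
    cohort["PC2"] = rng.normal(0.0, 1.0, n)
    cohort["smoking"] = smoking
    cohort["bmi"] = bmi
    cohort["whr"] = whr
    cohort["diabetes"] = diabetes
    cohort = pd.concat([cohort, lipids], axis=1)
    return cohort, TrueParameters(config)


# ---------------------------------------------------------------------------
# on-disk formats

def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_vcf(cohort: pd.DataFrame, path, roster=None) -> None:
    """Write hard-call genotypes as a minimal VCF 4.2 (GT only).

    The ALT allele is the alcohol-raising allele, so the per-sample ALT
    count equals the dosage column in the cohort table.
    """
    roster = roster if roster is not None else reference.INSTRUMENT_SNPS
    samples = [f"S{int(i)}" for i in cohort["id"]]
    contigs = sorted({rec["chrom"] for rec in roster})
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for rec in roster:
        snp = rec["snp_id"]
        if snp not in cohort.columns:
            continue
        dos = cohort[snp].to_numpy()
        calls = "\t".join(gt_map[int(d)] for d in dos)
        lines.append(
            f"{rec['chrom']}\t{rec['pos']}\t{snp}\t{rec['other_allele']}\t"
            f"{rec['raising_allele']}\t.\tPASS\t.\tGT\t{calls}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf_dosages(path) -> pd.DataFrame:
    """ALT-allele dosage matrix (individuals × SNPs) from a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols = {}
    for var in vcf:
        gts = np.asarray(var.genotype.array())[:, :2]
        cols[var.ID] = (gts > 0).sum(axis=1)
    return pd.DataFrame(cols, index=list(vcf.samples))
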