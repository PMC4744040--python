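"""Published reference values used as generator defaults and sanity anchors.

Two blocks live here:

* the five-SNP instrument roster for alcohol consumption (alcohol- and
  acetaldehyde-dehydrogenase loci), with minor-allele frequencies and
  per-allele effects on ln(alcohol g/wk + 1) taken from the published
  European-ancestry analysis these tools emulate, and
* the published cohort summary (n = 10,893 European-American adults)
  whose category counts and lipid means parametrise the synthetic
  cohort generator.

Functional-class labels, source sample sizes and chromosome-4 positions
in the roster are synthetic package defaults (they matter only for
deterministic tie-breaking and VCF round-trips, not for estimation).
"""

from __future__ import annotations

#: instrument SNPs: per-allele effect is on the ln(g/wk + 1) scale,
#: for the alcohol-raising allele
INSTRUMENT_SNPS = [
    {"snp_id": "rs2066702", "gene": "ADH1B", "maf": 0.001, "raising_allele": "G",
     "other_allele": "A", "alcohol_beta": 0.33, "functional_class": "exonic",
     "source_sample_size": 38000, "chrom": "4", "pos": 99307860},
    {"snp_id": "rs1693457", "gene": "ADH1B", "maf": 0.172, "raising_allele": "T",
     "other_allele": "C", "alcohol_beta": 0.06, "functional_class": "intronic",
     "source_sample_size": 42000, "chrom": "4", "pos": 99313400},
    {"snp_id": "rs1789891", "gene": "ADH1B/1C", "maf": 0.169, "raising_allele": "A",
     "other_allele": "C", "alcohol_beta": 0.07, "functional_class": "intergenic",
     "source_sample_size": 26000, "chrom": "4", "pos": 99332148},
    {"snp_id": "rs698", "gene": "ADH1C", "maf": 0.409, "raising_allele": "C",
     "other_allele": "T", "alcohol_beta": 0.05, "functional_class": "exonic",
     "source_sample_size": 47000, "chrom": "4", "pos": 99339632},
    {"snp_id": "rs1126671", "gene": "ADH4", "maf": 0.313, "raising_allele": "A",
     "other_allele": "G", "alcohol_beta": 0.07, "functional_class": "exonic",
     "source_sample_size": 20000, "chrom": "4", "pos": 99123018},
]

INSTRUMENT_SNP_IDS = tuple(s["snp_id"] for s in INSTRUMENT_SNPS)
INSTRUMENT_MAFS = tuple(s["maf"] for s in INSTRUMENT_SNPS)
INSTRUMENT_BETAS = tuple(s["alcohol_beta"] for s in INSTRUMENT_SNPS)

#: published cohort summary: counts, percentages and mean (SD) values
REFERENCE_COHORT = {
    "n_total": 10893,
    "n_female": 5784,
    "age_mean": 54.3,
    "age_sd": 5.7,
    "alcohol_g_wk_mean": 45.7,
    "alcohol_g_wk_sd": 93.9,
    "category_counts": {
        "never": 1965,
        "former": 1848,
        "infrequent": 2369,
        "low_to_moderate": 3734,
        "heavy": 951,
    },
    "category_pct": {
        "never": 18.10,
        "former": 17.00,
        "infrequent": 21.80,
        "low_to_moderate": 34.36,
        "heavy": 8.75,
    },
    "lipid_mean_sd": {
        "tg": (137.1, 90.7),
        "total_chol": (214.5, 40.0),
        "hdl": (50.5, 16.8),
        "hdl2": (13.7, 8.6),
        "hdl3": (36.8, 10.9),
        "ldl": (137.6, 37.6),
        "sdldl": (45.2, 21.0),
        "apob": (100.6, 25.1),
    },
    "lpa_median_iqr": (8.2, (3.0, 19.6)),
    "smoking_pct": {"never": 40.30, "former": 35.40, "current": 24.30},
    "bmi_mean_sd": (27.0, 4.9),
    "whr_mean_sd": (0.9, 0.1),
    "diabetic_pct": 8.78,
}


def female_percent() -> float:
    """Percent female recomputed from the reference counts."""
    ref = REFERENCE_COHORT
    return 100.0 * ref["n_female"] / ref["n_total"]


def regular_drinker_percent() -> float:
    """Percent with one or more drink per week (low-to-moderate plus
    heavy current drinkers), from the reference category percentages."""
    pct = REFERENCE_COHORT["category_pct"]
    return pct["low_to_moderate"] + pct["heavy"]


def reference_hdl2_mean() -> float:
    """Mean HDL2-c implied by the HDL-c and HDL3-c reference means via
    the subfraction identity HDL2-c = HDL-c − HDL3-c."""
    lip = REFERENCE_COHORT["lipid_mean_sd"]
    return lip["hdl"][0] - lip["hdl3"][0]
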