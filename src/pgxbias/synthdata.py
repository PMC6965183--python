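"""Synthetic genotypes and EHR-like statin cohorts.

The generator emulates the structure a pharmacogenomic change-score
analysis assumes: independent biallelic variants under Hardy–Weinberg
proportions, a log-normal baseline LDL-C with additive per-allele genetic
effects, a multiplicative statin response, and independent log-scale
measurement error on both the baseline and the on-treatment measurement.
On the log scale the model is

    lnB_i = mu + sum_j bb_j g_ij + c'z_i + e_i,     e ~ N(0, sigma_biology^2)
    lnX_i = lnB_i + u_i,                            u ~ N(0, sigma_measure^2)
    lnY_i = lnB_i + ln(1 - r) + sum_j br_j g_ij + w_i,
                                                    w ~ N(0, sigma_measure^2)

where X is the observed baseline, Y the observed on-treatment value and r
the median fractional reduction under therapy.  Measurement error being
additive in the log keeps X and Y positive and makes the bias algebra in
:mod:`pgxbias.bias_theory` exact.

Alongside the measurement pair the module fabricates dated dispensing and
lipid-panel records so that every eligibility filter in
:mod:`pgxbias.cohort` can be exercised, with a violation ledger recording
which individuals were deliberately made ineligible.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Variant",
    "SimParams",
    "CovariateParams",
    "RecordGenParams",
    "GenotypePanel",
    "TrueState",
    "CohortRecord",
    "Dispensing",
    "CoTherapyFill",
    "LipidMeasurement",
    "variant_class",
    "default_sigma_measure",
    "simulate_genotypes",
    "simulate_ldl_pair",
    "simulate_ehr_records",
    "write_dosages_tsv",
    "write_sites_tsv",
]

STATIN_TYPES = ("atorvastatin", "simvastatin", "rosuvastatin")

#: non-statin LDL-C therapies whose coverage windows disqualify a lipid value
COTHERAPY_CLASSES = (
    "bile acid sequestrant",
    "ezetimibe",
    "fibrate",
    "prescription niacin",
    "prescription omega-3",
)


def default_sigma_measure(sigma_biology: float, error_fraction: float = 0.34) -> float:
    """Measurement-error SD such that sigma_m^2/(sigma_b^2+sigma_m^2) equals
    ``error_fraction``.

    The cohort the model emulates reports an overall LDL-C measurement-error
    figure of 34% without a precise formula; interpreting it as the error
    share of observed (single-measurement) log variance is a configurable
    default, not a claim.
    """
    if not 0.0 <= error_fraction < 1.0:
        raise ValueError("error_fraction must be in [0, 1)")
    return sigma_biology * math.sqrt(error_fraction / (1.0 - error_fraction))


@dataclass(frozen=True)
class Variant:
    """One biallelic site: metadata plus its two per-allele log-scale effects."""

    vid: str
    chrom: str
    pos: int
    maf: float
    beta_baseline: float = 0.0
    beta_response: float = 0.0
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"{self.vid}: maf must be in (0,1), got {self.maf}")
        if self.pos < 0:
            raise ValueError(f"{self.vid}: negative position")


def variant_class(v: Variant) -> str:
    """Classify a planted variant by which effects are nonzero."""
    b = v.beta_baseline != 0.0
    r = v.beta_response != 0.0
    if b and r:
        return "both"
    if b:
        return "baseline_only"
    if r:
        return "response_only"
    return "null"


@dataclass
class CovariateParams:
    """Distributions for the covariates recorded at statin initiation.

    All covariates are drawn independently of genotype.  Effects act on the
    true log baseline; statin type and dose never affect baseline (they are
    assigned at initiation) and by default do not modify the response either,
    so they enter the analysis purely as adjustment columns.
    """

    age_mean: float = 62.0
    age_sd: float = 10.0
    bmi_mean: float = 28.0
    bmi_sd: float = 5.0
    p_female: float = 0.5
    p_smoking: float = 0.2
    p_diabetes: float = 0.15
    p_hypertension: float = 0.4
    statin_type_probs: Mapping[str, float] = field(
        default_factory=lambda: {"atorvastatin": 0.5, "simvastatin": 0.35, "rosuvastatin": 0.15}
    )
    dose_log_sd: float = 0.5
    # per-unit effects on ln baseline (age and BMI centered at their means)
    age_effect: float = 0.002
    bmi_effect: float = 0.003
    female_effect: float = -0.04
    smoking_effect: float = 0.02
    diabetes_effect: float = -0.05
    hypertension_effect: float = 0.02


@dataclass
class RecordGenParams:
    """Controls for the fabricated dispensing / lipid-panel records.

    The ``p_*`` rates inject specific eligibility violations; at the default
    of zero every simulated individual passes every downstream filter.
    """

    start_date: datetime.date = datetime.date(2010, 1, 1)
    enrollment_days: int = 2000
    first_fill_days_supply: tuple[int, ...] = (30, 90)
    first_fill_probs: tuple[float, ...] = (0.7, 0.3)
    mean_extra_fills: float = 3.0
    baseline_lag_max: int = 365
    p_single_fill: float = 0.0      # only one statin dispensing ever
    p_no_baseline: float = 0.0      # no pre-initiation lipid at all
    p_late_ontreat: float = 0.0     # only post lipid falls after the window
    p_cotherapy: float = 0.0        # co-therapy coverage over the on-treatment lipid
    p_decoy_prebaseline: float = 0.5  # extra, older pre-treatment lipid
    p_early_post: float = 0.3         # post lipid before day 21 (never eligible)

    def __post_init__(self) -> None:
        for name in ("p_single_fill", "p_no_baseline", "p_late_ontreat",
                     "p_cotherapy", "p_decoy_prebaseline", "p_early_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimParams:
    """All generative parameters for one experiment.

    Parameters
    ----------
    n_individuals
        Mapping of group label (self-reported race/ethnicity stratum in the
        emulated design) to cohort size.  Groups are independent cohorts;
        no admixture is modelled.
    variants
        Planted variants shared across groups.  Per-group allele-frequency
        overrides go in ``maf_by_group``.
    mu_baseline
        Mean log baseline LDL-C (log mg/dL); default ln(130).
    sigma_biology, sigma_measure
        SD of the biological and measurement components of log LDL-C.  The
        default measurement SD makes the error share of single-measurement
        variance 34%.
    response_fraction
        Median fractional LDL-C reduction on statin, default 0.35.
    dosage_jitter
        Half-width of uniform jitter added to integer dosages (clipped to
        [0, 2]) to emulate imputation uncertainty; 0 disables.
    """

    n_individuals: Mapping[str, int]
    variants: Sequence[Variant]
    seed: int
    mu_baseline: float = math.log(130.0)
    sigma_biology: float = 0.25
    sigma_measure: float = dataclasses.field(default=-1.0)  # sentinel: derive from 34%
    response_fraction: float = 0.35
    dosage_jitter: float = 0.0
    covariates: CovariateParams | None = field(default_factory=CovariateParams)
    records: RecordGenParams = field(default_factory=RecordGenParams)
    maf_by_group: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.seed = int(self.seed)
        if self.sigma_measure == -1.0:
            self.sigma_measure = default_sigma_measure(self.sigma_biology)
        if self.sigma_measure < 0:
            raise ValueError("sigma_measure must be >= 0")
        if self.sigma_biology < 0:
            raise ValueError("sigma_biology must be >= 0")
        if not 0.0 < self.response_fraction < 1.0:
            raise ValueError("response_fraction must be in (0,1)")
        if not self.n_individuals:
            raise ValueError("at least one group required")
        for g, n in self.n_individuals.items():
            if n <= 0:
                raise ValueError(f"group {g!r}: n must be positive")
        # positions strictly increasing within a chromosome
        by_chrom: dict[str, int] = {}
        for v in self.variants:
            last = by_chrom.get(v.chrom)
            if last is not None and v.pos <= last:
                raise ValueError(
                    f"variant positions must be strictly increasing within a "
                    f"chromosome; {v.vid} at {v.chrom}:{v.pos} violates this"
                )
            by_chrom[v.chrom] = v.pos


@dataclass
class GenotypePanel:
    """Per-group allelic dosages with variant metadata.

    ``dosages`` is individuals x variants with values in [0, 2]; columns
    align with ``variants``.
    """

    group: str
    variants: Sequence[Variant]
    dosages: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix shape does not match variant metadata")
        if self.dosages.shape[0] != len(self.ids):
            raise ValueError("dosage matrix shape does not match ids")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def empirical_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

    def empirical_maf(self) -> np.ndarray:
        f = self.empirical_freq()
        return np.minimum(f, 1.0 - f)

    def subset_variants(self, keep: np.ndarray) -> "GenotypePanel":
        keep = np.asarray(keep)
        return GenotypePanel(
            group=self.group,
            variants=[v for v, k in zip(self.variants, keep) if k],
            dosages=self.dosages[:, keep],
            ids=self.ids,
        )


@dataclass
class TrueState:
    """Latent quantities retained for oracle checks only.

    Analysis stages must never consume this: it exists so tests can compare
    observed behaviour against the generating mechanism (the true log
    baseline and the two measurement-error draws).
    """

    ln_baseline: np.ndarray
    u: np.ndarray
    w: np.ndarray
    covariates: pd.DataFrame


@dataclass(frozen=True)
class Dispensing:
    date: datetime.date
    statin_type: str
    dose: float
    days_supply: int


@dataclass(frozen=True)
class CoTherapyFill:
    date: datetime.date
    drug_class: str
    days_supply: int


@dataclass(frozen=True)
class LipidMeasurement:
    date: datetime.date
    ldl: float


@dataclass
class CohortRecord:
    """One individual's EHR extract: statin fills, co-therapy fills, dated
    LDL-C measurements, and covariates at initiation."""

    iid: str
    statin_fills: list[Dispensing]
    cotherapy_fills: list[CoTherapyFill]
    lipids: list[LipidMeasurement]
    covariates: dict


def _group_rng(seed: int, group: str, stream: int) -> np.random.Generator:
    """Deterministic, group- and stage-specific RNG stream."""
    return np.random.default_rng([seed, zlib.crc32(group.encode()), stream])


def simulate_genotypes(params: SimParams, group: str) -> GenotypePanel:
    """Draw integer dosages under Hardy–Weinberg proportions per variant.

    Per-group allele frequencies come from ``params.maf_by_group`` when
    present, else the variant's ``maf``.  With ``dosage_jitter`` > 0,
    uniform noise in [-jitter, +jitter] is added and clipped to [0, 2] to
    emulate imputation uncertainty.
    """
    if group not in params.n_individuals:
        raise ValueError(f"unknown group {group!r}")
    n = params.n_individuals[group]
    rng = _group_rng(params.seed, group, 0)
    overrides = params.maf_by_group.get(group, {})
    mafs = np.array([overrides.get(v.vid, v.maf) for v in params.variants])
    if mafs.size and (mafs.min() <= 0 or mafs.max() >= 1):
        raise ValueError("per-group maf must be in (0,1)")
    dosages = rng.binomial(2, mafs[None, :], size=(n, len(mafs))).astype(float)
    if params.dosage_jitter > 0:
        jit = rng.uniform(-params.dosage_jitter, params.dosage_jitter, size=dosages.shape)
        dosages = np.clip(dosages + jit, 0.0, 2.0)
    ids = np.array([f"{group}-{i:06d}" for i in range(n)])
    return GenotypePanel(group=group, variants=list(params.variants), dosages=dosages, ids=ids)


def _simulate_covariates(params: SimParams, n: int, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the covariate table and its additive contribution to ln baseline."""
    cp = params.covariates
    if cp is None:
        return pd.DataFrame(index=range(n)), np.zeros(n)
    age = rng.normal(cp.age_mean, cp.age_sd, n)
    bmi = rng.normal(cp.bmi_mean, cp.bmi_sd, n)
    female = rng.random(n) < cp.p_female
    smoking = rng.random(n) < cp.p_smoking
    diabetes = rng.random(n) < cp.p_diabetes
    hypertension = rng.random(n) < cp.p_hypertension
    types = list(cp.statin_type_probs)
    probs = np.array([cp.statin_type_probs[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    statin_type = rng.choice(types, size=n, p=probs)
    statin_dose = np.exp(rng.normal(0.0, cp.dose_log_sd, n))
    cov = pd.DataFrame(
        {
            "age": age,
            "sex_female": female.astype(int),
            "bmi": bmi,
            "smoking": smoking.astype(int),
            "diabetes": diabetes.astype(int),
            "hypertension": hypertension.astype(int),
            "statin_type": statin_type,
            "statin_dose": statin_dose,
        }
    )
    contribution = (
        cp.age_effect * (age - cp.age_mean)
        + cp.bmi_effect * (bmi - cp.bmi_mean)
        + cp.female_effect * female
        + cp.smoking_effect * smoking
        + cp.diabetes_effect * diabetes
        + cp.hypertension_effect * hypertension
    )
    return cov, contribution


def simulate_ldl_pair(panel: GenotypePanel, params: SimParams) -> tuple[np.ndarray, np.ndarray, TrueState]:
    """Generate the observed (baseline X, on-treatment Y) pair in mg/dL.

    Implements the log-scale generative model in the module docstring;
    returns strictly positive X and Y plus the :class:`TrueState` with the
    latent baseline and both error draws.
    """
    rng = _group_rng(params.seed, panel.group, 1)
    n = panel.n_individuals
    bb = np.array([v.beta_baseline for v in panel.variants])
    br = np.array([v.beta_response for v in panel.variants])
    cov, cov_effect = _simulate_covariates(params, n, rng)
    cov.index = pd.Index(panel.ids, name="iid")
    e = rng.normal(0.0, params.sigma_biology, n)
    u = rng.normal(0.0, params.sigma_measure, n)
    w = rng.normal(0.0, params.sigma_measure, n)
    ln_b = params.mu_baseline + panel.dosages @ bb + cov_effect + e
    ln_x = ln_b + u
    ln_y = ln_b + math.log(1.0 - params.response_fraction) + panel.dosages @ br + w
    state = TrueState(ln_baseline=ln_b, u=u, w=w, covariates=cov)
    return np.exp(ln_x), np.exp(ln_y), state


def simulate_ehr_records(
    params: SimParams,
    panel: GenotypePanel,
    x: np.ndarray,
    y: np.ndarray,
    state: TrueState,
) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Fabricate dated dispensing and lipid records carrying (X, Y).

    Returns the records plus a violation ledger with one row per individual:
    boolean columns for each injected violation and ``expected_retained``,
    the generator's own prediction of whether the cohort filters keep the
    individual.  Decoy lipids (an older pre-treatment value, an early
    post-initiation value before day 21) exercise the selection logic
    without changing eligibility.
    """
    rp = params.records
    rng = _group_rng(params.seed, panel.group, 2)
    one_day = datetime.timedelta(days=1)
    records: list[CohortRecord] = []
    rows = []
    supplies = np.asarray(rp.first_fill_days_supply)
    sprobs = np.asarray(rp.first_fill_probs, dtype=float)
    sprobs = sprobs / sprobs.sum()
    for i, iid in enumerate(panel.ids):
        init = rp.start_date + one_day * int(rng.integers(0, rp.enrollment_days))
        supply = int(rng.choice(supplies, p=sprobs))
        cov = state.covariates.iloc[i].to_dict() if len(state.covariates.columns) else {}
        stype = cov.get("statin_type", STATIN_TYPES[0])
        dose = float(cov.get("statin_dose", 1.0))

        single_fill = rng.random() < rp.p_single_fill
        no_baseline = rng.random() < rp.p_no_baseline
        late_ontreat = rng.random() < rp.p_late_ontreat
        cotherapy = rng.random() < rp.p_cotherapy

        fills = [Dispensing(init, stype, dose, supply)]
        if not single_fill:
            n_extra = 1 + int(rng.poisson(rp.mean_extra_fills))
            d = init
            for _ in range(n_extra):
                d = d + one_day * int(supply + rng.integers(0, 15))
                fills.append(Dispensing(d, stype, dose, supply))

        lipids: list[LipidMeasurement] = []
        if not no_baseline:
            lag = 1 + int(rng.integers(0, rp.baseline_lag_max))
            lipids.append(LipidMeasurement(init - one_day * lag, float(x[i])))
            if rng.random() < rp.p_decoy_prebaseline:
                decoy = float(x[i] * math.exp(rng.normal(0.0, 0.1)))
                lipids.append(LipidMeasurement(init - one_day * (lag + 400), decoy))
        if rng.random() < rp.p_early_post:
            early = float(x[i] * math.exp(rng.normal(0.0, 0.1)))
            lipids.append(LipidMeasurement(init + one_day * int(rng.integers(0, 21)), early))
        if late_ontreat:
            on_date = init + one_day * (supply + 21 + 1 + int(rng.integers(0, 60)))
        else:
            on_date = init + one_day * (21 + int(rng.integers(0, supply)))
        lipids.append(LipidMeasurement(on_date, float(y[i])))
        lipids.sort(key=lambda m: m.date)

        cofills: list[CoTherapyFill] = []
        if cotherapy:
            drug = str(rng.choice(COTHERAPY_CLASSES))
            cofills.append(CoTherapyFill(on_date - one_day * 10, drug, 30))

        retained = not (single_fill or no_baseline or late_ontreat or cotherapy)
        records.append(CohortRecord(str(iid), fills, cofills, lipids, cov))
        rows.append(
            {
                "iid": str(iid),
                "single_fill": single_fill,
                "no_baseline": no_baseline,
                "late_ontreat": late_ontreat,
                "cotherapy": cotherapy,
                "expected_retained": retained,
            }
        )
    return records, pd.DataFrame(rows).set_index("iid")


# ---------------------------------------------------------------------------
# plain-text export

def write_dosages_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages, index=pd.Index(panel.ids, name="iid"),
                      columns=[v.vid for v in panel.variants])
    df.to_csv(path, sep="\t")


def write_sites_tsv(variants: Sequence[Variant], path) -> None:
    """Minimal VCF-like 5-column site table (CHROM, POS, ID, REF, ALT)."""
    pd.DataFrame(
        {
            "CHROM": [v.chrom for v in variants],
            "POS": [v.pos for v in variants],
            "ID": [v.vid for v in variants],
            "REF": [v.ref for v in variants],
            "ALT": [v.alt for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)
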