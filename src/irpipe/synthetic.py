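"""Synthetic cohorts with the statistical structure the pipeline assumes.

Every downstream stage gets a ground-truth recovery test from these
generators: correlated signature gene blocks built from a latent factor
model (loading sqrt(rho) plus independent noise, giving a closed-form
within-set correlation), exponential proportional-hazards survival with
planted group effects, preserver/reconstituter/degrader trajectory
mixtures, T-cell counts targeting requested grade prevalences, and
proteomic tables with planted associations.

All generators draw from deterministic per-generator substreams of a
single global seed, so partial pipelines are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .ihg import GRADES, IHGThresholds, assign_ihg
from .signatures import PROFILES

__all__ = [
    "SignatureSpec",
    "ProteomicSpec",
    "SimConfig",
    "SyntheticCohort",
    "gen_expression",
    "gen_survival",
    "gen_longitudinal",
    "gen_counts",
    "gen_proteomics",
    "gen_profiles",
    "calibrate_baseline_hazard",
    "simulate_cohort",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-generator RNG substream of a global seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SignatureSpec:
    """One planted signature block: n_genes sharing a latent factor."""

    name: str
    n_genes: int = 10
    rho: float = 0.5
    cluster: str = "sas"  # "sas" latents co-vary; "mas" latents are independent
    n_negative: int = 0  # genes given orientation -1

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError(f"signature {self.name!r}: n_genes must be >= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"signature {self.name!r}: rho must be in [0, 1)")
        if self.cluster not in ("sas", "mas"):
            raise ValueError(f"signature {self.name!r}: cluster must be 'sas' or 'mas'")
        if not (0 <= self.n_negative <= self.n_genes):
            raise ValueError(f"signature {self.name!r}: n_negative out of range")


@dataclass(frozen=True)
class ProteomicSpec:
    """Planted proteomic association structure.

    ``n_true_sas``/``n_true_mas`` are exclusive single-signature
    associations; ``n_shared`` proteins load on both scores; the
    remainder of ``n_proteins`` is pure noise.
    """

    n_proteins: int = 1304
    n_true_sas: int = 40
    n_true_mas: int = 30
    n_shared: int = 25
    effect: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_true_sas + self.n_true_mas + self.n_shared > self.n_proteins:
            raise ValueError("planted protein counts exceed n_proteins")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _default_signature_specs() -> tuple[SignatureSpec, ...]:
    return (
        SignatureSpec("SAS-1", 20, 0.5, "sas"),
        SignatureSpec("MAS-1", 20, 0.5, "mas"),
        SignatureSpec("IMM-AGE", 10, 0.5, "sas"),
        SignatureSpec("EL_down", 10, 0.5, "sas"),
        SignatureSpec("tTCH_high", 10, 0.5, "sas"),
        SignatureSpec("Age_IL6_up", 10, 0.5, "mas"),
        SignatureSpec("InflammDage_up", 10, 0.5, "mas"),
        SignatureSpec("SenMayo", 10, 0.5, "mas"),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic cohort."""

    n_subjects: int = 500
    seed: int = 0
    age_range: tuple[float, float] = (40.0, 92.0)
    sex_ratio: float = 0.5  # fraction female
    signature_specs: tuple[SignatureSpec, ...] = field(default_factory=_default_signature_specs)
    n_noise_genes: int = 50
    tcf7_coupling: float = 1.5  # log-odds of SAS-1 high per unit TCF7 z
    cluster_weight: float = 0.6  # loading of co-cluster latents on the SAS-1 latent
    profile_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {"H-L": 0.35, "H-H": 0.15, "L-L": 0.15, "L-H": 0.35}
    )
    age_ref: float = 40.0
    beta_age: float = 0.1467  # per-year log-hazard slope
    beta_group: Mapping[str, float] = field(
        default_factory=lambda: {"H-L": 0.0, "H-H": 0.9, "L-L": 0.9, "L-H": 2.273}
    )
    baseline_hazard: float | None = None  # None -> calibrate to target_event_fraction
    target_event_fraction: float = 0.2
    censor_horizon: float = 9.0
    trajectory_mix: Mapping[str, float] = field(
        default_factory=lambda: {"preserver": 0.4, "reconstituter": 0.3, "degrader": 0.3}
    )
    timepoints: tuple[str, ...] = ("T0", "T1", "T6")
    grade_prevalences: Mapping[str, float] = field(
        default_factory=lambda: {
            "I": 0.60, "IIa": 0.20, "IIb": 0.05, "IIc": 0.02,
            "III": 0.04, "IVa": 0.04, "IVb": 0.03, "IVc": 0.02,
        }
    )
    ihg_thresholds: IHGThresholds = field(default_factory=IHGThresholds)
    proteomic_spec: ProteomicSpec = field(default_factory=ProteomicSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be a fraction")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (low, high) with low < high")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be positive")
        if self.baseline_hazard is not None and self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        for label, frac in (("profile_prevalences", self.profile_prevalences),
                            ("trajectory_mix", self.trajectory_mix),
                            ("grade_prevalences", self.grade_prevalences)):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"{label} must sum to 1 (got {total})")
            if any(v < 0 for v in frac.values()):
                raise ValueError(f"{label} fractions must be nonnegative")
        if set(self.trajectory_mix) != {"preserver", "reconstituter", "degrader"}:
            raise ValueError("trajectory_mix must cover exactly preserver/reconstituter/degrader")
        if unknown := set(self.grade_prevalences) - set(GRADES):
            raise ValueError(f"unknown grades in grade_prevalences: {sorted(unknown)}")
        if unknown := set(self.profile_prevalences) - set(PROFILES):
            raise ValueError(f"unknown profiles in profile_prevalences: {sorted(unknown)}")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 timepoints")
        if not all(np.isfinite(list(self.beta_group.values()))) or not np.isfinite(self.beta_age):
            raise ValueError("hazard coefficients must be finite")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class ExpressionSim:
    """Expression matrix plus the latent truth that generated it."""

    expression: pd.DataFrame  # genes x samples
    latents: pd.DataFrame  # samples x signatures
    truth: pd.DataFrame  # per-sample tcf7_z, planted strata and profile


@dataclass
class SyntheticCohort:
    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    longitudinal: pd.DataFrame
    proteomics: pd.DataFrame
    truth: pd.DataFrame
    protein_truth: dict[str, frozenset]
    config: SimConfig


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:05d}" for i in range(n)]


def gen_expression(config: SimConfig, ages: np.ndarray | None = None) -> ExpressionSim:
    """Factor-model expression with planted signature blocks.

    Genes of a signature load sqrt(rho) on the signature latent plus
    independent sqrt(1-rho) noise, so the expected within-set pairwise
    correlation equals rho. All "sas"-cluster latents co-vary with the
    SAS-1 latent (loading ``cluster_weight``); "mas"-cluster latents are
    independent of it. A TCF7 gene row carries the TCF7 z-value, and the
    planted SAS-1 stratum is drawn logistically from it with slope
    ``tcf7_coupling``, making the coupling exactly recoverable from the
    truth table.
    """
    n = config.n_subjects
    samples = _sample_ids(n)
    rng = substream(config.seed, "expression")

    tcf7 = rng.standard_normal(n)
    p_high = 1.0 / (1.0 + np.exp(-config.tcf7_coupling * tcf7))
    sas_high = rng.random(n) < p_high
    # symmetric latent whose sign encodes the planted stratum exactly
    magnitude = np.abs(rng.standard_normal(n))
    sas1_latent = magnitude * np.where(sas_high, 1.0, -1.0)

    mas_anchor = rng.standard_normal(n)

    specs = config.signature_specs
    names = [s.name for s in specs]
    latents = {}
    w = config.cluster_weight
    for spec in specs:
        if spec.cluster == "sas":
            anchor = sas1_latent
        else:
            anchor = mas_anchor
        if spec.name in ("SAS-1",) and spec.cluster == "sas":
            latents[spec.name] = sas1_latent
        elif spec.name in ("MAS-1",) and spec.cluster == "mas":
            latents[spec.name] = mas_anchor
        else:
            latents[spec.name] = w * anchor + np.sqrt(1 - w**2) * rng.standard_normal(n)

    rows = []
    gene_ids = []
    for spec in specs:
        factor = latents[spec.name]
        load = np.sqrt(spec.rho)
        noise_sd = np.sqrt(1.0 - spec.rho)
        for j in range(spec.n_genes):
            orient = -1.0 if j < spec.n_negative else 1.0
            rows.append(orient * (load * factor + noise_sd * rng.standard_normal(n)))
            gene_ids.append(f"{spec.name}_g{j:03d}")
    rows.append(tcf7)
    gene_ids.append("TCF7")
    for j in range(config.n_noise_genes):
        rows.append(rng.standard_normal(n))
        gene_ids.append(f"NOISE_g{j:03d}")

    expr = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=samples)
    latents_df = pd.DataFrame(latents, index=samples)
    mas_high = latents_df["MAS-1"].to_numpy() > 0 if "MAS-1" in latents_df else np.zeros(n, bool)
    truth = pd.DataFrame(
        {
            "tcf7_z": tcf7,
            "sas1_latent": sas1_latent,
            "sas1_stratum": np.where(sas_high, "H", "L"),
            "mas1_stratum": np.where(mas_high, "H", "L"),
        },
        index=samples,
    )
    truth["profile"] = truth["sas1_stratum"].str.cat(truth["mas1_stratum"], sep="-")
    return ExpressionSim(expression=expr, latents=latents_df, truth=truth)


def gen_profiles(config: SimConfig) -> pd.Series:
    """IR profiles drawn from the configured prevalences."""
    rng = substream(config.seed, "profiles")
    labels = list(config.profile_prevalences)
    probs = np.array([config.profile_prevalences[k] for k in labels])
    draw = rng.choice(labels, size=config.n_subjects, p=probs / probs.sum())
    return pd.Series(draw, index=_sample_ids(config.n_subjects), name="profile")


def calibrate_baseline_hazard(
    linear_predictor: np.ndarray,
    horizon: float,
    target_event_fraction: float,
) -> float:
    """Baseline exponential rate giving the target pre-horizon event fraction."""
    lp = np.asarray(linear_predictor, dtype=float)

    def frac(lam: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam * np.exp(lp) * horizon)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target_event_fraction:
        hi *= 10
        if hi > 1e12:
            raise ValueError("cannot reach target event fraction")
    return float(optimize.brentq(lambda lam: frac(lam) - target_event_fraction, lo, hi))


def gen_survival(
    config: SimConfig,
    ages: np.ndarray,
    groups: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential PH event times with administrative censoring.

    Individual rate is ``lambda0 * exp(beta_age*(age - age_ref) +
    beta_group[group])``; events after ``censor_horizon`` are censored at
    the horizon. Returns ``(time, event)``.
    """
    rng = substream(config.seed, "survival")
    ages = np.asarray(ages, dtype=float)
    groups = np.asarray(groups)
    if ages.shape != groups.shape:
        raise ValueError("ages and groups differ in length")
    if unknown := set(np.unique(groups)) - set(config.beta_group):
        raise ValueError(f"groups without a beta_group entry: {sorted(unknown)}")
    offsets = np.array([config.beta_group[g] for g in groups])
    lp = config.beta_age * (ages - config.age_ref) + offsets
    lam0 = config.baseline_hazard
    if lam0 is None:
        lam0 = calibrate_baseline_hazard(lp, config.censor_horizon, config.target_event_fraction)
    if lam0 <= 0:
        raise ValueError("baseline hazard must be positive")
    raw = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    event = (raw <= config.censor_horizon).astype(int)
    time = np.minimum(raw, config.censor_horizon)
    time = np.maximum(time, 1e-9)  # invariant: time > 0
    return time, event


_NON_OPTIMAL = ("H-H", "L-L", "L-H")


def gen_longitudinal(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject ordered profile sequences by trajectory class.

    Baseline is always H-L. Preservers stay H-L; reconstituters degrade
    at one or more intermediates but finish H-L; degraders finish
    non-H-L. Returns a long-format frame (subject, timepoint, profile)
    plus the planted labels.
    """
    if len(config.timepoints) < 3:
        raise ValueError("need at least 3 timepoints")
    rng = substream(config.seed, "longitudinal")
    labels = list(config.trajectory_mix)
    probs = np.array([config.trajectory_mix[k] for k in labels])
    assigned = rng.choice(labels, size=config.n_subjects, p=probs / probs.sum())
    subjects = _sample_ids(config.n_subjects)
    tps = config.timepoints
    n_mid = len(tps) - 2

    records = []
    for subj, label in zip(subjects, assigned):
        if label == "preserver":
            profiles = ["H-L"] * len(tps)
        elif label == "reconstituter":
            mids = [str(rng.choice(_NON_OPTIMAL)) for _ in range(n_mid)]
            # guarantee at least one degraded intermediate
            if not any(m != "H-L" for m in mids):  # pragma: no cover - _NON_OPTIMAL excludes H-L
                mids[0] = "L-H"
            profiles = ["H-L", *mids, "H-L"]
        else:  # degrader
            mids = [str(rng.choice(PROFILES)) for _ in range(n_mid)]
            profiles = ["H-L", *mids, str(rng.choice(_NON_OPTIMAL))]
        for tp, prof in zip(tps, profiles):
            records.append({"subject": subj, "timepoint": tp, "profile": prof})
    long = pd.DataFrame(records)
    truth = pd.Series(assigned, index=pd.Index(subjects, name="subject"), name="trajectory")
    return long, truth


# log-space count centers per grade region, derived from the thresholds
def _grade_centers(thr: IHGThresholds) -> dict[str, tuple[float, float]]:
    a_edge, b_edge = thr.subgrade_bands
    cd4 = {
        "high": thr.cd4_high * 1.3,
        "a": (a_edge + thr.cd4_high) / 2,
        "b": (b_edge + a_edge) / 2,
        "c": b_edge * 0.6,
    }
    centers = {}
    for grade in GRADES:
        if grade == "I":
            c4 = cd4["high"]
            c8 = c4 / (thr.ratio_cutoff * 1.6)
        elif grade == "III":
            c4 = cd4["high"]
            c8 = c4 / (thr.ratio_cutoff * 0.6)
        else:
            sub = grade[-1]
            c4 = cd4[sub]
            factor = 1.6 if grade.startswith("II") else 0.6
            c8 = c4 / (thr.ratio_cutoff * factor)
        centers[grade] = (c4, c8)
    return centers


def gen_counts(
    config: SimConfig,
    locations: Mapping[str, tuple[float, float]] | None = None,
    log_sd: float = 0.3,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """CD4/CD8 counts whose grade assignment matches the target prevalences.

    Grades are drawn from ``grade_prevalences``; counts are sampled
    log-normally around per-grade centers and rejection-sampled until
    they fall in the requested grade's region, so the realized prevalence
    matches the multinomial draw exactly.
    """
    rng = substream(config.seed, "counts")
    thr = config.ihg_thresholds
    centers = dict(_grade_centers(thr))
    if locations:
        centers.update(locations)
    for grade, (c4, c8) in centers.items():
        if c4 <= 0 or c8 <= 0:
            raise ValueError(f"grade {grade}: count locations must be positive")
    labels = list(config.grade_prevalences)
    probs = np.array([config.grade_prevalences[k] for k in labels])
    assigned = rng.choice(labels, size=config.n_subjects, p=probs / probs.sum())

    cd4 = np.empty(config.n_subjects)
    cd8 = np.empty(config.n_subjects)
    for i, grade in enumerate(assigned):
        c4_loc, c8_loc = centers[grade]
        for _ in range(max_tries):
            v4 = float(np.exp(np.log(c4_loc) + log_sd * rng.standard_normal()))
            v8 = float(np.exp(np.log(c8_loc) + log_sd * rng.standard_normal()))
            if assign_ihg(v4, v8, thr) == grade:
                cd4[i], cd8[i] = v4, v8
                break
        else:
            raise RuntimeError(f"could not sample counts inside grade {grade} region")
    return pd.DataFrame(
        {"cd4": cd4, "cd8": cd8, "grade": assigned},
        index=_sample_ids(config.n_subjects),
    )


def gen_proteomics(
    config: SimConfig,
    sas_scores: pd.Series,
    mas_scores: pd.Series,
) -> tuple[pd.DataFrame, dict[str, frozenset]]:
    """Protein table with planted SAS/MAS associations.

    Returns the samples x proteins frame and truth sets
    ``{"sas": ..., "mas": ..., "shared": ...}`` (sas/mas exclusive of
    shared).
    """
    if not sas_scores.index.equals(mas_scores.index):
        raise ValueError("SAS and MAS scores are not aligned")
    spec = config.proteomic_spec
    rng = substream(config.seed, "proteomics")
    n = len(sas_scores)
    names = [f"protein_{i:04d}" for i in range(spec.n_proteins)]
    sas = sas_scores.to_numpy(dtype=float)
    mas = mas_scores.to_numpy(dtype=float)

    data = rng.normal(scale=spec.noise_sd, size=(n, spec.n_proteins))
    i0 = 0
    sas_idx = range(i0, i0 + spec.n_true_sas)
    i0 += spec.n_true_sas
    mas_idx = range(i0, i0 + spec.n_true_mas)
    i0 += spec.n_true_mas
    shared_idx = range(i0, i0 + spec.n_shared)
    for i in sas_idx:
        data[:, i] += spec.effect * sas
    for i in mas_idx:
        data[:, i] += spec.effect * mas
    for i in shared_idx:
        data[:, i] += spec.effect * (sas + mas)

    table = pd.DataFrame(data, index=sas_scores.index, columns=names)
    truth = {
        "sas": frozenset(names[i] for i in sas_idx),
        "mas": frozenset(names[i] for i in mas_idx),
        "shared": frozenset(names[i] for i in shared_idx),
    }
    return table, truth


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full cohort: expression, phenotypes, longitudinal, proteomics, truth."""
    rng = substream(config.seed, "phenotypes")
    n = config.n_subjects
    samples = _sample_ids(n)
    ages = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")

    esim = gen_expression(config, ages)
    profiles = esim.truth["profile"]
    time, event = gen_survival(config, ages, profiles.to_numpy())
    counts = gen_counts(config)
    long, traj_truth = gen_longitudinal(config)

    sas_latent = esim.latents["SAS-1"] if "SAS-1" in esim.latents else pd.Series(0.0, index=samples)
    mas_latent = esim.latents["MAS-1"] if "MAS-1" in esim.latents else pd.Series(0.0, index=samples)
    proteomics, protein_truth = gen_proteomics(config, sas_latent, mas_latent)

    phenotypes = pd.DataFrame(
        {
            "subject": samples,
            "age": ages,
            "sex": sex,
            "cd4": counts["cd4"].to_numpy(),
            "cd8": counts["cd8"].to_numpy(),
            "time": time,
            "event": event,
        }
    )
    truth = esim.truth.copy()
    truth["grade"] = counts["grade"].to_numpy()
    truth["trajectory"] = traj_truth.to_numpy()
    truth.index.name = "subject"

    for df in (esim.expression, phenotypes.drop(columns=["subject", "sex"]), proteomics):
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise AssertionError("generated output contains non-finite values")

    return SyntheticCohort(
        expression=esim.expression,
        phenotypes=phenotypes,
        longitudinal=long,
        proteomics=proteomics,
        truth=truth,
        protein_truth=protein_truth,
        config=config,
    )
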