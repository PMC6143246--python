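"""Synthetic-study generator for the biocultural blood-pressure pipeline.

The field study this package models (138 African-American adults in
Tallahassee, FL) deposited no individual-level data, so every downstream
stage is exercised on synthetic cohorts that reproduce the study's published
statistical structure:

* demographics — mean age 41 y (SD 11.9, range 25-65), 66.7 % female, BMI
  28.8 (male) / 34.2 (female) kg/m^2, 31 % on antihypertensive medication;
* genetics — Hardy–Weinberg draws from the four named ACE haplotypes
  (rs4313–rs4337–Alu), default frequencies chosen so the categorical group
  sizes approximate the published 30/17/1/90 split of 138;
* networks — 30 alters per ego with a per-ego family share ~ N(0.503, 0.255)
  truncated to [0, 1]; a latent tie is drawn per alter pair with a
  class-dependent probability (both-family / mixed / both-non-family) and the
  1-5 contact rating is then drawn conditionally on the tie (support {4, 5}
  given a tie, {1, 2, 3} otherwise) so that thresholding ratings at 4 exactly
  recovers the latent graph.  The three tie probabilities are calibrated so
  that study means of ego mean-betweenness and mean-distance land near the
  published 6.9 and 1.76;
* blood pressure — latent SBP/DBP are linear in age, BMI, sex, haplotype
  dosages, and square-root-transformed network terms with the published
  optimal-model coefficients, plus N(0, sigma) residuals; medicated
  participants' observed pressure is reduced by 10/5 mmHg so the downstream
  correction restores the model scale; three readings are emitted with
  independent per-reading noise.

Determinism: a single root seed; every stage and every ego draws from its own
counter-derived substream, so row order never changes results.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import ego_network, phenotype
from .haplotype import NAMED_HAPLOTYPES

logger = logging.getLogger(__name__)

# substream stage tags
_STAGE_DEMOGRAPHICS = 1
_STAGE_GENETICS = 2
_STAGE_NETWORK = 3
_STAGE_BP = 4

HAPLOTYPE_ORDER = ("hap1", "hap2", "hap3", "hap4")

#: published optimal-model coefficients (mmHg per unit), used as the
#: generating truth; intercepts are calibrated so that population mean
#: SBP/DBP land near 129.5 / 81.9 mmHg given the default covariate means.
DEFAULT_SBP_COEFFICIENTS = {
    "intercept": 118.3,
    "age": 0.55,
    "bmi": 0.74,
    "sex": -14.05,
    "dosage_hap2": -14.75,
    "dosage_hap3": -32.42,
    "dosage_hap4": -13.70,
    "sqrt_mean_betweenness": 2.59,
    "sqrt_pct_central_family": 9.39,
}
DEFAULT_DBP_COEFFICIENTS = {
    "intercept": 54.4,
    "age": 0.17,
    "bmi": 0.47,
    "sex": -4.59,
    "dosage_hap2": -5.52,
    "dosage_hap3": -25.34,
    "dosage_hap4": -6.28,
    "sqrt_mean_distance": 9.60,
    "sqrt_pct_family": 15.47,
}


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


def _check_prob(value, name):
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


def _check_dist(dist: Mapping, name: str, support: tuple):
    if set(dist) - set(support):
        raise ConfigurationError(f"{name}: support must be within {support}")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: probabilities sum to {total}, not 1")
    for k, v in dist.items():
        _check_prob(v, f"{name}[{k}]")


@dataclass
class GeneratorConfig:
    """All tunable study conditions; defaults reproduce the published cohort."""

    n_participants: int = 138
    seed: int = 0
    p_female: float = 0.667
    age_mean: float = 41.0
    age_sd: float = 11.9
    age_range: tuple = (25.0, 65.0)
    bmi_mean_by_sex: dict = field(default_factory=lambda: {"male": 28.8, "female": 34.2})
    bmi_sd_by_sex: dict = field(default_factory=lambda: {"male": 7.4, "female": 10.3})
    bmi_floor: float = 15.0
    p_medicated: float = 0.31
    haplotype_freqs: dict = field(default_factory=lambda: {
        "hap1": 0.15, "hap2": 0.07, "hap3": 0.005, "hap4": 0.775})
    fam_share_mean: float = 0.503
    fam_share_sd: float = 0.255
    tie_prob_within_family: float = 0.52
    tie_prob_mixed: float = 0.0003
    tie_prob_nonfamily: float = 0.265
    rating_given_tie: dict = field(default_factory=lambda: {4: 0.4, 5: 0.6})
    rating_given_no_tie: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    bp_coefficients: dict = field(default_factory=lambda: {
        "sbp": dict(DEFAULT_SBP_COEFFICIENTS),
        "dbp": dict(DEFAULT_DBP_COEFFICIENTS)})
    sigma_sbp: float = 17.0
    sigma_dbp: float = 12.0
    reading_noise_sd: float = 3.0
    n_alters: int = 30

    def validate(self) -> "GeneratorConfig":
        if self.n_participants < 1:
            raise ConfigurationError(
                f"n_participants must be >= 1, got {self.n_participants}")
        for name in ("p_female", "p_medicated", "tie_prob_within_family",
                     "tie_prob_mixed", "tie_prob_nonfamily"):
            _check_prob(getattr(self, name), name)
        _check_prob(self.fam_share_mean, "fam_share_mean")
        if self.age_sd < 0 or self.fam_share_sd < 0 or self.reading_noise_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if self.sigma_sbp < 0 or self.sigma_dbp < 0:
            raise ConfigurationError("sigma_sbp/sigma_dbp must be non-negative")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range must satisfy min < max, got {self.age_range}")
        for sex in ("male", "female"):
            if sex not in self.bmi_mean_by_sex or sex not in self.bmi_sd_by_sex:
                raise ConfigurationError(f"bmi_mean_by_sex/bmi_sd_by_sex missing {sex!r}")
        if set(self.haplotype_freqs) != set(HAPLOTYPE_ORDER):
            raise ConfigurationError(
                f"haplotype_freqs must be over {HAPLOTYPE_ORDER}")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ConfigurationError(
                f"haplotype_freqs sum to {total!r}, must be 1")
        for name, f in self.haplotype_freqs.items():
            if f < 0:
                raise ConfigurationError(f"haplotype_freqs[{name}] negative")
        _check_dist(self.rating_given_tie, "rating_given_tie", (4, 5))
        _check_dist(self.rating_given_no_tie, "rating_given_no_tie", (1, 2, 3))
        for resp in ("sbp", "dbp"):
            if resp not in self.bp_coefficients:
                raise ConfigurationError(f"bp_coefficients missing {resp!r}")
            if "intercept" not in self.bp_coefficients[resp]:
                raise ConfigurationError(f"bp_coefficients[{resp}] missing intercept")
        return self

    @classmethod
    def from_dict(cls, overrides: Mapping) -> "GeneratorConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(overrides) - known
        if bad:
            raise ConfigurationError(f"unknown configuration fields: {sorted(bad)}")
        cfg = cls(**overrides)
        if "age_range" in overrides:
            cfg.age_range = tuple(overrides["age_range"])
        return cfg.validate()


@dataclass
class SyntheticStudy:
    participants: pd.DataFrame
    alters: pd.DataFrame
    ties: pd.DataFrame
    genotypes: pd.DataFrame
    truth: dict
    config: GeneratorConfig


def _rng(seed: int, stage: int, index: int = 0) -> np.random.Generator:
    """Counter-derived substream: (root seed, stage, index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage, index]))


def _truncated_normal(u: np.ndarray, mean: float, sd: float, lo: float,
                      hi: float) -> np.ndarray:
    """Inverse-CDF truncated normal (one uniform per value, keeps counters)."""
    u = np.asarray(u, dtype=float)
    if sd == 0:
        return np.full_like(u, np.clip(mean, lo, hi))
    fa = ndtr((lo - mean) / sd) if np.isfinite(lo) else 0.0
    fb = ndtr((hi - mean) / sd) if np.isfinite(hi) else 1.0
    return mean + sd * ndtri(fa + u * (fb - fa))


def participant_ids(n: int) -> list:
    return [f"P{i:05d}" for i in range(1, n + 1)]


def generate_demographics(config: GeneratorConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Participant table: id, age, sex (male = 1, female = 2), BMI, medication."""
    config.validate()
    seed = config.seed if seed is None else seed
    n = config.n_participants
    sex = np.where(_rng(seed, _STAGE_DEMOGRAPHICS, 0).random(n) < config.p_female, 2, 1)
    lo, hi = config.age_range
    age = _truncated_normal(_rng(seed, _STAGE_DEMOGRAPHICS, 1).random(n),
                            config.age_mean, config.age_sd, lo, hi)
    u_bmi = _rng(seed, _STAGE_DEMOGRAPHICS, 2).random(n)
    bmi = np.empty(n)
    for code, label in ((1, "male"), (2, "female")):
        mask = sex == code
        bmi[mask] = _truncated_normal(u_bmi[mask], config.bmi_mean_by_sex[label],
                                      config.bmi_sd_by_sex[label],
                                      config.bmi_floor, np.inf)
    medicated = (_rng(seed, _STAGE_DEMOGRAPHICS, 3).random(n)
                 < config.p_medicated).astype(int)
    return pd.DataFrame({
        "participant_id": participant_ids(n),
        "age": np.round(age, 1),
        "sex": sex,
        "bmi": np.round(bmi, 1),
        "medicated": medicated,
    })


def sample_diplotypes(haplotype_freqs: Mapping[str, float], n: int,
                      seed: int = 0):
    """Hardy–Weinberg diplotype draws and the unphased genotypes they imply.

    Returns ``(genotypes, truth)``: the genotypes table has one unordered
    ``"X/Y"`` column per marker; truth records the two named haplotypes per
    individual (sorted) and the implied dosages of hap2-hap4.
    """
    freqs = np.array([haplotype_freqs[h] for h in HAPLOTYPE_ORDER], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-12:
        raise ConfigurationError(f"haplotype_freqs sum to {freqs.sum()!r}, must be 1")
    if (freqs < 0).any():
        raise ConfigurationError("haplotype_freqs must be non-negative")
    cum = np.cumsum(freqs)
    rng = _rng(seed, _STAGE_GENETICS, 0)
    draws = np.searchsorted(cum, rng.random((n, 2)), side="right")
    draws = np.minimum(draws, len(HAPLOTYPE_ORDER) - 1)

    alleles = np.array([NAMED_HAPLOTYPES[h] for h in HAPLOTYPE_ORDER])  # (4, 3)
    ids = participant_ids(n)
    geno_cols = {}
    for m, marker in enumerate(("rs4313", "rs4337", "ace_alu")):
        a1 = alleles[draws[:, 0], m]
        a2 = alleles[draws[:, 1], m]
        lohi = np.sort(np.stack([a1, a2]), axis=0)
        geno_cols[marker] = np.char.add(np.char.add(lohi[0], "/"), lohi[1])
    genotypes = pd.DataFrame({"participant_id": ids, **geno_cols})

    names = np.array(HAPLOTYPE_ORDER)
    pair = np.sort(names[draws], axis=1)
    truth = pd.DataFrame({"participant_id": ids,
                          "hap_a": pair[:, 0], "hap_b": pair[:, 1]})
    for h in HAPLOTYPE_ORDER[1:]:
        truth[f"dosage_{h}"] = (pair == h).sum(axis=1)
    return genotypes, truth


def _rating_from_uniform(u: np.ndarray, dist: Mapping[int, float]) -> np.ndarray:
    levels = sorted(dist)
    cum = np.cumsum([dist[l] for l in levels])
    idx = np.searchsorted(cum, u, side="right")
    return np.array(levels)[np.minimum(idx, len(levels) - 1)]


def simulate_network(config: GeneratorConfig, seed: Optional[int] = None,
                     ids: Optional[list] = None):
    """Alters and tie-rating tables for every ego.

    Per ego: a family share drawn from the truncated normal, per-alter family
    flags Bernoulli(share), then one latent tie per alter pair with the
    class-dependent probability and a rating drawn conditional on the tie.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    if ids is None:
        ids = participant_ids(config.n_participants)
    n_alt = config.n_alters
    n_ego = len(ids)
    iu, ju = np.triu_indices(n_alt, k=1)
    n_pairs = len(iu)
    rel_all = np.empty((n_ego, n_alt), dtype=np.int64)
    age_all = np.empty((n_ego, n_alt), dtype=np.int64)
    sex_all = np.empty((n_ego, n_alt), dtype=np.int64)
    tone_all = np.empty((n_ego, n_alt), dtype=np.int64)
    rating_all = np.empty((n_ego, n_pairs), dtype=np.int64)
    for e in range(n_ego):
        rng = _rng(seed, _STAGE_NETWORK, e)
        share = float(_truncated_normal(rng.random(1), config.fam_share_mean,
                                        config.fam_share_sd, 0.0, 1.0)[0])
        family = rng.random(n_alt) < share
        # pass-through alter attributes (stored, not modelled)
        age_all[e] = np.clip(np.round(rng.normal(38.4, 9.9, n_alt)), 16, 90)
        sex_all[e] = np.where(rng.random(n_alt) < 0.41, 1, 2)
        tone_all[e] = rng.integers(1, 6, n_alt)
        rel_all[e] = np.where(
            family,
            _rating_from_uniform(rng.random(n_alt), {1: 0.75, 2: 0.20, 3: 0.05}),
            rng.integers(4, 12, n_alt))
        both_fam = family[iu] & family[ju]
        both_non = ~family[iu] & ~family[ju]
        p_tie = np.where(both_fam, config.tie_prob_within_family,
                         np.where(both_non, config.tie_prob_nonfamily,
                                  config.tie_prob_mixed))
        tied = rng.random(n_pairs) < p_tie
        u = rng.random(n_pairs)
        rating_all[e] = np.where(
            tied, _rating_from_uniform(u, config.rating_given_tie),
            _rating_from_uniform(u, config.rating_given_no_tie))
    ids_arr = np.asarray(ids, dtype=object)
    alters = pd.DataFrame({
        "participant_id": np.repeat(ids_arr, n_alt),
        "alter_index": np.tile(np.arange(n_alt), n_ego),
        "relationship_codes": rel_all.ravel().astype(str),
        "alter_age": age_all.ravel(),
        "alter_sex": sex_all.ravel(),
        "skin_tone": tone_all.ravel(),
    })
    ties = pd.DataFrame({
        "participant_id": np.repeat(ids_arr, n_pairs),
        "alter_i": np.tile(iu, n_ego),
        "alter_j": np.tile(ju, n_ego),
        "rating": rating_all.ravel(),
    })
    return alters, ties


def linear_predictor(table: pd.DataFrame, coefficients: Mapping[str, float]) -> np.ndarray:
    """Intercept + sum of coefficient * column over the coefficient terms."""
    eta = np.full(len(table), float(coefficients["intercept"]))
    for term, coef in coefficients.items():
        if term == "intercept":
            continue
        if term not in table.columns:
            raise ConfigurationError(f"model term {term!r} missing from table")
        col = table[term].to_numpy(dtype=float)
        if np.isnan(col).any():
            pid = table.loc[np.isnan(col), "participant_id"].iloc[0]
            raise ConfigurationError(
                f"participant {pid}: missing value for model term {term!r}")
        eta = eta + coef * col
    return eta


def simulate_bp(terms_table: pd.DataFrame, config: GeneratorConfig,
                seed: Optional[int] = None):
    """Latent and observed BP readings for each participant.

    ``terms_table`` must contain ``participant_id``, ``medicated`` and every
    term named by the configured coefficients.  Returns ``(readings, latent)``
    where readings has ``sbp1..sbp3, dbp1..dbp3`` and latent the noiseless
    linear predictors plus residuals (the generating scale the +10/+5
    correction restores).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    n = len(terms_table)
    # separate substreams per noise source: row k depends only on (seed, k)
    latent_sbp = (linear_predictor(terms_table, config.bp_coefficients["sbp"])
                  + _rng(seed, _STAGE_BP, 0).normal(0.0, config.sigma_sbp, n))
    latent_dbp = (linear_predictor(terms_table, config.bp_coefficients["dbp"])
                  + _rng(seed, _STAGE_BP, 1).normal(0.0, config.sigma_dbp, n))
    med = terms_table["medicated"].to_numpy(dtype=bool)
    obs_sbp = latent_sbp - np.where(med, phenotype.SBP_MED_OFFSET, 0.0)
    obs_dbp = latent_dbp - np.where(med, phenotype.DBP_MED_OFFSET, 0.0)
    noise = _rng(seed, _STAGE_BP, 2).normal(0.0, config.reading_noise_sd, (n, 6))
    readings = pd.DataFrame({"participant_id": terms_table["participant_id"]})
    for r in range(3):
        readings[f"sbp{r + 1}"] = np.round(obs_sbp + noise[:, r], 1)
    for r in range(3):
        readings[f"dbp{r + 1}"] = np.round(obs_dbp + noise[:, 3 + r], 1)
    latent = pd.DataFrame({"participant_id": terms_table["participant_id"],
                           "latent_sbp": latent_sbp, "latent_dbp": latent_dbp})
    return readings, latent


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Full synthetic study: demographics, genetics, networks, BP readings.

    The hidden truth carries the generating coefficients, true diplotypes and
    dosages, the latent (pre-noise, medication-restored) pressures, and the
    per-ego network measures computed on the latent graphs.
    """
    config.validate()
    seed = config.seed
    participants = generate_demographics(config, seed)
    genotypes, dip_truth = sample_diplotypes(config.haplotype_freqs,
                                             config.n_participants, seed)
    alters, ties = simulate_network(config, seed, list(participants["participant_id"]))
    measures = ego_network.compute_measures_table(ties, alters)
    transformed = phenotype.transform_for_model(
        measures[["participant_id", "mean_betweenness", "mean_distance",
                  "pct_family", "pct_central_family"]].copy())
    terms = (participants.merge(dip_truth, on="participant_id")
             .merge(transformed, on="participant_id"))
    readings, latent = simulate_bp(terms, config, seed)
    participants = participants.merge(readings, on="participant_id")
    truth = {
        "coefficients": {r: dict(config.bp_coefficients[r]) for r in ("sbp", "dbp")},
        "diplotypes": dip_truth,
        "latent_bp": latent,
        "measures": measures,
    }
    return SyntheticStudy(participants=participants, alters=alters, ties=ties,
                          genotypes=genotypes, truth=truth, config=config)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the four CSV tables plus truth.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.participants.to_csv(outdir / "participants.csv", index=False)
    study.alters.to_csv(outdir / "alters.csv", index=False)
    study.ties.to_csv(outdir / "ties.csv", index=False)
    study.genotypes.to_csv(outdir / "genotypes.csv", index=False)
    truth = {
        "coefficients": study.truth["coefficients"],
        "diplotypes": study.truth["diplotypes"].to_dict(orient="records"),
        "latent_bp": study.truth["latent_bp"].round(4).to_dict(orient="records"),
        "seed": study.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    logger.info("wrote synthetic study (n=%d) to %s", len(study.participants), outdir)
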