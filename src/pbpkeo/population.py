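"""Virtual patient populations and synthetic "observed" PK datasets.

Between-subject variability is applied as independent log-normal multipliers
on {hepatic CLint, Peff, brain passive PS, ABCB1 activity, albumin}.  The
source model used a proprietary population algorithm whose internals are not
published; the CV defaults here are surrogate behaviour chosen once so that
simulated steady-state exposure spreads match the published population CV%
(~34–46 % on AUC/Ctrough).  Every subject is reproducible from
(population seed, subject id).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .pbpk import MEAN_SUBJECT, VirtualSubject

#: default between-subject CVs (fractions); chosen once, see methods note
DEFAULT_VARIABILITY = {
    "hepatic_clint_mult": 0.35,
    "peff_mult": 0.30,
    "brain_ps_mult": 0.30,
    "abcb1_mult": 0.30,
    "albumin_fold": 0.10,
    "body_weight": 0.15,
}


@dataclass(frozen=True)
class Demographics:
    study: str
    race_population: str
    dose_mg: float
    n_subjects: int
    age_range: str = ""
    proportion_female: float = 0.5
    bmi_or_weight: str = ""
    albumin_g_dl: float | None = None   # None = not reported; patient mean used

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.proportion_female <= 1.0):
            raise ValueError("proportion_female must be in [0,1]")


def load_demographics(path: str | Path | None = None) -> dict:
    """Digitized study demographics keyed by study label."""
    p = Path(path) if path else Path(str(resources.files("pbpkeo").joinpath(
        "data", "table2_demographics.csv")))
    df = pd.read_csv(p)
    out = {}
    for _, row in df.iterrows():
        dose = str(row["dose_mg"]).split(";")[0]
        alb = row.get("albumin_g_dL")
        alb_val = None
        if isinstance(alb, str) and "-" in alb:
            lo, hi = (float(x) for x in alb.split("-"))
            alb_val = (lo + hi) / 2.0
        elif pd.notna(alb):
            alb_val = float(alb)
        out[row["study"]] = Demographics(
            study=row["study"], race_population=row["race_population"],
            dose_mg=float(dose), n_subjects=int(row["n_subjects"]),
            age_range=str(row["age_range_yr"]),
            proportion_female=float(row["proportion_female_pct"]) / 100.0,
            bmi_or_weight=str(row.get("bmi_or_weight", "")),
            albumin_g_dl=alb_val,
        )
    return out


def _lognormal_mult(rng: np.random.Generator, cv: float) -> float:
    """Unit-median log-normal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    return float(np.exp(rng.normal(0.0, sigma)))


def sample_population(demographics: Demographics | None, n: int, seed: int,
                      variability: dict | None = None,
                      base_subject: VirtualSubject = MEAN_SUBJECT) -> list[VirtualSubject]:
    """Draw ``n`` virtual subjects; deterministic under a fixed seed.

    Each subject gets its own child generator spawned from (seed, id), so a
    population is reproducible subject-by-subject.  All CVs zero reproduces
    the mean subject exactly.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    cvs = dict(DEFAULT_VARIABILITY)
    if variability:
        cvs.update(variability)
    subjects = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        subjects.append(replace(
            base_subject,
            subject_id=i,
            body_weight=base_subject.body_weight * _lognormal_mult(rng, cvs["body_weight"]),
            albumin_fold=base_subject.albumin_fold * _lognormal_mult(rng, cvs["albumin_fold"]),
            hepatic_clint_mult=_lognormal_mult(rng, cvs["hepatic_clint_mult"]),
            peff_mult=_lognormal_mult(rng, cvs["peff_mult"]),
            brain_ps_mult=_lognormal_mult(rng, cvs["brain_ps_mult"]),
            abcb1_mult=_lognormal_mult(rng, cvs["abcb1_mult"]),
            seed_provenance=(int(seed), i),
        ))
    return subjects


def population_to_frame(subjects: list[VirtualSubject]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": s.subject_id, "body_weight_kg": s.body_weight,
        "albumin_fold": s.albumin_fold, "hematocrit": s.hematocrit,
        "hepatic_clint_mult": s.hepatic_clint_mult, "peff_mult": s.peff_mult,
        "brain_ps_mult": s.brain_ps_mult, "abcb1_mult": s.abcb1_mult,
        "seed": str(s.seed_provenance),
    } for s in subjects])


@dataclass
class SyntheticPKDataset:
    """Noisy observations around a known-truth model prediction."""
    time_h: np.ndarray
    true_concentrations: np.ndarray      # nmol/L, noiseless model output
    observed_concentrations: np.ndarray  # nmol/L, multiplicative log-normal noise
    noise_cv: float
    seed: int
    true_parameters: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)


def generate_synthetic_observed(time_h: np.ndarray, predictions_nmol_l: np.ndarray,
                                noise_cv: float, seed: int,
                                true_parameters: dict | None = None,
                                design: dict | None = None) -> SyntheticPKDataset:
    """observations = prediction × exp(ε), ε ~ N(0, σ²) with σ matching the CV."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(int(seed))
    sigma = np.sqrt(np.log(1.0 + noise_cv * noise_cv))
    eps = rng.normal(0.0, sigma, size=len(predictions_nmol_l)) if noise_cv > 0 \
        else np.zeros(len(predictions_nmol_l))
    return SyntheticPKDataset(
        time_h=np.asarray(time_h, float),
        true_concentrations=np.asarray(predictions_nmol_l, float),
        observed_concentrations=np.asarray(predictions_nmol_l, float) * np.exp(eps),
        noise_cv=noise_cv, seed=int(seed),
        true_parameters=dict(true_parameters or {}), design=dict(design or {}),
    )
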