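"""Validated configuration objects for linkage and simulation runs.

Configs are plain YAML on disk; unknown keys and out-of-range values are
rejected with every violation listed.  An empty config yields the full
packaged defaults: the maternal cutoff of 40 and infant cutoff of 31, the
maternal pass schedule A-F, and the infant schedule A-I (with the repeat
passes that pick up duplicate records for twins and higher multiples).
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "BlockingPass",
    "LinkageConfig",
    "ConditionModel",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "default_maternal_passes",
    "default_infant_passes",
]

_BLOCK_KEYS = ("mother_dob", "infant_dob", "hospital", "zip", "sex",
               "payer", "preterm")


class ConfigError(ValueError):
    """Configuration failed validation; the message lists every violation."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BlockingPass(_Model):
    """One blocking round: a label and the exact-agreement key set.

    ``dedup_repeat`` marks infant passes that repeat an earlier key set so
    the remaining records of a twin or higher-multiple delivery can link
    to the duplicate hospital records.
    """

    label: str
    keys: tuple[str, ...] = Field(min_length=1)
    dedup_repeat: bool = False

    @model_validator(mode="after")
    def _check_keys(self):
        bad = [k for k in self.keys if k not in _BLOCK_KEYS]
        if bad:
            raise ValueError(f"unknown blocking keys {bad}; valid: {_BLOCK_KEYS}")
        return self


def default_maternal_passes() -> list[BlockingPass]:
    """Maternal schedule A-F.

    The published schedule labels two passes "C"; they are relabeled C and
    D here (order preserved), shifting the remaining labels accordingly.
    Pass F blocks on a preterm indicator (<37 wk on both sides) together
    with the infant's date of birth.
    """
    return [
        BlockingPass(label="A", keys=("mother_dob", "hospital")),
        BlockingPass(label="B", keys=("infant_dob", "zip")),
        BlockingPass(label="C", keys=("infant_dob", "hospital")),
        BlockingPass(label="D", keys=("mother_dob", "zip")),
        BlockingPass(label="E", keys=("zip", "hospital")),
        BlockingPass(label="F", keys=("preterm", "infant_dob")),
    ]


def default_infant_passes() -> list[BlockingPass]:
    """Infant schedule A-I (B-D repeat A; F repeats E, for multiples)."""
    return [
        BlockingPass(label="A", keys=("hospital", "infant_dob")),
        BlockingPass(label="B", keys=("hospital", "infant_dob"), dedup_repeat=True),
        BlockingPass(label="C", keys=("hospital", "infant_dob"), dedup_repeat=True),
        BlockingPass(label="D", keys=("hospital", "infant_dob"), dedup_repeat=True),
        BlockingPass(label="E", keys=("infant_dob", "zip")),
        BlockingPass(label="F", keys=("infant_dob", "zip"), dedup_repeat=True),
        BlockingPass(label="G", keys=("zip", "sex")),
        BlockingPass(label="H", keys=("zip", "payer")),
        BlockingPass(label="I", keys=("zip", "hospital")),
    ]


class LinkageConfig(_Model):
    """Linkage parameters: cutoffs, pass schedules, tie-break seed."""

    mother_cutoff: int = Field(default=40, gt=0)
    infant_cutoff: int = Field(default=31, gt=0)
    rng_seed: int = 0
    maternal_passes: list[BlockingPass] = Field(default_factory=default_maternal_passes)
    infant_passes: list[BlockingPass] = Field(default_factory=default_infant_passes)
    require_plurality_concordance: bool = True
    ssn_requires_extra_variable: bool = True
    longitudinal_cutoff: int = Field(default=20, gt=0)
    longitudinal_window_days: int = Field(default=365, gt=0)

    @model_validator(mode="after")
    def _check_labels(self):
        for side, passes in (("maternal", self.maternal_passes),
                             ("infant", self.infant_passes)):
            labels = [p.label for p in passes]
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {side} pass labels: {labels}")
        return self


class ConditionModel(_Model):
    """One condition's true prevalence and per-source recording sensitivity.

    ``prevalence`` is the underlying cohort rate; ``sens_vs`` and
    ``sens_hospital`` are the independent probabilities that a truly present
    condition is recorded on the certificate and on the hospital abstract
    respectively — the mechanism behind dual-source ascertainment gain.
    """

    prevalence: float = Field(ge=0, le=1)
    sens_vs: float = Field(default=0.5, ge=0, le=1)
    sens_hospital: float = Field(default=0.85, ge=0, le=1)


def _default_conditions() -> dict[str, ConditionModel]:
    # Magnitudes are plausible for a contemporary US birth cohort but are
    # deliberately round and NOT calibrated to any published table.
    raw = {
        "gestational_diabetes": (0.095, 0.48, 0.88),
        "preexisting_diabetes": (0.018, 0.39, 0.77),
        "prepregnancy_hypertension": (0.017, 0.38, 0.82),
        "gestational_hypertension": (0.070, 0.40, 0.90),
        "eclampsia": (0.0016, 0.49, 0.56),
        "placental_abruption": (0.011, 0.32, 0.89),
        "chorioamnionitis": (0.026, 0.21, 0.97),
        "neural_tube_defect": (0.0005, 0.21, 0.92),
        "gastroschisis_omphalocele": (0.0009, 0.20, 0.95),
        "cleft_lip_palate": (0.0022, 0.19, 0.88),
        "major_heart_defect": (0.0039, 0.04, 0.98),
    }
    return {name: ConditionModel(prevalence=p, sens_vs=sv, sens_hospital=sh)
            for name, (p, sv, sh) in raw.items()}


class SimulationConfig(_Model):
    """Parameters of the ground-truthed synthetic cohort generator.

    Rates follow the broad magnitudes of a large contemporary US state
    birth cohort: a twin rate near 3%, fetal deaths near 0.55% of
    deliveries, about 89% of births at term, encrypted SSNs on roughly
    80% of maternal and well under 10% of infant hospital records, and a
    few percent of episodes withheld per side so that some records have no
    counterpart to link.  Error probabilities (date transposition, field
    deletion, zip typos) apply independently per episode and field.
    """

    n_deliveries: int = Field(default=1000, gt=0)
    year_start: int = 2005
    year_end: int = 2020
    rng_seed: int = 0

    twin_rate: float = Field(default=0.0303, ge=0, le=1)
    higher_multiple_rate: float = Field(default=0.0011, ge=0, le=1)
    fetal_death_rate: float = Field(default=0.0055, ge=0, le=1)
    infant_death_rate: float = Field(default=0.0035, ge=0, le=1)
    cesarean_rate: float = Field(default=0.32, ge=0, le=1)
    previous_cesarean_rate: float = Field(default=0.14, ge=0, le=1)

    # Gestational-age strata of the delivered cohort (weeks; "missing" is
    # an unrecorded gestational age on the certificate).
    ga_band_probs: dict[str, float] = Field(default_factory=lambda: {
        "20-27": 0.0053, "28-31": 0.0081, "32-36": 0.0757,
        "37-42": 0.8918, "43-44": 0.0113, "missing": 0.0078})
    payer_probs: dict[str, float] = Field(default_factory=lambda: {
        "private": 0.4762, "public": 0.4476, "self_pay": 0.0303,
        "other": 0.0441, "unknown": 0.0018})
    race_probs: dict[str, float] = Field(default_factory=lambda: {
        "amer_indian_alaska_native": 0.0034, "asian": 0.1314, "black": 0.0512,
        "hawaiian_pacific_islander": 0.0041, "hispanic": 0.4864,
        "white_nh": 0.2786, "other": 0.0006, "multiple": 0.0208,
        "unknown": 0.0235})
    education_probs: dict[str, float] = Field(default_factory=lambda: {
        "lt12": 0.1994, "12": 0.2438, "gt12": 0.5127, "unknown": 0.0441})
    age_band_probs: dict[str, float] = Field(default_factory=lambda: {
        "lt18": 0.0210, "18to34": 0.7787, "gt34": 0.2001, "missing": 0.0002})

    conditions: dict[str, ConditionModel] = Field(default_factory=_default_conditions)

    n_hospitals: int = Field(default=25, gt=0)
    n_zips: int = Field(default=150, gt=0)
    n_counties: int = Field(default=15, gt=0)

    p_mother_unlinked: float = Field(default=0.076, ge=0, le=1)
    p_infant_unlinked: float = Field(default=0.045, ge=0, le=1)
    # Optional per-payer multiplier on the withholding probabilities, to
    # reproduce differential linkability across strata.
    withholding_payer_multiplier: Optional[dict[str, float]] = None

    p_dob_transposed: float = Field(default=0.02, ge=0, le=1)
    p_field_missing: float = Field(default=0.03, ge=0, le=1)
    p_zip_error: float = Field(default=0.02, ge=0, le=1)

    enc_ssn_mother: float = Field(default=0.80, ge=0, le=1)
    enc_ssn_infant: float = Field(default=0.05, ge=0, le=1)

    p_extra_episode_mother: float = Field(default=0.20, ge=0, le=1)
    p_extra_episode_infant: float = Field(default=0.10, ge=0, le=1)
    p_extra_outside_window: float = Field(default=0.10, ge=0, le=1)

    @model_validator(mode="after")
    def _check_probs(self):
        if self.twin_rate + self.higher_multiple_rate > 1:
            raise ValueError("twin_rate + higher_multiple_rate exceeds 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end before year_start")
        for name in ("ga_band_probs", "payer_probs", "race_probs",
                     "education_probs", "age_band_probs"):
            probs = getattr(self, name)
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name}: negative probability")
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name}: probabilities must sum to 1")
        return self


def load_config(path, kind: Literal["linkage", "simulation"]):
    """Load and validate a YAML config; empty files yield full defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    model = {"linkage": LinkageConfig, "simulation": SimulationConfig}[kind]
    try:
        return model.model_validate(raw)
    except ValidationError as exc:
        lines = [f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                 for err in exc.errors()]
        raise ConfigError(f"{path}: invalid {kind} config:\n  " + "\n  ".join(lines)) from exc
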