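"""Seeded synthetic cohorts with the structure of the observational CP study.

The generator emulates a prospective cohort of children with cerebral palsy
(CP) followed for 12 months: a treatment arm receiving standard care plus
Intensive and Emerging Rehabilitation Therapies (IERT) and a comparator arm on
standard care alone.  Within the treatment arm each child receives at most one
Intensive therapy (speech / physiotherapy / occupational) and at most one
Emerging therapy (hippotherapy / Therasuit / Peto method / homeopathy) --
overlap between the two subgroups is allowed, overlap within a subgroup is not.

Ground truth is known by construction, which is what makes the cohort useful
for estimator testing:

* per-child bivariate Gaussian disturbances (cost, effect) with configured
  standard deviations and correlation, shared between the cost and utility
  constructions;
* utility trajectory u0/u6/u12 built so that the AUC QALY of a treated child
  exceeds the counterfactual untreated QALY by exactly the configured
  per-therapy QALY increments (before truncation at full health);
* annual cost = public baseline + configured per-therapy cost increments.

Allocation (arm sizes, GMFCS distribution per arm, therapy counts, age/sex
bins) is exact and deterministic; only outcomes are stochastic.  The same seed
always yields a byte-identical table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

IRT_THERAPIES = ("speech", "physio", "occupational")
ERT_THERAPIES = ("hippotherapy", "therasuit", "peto", "homeopathy")
THERAPIES = IRT_THERAPIES + ERT_THERAPIES

GROUP_TREATMENT = "IERT_ST"
GROUP_CONTROL = "ST"

#: Exact CSV column order of the cohort table.
COHORT_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "gmfcs",
    "group",
    *THERAPIES,
    "u0",
    "u6",
    "u12",
    "cost_public",
    "cost_iert",
    "cost_total",
    "completed_followup",
]

# Age bins used for the cosmetic age covariate: (low, high, count per arm).
_AGE_BINS = ((3, 6), (7, 12), (13, 18))
_AGE_BIN_COUNTS_TREATMENT = (24, 39, 29)
_AGE_BIN_COUNTS_CONTROL = (21, 21, 14)
_SEX_COUNTS_TREATMENT = {"F": 46, "M": 46}
_SEX_COUNTS_CONTROL = {"F": 24, "M": 32}

# Standard-care annual cost breakdown (EUR) used as the default category
# profile: GP care, specialist care, diagnostic tests, hospitalisation,
# medication, standard therapies.
DEFAULT_COST_CATEGORY_PROFILE = {
    "general_practitioner": 47.0,
    "specialist": 196.0,
    "diagnostic_tests": 222.0,
    "hospitalisation": 643.0,
    "medication": 878.0,
    "standard_therapies": 3170.0,
}


def _default_irt_assignment() -> dict[str, int]:
    return {"speech": 42, "physio": 39, "occupational": 11}


def _default_ert_assignment() -> dict[str, int]:
    return {"hippotherapy": 15, "therasuit": 32, "peto": 34, "homeopathy": 6}


def _default_cost_increments() -> dict[str, float]:
    # Per-therapy annual incremental cost versus standard care (EUR), on the
    # system-specific cost outcome scale of the short-term regressions.
    return {
        "speech": 7997.73,
        "physio": 6863.01,
        "occupational": 9258.25,
        "hippotherapy": 5130.24,
        "therasuit": 4193.84,
        "peto": 4338.16,
        "homeopathy": 4898.51,
    }


def _default_effect_increments() -> dict[str, float]:
    # Per-therapy 12-month QALY increment versus standard care.
    return {
        "speech": -0.081,
        "physio": 0.216,
        "occupational": -0.067,
        "hippotherapy": -0.046,
        "therasuit": 0.222,
        "peto": 0.066,
        "homeopathy": 0.058,
    }


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Defaults reproduce the study conditions: 148 children split 92/56 between
    the IERT+standard-care and standard-care arms, GMFCS level counts
    24/35/29/21/39 with the severer levels concentrated in the treatment arm,
    exactly-one-therapy-per-subgroup assignment, and cost/effect increments on
    the scale of the short-term regression coefficients.
    """

    n_total: int = 148
    n_treatment_group: int = 92
    gmfcs_counts: tuple[int, ...] = (24, 35, 29, 21, 39)
    #: GMFCS counts within the treatment arm (levels I..V); the control arm
    #: receives the remainder.  Default reflects the observed severity
    #: imbalance (severer children more often in the treatment arm).
    gmfcs_counts_treatment: tuple[int, ...] = (7, 16, 20, 18, 31)
    irt_assignment: dict[str, int] = field(default_factory=_default_irt_assignment)
    ert_assignment: dict[str, int] = field(default_factory=_default_ert_assignment)
    baseline_utility_mean: float = 0.517
    #: Baseline-utility offsets by GMFCS level (I..V), re-centred internally so
    #: the population mean equals ``baseline_utility_mean``.  Monotone
    #: decreasing: severer motor impairment, lower utility.  Set all-zero to
    #: remove the GMFCS-utility gradient (useful for estimator-recovery
    #: experiments free of severity confounding).
    gmfcs_utility_offsets: tuple[float, ...] = (0.20, 0.10, 0.0, -0.10, -0.20)
    baseline_cost_mean: float = 5156.48
    cost_category_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COST_CATEGORY_PROFILE)
    )
    therapy_cost_increments: dict[str, float] = field(
        default_factory=_default_cost_increments
    )
    therapy_effect_increments: dict[str, float] = field(
        default_factory=_default_effect_increments
    )
    error_sd_cost: float = 2650.0
    error_sd_effect: float = 0.20
    error_correlation: float = 0.3
    dropout_count: int = 5
    seed: int = 20230901

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if self.n_total < 1:
            raise ConfigError("n_total must be >= 1")
        if not 0 <= self.n_treatment_group <= self.n_total:
            raise ConfigError(
                f"n_treatment_group = {self.n_treatment_group} must lie in "
                f"[0, n_total = {self.n_total}]"
            )
        if len(self.gmfcs_counts) != 5 or any(c < 0 for c in self.gmfcs_counts):
            raise ConfigError("gmfcs_counts must be 5 non-negative counts (levels I-V)")
        if sum(self.gmfcs_counts) != self.n_total:
            raise ConfigError(
                f"gmfcs_counts sum to {sum(self.gmfcs_counts)}, expected n_total = "
                f"{self.n_total}"
            )
        if len(self.gmfcs_counts_treatment) != 5 or any(
            c < 0 for c in self.gmfcs_counts_treatment
        ):
            raise ConfigError("gmfcs_counts_treatment must be 5 non-negative counts")
        if sum(self.gmfcs_counts_treatment) != self.n_treatment_group:
            raise ConfigError(
                "gmfcs_counts_treatment must sum to n_treatment_group "
                f"({self.n_treatment_group})"
            )
        if any(
            t > c for t, c in zip(self.gmfcs_counts_treatment, self.gmfcs_counts)
        ):
            raise ConfigError(
                "gmfcs_counts_treatment exceeds gmfcs_counts for some level"
            )
        for name, mapping, allowed in (
            ("irt_assignment", self.irt_assignment, IRT_THERAPIES),
            ("ert_assignment", self.ert_assignment, ERT_THERAPIES),
        ):
            unknown = set(mapping) - set(allowed)
            if unknown:
                raise ConfigError(f"{name} has unknown therapies {sorted(unknown)}")
            if any(v < 0 for v in mapping.values()):
                raise ConfigError(f"{name} counts must be non-negative")
            if sum(mapping.values()) > self.n_treatment_group:
                raise ConfigError(
                    f"{name} counts sum to {sum(mapping.values())}, exceeding the "
                    f"treatment-group size {self.n_treatment_group}"
                )
        if len(self.gmfcs_utility_offsets) != 5:
            raise ConfigError("gmfcs_utility_offsets must have 5 entries (levels I-V)")
        if self.error_sd_cost < 0:
            raise ConfigError("error_sd_cost must be >= 0")
        if self.error_sd_effect < 0:
            raise ConfigError("error_sd_effect must be >= 0")
        if not -1.0 <= self.error_correlation <= 1.0:
            raise ConfigError("error_correlation must lie in [-1, 1]")
        if self.baseline_cost_mean < 0:
            raise ConfigError("baseline_cost_mean must be >= 0")
        if self.dropout_count < 0:
            raise ConfigError("dropout_count must be >= 0")
        if self.dropout_count > sum(self.ert_assignment.values()):
            raise ConfigError(
                f"dropout_count = {self.dropout_count} exceeds the ERT subgroup size "
                f"{sum(self.ert_assignment.values())}"
            )

    # -- helpers ------------------------------------------------------------

    def scaled(self, factor: int) -> "CohortConfig":
        """Return a copy with all allocation counts multiplied by ``factor``.

        Used for Monte Carlo calibration experiments at larger n.
        """
        if factor < 1:
            raise ConfigError("scale factor must be >= 1")
        return dataclasses.replace(
            self,
            n_total=self.n_total * factor,
            n_treatment_group=self.n_treatment_group * factor,
            gmfcs_counts=tuple(c * factor for c in self.gmfcs_counts),
            gmfcs_counts_treatment=tuple(
                c * factor for c in self.gmfcs_counts_treatment
            ),
            irt_assignment={k: v * factor for k, v in self.irt_assignment.items()},
            ert_assignment={k: v * factor for k, v in self.ert_assignment.items()},
            dropout_count=self.dropout_count * factor,
        )

    def centred_gmfcs_offsets(self) -> np.ndarray:
        """GMFCS utility offsets re-centred to the configured level weights."""
        offsets = np.asarray(self.gmfcs_utility_offsets, dtype=float)
        weights = np.asarray(self.gmfcs_counts, dtype=float)
        if weights.sum() == 0:
            return offsets
        return offsets - float(offsets @ weights / weights.sum())


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("allocation", "outcomes", "covariates", "dropout")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _labels_from_counts(
    counts: Mapping[str, int], total: int, filler: str | None = None
) -> list[str | None]:
    labels: list[str | None] = []
    for name, count in counts.items():
        labels.extend([name] * count)
    labels.extend([filler] * (total - len(labels)))
    return labels


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    Returns a DataFrame with the columns of :data:`COHORT_COLUMNS` (all
    follow-up flags set to 1; apply :func:`apply_dropout` afterwards).  The
    record-level generating truth is attached as ``df.attrs["truth"]`` -- a
    DataFrame with the drawn disturbances (``e_cost``, ``e_effect``), the
    pre-truncation QALY and the per-child true cost/QALY increments -- and the
    config as ``df.attrs["config"]``.
    """
    config = config or CohortConfig()
    config.validate()
    rngs = _spawn_rngs(config.seed)
    n = config.n_total
    n_t = config.n_treatment_group
    n_c = n - n_t

    group = np.array([GROUP_TREATMENT] * n_t + [GROUP_CONTROL] * n_c)

    # GMFCS levels 1..5, allocated in deterministic blocks within each arm.
    gmfcs_t = np.repeat(np.arange(1, 6), config.gmfcs_counts_treatment)
    counts_control = tuple(
        tot - t for tot, t in zip(config.gmfcs_counts, config.gmfcs_counts_treatment)
    )
    gmfcs_c = np.repeat(np.arange(1, 6), counts_control)
    gmfcs = np.concatenate([gmfcs_t, gmfcs_c])

    # Therapy labels: exact counts, randomly matched to treatment-arm children
    # so therapy is independent of GMFCS within the arm.
    irt_labels = _labels_from_counts(config.irt_assignment, n_t)
    ert_labels = _labels_from_counts(config.ert_assignment, n_t)
    rngs["allocation"].shuffle(irt_labels)
    rngs["allocation"].shuffle(ert_labels)

    flags = {t: np.zeros(n, dtype=int) for t in THERAPIES}
    for i, (irt, ert) in enumerate(zip(irt_labels, ert_labels)):
        if irt is not None:
            flags[irt][i] = 1
        if ert is not None:
            flags[ert][i] = 1

    # Cosmetic covariates: ages uniform within per-arm bins, sex counts exact.
    def _ages(bin_counts: Sequence[int], size: int) -> np.ndarray:
        counts = list(bin_counts)
        # Rescale the default bin counts if the arm size differs (scaled configs).
        if sum(counts) != size:
            total = sum(counts)
            counts = [c * size // total for c in counts]
            counts[-1] += size - sum(counts)
        ages = np.concatenate(
            [
                rngs["covariates"].integers(lo, hi + 1, size=c)
                for (lo, hi), c in zip(_AGE_BINS, counts)
            ]
        )
        rngs["covariates"].shuffle(ages)
        return ages

    def _sexes(sex_counts: Mapping[str, int], size: int) -> np.ndarray:
        n_f = sex_counts["F"] * size // sum(sex_counts.values())
        sexes = np.array(["F"] * n_f + ["M"] * (size - n_f))
        rngs["covariates"].shuffle(sexes)
        return sexes

    age = np.concatenate(
        [_ages(_AGE_BIN_COUNTS_TREATMENT, n_t), _ages(_AGE_BIN_COUNTS_CONTROL, n_c)]
    )
    sex = np.concatenate(
        [_sexes(_SEX_COUNTS_TREATMENT, n_t), _sexes(_SEX_COUNTS_CONTROL, n_c)]
    )

    # Bivariate Gaussian disturbances shared across the cost and utility
    # constructions (Cholesky of the configured 2x2 covariance).
    rho = config.error_correlation
    z = rngs["outcomes"].standard_normal((2, n))
    e_cost = config.error_sd_cost * z[0]
    e_effect = config.error_sd_effect * (rho * z[0] + np.sqrt(1 - rho**2) * z[1])

    # True per-child increments: sum of configured increments over flagged
    # therapies (a child may combine one IRT and one ERT therapy).
    delta_cost = np.zeros(n)
    delta_qaly = np.zeros(n)
    for t in THERAPIES:
        delta_cost += flags[t] * config.therapy_cost_increments.get(t, 0.0)
        delta_qaly += flags[t] * config.therapy_effect_increments.get(t, 0.0)

    # Utility trajectory.  The child-level utility plateau is the GMFCS-specific
    # baseline plus the effect disturbance; the therapy effect ramps linearly
    # (half at 6 months, full at 12), so the AUC QALY gain equals the configured
    # QALY increment: with u6 = u0 + d and u12 = u0 + 2d, QALY = u0 + d.
    offsets = config.centred_gmfcs_offsets()
    level = config.baseline_utility_mean + offsets[gmfcs - 1] + e_effect
    u0 = level
    u6 = level + delta_qaly
    u12 = level + 2.0 * delta_qaly
    qaly_true = level + delta_qaly  # pre-truncation AUC
    # EQ-5D-Y utilities are bounded above by full health.
    u0, u6, u12 = (np.minimum(u, 1.0) for u in (u0, u6, u12))

    cost_public = np.round(np.maximum(config.baseline_cost_mean + e_cost, 0.0), 6)
    cost_iert = np.round(delta_cost, 6)
    cost_total = cost_public + cost_iert  # exact additive identity

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age_years": age.astype(int),
            "sex": sex,
            "gmfcs": gmfcs,
            "group": group,
            **{t: flags[t] for t in THERAPIES},
            "u0": np.round(u0, 10),
            "u6": np.round(u6, 10),
            "u12": np.round(u12, 10),
            "cost_public": cost_public,
            "cost_iert": cost_iert,
            "cost_total": cost_total,
            "completed_followup": np.ones(n, dtype=int),
        },
        columns=COHORT_COLUMNS,
    )
    df.attrs["truth"] = pd.DataFrame(
        {
            "id": df["id"],
            "e_cost": e_cost,
            "e_effect": e_effect,
            "delta_cost_true": delta_cost,
            "delta_qaly_true": delta_qaly,
            "qaly_true": qaly_true,
        }
    )
    df.attrs["config"] = config
    return df


def apply_dropout(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Flag ``config.dropout_count`` ERT-subgroup children as lost to follow-up.

    Dropout is missing-at-random within the ERT subgroup; no record is deleted
    (complete-case filtering happens downstream in the estimators).
    """
    ert_flagged = cohort[list(ERT_THERAPIES)].sum(axis=1) > 0
    n_ert = int(ert_flagged.sum())
    if config.dropout_count > n_ert:
        raise ConfigError(
            f"dropout_count = {config.dropout_count} exceeds the number of "
            f"ERT-flagged records ({n_ert})"
        )
    out = cohort.copy()
    out["completed_followup"] = 1
    if config.dropout_count > 0:
        rng = _spawn_rngs(config.seed)["dropout"]
        candidates = np.flatnonzero(ert_flagged.to_numpy())
        dropped = rng.choice(candidates, size=config.dropout_count, replace=False)
        out.iloc[dropped, out.columns.get_loc("completed_followup")] = 0
    for key, value in cohort.attrs.items():
        out.attrs[key] = value
    return out


def cohort_summary(cohort: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive summary over completed records only.

    Returns per-group counts and mean annual costs, the GMFCS distribution by
    group, and per-therapy recipient counts.
    """
    if len(cohort) == 0:
        raise InputError("cannot summarise an empty cohort")
    done = cohort[cohort["completed_followup"] == 1]
    if len(done) == 0:
        raise InputError("no completed records to summarise")
    groups = done.groupby("group").agg(
        n=("id", "size"),
        mean_cost_public=("cost_public", "mean"),
        mean_cost_iert=("cost_iert", "mean"),
        mean_cost_total=("cost_total", "mean"),
        mean_u0=("u0", "mean"),
        mean_u12=("u12", "mean"),
    )
    gmfcs = pd.crosstab(done["gmfcs"], done["group"])
    therapy_counts = done[list(THERAPIES)].sum().to_frame("n_recipients")
    return {"groups": groups, "gmfcs": gmfcs, "therapies": therapy_counts}


def check_cohort_invariants(cohort: pd.DataFrame) -> None:
    """Raise :class:`InputError` if structural invariants are violated.

    Checks subgroup exclusivity (at most one therapy per subgroup), that
    control-arm children carry no therapy flags or intervention costs, and the
    additive cost identity.
    """
    irt_sum = cohort[list(IRT_THERAPIES)].sum(axis=1)
    ert_sum = cohort[list(ERT_THERAPIES)].sum(axis=1)
    if (irt_sum > 1).any() or (ert_sum > 1).any():
        raise InputError("a child may receive at most one therapy per subgroup")
    control = cohort["group"] == GROUP_CONTROL
    if (irt_sum[control] + ert_sum[control] > 0).any():
        raise InputError("control-arm children must have no therapy flags")
    if (cohort.loc[control, "cost_iert"] != 0).any():
        raise InputError("control-arm children must have cost_iert = 0")
    gap = (cohort["cost_total"] - cohort["cost_public"] - cohort["cost_iert"]).abs()
    if (gap > 1e-6).any():
        raise InputError("cost_total must equal cost_public + cost_iert")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as CSV in the documented column order (no missing values)."""
    out = cohort[COHORT_COLUMNS]
    if out.isna().any().any():
        raise InputError("cohort contains missing values; refusing to write")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, enforcing schema and completeness."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"cohort file lacks required columns {missing}")
    df = df[COHORT_COLUMNS]
    if df.isna().any().any():
        raise InputError("cohort file contains missing values")
    return df
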