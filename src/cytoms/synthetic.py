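"""Synthetic cohort generator.

Generates individual-level cohorts with the statistical structure the
downstream classification pipeline assumes: two groups (MS, control) with
per-cytokine location shifts expressed in units of the control SD, clinical
covariates (age, disease duration, EDSS, MSSS), exact course quotas, and
matching summary-statistics tables for round-trip tests against the
reconstruction module.

Cytokine marginals default to lognormal — serum concentrations are positive
and right-skewed — parameterised by the target mean and SD on the
concentration scale; a normal family (clipped at 0 pg/mL) is available for
parity with the reconstruction module's normality assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    BASE_COLUMNS,
    CORE_CYTOKINES,
    COURSES,
    COURSE_NONE,
    STATUS_CONTROL,
    STATUS_MS,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CytokineEffectSpec:
    """Marginal distribution of one cytokine in controls, plus the MS shift.

    ``ms_shift`` is a standardized effect size d: the MS group mean is
    ``control_mean + ms_shift * control_sd`` (same SD in both groups).
    """

    cytokine_name: str
    control_mean: float
    control_sd: float
    ms_shift: float = 0.0
    distribution_family: str = "lognormal"

    def __post_init__(self) -> None:
        if self.control_mean <= 0:
            raise ValueError(f"{self.cytokine_name}: control_mean must be > 0")
        if self.control_sd < 0:
            raise ValueError(f"{self.cytokine_name}: control_sd must be >= 0")
        if not np.isfinite(self.ms_shift):
            raise ValueError(f"{self.cytokine_name}: ms_shift must be finite")
        if self.distribution_family not in ("normal", "lognormal"):
            raise ValueError(
                f"{self.cytokine_name}: unknown distribution_family "
                f"{self.distribution_family!r}"
            )

    def group_mean(self, status: str) -> float:
        if status == STATUS_MS:
            return self.control_mean + self.ms_shift * self.control_sd
        return self.control_mean


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort (both groups)."""

    cohort_label: str
    n_ms: int
    n_control: int
    cytokine_specs: Sequence[CytokineEffectSpec]
    age_ms_mean: float = 39.1
    age_ms_sd: float = 13.4
    age_control_mean: float = 28.6
    age_control_sd: float = 8.8
    female_fraction_ms: float = 67 / 97
    female_fraction_control: float = 53 / 71
    course_proportions: Sequence[float] = (46 / 97, 31 / 97, 20 / 97)
    duration_mean: float = 3.9
    duration_sd: float = 2.2
    edss_mean: float = 2.6
    edss_sd: float = 1.5
    msss_mean: float = 4.9
    msss_sd: float = 2.3
    treatment_fraction: float = 22 / 97
    equicorrelation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ms <= 0 or self.n_control <= 0:
            raise ValueError("n_ms and n_control must be positive")
        props = np.asarray(self.course_proportions, dtype=float)
        if props.shape != (3,) or (props < 0).any():
            raise ValueError("course_proportions must be 3 non-negative numbers")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"course_proportions must sum to 1 (got {props.sum():.12f})"
            )
        for name, val in [
            ("female_fraction_ms", self.female_fraction_ms),
            ("female_fraction_control", self.female_fraction_control),
            ("treatment_fraction", self.treatment_fraction),
        ]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("age_ms_sd", "age_control_sd", "duration_sd", "edss_sd", "msss_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1 / (len(self.cytokine_specs) or 1) <= self.equicorrelation < 1:
            raise ValueError("equicorrelation out of the valid range")
        names = [s.cytokine_name for s in self.cytokine_specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cytokine names in cytokine_specs")


def largest_remainder_quota(n: int, proportions: Sequence[float]) -> List[int]:
    """Integer counts summing to *n* that best match *proportions*.

    Largest-remainder rounding: floor each quota, then hand the remaining
    units to the largest fractional parts (ties broken by position).
    """
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    short = n - counts.sum()
    order = np.argsort(-remainder, kind="stable")
    for idx in order[:short]:
        counts[idx] += 1
    return counts.tolist()


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with the given mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def _draw_cytokines(
    rng: np.random.Generator,
    specs: Sequence[CytokineEffectSpec],
    status: str,
    n: int,
    equicorrelation: float,
) -> Dict[str, np.ndarray]:
    """Draw the cytokine block for one group.

    Correlation is induced on the latent standard-normal scale via a shared
    factor; with equicorrelation 0 analytes are independent.
    """
    k = len(specs)
    z = rng.standard_normal((n, k))
    if equicorrelation != 0.0 and k > 1:
        shared = rng.standard_normal((n, 1))
        rho = equicorrelation
        z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * z

    out: Dict[str, np.ndarray] = {}
    n_clipped = 0
    for j, spec in enumerate(specs):
        mean = spec.group_mean(status)
        sd = spec.control_sd
        if spec.distribution_family == "normal":
            vals = mean + sd * z[:, j]
            clip = vals < 0
            n_clipped += int(clip.sum())
            vals = np.where(clip, 0.0, vals)
        else:
            if sd == 0:
                vals = np.full(n, mean)
            else:
                if mean <= 0:
                    raise ValueError(
                        f"{spec.cytokine_name}: lognormal requires a positive "
                        f"group mean (got {mean}); reduce |ms_shift| or use "
                        "the normal family"
                    )
                mu, sigma = _lognormal_params(mean, sd)
                vals = np.exp(mu + sigma * z[:, j])
        out[spec.cytokine_name] = vals
    if n_clipped:
        logger.info("clipped %d negative normal-family draws to 0 pg/mL", n_clipped)
    return out


def _clipped_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int,
    lo: float, hi: float, what: str,
) -> np.ndarray:
    vals = rng.normal(mean, sd, size=n)
    n_clip = int(((vals < lo) | (vals > hi)).sum())
    if n_clip:
        logger.info("clipped %d %s draws into [%g, %g]", n_clip, what, lo, hi)
    return np.clip(vals, lo, hi)


def _gender_quota(rng: np.random.Generator, female_fraction: float, n: int) -> np.ndarray:
    n_f = largest_remainder_quota(n, [female_fraction, 1 - female_fraction])[0]
    g = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(g)
    return g


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one synthetic cohort table from *spec*.

    Deterministic for a fixed spec (including seed). Course labels and
    genders are assigned by exact quota (largest-remainder rounding) so the
    stated demographic counts are reproduced exactly, not just in
    expectation; cytokine values are random draws from the stated family.
    """
    rng = np.random.default_rng(spec.seed)
    specs = list(spec.cytokine_specs)

    rows: List[dict] = []
    for status, n in ((STATUS_MS, spec.n_ms), (STATUS_CONTROL, spec.n_control)):
        cyto = _draw_cytokines(rng, specs, status, n, spec.equicorrelation)
        if status == STATUS_MS:
            quotas = largest_remainder_quota(n, spec.course_proportions)
            courses = np.repeat(COURSES, quotas)
            rng.shuffle(courses)
            age = _clipped_normal(rng, spec.age_ms_mean, spec.age_ms_sd, n, 0, 120, "age")
            gender = _gender_quota(rng, spec.female_fraction_ms, n)
            duration = _clipped_normal(
                rng, spec.duration_mean, spec.duration_sd, n, 0, np.inf, "duration")
            edss = _clipped_normal(rng, spec.edss_mean, spec.edss_sd, n, 0, 10, "EDSS")
            msss = _clipped_normal(rng, spec.msss_mean, spec.msss_sd, n, 0, 10, "MSSS")
            n_treat = largest_remainder_quota(
                n, [spec.treatment_fraction, 1 - spec.treatment_fraction])[0]
            treatment = np.array([1] * n_treat + [0] * (n - n_treat))
            rng.shuffle(treatment)
        else:
            courses = np.full(n, COURSE_NONE, dtype=object)
            age = _clipped_normal(
                rng, spec.age_control_mean, spec.age_control_sd, n, 0, 120, "age")
            gender = _gender_quota(rng, spec.female_fraction_control, n)
            duration = np.full(n, np.nan)
            edss = np.full(n, np.nan)
            msss = np.full(n, np.nan)
            treatment = np.full(n, np.nan)

        tag = "ms" if status == STATUS_MS else "ctl"
        for i in range(n):
            row = {
                "subject_id": f"{spec.cohort_label}-{tag}-{i:05d}",
                "cohort": spec.cohort_label,
                "status": status,
                "course": courses[i],
                "age": age[i],
                "gender": gender[i],
                "duration": duration[i],
                "edss": edss[i],
                "msss": msss[i],
                "treatment": treatment[i],
            }
            for s in specs:
                row[s.cytokine_name] = cyto[s.cytokine_name][i]
            rows.append(row)

    cols = BASE_COLUMNS + [s.cytokine_name for s in specs]
    return pd.DataFrame(rows, columns=cols)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per cohort x group x cytokine summary statistics.

    Returns a table with columns cohort, group, cytokine, n, mean, sd, sem —
    SD with the n-1 denominator, SEM = SD/sqrt(n). Groups of size 1 get NaN
    SD/SEM and are flagged in the log.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty cohort table")
    cyto_cols = [c for c in table.columns if c not in BASE_COLUMNS]
    if not cyto_cols:
        raise ValueError("cohort table carries no cytokine columns")
    records = []
    for (cohort, group), sub in table.groupby(["cohort", "status"], sort=True):
        n = len(sub)
        if n == 1:
            logger.warning(
                "group %s/%s has a single record; SD reported as n/a", cohort, group)
        for c in cyto_cols:
            vals = sub[c].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
            records.append({
                "cohort": cohort,
                "group": group,
                "cytokine": c,
                "n": n,
                "mean": float(vals.mean()),
                "sd": sd,
                "sem": sd / np.sqrt(n) if n > 1 else np.nan,
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Study-condition presets.
#
# The published analysis pools three cohorts: two USA studies known only
# through summary statistics (833 MS / 117 controls and 26 MS / 11 controls)
# and one Russian cohort measured directly (97 MS / 71 controls). Per-analyte
# means and SDs were never published for the Russian cohort, so the control
# levels and effect sizes below are free parameters: plausible serum
# concentrations with a large standardized MS shift (d = 0.8) on the seven
# analytes reported elevated, and a cohort-dependent IL-8 direction (lower in
# the USA cohorts, higher in the Russian one).
# ---------------------------------------------------------------------------

#: Control-group serum levels (pg/mL): (mean, sd) per analyte.
DEFAULT_CONTROL_LEVELS: Dict[str, tuple] = {
    "IL1b": (1.2, 0.8),
    "IL2": (2.5, 1.5),
    "IL4": (2.0, 1.2),
    "IL8": (12.0, 6.0),
    "IL10": (3.5, 2.0),
    "IL13": (4.0, 2.5),
    "IFNg": (15.0, 8.0),
    "TNFa": (8.0, 4.0),
    "IL6": (3.0, 2.0),
    "IFNa": (10.0, 5.0),
}

#: Default standardized MS shift for the consistently elevated analytes.
DEFAULT_EFFECT_SIZE = 0.8
#: IL-8 moves in opposite directions in the two populations.
DEFAULT_IL8_SHIFT = {"usa": -0.5, "russian": 0.5}


def default_cytokine_specs(
    direction: str = "russian",
    effect_size: float = DEFAULT_EFFECT_SIZE,
    panel: Optional[Sequence[str]] = None,
    distribution_family: str = "lognormal",
) -> List[CytokineEffectSpec]:
    """Build the default panel of effect specs for one population.

    *direction* selects the IL-8 sign ('usa': lower in MS, 'russian': higher
    in MS); all other analytes shift up in MS by *effect_size* control SDs.
    """
    if direction not in DEFAULT_IL8_SHIFT:
        raise ValueError(f"direction must be one of {sorted(DEFAULT_IL8_SHIFT)}")
    panel = list(panel) if panel is not None else list(CORE_CYTOKINES)
    specs = []
    for name in panel:
        mean, sd = DEFAULT_CONTROL_LEVELS[name]
        if name == "IL8":
            # IL-8 keeps its population-specific direction and scales with
            # the requested overall effect strength.
            shift = DEFAULT_IL8_SHIFT[direction] * effect_size / DEFAULT_EFFECT_SIZE
        else:
            shift = effect_size
        specs.append(CytokineEffectSpec(
            cytokine_name=name,
            control_mean=mean,
            control_sd=sd,
            ms_shift=float(shift),
            distribution_family=distribution_family,
        ))
    return specs


def russian_like_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A cohort shaped like the directly measured Russian one: 97 MS / 71
    controls, demographic and clinical defaults from the published table."""
    base = dict(
        cohort_label="russian",
        n_ms=97,
        n_control=71,
        cytokine_specs=default_cytokine_specs("russian"),
        seed=seed,
    )
    base.update(overrides)
    return CohortSpec(**base)


def usa_like_specs(seed: int = 0) -> List[CohortSpec]:
    """The two USA-like cohorts (833/117 and 26/11), used as the ground truth
    that the summary-statistic reconstruction round-trips against."""
    common = dict(
        cytokine_specs=default_cytokine_specs("usa"),
        age_ms_mean=40.0, age_ms_sd=11.0,
        age_control_mean=38.0, age_control_sd=11.0,
    )
    return [
        CohortSpec(cohort_label="usa_large", n_ms=833, n_control=117,
                   seed=seed + 1, **common),
        CohortSpec(cohort_label="usa_small", n_ms=26, n_control=11,
                   seed=seed + 2, **common),
    ]
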