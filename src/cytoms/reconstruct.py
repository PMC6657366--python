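"""Reconstruction of individual-level values from mean +/- SD/SEM summaries.

Many published cytokine panels report only per-group summary statistics.
Under a normality assumption, n individual values can be recovered by
placing n evenly spaced percentiles inside a central probability mass
(default 99.7%, treating the remaining 0.3% as outliers) and mapping them
through the inverse normal CDF:

    value_i = mean + sd * Phi^{-1}(p_i),
    p_i = (1 - mass)/2 + (i - 1/2)/n * mass,   i = 1..n.

The midpoint percentile grid is symmetric about 0.5, so the sample mean of
the reconstructed values equals the published mean to machine precision for
every n. The sample SD is deterministically *smaller* than the published SD
(the grid is truncated to the central mass and discretized); no rescaling is
applied to hide that shrinkage — it converges to ~0.9839 of sigma for a
99.7% mass as n grows, and is documented rather than corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASE_COLUMNS, STATUS_CONTROL, STATUS_MS, empty_clinical_row

logger = logging.getLogger(__name__)

DISPERSION_KINDS = ("SD", "SEM")


@dataclass(frozen=True)
class SummaryStat:
    """One published summary cell: a cytokine in one group of one cohort."""

    cytokine_name: str
    group: str  # STATUS_MS or STATUS_CONTROL
    cohort_label: str
    mean: float
    dispersion: float
    dispersion_kind: str  # 'SD' or 'SEM'
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"{self.cytokine_name}/{self.group}: n must be >= 1")
        if self.dispersion < 0:
            raise ValueError(f"{self.cytokine_name}/{self.group}: dispersion < 0")
        if self.dispersion_kind not in DISPERSION_KINDS:
            raise ValueError(
                f"dispersion_kind must be one of {DISPERSION_KINDS}, "
                f"got {self.dispersion_kind!r}")
        if self.group not in (STATUS_MS, STATUS_CONTROL):
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def sd(self) -> float:
        """Dispersion on the SD scale (SEM entries converted via sqrt(n))."""
        if self.dispersion_kind == "SEM":
            return sem_to_sd(self.dispersion, self.n)
        return self.dispersion


@dataclass(frozen=True)
class ReconstructionConfig:
    """Knobs of the percentile reconstruction.

    included_mass: central normal mass covered by the percentile grid.
    coupling: 'independent' shuffles each cytokine's value vector with its
      own seeded permutation before assigning to subjects (no fabricated
      inter-cytokine correlation); 'comonotone' gives subject i the i-th
      order statistic of every cytokine (perfect rank correlation).
    clamp_negative: clip reconstructed concentrations at 0 pg/mL instead of
      keeping moment-preserving negative values.
    """

    included_mass: float = 0.997
    coupling: str = "independent"
    seed: int = 0
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.included_mass < 1:
            raise ValueError("included_mass must lie strictly in (0, 1)")
        if self.coupling not in ("independent", "comonotone"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


def sem_to_sd(sem: float, n: int) -> float:
    """Convert a standard error of the mean to an SD: sem * sqrt(n)."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return sem * math.sqrt(n)


def percentile_grid(n: int, included_mass: float = 0.997) -> np.ndarray:
    """The n midpoint percentiles inside the central *included_mass*."""
    lower = (1.0 - included_mass) / 2.0
    i = np.arange(1, n + 1)
    return lower + (i - 0.5) / n * included_mass


def zscore_percentile_values(
    mean: float, sd: float, n: int,
    config: ReconstructionConfig = ReconstructionConfig(),
) -> np.ndarray:
    """Reconstruct n values from (mean, sd) via the inverse-normal grid.

    Returns the values sorted ascending; extremes stay inside
    mean +/- sd * Phi^{-1}((1 + included_mass)/2).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = stats.norm.ppf(percentile_grid(n, config.included_mass))
    return mean + sd * z


def grid_sd_shrinkage(n: int, included_mass: float = 0.997) -> float:
    """Sample SD (population denominator n) of the unit-variance grid.

    A deterministic constant for each n: the reconstruction's SD fidelity.
    Converges from below to the truncated-normal SD over the central mass
    (< 1) as n -> infinity.
    """
    z = stats.norm.ppf(percentile_grid(n, included_mass))
    return float(np.std(z))


def read_summary_csv(path) -> List[SummaryStat]:
    """Read a summary-statistics table.

    Expected columns: cohort, group, cytokine, mean, dispersion,
    dispersion_kind, n.
    """
    df = pd.read_csv(path)
    required = {"cohort", "group", "cytokine", "mean", "dispersion",
                "dispersion_kind", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV missing columns: {sorted(missing)}")
    return [
        SummaryStat(
            cytokine_name=row.cytokine,
            group=row.group,
            cohort_label=row.cohort,
            mean=float(row.mean),
            dispersion=float(row.dispersion),
            dispersion_kind=str(row.dispersion_kind),
            n=int(row.n),
        )
        for row in df.itertuples()
    ]


def summary_stats_from_table(summary: pd.DataFrame,
                             dispersion_kind: str = "SD") -> List[SummaryStat]:
    """Adapt the generator's summarize_cohort output into SummaryStat rows."""
    col = "sd" if dispersion_kind == "SD" else "sem"
    return [
        SummaryStat(
            cytokine_name=row.cytokine,
            group=row.group,
            cohort_label=row.cohort,
            mean=float(row.mean),
            dispersion=float(getattr(row, col)),
            dispersion_kind=dispersion_kind,
            n=int(row.n),
        )
        for row in summary.itertuples()
    ]


def reconstruct_cohort(
    stats_list: Sequence[SummaryStat],
    config: ReconstructionConfig = ReconstructionConfig(),
) -> pd.DataFrame:
    """Reconstruct an individual-level cohort table from summary cells.

    Every (cohort, group) must contribute one SummaryStat per cytokine, all
    with the same n; all groups must share the same cytokine panel. Clinical
    covariate columns are left empty — only the cytokine block is known.
    """
    if not stats_list:
        raise ValueError("no summary statistics supplied")

    groups: Dict[Tuple[str, str], List[SummaryStat]] = {}
    for s in stats_list:
        groups.setdefault((s.cohort_label, s.group), []).append(s)

    panels = {tuple(sorted(x.cytokine_name for x in v)) for v in groups.values()}
    if len(panels) > 1:
        raise ValueError(f"groups carry different cytokine panels: {panels}")
    panel = list(panels.pop())
    for key, v in groups.items():
        if len({x.cytokine_name for x in v}) != len(v):
            raise ValueError(f"duplicate cytokine summary in group {key}")

    rng = np.random.default_rng(config.seed)
    rows: List[dict] = []
    negatives = 0
    for (cohort, group), cells in sorted(groups.items()):
        ns = {c.cytokine_name: c.n for c in cells}
        if len(set(ns.values())) > 1:
            raise ValueError(
                f"group ({cohort}, {group}): cytokines disagree on n: {ns}")
        n = cells[0].n
        values: Dict[str, np.ndarray] = {}
        for c in sorted(cells, key=lambda c: c.cytokine_name):
            v = zscore_percentile_values(c.mean, c.sd, n, config)
            if config.coupling == "independent":
                v = rng.permutation(v)
            neg = v < 0
            if neg.any():
                negatives += int(neg.sum())
                if config.clamp_negative:
                    v = np.where(neg, 0.0, v)
            values[c.cytokine_name] = v
        tag = "ms" if group == STATUS_MS else "ctl"
        for i in range(n):
            row = {"subject_id": f"{cohort}-{tag}-r{i:05d}",
                   "cohort": cohort, "status": group}
            row.update(empty_clinical_row())
            for name in panel:
                row[name] = values[name][i]
            rows.append(row)

    if negatives:
        msg = "clamped to 0" if config.clamp_negative else \
            "kept as-is (moment-preserving); pass clamp_negative=True to clip"
        logger.warning("%d reconstructed concentrations were negative; %s",
                       negatives, msg)
    cols = BASE_COLUMNS + panel
    return pd.DataFrame(rows, columns=cols)
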