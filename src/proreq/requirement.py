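"""Net protein requirements for maintenance and growth by regression.

The factorial estimate regresses nitrogen intake on average daily gain,
both scaled by metabolic body weight:

    N intake (g/kg W^0.75/d) = b0 + b1 * ADG (g/kg W^0.75/d)

The intercept b0 is the N intake at zero gain — the net maintenance
requirement (g N/kg W^0.75/d) — and the slope b1 is the marginal N per
gram of gain — the net growth requirement (g N/g ADG; metabolic scaling
cancels in the slope).  Multiplying by 6.25 converts both to crude
protein equivalents.

Organised statsmodels-style: :class:`ProteinRequirementModel` is built
from points, a DataFrame, or a :class:`~proreq.trial_io.TrialDataset`;
``fit()`` returns a :class:`ProteinRequirementResults` carrying the
estimates, their uncertainties and a ``summary()`` table, with a
case-resampling ``bootstrap()`` for distribution-free intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import n_from_cp
from .performance import daily_gain, metabolic_weight
from .trial_io import RunConfig, TrialDataset

__all__ = [
    "RequirementPoint",
    "ProteinRequirementModel",
    "ProteinRequirementResults",
    "points_from_trial",
]


def _round_half_up(value: float, n_decimals: int) -> float:
    """Display rounding in the half-up convention (0.0725 -> 0.073).

    Snaps float noise at the 8th decimal first so a numerically-computed
    tie (0.072499999...94) still rounds the way the exact value would.
    """
    d = Decimal(repr(value)).quantize(Decimal("1e-8"), rounding=ROUND_HALF_UP)
    q = Decimal(1).scaleb(-n_decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RequirementPoint:
    """One animal's (ADG, N intake) pair on metabolic-weight-scaled axes."""

    adg_g_per_kg_w075: float
    n_intake_g_per_kg_w075: float
    animal_id: str = ""

    def __post_init__(self) -> None:
        if self.n_intake_g_per_kg_w075 < 0:
            raise ValueError("N intake cannot be negative")


def points_from_trial(
    dataset: TrialDataset,
    config: RunConfig | None = None,
    period_handling: str = "animal_mean",
) -> list[RequirementPoint]:
    """Build regression points from a trial dataset.

    Per animal-period, ADG = (final - initial BW)/days scaled by W^0.75
    of the period-mean BW, and N intake = DMI x diet CP / 6.25 similarly
    scaled.  ``period_handling``:

    * ``"animal_mean"`` (default) — average the periods per animal, one
      point per animal (the convention matching n = number of animals);
    * ``"per_period"`` — one point per animal-period.
    """
    cfg = config or RunConfig()
    if period_handling not in ("animal_mean", "per_period"):
        raise ValueError(f"unknown period_handling {period_handling!r}")
    rows = []
    for r in dataset.records:
        diet = dataset.diet_for(r.treatment_label)
        w075 = metabolic_weight(r.average_bw_kg)
        adg_g = daily_gain(r.initial_bw_kg, r.final_bw_kg, r.days_on_feed) * 1000.0
        n_intake = n_from_cp(r.dm_intake_kg_d * diet.cp_gkg_dm, cfg.cp_conversion_factor)
        rows.append(
            {
                "animal_id": r.animal_id,
                "x": adg_g / w075,
                "y": n_intake / w075,
            }
        )
    df = pd.DataFrame(rows)
    if period_handling == "animal_mean":
        df = df.groupby("animal_id", as_index=False, sort=True).mean()
    return [
        RequirementPoint(row.x, row.y, str(row.animal_id)) for row in df.itertuples()
    ]


class ProteinRequirementModel:
    """OLS model of metabolic-weight-scaled N intake on ADG.

    Parameters
    ----------
    adg : array-like
        ADG per animal, g/kg W^0.75/d (may be negative).
    n_intake : array-like
        N intake per animal, g N/kg W^0.75/d.
    animal_ids : sequence of str, optional
    config : RunConfig, optional
        Supplies the N -> CP conversion factor (default 6.25).
    """

    def __init__(
        self,
        adg: Sequence[float],
        n_intake: Sequence[float],
        animal_ids: Sequence[str] | None = None,
        config: RunConfig | None = None,
    ) -> None:
        x = np.asarray(adg, dtype=float)
        y = np.asarray(n_intake, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("adg and n_intake must be 1-d arrays of equal length")
        if len(x) < 3:
            raise ValueError("need at least 3 points to fit the requirement model")
        if np.ptp(x) == 0:
            raise ValueError("ADG values are all identical; slope is not estimable")
        if (y < 0).any():
            raise ValueError("N intake cannot be negative")
        self.adg = x
        self.n_intake = y
        self.animal_ids = list(animal_ids) if animal_ids is not None else [
            str(i) for i in range(len(x))
        ]
        self.config = config or RunConfig()

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_points(
        cls, points: Sequence[RequirementPoint], config: RunConfig | None = None
    ) -> "ProteinRequirementModel":
        return cls(
            [p.adg_g_per_kg_w075 for p in points],
            [p.n_intake_g_per_kg_w075 for p in points],
            [p.animal_id for p in points],
            config,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        adg_col: str = "adg_g_per_kg_w075",
        n_intake_col: str = "n_intake_g_per_kg_w075",
        id_col: str | None = "animal_id",
        config: RunConfig | None = None,
    ) -> "ProteinRequirementModel":
        ids = df[id_col].astype(str) if id_col and id_col in df else None
        return cls(df[adg_col], df[n_intake_col], ids, config)

    @classmethod
    def from_trial(
        cls,
        dataset: TrialDataset,
        config: RunConfig | None = None,
        period_handling: str = "animal_mean",
    ) -> "ProteinRequirementModel":
        return cls.from_points(
            points_from_trial(dataset, config, period_handling), config
        )

    # -- estimation -------------------------------------------------------

    def fit(self, ci_level: float = 0.95) -> "ProteinRequirementResults":
        X = sm.add_constant(self.adg)
        res = sm.OLS(self.n_intake, X).fit()
        ci = res.conf_int(alpha=1 - ci_level)
        return ProteinRequirementResults(
            model=self,
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            se_intercept=float(res.bse[0]),
            se_slope=float(res.bse[1]),
            p_slope=float(res.pvalues[1]),
            r_squared=float(res.rsquared),
            n_points=int(res.nobs),
            ci_level=ci_level,
            ci_intercept=(float(ci[0, 0]), float(ci[0, 1])),
            ci_slope=(float(ci[1, 0]), float(ci[1, 1])),
            _sm_results=res,
        )


@dataclass
class ProteinRequirementResults:
    """Fitted requirement regression and its nutritional interpretation."""

    model: ProteinRequirementModel
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    p_slope: float
    r_squared: float
    n_points: int
    ci_level: float
    ci_intercept: tuple[float, float]
    ci_slope: tuple[float, float]
    _sm_results: object = None

    # -- requirement interpretation --------------------------------------

    @property
    def maintenance_n(self) -> float:
        """Net maintenance requirement, g N/kg W^0.75/d (the intercept)."""
        return self.intercept

    @property
    def growth_n(self) -> float:
        """Net growth requirement, g N/g ADG (the slope)."""
        return self.slope

    @property
    def maintenance_cp(self) -> float:
        """Maintenance requirement in CP terms, g CP/kg W^0.75/d."""
        return self.intercept * self.model.config.cp_conversion_factor

    @property
    def growth_cp(self) -> float:
        """Growth requirement in CP terms, g CP/g ADG."""
        return self.slope * self.model.config.cp_conversion_factor

    def display_requirements(self, n_decimals: int = 2) -> dict[str, float]:
        """Requirements at display precision, rounding N estimates first.

        The convention rounds the N-scale estimates to 3-4 significant
        figures before converting to CP (0.0725 -> 0.073 -> 0.46), so the
        published-style figures come from the rounded N values; the
        unrounded conversions stay available as properties.
        """
        n_maint = _round_half_up(self.maintenance_n, 3)
        n_growth = _round_half_up(self.growth_n, 3)
        factor = self.model.config.cp_conversion_factor
        return {
            "maintenance_n": n_maint,
            "growth_n": n_growth,
            "maintenance_cp": _round_half_up(n_maint * factor, n_decimals),
            "growth_cp": _round_half_up(n_growth * factor, n_decimals),
        }

    # -- uncertainty ------------------------------------------------------

    def bootstrap(
        self, n_boot: int = 2000, seed: int | None = None, ci_level: float = 0.95
    ) -> dict[str, tuple[float, float]]:
        """Case-resampling bootstrap percentile intervals for both parameters.

        Resamples animals with replacement; degenerate resamples with no
        ADG spread are redrawn.  Deterministic for a fixed seed.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        rng = np.random.default_rng(seed)
        x, y = self.model.adg, self.model.n_intake
        n = len(x)
        intercepts = np.empty(n_boot)
        slopes = np.empty(n_boot)
        for b in range(n_boot):
            while True:
                idx = rng.integers(0, n, size=n)
                if np.ptp(x[idx]) > 0:
                    break
            xb, yb = x[idx], y[idx]
            xm, ym = xb.mean(), yb.mean()
            slope = float(((xb - xm) @ (yb - ym)) / ((xb - xm) @ (xb - xm)))
            slopes[b] = slope
            intercepts[b] = ym - slope * xm
        lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
        return {
            "intercept": tuple(np.percentile(intercepts, [lo, hi])),
            "slope": tuple(np.percentile(slopes, [lo, hi])),
        }

    # -- presentation -----------------------------------------------------

    def predict(self, adg: Sequence[float]) -> np.ndarray:
        """Predicted N intake (g/kg W^0.75/d) at the given ADG values."""
        return self.intercept + self.slope * np.asarray(adg, dtype=float)

    def to_dict(self) -> dict:
        d = {
            "intercept_g_n_per_kg_w075": self.intercept,
            "slope_g_n_per_g_adg": self.slope,
            "se_intercept": self.se_intercept,
            "se_slope": self.se_slope,
            "p_slope": self.p_slope,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "maintenance_cp_g_per_kg_w075": self.maintenance_cp,
            "growth_cp_g_per_g_adg": self.growth_cp,
            "ci_level": self.ci_level,
            "ci_intercept": list(self.ci_intercept),
            "ci_slope": list(self.ci_slope),
        }
        d["display"] = self.display_requirements()
        return d

    def summary(self) -> str:
        disp = self.display_requirements()
        lines = [
            "Net protein requirement regression",
            "==================================",
            "model: N intake = b0 + b1 * ADG   (both g/kg W^0.75/d)",
            f"n = {self.n_points}, R^2 = {self.r_squared:.3f}, "
            f"slope p = {self.p_slope:.4g}",
            "",
            f"{'':<14}{'estimate':>10}{'SE':>10}"
            f"{f'{self.ci_level:.0%} CI':>22}",
            f"{'intercept b0':<14}{self.intercept:>10.4f}{self.se_intercept:>10.4f}"
            f"{f'[{self.ci_intercept[0]:.4f}, {self.ci_intercept[1]:.4f}]':>22}",
            f"{'slope b1':<14}{self.slope:>10.4f}{self.se_slope:>10.4f}"
            f"{f'[{self.ci_slope[0]:.4f}, {self.ci_slope[1]:.4f}]':>22}",
            "",
            "requirements (x6.25 for CP):",
            f"  maintenance: {self.maintenance_n:.4f} g N/kg W^0.75/d"
            f"  ->  {disp['maintenance_cp']:.2f} g CP/kg W^0.75/d",
            f"  growth:      {self.growth_n:.4f} g N/g ADG"
            f"      ->  {disp['growth_cp']:.2f} g CP/g ADG",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the points with the fitted requirement line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        x, y = self.model.adg, self.model.n_intake
        ax.scatter(x, y, color="k", s=25, zorder=3)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, self.predict(grid), color="tab:red")
        ax.set_xlabel("ADG (g/kg $W^{0.75}$/d)")
        ax.set_ylabel("N intake (g N/kg $W^{0.75}$/d)")
        ax.set_title(
            f"y = {self.slope:.4f}x + {self.intercept:.4f}  "
            f"($R^2$ = {self.r_squared:.3f}, n = {self.n_points})"
        )
        return ax
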