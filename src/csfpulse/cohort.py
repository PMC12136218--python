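"""Synthetic cohort tables with a controlled flow/age/biomarker structure.

The generative model mimics a small aging nonhuman-primate cohort:

* ``age`` ~ Uniform(age_range)                              [years]
* latent flow ``L = b0 + beta_age_flow * age + eps_L``      [mm^3/s x phase]
* the six flow-metric columns are affine transforms of ``L`` (caudal volume
  decreasing, the rest increasing) plus small independent measurement noise,
  so they inter-correlate highly;
* CSF Abeta42/40 ratio = ``r0 + beta_age_ratio * age +
  beta_flow_ratio * eps_L + eps_R`` — i.e. it carries both a direct age
  effect and an effect of the *age-independent* component of flow, which is
  what an age-adjusted (partial-correlation) analysis should recover;
* CSF Abeta40 is flow- and age-independent; Abeta42 = ratio * Abeta40;
* the remaining CSF and plasma biomarkers are generated independent of flow
  given age ("null" biomarkers: age trends allowed, no flow effect).

Slopes and noise SDs default to values derived analytically from population
Spearman targets (``rho_age_flow``, ``rho_flow_ratio``, ``rho_age_ratio``).
The age-flow noise SD is solved from the exact population Spearman of a
linear model with a *uniform* regressor (2-D quadrature); the Gaussian
residual pairs (flow residual vs ratio) use the Gaussian-copula conversion
``rho_pearson = 2 sin(pi rho_s / 6)``.
The defaults target rho(age, flow) = -0.75 and age-adjusted
rho(flow, ratio) = +0.70, inside the observed ranges for this kind of
cohort.  Partial-correlation analysis needs df = n - 3 >= 1, hence the
n_subjects >= 4 guard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

#: Direction of each flow-metric column as a function of latent flow:
#: +1 increases with overall flow strength, -1 decreases (caudal volume).
METRIC_DIRECTIONS: dict[str, int] = {
    "cranial_volume": +1,
    "caudal_volume": -1,
    "net_stroke": +1,
    "absolute_stroke": +1,
    "amplitude": +1,
    "peak": +1,
}

METRIC_COLUMNS = tuple(METRIC_DIRECTIONS)

DEFAULT_NULL_BIOMARKERS = (
    "csf_ab38",
    "csf_ptau181",
    "csf_nfl",
    "csf_gfap",
    "plasma_ab42_40_ratio",
    "plasma_ptau181",
    "plasma_nfl",
    "plasma_gfap",
)

# name -> (intercept, age slope, noise sd); unlisted null biomarkers fall
# back to unit-variance noise with no age trend.
_NULL_RECIPES: dict[str, tuple[float, float, float]] = {
    "csf_ab38": (2500.0, 0.0, 300.0),
    "csf_ptau181": (12.0, 0.8, 3.0),
    "csf_nfl": (150.0, 25.0, 120.0),
    "csf_gfap": (3500.0, 180.0, 1400.0),
    # plasma analogues carry no age trend: the emulated panel shows no
    # plasma-flow association, and an age slope would leak a marginal
    # correlation with the (strongly age-linked) flow metrics
    "plasma_ab42_40_ratio": (0.06, 0.0, 0.008),
    "plasma_ptau181": (2.0, 0.0, 0.6),
    "plasma_nfl": (55.0, 0.0, 18.0),
    "plasma_gfap": (230.0, 0.0, 45.0),
}

# affine maps from standardized latent flow to the non-anchor metric columns:
# name -> (centre, slope per latent SD, measurement-noise sd)
_METRIC_MAPS: dict[str, tuple[float, float, float]] = {
    "caudal_volume": (90.0, -28.0, 3.0),
    "amplitude": (24.0, 5.5, 0.5),
    "peak": (12.0, 3.2, 0.3),
}
_CRANIAL_NOISE_SD = 4.0


def gaussian_rho_from_spearman(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman rho is rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


@lru_cache(maxsize=None)
def _spearman_linear_uniform(t: float) -> float:
    """Population Spearman of (X, t*X + Z), X ~ Uniform, Z ~ standard normal.

    Uses rho_s = 6 P[(X1 - X2)(Y1 - Y3) > 0] - 3 for continuous pairs, with
    the probability reduced to a 2-D quadrature over (X1, X3):
    P = E[ X1 * Phi(t (X1 - X3) / sqrt(2)) + (1 - X1) * (1 - Phi(...)) ].
    """
    from scipy.stats import norm

    u = (np.arange(400) + 0.5) / 400.0
    d = norm.cdf(t * (u[:, None] - u[None, :]) / math.sqrt(2.0))
    p = float(np.mean(u[:, None] * d + (1.0 - u[:, None]) * (1.0 - d)))
    return 6.0 * p - 3.0


@lru_cache(maxsize=None)
def _noise_ratio_for_spearman(rho_s_abs: float) -> float:
    """Signal-to-noise ratio t = swing/noise_sd giving the target |Spearman|
    for a uniform regressor with additive Gaussian noise."""
    from scipy.optimize import brentq

    if not 0.0 < rho_s_abs < 1.0:
        raise ValueError("Spearman target must have magnitude in (0, 1)")
    return float(
        brentq(lambda t: _spearman_linear_uniform(t) - rho_s_abs, 1e-9, 200.0)
    )


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the synthetic cohort generator.

    Slope/noise fields left as ``None`` are resolved from the Spearman
    targets; setting any of them explicitly (e.g. ``beta_flow_ratio = 0``
    for a null experiment) overrides the target-derived value.
    """

    n_subjects: int = 16
    age_range: tuple[float, float] = (10.0, 27.0)
    rho_age_flow: float = -0.75
    rho_flow_ratio: float = 0.70
    rho_age_ratio: float = -0.50
    beta_age_flow: float = -9.0
    flow_intercept: float = 400.0
    noise_sd_flow: float | None = None
    beta_flow_ratio: float | None = None
    beta_age_ratio: float | None = None
    ratio_intercept: float | None = None
    noise_sd_ratio: float | None = None
    null_biomarkers: tuple[str, ...] = DEFAULT_NULL_BIOMARKERS
    metric_noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError(
                f"n_subjects must be >= 4 (partial correlation needs "
                f"df = n - 3 >= 1), got {self.n_subjects}"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range low must be < high, got {self.age_range}")
        if not -1 < self.rho_age_flow < 0:
            raise ValueError("rho_age_flow must be in (-1, 0)")
        if not 0 <= self.rho_flow_ratio < 1:
            raise ValueError("rho_flow_ratio must be in [0, 1)")
        if self.noise_sd_flow is not None and not self.noise_sd_flow > 0:
            raise ValueError("noise_sd_flow must be > 0")
        if self.noise_sd_ratio is not None and not self.noise_sd_ratio > 0:
            raise ValueError("noise_sd_ratio must be > 0")

    # --- analytic resolution of the generative parameters ----------------

    @property
    def age_sd(self) -> float:
        lo, hi = self.age_range
        return (hi - lo) / math.sqrt(12.0)

    @property
    def age_mean(self) -> float:
        lo, hi = self.age_range
        return (lo + hi) / 2.0

    def resolved(self) -> "CohortSpec":
        """Fill None slope/noise fields from the Spearman targets."""
        rho_fr = gaussian_rho_from_spearman(self.rho_flow_ratio)
        rho_ar = gaussian_rho_from_spearman(self.rho_age_ratio)

        changes: dict[str, float] = {}
        lo, hi = self.age_range
        swing = abs(self.beta_age_flow) * (hi - lo)
        sd_flow = self.noise_sd_flow
        if sd_flow is None:
            # exact uniform-regressor calibration, not the Gaussian copula:
            # age is uniform, so solve swing/sd for the target Spearman
            sd_flow = swing / _noise_ratio_for_spearman(abs(self.rho_age_flow))
            changes["noise_sd_flow"] = sd_flow

        beta_fr = self.beta_flow_ratio
        if beta_fr is None:
            beta_fr = 4.0e-4
            changes["beta_flow_ratio"] = beta_fr
        sd_ratio = self.noise_sd_ratio
        if sd_ratio is None:
            if rho_fr > 0 and beta_fr != 0:
                sd_ratio = abs(beta_fr) * sd_flow * math.sqrt(1.0 / rho_fr**2 - 1.0)
            else:
                sd_ratio = 0.0145
            changes["noise_sd_ratio"] = sd_ratio

        if self.beta_age_ratio is None:
            other_var = (beta_fr * sd_flow) ** 2 + sd_ratio**2
            total_sd = math.sqrt(other_var / (1.0 - rho_ar**2))
            changes["beta_age_ratio"] = -abs(rho_ar) * total_sd / self.age_sd
        beta_ar = changes.get("beta_age_ratio", self.beta_age_ratio)
        if self.ratio_intercept is None:
            # centre the ratio at 0.10 at the mean age
            changes["ratio_intercept"] = 0.10 - beta_ar * self.age_mean
        return replace(self, **changes) if changes else self

    @property
    def latent_flow_sd(self) -> float:
        """Total SD of the latent flow (age signal + noise), resolved spec."""
        r = self.resolved()
        return math.sqrt(
            (r.beta_age_flow * r.age_sd) ** 2 + r.noise_sd_flow**2
        )


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort table; deterministic per ``spec.seed``.

    Columns: ``subject_id``, ``age_years``, the six flow-metric columns
    (phase-sum units for the volumes, mm^3/s for amplitude/peak),
    ``csf_ab42``, ``csf_ab40``, ``csf_ab42_40_ratio``, and the configured
    null biomarkers.
    """
    spec = (spec or CohortSpec()).resolved()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    age = rng.uniform(*spec.age_range, size=n)
    eps_flow = rng.normal(0.0, spec.noise_sd_flow, size=n)
    latent = spec.flow_intercept + spec.beta_age_flow * age + eps_flow

    latent_mean = spec.flow_intercept + spec.beta_age_flow * spec.age_mean
    latent_z = (latent - latent_mean) / spec.latent_flow_sd

    def noise_sd(name: str, default: float) -> float:
        return spec.metric_noise_sd.get(name, default)

    cranial = latent + rng.normal(0.0, noise_sd("cranial_volume", _CRANIAL_NOISE_SD), n)
    derived = {}
    for name, (centre, slope, sd) in _METRIC_MAPS.items():
        derived[name] = centre + slope * latent_z + rng.normal(0.0, noise_sd(name, sd), n)

    ratio = (
        spec.ratio_intercept
        + spec.beta_age_ratio * age
        + spec.beta_flow_ratio * eps_flow
        + rng.normal(0.0, spec.noise_sd_ratio, n)
    )
    ab40 = rng.normal(8000.0, 900.0, n)

    table = pd.DataFrame(
        {
            "subject_id": [f"V{i + 1:03d}" for i in range(n)],
            "age_years": age,
            "cranial_volume": cranial,
            "caudal_volume": derived["caudal_volume"],
            "net_stroke": cranial - derived["caudal_volume"],
            "absolute_stroke": cranial + derived["caudal_volume"],
            "amplitude": derived["amplitude"],
            "peak": derived["peak"],
            "csf_ab42": ratio * ab40,
            "csf_ab40": ab40,
            "csf_ab42_40_ratio": ratio,
        }
    )
    for name in spec.null_biomarkers:
        b0, b_age, sd = _NULL_RECIPES.get(name, (0.0, 0.0, 1.0))
        table[name] = b0 + b_age * age + rng.normal(0.0, sd, n)
    return table
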