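"""Monte-Carlo uncertainty propagation for the dose model.

Because both dose formulas are products, parameter uncertainty propagates
as a multiplicative *fold factor* R relative to the central point
estimate, independent of the dose magnitude:

* inhalation:  R = L · (FC/FC₀) · (DF/DF₀), with L the atmospheric-model
  (ATDM) error ~ lognormal(GM 1, GSD 3), FC ~ Normal(18.6, 6.0)/30
  truncated at 0, DF ~ Triangular(0.1, mode 0.5, 0.95); centrals
  FC₀ = 18.6/30 and DF₀ = 0.5 (the mode).  Sampled once with 500 000
  Latin-Hypercube draws.

* ingestion:   R = L · (pTWI/pTWI₀) · (FC/FC₀), with pTWI ~
  Gamma(shape k = 4.94009, scale θ = 186.15) mL/day (1-year-olds) and
  pTWI₀ its median.  pTWI is inter-individual *variability*, L and FC are
  *uncertainty*, so a two-dimensional Monte Carlo keeps them apart:
  1000 outer draws of pTWI, each with 5000 inner LHS draws of (L, FC).
  The headline 95% interval is the median across outer iterations of the
  per-outer (uncertainty-loop) interval; the pooled outer×inner interval
  and the full per-outer table are also returned, preserving the
  variability/uncertainty distinction.

Sheltering (DF) does not affect drinking water and is excluded from the
ingestion ratio.

All sampling is Latin-Hypercube: one draw per equal-probability stratum
per marginal, with mutually independent stratum permutations.  A single
master seed derives per-variable substream seeds deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FC_CENTRAL",
    "DF_CENTRAL",
    "PointMass",
    "UncertaintyModel",
    "FoldInterval",
    "Ingestion2DResult",
    "sample_lhs",
    "inhalation_fold_ui",
    "ingestion_fold_ui_2d",
]

log = logging.getLogger(__name__)

FC_CENTRAL = 18.6 / 30.0
DF_CENTRAL = 0.5


class PointMass:
    """Degenerate distribution: every quantile is the single support point."""

    def __init__(self, value: float):
        self.value = float(value)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        out = np.full_like(q, self.value)
        out = np.where((q < 0) | (q > 1), np.nan, out)
        return out if out.shape else float(out)

    def median(self):
        return self.value

    def mean(self):
        return self.value


@dataclass(frozen=True)
class FoldInterval:
    """95% uncertainty interval as fold factors of the central estimate."""

    lower_fold: float
    upper_fold: float
    percentiles: tuple = (2.5, 97.5)

    def as_tuple(self) -> tuple[float, float]:
        return (self.lower_fold, self.upper_fold)


@dataclass(frozen=True)
class UncertaintyModel:
    """PDFs and sampling plan for the fold-factor Monte Carlo.

    Setting ``atdm_gsd=1``, ``fc_sd=0`` or ``df_min=df_mode=df_max``
    degenerates the corresponding marginal to its central point, which is
    how single-parameter intervals and closed-form checks are obtained.
    """

    atdm_gm: float = 1.0
    atdm_gsd: float = 3.0
    fc_mean: float = 18.6
    fc_sd: float = 6.0
    fc_scale: float = 30.0
    df_min: float = 0.1
    df_mode: float = 0.5
    df_max: float = 0.95
    ptwi_theta: float = 186.15  # gamma scale, mL/day (age 1)
    ptwi_k: float = 4.94009  # gamma shape
    n_samples: int = 500_000
    n_outer: int = 1_000
    n_inner: int = 5_000
    seed: int = 0
    ptwi_central: str = "median"  # or "mean"

    def __post_init__(self) -> None:
        if self.atdm_gsd < 1:
            raise ValueError("geometric SD must be >= 1")
        if self.fc_sd < 0 or self.fc_mean <= 0 or self.fc_scale <= 0:
            raise ValueError("FC parameters must be positive (sd >= 0)")
        if not self.df_min <= self.df_mode <= self.df_max:
            raise ValueError("triangular parameters must satisfy min <= mode <= max")
        if not (0.1 <= self.df_min and self.df_max <= 0.95):
            raise ValueError("DF support must stay within [0.1, 0.95]")
        if self.ptwi_theta <= 0 or self.ptwi_k <= 0:
            raise ValueError("gamma parameters must be strictly positive")

    # -- marginal distributions (scipy-frozen or PointMass) ----------------
    def atdm_dist(self):
        if self.atdm_gsd == 1.0:
            return PointMass(self.atdm_gm)
        return stats.lognorm(s=np.log(self.atdm_gsd), scale=self.atdm_gm)

    def fc_dist(self):
        mean = self.fc_mean / self.fc_scale
        sd = self.fc_sd / self.fc_scale
        if sd == 0.0:
            return PointMass(mean)
        # normal truncated at 0: negative uptake is unphysical; the clipped
        # probability is ~1e-3 at mean/sd ~ 3.1
        log.debug("FC normal truncated at 0 (P[<0] = %.2e)", stats.norm.cdf(0, mean, sd))
        return stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)

    def df_dist(self):
        width = self.df_max - self.df_min
        if width == 0.0:
            return PointMass(self.df_mode)
        return stats.triang(
            c=(self.df_mode - self.df_min) / width, loc=self.df_min, scale=width
        )

    def ptwi_dist(self):
        return stats.gamma(self.ptwi_k, scale=self.ptwi_theta)

    # -- central (denominator) values --------------------------------------
    @property
    def fc_central(self) -> float:
        return self.fc_mean / self.fc_scale

    @property
    def df_central(self) -> float:
        return self.df_mode

    @property
    def ptwi_central_value(self) -> float:
        dist = self.ptwi_dist()
        return float(dist.mean() if self.ptwi_central == "mean" else dist.median())


def sample_lhs(dists: dict, n: int, seed: int = 0) -> pd.DataFrame:
    """Latin-Hypercube sample: per variable, exactly one draw in each of the
    ``n`` equal-probability strata, strata independently permuted across
    variables.  Reproducible for a fixed seed."""
    if n < 2:
        raise ValueError("LHS needs n >= 2")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(dists))
    cols = {}
    for (name, dist), child in zip(dists.items(), children):
        rng = np.random.default_rng(child)
        u = (rng.permutation(n) + rng.uniform(size=n)) / n
        cols[name] = np.asarray(dist.ppf(u), dtype=float)
    return pd.DataFrame(cols)


def inhalation_fold_ui(
    model: UncertaintyModel, n: int | None = None, seed: int | None = None
) -> FoldInterval:
    """95% fold interval of the inhalation dose from LHS Monte Carlo over
    the ATDM, FC and DF distributions."""
    n = model.n_samples if n is None else n
    seed = model.seed if seed is None else seed
    table = sample_lhs(
        {"atdm": model.atdm_dist(), "fc": model.fc_dist(), "df": model.df_dist()}, n, seed
    )
    r = (
        (table["atdm"] / model.atdm_gm)
        * (table["fc"] / model.fc_central)
        * (table["df"] / model.df_central)
    ).to_numpy()
    lo, hi = np.percentile(r, [2.5, 97.5])
    return FoldInterval(float(lo), float(hi))


@dataclass
class Ingestion2DResult:
    """Output of the two-dimensional (variability × uncertainty) Monte Carlo."""

    interval: FoldInterval  # headline: median across outer iterations
    pooled: FoldInterval  # percentile of all outer×inner samples
    per_outer: pd.DataFrame  # ptwi_ratio, lower_fold, upper_fold per outer draw


def ingestion_fold_ui_2d(
    model: UncertaintyModel,
    n_outer: int | None = None,
    n_inner: int | None = None,
    seed: int | None = None,
) -> Ingestion2DResult:
    """Two-dimensional Monte Carlo for the ingestion fold interval.

    Outer loop: pTWI variability; inner loop: LHS over (ATDM, FC)
    uncertainty.  Per-outer intervals scale the inner interval by that
    draw's pTWI ratio; the headline interval is their median across the
    outer loop, and the pooled interval uses all outer×inner samples.
    """
    n_outer = model.n_outer if n_outer is None else n_outer
    n_inner = model.n_inner if n_inner is None else n_inner
    seed = model.seed if seed is None else seed

    ss = np.random.SeedSequence(seed)
    outer_seed, inner_seed = ss.spawn(2)

    ptwi = sample_lhs({"ptwi": model.ptwi_dist()}, n_outer, _seed_int(outer_seed))["ptwi"]
    ptwi_ratio = (ptwi / model.ptwi_central_value).to_numpy()

    inner_children = inner_seed.spawn(n_outer)
    lowers = np.empty(n_outer)
    uppers = np.empty(n_outer)
    pooled = np.empty(n_outer * n_inner)
    for i in range(n_outer):
        inner = sample_lhs(
            {"atdm": model.atdm_dist(), "fc": model.fc_dist()},
            n_inner,
            _seed_int(inner_children[i]),
        )
        u = ((inner["atdm"] / model.atdm_gm) * (inner["fc"] / model.fc_central)).to_numpy()
        lo, hi = np.percentile(u, [2.5, 97.5])
        lowers[i] = ptwi_ratio[i] * lo
        uppers[i] = ptwi_ratio[i] * hi
        pooled[i * n_inner : (i + 1) * n_inner] = ptwi_ratio[i] * u

    headline = FoldInterval(float(np.median(lowers)), float(np.median(uppers)))
    plo, phi = np.percentile(pooled, [2.5, 97.5])
    per_outer = pd.DataFrame(
        {"ptwi_ratio": ptwi_ratio, "lower_fold": lowers, "upper_fold": uppers}
    )
    return Ingestion2DResult(headline, FoldInterval(float(plo), float(phi)), per_outer)


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, np.uint32)[0])
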