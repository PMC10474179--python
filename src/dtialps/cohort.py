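"""Synthetic participant cohorts with prescribed association structure.

Cohorts are drawn from a Gaussian copula: every variable has a latent
standard normal, the latents share a target correlation matrix, continuous
variables are affine transforms of their latent and binary variables are
obtained by thresholding theirs at the prevalence quantile.

Group effects on a continuous outcome are specified as a standardized mean
difference (|SMD| plus a direction flag).  Rather than shifting the
outcome after the draw — which would distort its marginal and attenuate
every other correlation target — the requested SMD is converted into the
latent correlation between the binary's latent and the outcome that
produces exactly that expected Cohen's d after thresholding (a
point-biserial inversion using truncated-normal moments).  The copula
therefore stays internally consistent: marginals are exact and all
correlation/SMD targets hold simultaneously in expectation.

``published_screen_spec`` encodes the study conditions of the screen this
package models: a 71-participant cohort whose ALPS index is N(1.24, 0.10)
with the published effect set (age r = −0.434, waist r = −0.455, blood
GFAP r = −0.201, female-sex SMD = +1.0769 at prevalence 44/71, and so on)
arranged as a single-factor correlation structure, which is guaranteed
positive semi-definite while reproducing every pairwise target with the
ALPS index.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Variable",
    "SMDTarget",
    "CohortSpec",
    "make_cohort",
    "smd_to_latent_corr",
    "expected_smd",
    "published_screen_spec",
    "PUBLISHED_CORRELATIONS",
    "PUBLISHED_GROUP_EFFECTS",
]


@dataclass(frozen=True)
class Variable:
    """One cohort column: a normal marginal or a thresholded binary."""

    name: str
    kind: str = "continuous"  # or "binary"
    mean: float = 0.0
    sd: float = 1.0
    prevalence: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"kind must be continuous/binary, got {self.kind!r}")
        if self.kind == "continuous" and self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if self.kind == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError(f"{self.name}: prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class SMDTarget:
    """Target |SMD| of a continuous variable between a binary's groups.

    ``direction`` is +1 when the condition-present group is higher, −1 when
    lower; the magnitude is always nonnegative.
    """

    binary: str
    continuous: str
    magnitude: float
    direction: int = 1

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("SMD magnitude must be ≥ 0 (use direction for sign)")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    @property
    def signed(self) -> float:
        return self.direction * self.magnitude


@dataclass
class CohortSpec:
    """Size, marginals, latent correlations and SMD targets of a cohort."""

    n_subjects: int
    variables: list[Variable]
    latent_corr: np.ndarray | None = None
    smd_targets: list[SMDTarget] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be ≥ 1")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        k = len(self.variables)
        if self.latent_corr is None:
            self.latent_corr = np.eye(k)
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        if self.latent_corr.shape != (k, k):
            raise ValueError(
                f"latent_corr must be {k}×{k}, got {self.latent_corr.shape}"
            )
        byname = {v.name: v for v in self.variables}
        for t in self.smd_targets:
            if t.binary not in byname or byname[t.binary].kind != "binary":
                raise ValueError(f"SMD target names unknown binary {t.binary!r}")
            if t.continuous not in byname or byname[t.continuous].kind != "continuous":
                raise ValueError(f"SMD target names unknown continuous {t.continuous!r}")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]


def _truncnorm_moments(c: float, upper: bool) -> tuple[float, float]:
    """Mean and variance of a standard normal truncated at c (above/below)."""
    if upper:
        d = sps.truncnorm(c, np.inf)
    else:
        d = sps.truncnorm(-np.inf, c)
    return float(d.mean()), float(d.var())


def expected_smd(rho: float, prevalence: float) -> float:
    """Expected Cohen's d (pooled SD) of a standard-normal outcome between
    the groups of a binary thresholded at ``prevalence``, when outcome and
    binary latent have correlation ``rho``."""
    p = prevalence
    c = sps.norm.ppf(1.0 - p)  # latent > c → condition present
    m1, v1 = _truncnorm_moments(c, upper=True)
    m0, v0 = _truncnorm_moments(c, upper=False)
    mean_diff = rho * (m1 - m0)
    # within-group variances of the outcome x = rho*z + sqrt(1-rho^2)*e
    var1 = rho**2 * v1 + (1.0 - rho**2)
    var0 = rho**2 * v0 + (1.0 - rho**2)
    pooled = p * var1 + (1.0 - p) * var0
    return mean_diff / np.sqrt(pooled)


def smd_to_latent_corr(smd: float, prevalence: float) -> float:
    """Invert :func:`expected_smd`: latent correlation giving the target d."""
    if smd == 0:
        return 0.0
    from scipy.optimize import brentq

    lim = 0.999999
    lo, hi = (-lim, 0.0) if smd < 0 else (0.0, lim)
    d_max = expected_smd(lim if smd > 0 else -lim, prevalence)
    if abs(smd) >= abs(d_max):
        raise ValueError(
            f"SMD {smd:g} unreachable at prevalence {prevalence:g} "
            f"(|d| must be < {abs(d_max):.3f})"
        )
    return float(brentq(lambda r: expected_smd(r, prevalence) - smd, lo, hi, xtol=1e-12))


def make_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from the Gaussian copula defined by ``spec``.

    SMD targets are first converted to latent correlations and written into
    the latent matrix (overriding any explicit entry for those pairs); the
    matrix must then be symmetric with unit diagonal and positive
    semi-definite, otherwise the offending eigenvalue is reported.
    Reproducible for a fixed seed (``seed`` argument overrides
    ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = spec.names
    idx = {n: i for i, n in enumerate(names)}
    corr = spec.latent_corr.copy()

    for t in spec.smd_targets:
        var = spec.variables[idx[t.binary]]
        rho = smd_to_latent_corr(t.signed, var.prevalence)
        corr[idx[t.binary], idx[t.continuous]] = rho
        corr[idx[t.continuous], idx[t.binary]] = rho

    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValueError("latent correlation matrix is not symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValueError("latent correlation matrix diagonal must be 1")
    evals, evecs = np.linalg.eigh(corr)
    if evals[0] < -1e-8:
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {evals[0]:.6g})"
        )

    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    z = rng.standard_normal((spec.n_subjects, len(names))) @ root.T

    data = {}
    for j, var in enumerate(spec.variables):
        if var.kind == "continuous":
            data[var.name] = var.mean + var.sd * z[:, j]
        else:
            cut = sps.norm.ppf(1.0 - var.prevalence)
            data[var.name] = (z[:, j] > cut).astype(int)
    df = pd.DataFrame(data)
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# Study conditions of the published multidomain screen (n = 71 older adults)
# ---------------------------------------------------------------------------

#: continuous variables: name -> (Pearson r with the ALPS index, mean, sd).
#: r values are the published screen's; marginal means/SDs are plausible
#: clinical values for community-dwelling older adults (the screen's
#: statistics are location/scale free, so only r matters downstream).
PUBLISHED_CORRELATIONS: dict[str, tuple[float, float, float]] = {
    "age": (-0.434, 67.65, 3.75),
    "waist": (-0.455, 85.0, 10.0),
    "weight": (-0.348, 62.0, 11.0),
    "bmi": (-0.295, 24.5, 3.5),
    "hdl": (0.292, 55.0, 14.0),
    "tchol": (0.396, 195.0, 35.0),
    "tg": (-0.342, 120.0, 60.0),
    "vldl": (-0.342, 24.0, 12.0),
    "hba1c": (-0.324, 5.9, 0.6),
    "phosphate": (0.300, 3.5, 0.45),
    "creatinine": (-0.387, 0.8, 0.2),
    "bun": (-0.303, 15.0, 4.0),
    "anion_gap": (-0.322, 12.0, 2.0),
    "uric_acid": (-0.381, 5.5, 1.3),
    "gfap": (-0.201, 300.0, 110.0),
    "hads_a": (0.238, 4.0, 3.0),
    "ess": (0.278, 6.0, 4.0),
    "dsst": (0.248, 45.0, 12.0),
    "fmt": (0.272, 35.0, 8.0),
}

#: binary variables: name -> (|SMD| on the ALPS index, direction, prevalence).
#: female prevalence is 44/71; the rest are plausible cohort rates.
PUBLISHED_GROUP_EFFECTS: dict[str, tuple[float, int, float]] = {
    "female": (1.0769, +1, 44 / 71),
    "dm": (0.7662, -1, 0.18),
    "overweight": (0.5818, -1, 0.42),
    "metabolic_syndrome": (0.6068, -1, 0.32),
    "smoking": (0.6292, -1, 0.17),
}

ALPS_MEAN, ALPS_SD = 1.24, 0.10


def published_screen_spec(n_subjects: int = 71, seed: int | None = None) -> CohortSpec:
    """CohortSpec reproducing the published screen's effect set.

    The latent correlation structure is a single-factor model: the ALPS
    latent is the factor and every continuous covariate loads on it with
    its published r (so cov(i, j) = rᵢ·rⱼ between covariates) — always
    positive semi-definite.  Binary variables are tied to the ALPS index
    through SMD targets.
    """
    variables = [Variable("alps", "continuous", ALPS_MEAN, ALPS_SD)]
    loadings = [1.0]
    for name, (r, mean, sd) in PUBLISHED_CORRELATIONS.items():
        variables.append(Variable(name, "continuous", mean, sd))
        loadings.append(r)
    smd_targets = []
    for name, (mag, direction, prev) in PUBLISHED_GROUP_EFFECTS.items():
        variables.append(Variable(name, "binary", prevalence=prev))
        # factor loading = the latent correlation the SMD target resolves to,
        # so the rank-one structure (and hence PSD-ness) is preserved exactly
        loadings.append(smd_to_latent_corr(direction * mag, prev))
        smd_targets.append(SMDTarget(name, "alps", mag, direction))

    load = np.asarray(loadings)
    corr = np.outer(load, load)
    np.fill_diagonal(corr, 1.0)
    return CohortSpec(
        n_subjects=n_subjects,
        variables=variables,
        latent_corr=corr,
        smd_targets=smd_targets,
        seed=seed,
    )
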