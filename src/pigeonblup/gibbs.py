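"""Bayesian liability-threshold animal model fitted by Gibbs sampling.

Each binary race trait Y (coded 1/2) is modelled through a latent normal
liability per phenotyped bird,

    L = SEX_i + u_j + e,    u ~ N(0, A sigma2_u),    e ~ N(0, I sigma2_e),

with Y = 1 iff L <= t.  A binary threshold model is only identified up to
location and scale, so the threshold is fixed at t = 0 and the residual
variance at sigma2_e = 1; heritability is reported as
h2 = sigma2_u / (sigma2_u + sigma2_e).

The Gibbs sweep is the classical data-augmentation scheme: liabilities from
truncated normals; sex effects and all breeding values (phenotyped and
unphenotyped pedigree animals alike) as one joint draw from their
conditional normal; sigma2_u from a scaled inverse chi-square.

The joint location draw is performed by an exact block factorization of the
mixed-model equations.  Writing A = L_A L_A' and rotating u into the
eigenbasis of G = (Z L_A)' (Z L_A) = Q S Q', the breeding-value block of the
coefficient matrix becomes diagonal (S + lambda I), so a full joint draw
costs two (n x q) mat-vecs per iteration instead of a q^3 factorization.
Sex effects are drawn first from their conditional with u integrated out
(a Woodbury identity in the same eigenbasis), then u given the drawn sex
effects — together an exact draw from the joint conditional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.special import log_ndtr, ndtri_exp

from .pedigree import Pedigree, relationship_matrix

logger = logging.getLogger(__name__)

# Schedule used in the original analysis; heavy (hours of CPU) but available.
PAPER_SCHEDULE = {"n_iterations": 5_050_000, "burn_in": 50_000, "thinning": 2_500}


@dataclass(frozen=True)
class GibbsConfig:
    """MCMC schedule, identification constraints, and the sigma2_u prior.

    The default schedule (51,000 iterations, 1,000 burn-in, thinning 25)
    retains 2,000 draws, matching the retained-draw count of the full
    schedule at a fraction of the cost.  ``prior_u_df = -2`` with
    ``prior_u_scale = 0`` is the flat prior on sigma2_u; ``sigma2_u_floor``
    prevents absorption at zero.  ``fix_sigma2_u`` freezes the additive
    variance (useful for the probit limit sigma2_u -> 0).
    """

    n_iterations: int = 51_000
    burn_in: int = 1_000
    thinning: int = 25
    seed: int = 0
    sigma2_e: float = 1.0
    threshold: float = 0.0
    prior_u_df: float = -2.0
    prior_u_scale: float = 0.0
    sigma2_u_floor: float = 1e-6
    sigma2_u_init: float = 0.5
    fix_sigma2_u: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning

    def with_paper_schedule(self) -> "GibbsConfig":
        return replace(self, **PAPER_SCHEDULE)


@dataclass
class PosteriorSamples:
    """Retained draws and the orderings they refer to."""

    animal_ids: list[str]
    sex_levels: list[str]
    sigma2_u: np.ndarray          # (m,)
    h2: np.ndarray                # (m,)
    sex_effects: np.ndarray       # (m, n_sex_levels)
    u: np.ndarray                 # (m, q) breeding values, all pedigree animals
    config: GibbsConfig
    trait: str = ""

    @property
    def n_draws(self) -> int:
        return len(self.sigma2_u)

    def summary(self) -> pd.Series:
        return pd.Series(
            {
                "trait": self.trait,
                "n_draws": self.n_draws,
                "h2_mean": float(self.h2.mean()),
                "h2_sd": float(self.h2.std(ddof=1)),
                "sigma2_u_mean": float(self.sigma2_u.mean()),
                **{
                    f"sex_{lev}_mean": float(self.sex_effects[:, i].mean())
                    for i, lev in enumerate(self.sex_levels)
                },
            }
        )

    def diagnostics(self) -> pd.DataFrame:
        """Effective sample size and Geweke z per scalar chain."""
        import arviz as az

        rows = []
        chains = {"sigma2_u": self.sigma2_u, "h2": self.h2}
        for i, lev in enumerate(self.sex_levels):
            chains[f"sex_{lev}"] = self.sex_effects[:, i]
        for name, x in chains.items():
            ess = float(az.ess(np.asarray(x)[None, :]))
            rows.append((name, ess, geweke_z(x)))
        return pd.DataFrame(rows, columns=["parameter", "ess", "geweke_z"])


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late segment means.

    Segment variances are autocorrelation-adjusted via the effective sample
    size of each segment.
    """
    import arviz as az

    x = np.asarray(chain, dtype=float)
    a = x[: max(2, int(first * len(x)))]
    b = x[-max(2, int(last * len(x))):]
    va = a.var(ddof=1) / max(float(az.ess(a[None, :])), 1.0)
    vb = b.var(ddof=1) / max(float(az.ess(b[None, :])), 1.0)
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def sample_liabilities(
    rng: np.random.Generator,
    mean: np.ndarray,
    y: np.ndarray,
    threshold: float = 0.0,
    sigma2_e: float = 1.0,
) -> np.ndarray:
    """Draw liabilities from normals truncated by the observed category.

    Y = 1 confines L to (-inf, t]; Y = 2 to (t, inf).  Inverse-CDF sampling
    in log space (``ndtri_exp`` on ``log_ndtr`` tail masses) keeps the draw
    finite and on the correct side even when the mean sits many residual
    SDs from the threshold.
    """
    mean = np.asarray(mean, dtype=float)
    y = np.asarray(y)
    sd = np.sqrt(sigma2_e)
    a = (threshold - mean) / sd  # standardized cut point
    log_u = np.log(rng.uniform(low=np.finfo(float).tiny, size=mean.shape))
    z = np.empty_like(mean)
    below = y == 1
    # below: z = Phi^-1(U * Phi(a)); above: z = -Phi^-1(U * Phi(-a))
    z[below] = ndtri_exp(log_u[below] + log_ndtr(a[below]))
    z[~below] = -ndtri_exp(log_u[~below] + log_ndtr(-a[~below]))
    # Guard against -inf/inf from underflow at extreme cut points.
    z = np.clip(z, -38.0, 38.0)
    z[below] = np.minimum(z[below], a[below])
    z[~below] = np.maximum(z[~below], np.nextafter(a[~below], np.inf))
    return mean + sd * z


def sample_variance(
    rng: np.random.Generator,
    quad_form: float,
    q: int,
    prior_df: float = -2.0,
    prior_scale: float = 0.0,
    floor: float = 1e-6,
) -> float:
    """Draw sigma2_u from its scaled inverse chi-square full conditional.

    Degrees of freedom ``prior_df + q`` and scale
    ``(u' A^-1 u + prior_df * prior_scale) / (prior_df + q)``; the draw is
    ``SS / chi2_df`` with SS the numerator above, floored at ``floor``.
    """
    df = prior_df + q
    if df <= 0:
        raise ValueError(f"posterior degrees of freedom {df} must be positive")
    ss = quad_form + prior_df * prior_scale
    draw = ss / rng.chisquare(df)
    return max(float(draw), floor)


def sample_location(
    rng: np.random.Generator,
    L: np.ndarray,
    X: np.ndarray,
    Z: sparse.spmatrix,
    A_inv: sparse.spmatrix,
    sigma2_u: float,
    sigma2_e: float = 1.0,
    sex_levels: Optional[Sequence[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint draw of (sex effects, breeding values) via the dense MME.

    Builds and Cholesky-factorizes the full mixed-model coefficient matrix

        [ X'X        X'Z      ]
        [ Z'X   Z'Z + A^-1 λ ],   λ = sigma2_e / sigma2_u,

    and returns one draw from N(C^-1 r, C^-1 sigma2_e).  Cubic in pedigree
    size — the reference implementation used for tests and small problems;
    :class:`ThresholdModel` performs the same draw in an eigenbasis.
    """
    X = np.asarray(X, dtype=float)
    n_fixed = X.shape[1]
    counts = np.asarray(X.sum(axis=0)).ravel()
    if (counts == 0).any():
        empty = int(np.argmin(counts))
        name = sex_levels[empty] if sex_levels is not None else str(empty)
        raise ValueError(f"fixed-effect class {name!r} has no records")
    lam = sigma2_e / sigma2_u
    Zd = Z.toarray() if sparse.issparse(Z) else np.asarray(Z, dtype=float)
    C = np.block(
        [
            [X.T @ X, X.T @ Zd],
            [Zd.T @ X, Zd.T @ Zd + A_inv.toarray() * lam],
        ]
    )
    r = np.concatenate([X.T @ L, Zd.T @ L])
    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ValueError(f"singular mixed-model coefficient matrix: {exc}") from exc
    mean = linalg.cho_solve(cf, r)
    # theta = mean + sqrt(sigma2_e) * Lc^-T z  gives cov = C^-1 sigma2_e
    z = rng.standard_normal(C.shape[0])
    pert = linalg.solve_triangular(cf[0], z, lower=True, trans="T")
    theta = mean + np.sqrt(sigma2_e) * pert
    return theta[:n_fixed], theta[n_fixed:]


class ThresholdModel:
    """Liability-threshold animal model for one pedigree + phenotyped set.

    Precomputes the Cholesky factor of the dense relationship matrix and an
    eigendecomposition coupling it to the incidence of phenotyped animals;
    both are shared across the five race traits, so fitting trait k after
    trait 1 costs only the Gibbs sweep itself.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        phenotyped_ids: Sequence[str],
        sex: Sequence[str],
        sex_levels: Optional[Sequence[str]] = None,
    ) -> None:
        self.pedigree = pedigree
        self.phenotyped_ids = list(phenotyped_ids)
        missing = [a for a in self.phenotyped_ids if a not in pedigree.index]
        if missing:
            raise ValueError(
                f"{len(missing)} phenotyped animals missing from pedigree, "
                f"e.g. {missing[:5]}"
            )
        self.obs_idx = np.array([pedigree.index[a] for a in self.phenotyped_ids])
        sex = list(sex)
        if len(sex) != len(self.phenotyped_ids):
            raise ValueError("sex vector length must match phenotyped ids")
        if sex_levels is None:
            sex_levels = sorted(set(sex))
        self.sex_levels = list(sex_levels)
        for lev in self.sex_levels:
            if sex.count(lev) == 0:
                raise ValueError(f"sex class {lev!r} has no phenotyped records")
        unknown_levels = set(sex) - set(self.sex_levels)
        if unknown_levels:
            raise ValueError(f"sex values outside declared levels: {unknown_levels}")
        lev_idx = {lev: i for i, lev in enumerate(self.sex_levels)}
        n, q = len(self.phenotyped_ids), len(pedigree)
        self.X = np.zeros((n, len(self.sex_levels)))
        self.X[np.arange(n), [lev_idx[s] for s in sex]] = 1.0

        A = relationship_matrix(pedigree).A
        self._L_A = np.linalg.cholesky(A)
        W = self._L_A[self.obs_idx, :]          # Z L_A, (n, q)
        G = W.T @ W
        s_eig, Q = np.linalg.eigh(G)
        self._s = np.clip(s_eig, 0.0, None)
        self._Wt = np.ascontiguousarray(W @ Q)  # Z L_A Q, (n, q)
        self._T = np.ascontiguousarray(self._L_A @ Q)  # maps w -> u, (q, q)
        self._WtX = self._Wt.T @ self.X         # (q, n_fixed)
        self._XtX = self.X.T @ self.X

    # -- one Gibbs iteration's location draw, exact joint via block factorization
    def _draw_location(
        self, rng: np.random.Generator, L: np.ndarray, sigma2_u: float, sigma2_e: float
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (sex effects b, rotated breeding values w, fitted Zu)."""
        s, Wt, WtX = self._s, self._Wt, self._WtX
        c = sigma2_u / sigma2_e
        WtL = Wt.T @ L
        # b | L (u marginalized): GLS with V = I + c W W'  (Woodbury in eigenbasis)
        g = 1.0 / (1.0 / c + s) if c > 0 else np.zeros_like(s)
        XtVinvX = self._XtX - WtX.T @ (g[:, None] * WtX)
        XtVinvL = self.X.T @ L - WtX.T @ (g * WtL)
        cov_b = sigma2_e * np.linalg.inv(XtVinvX)
        mean_b = cov_b @ XtVinvL / sigma2_e
        b = rng.multivariate_normal(mean_b, cov_b, method="cholesky")
        # w | b, L: diagonal precision (s + lambda) / sigma2_e
        lam = sigma2_e / sigma2_u
        prec = (s + lam) / sigma2_e
        mean_w = (WtL - WtX @ b) / sigma2_e / prec
        w = mean_w + rng.standard_normal(len(s)) / np.sqrt(prec)
        zu = Wt @ w
        return b, w, zu

    def fit(self, y: np.ndarray, config: GibbsConfig, trait: str = "") -> PosteriorSamples:
        """Run the Gibbs sampler for one binary trait (values in {1, 2}).

        Raises
        ------
        ValueError
            If only one category is observed ("no variation in trait") or
            y contains values outside {1, 2}.
        """
        y = np.asarray(y)
        if y.shape != (len(self.phenotyped_ids),):
            raise ValueError("y length must match phenotyped ids")
        if not np.isin(y, (1, 2)).all():
            raise ValueError("categories must be coded 1/2")
        if len(np.unique(y)) < 2:
            raise ValueError(f"no variation in trait {trait or '<unnamed>'}")
        rng = np.random.default_rng(config.seed)
        n, q = len(y), len(self.pedigree)
        m = config.n_retained
        sigma2_e, t = config.sigma2_e, config.threshold
        fixed_var = config.fix_sigma2_u
        if fixed_var is not None:
            sigma2_u = max(float(fixed_var), 1e-12)  # avoid a zero-division at the probit limit
        else:
            sigma2_u = config.sigma2_u_init

        b = np.zeros(len(self.sex_levels))
        zu = np.zeros(n)
        out_s2u = np.empty(m)
        out_b = np.empty((m, len(b)))
        out_u = np.empty((m, q))
        kept = 0
        for it in range(config.n_iterations):
            L = sample_liabilities(rng, self.X @ b + zu, y, t, sigma2_e)
            b, w, zu = self._draw_location(rng, L, sigma2_u, sigma2_e)
            if fixed_var is None:
                # u' A^-1 u = |w|^2 in the rotated basis
                sigma2_u = sample_variance(
                    rng,
                    float(w @ w),
                    q,
                    config.prior_u_df,
                    config.prior_u_scale,
                    config.sigma2_u_floor,
                )
            if it >= config.burn_in and (it - config.burn_in) % config.thinning == 0:
                if kept < m:
                    out_s2u[kept] = sigma2_u
                    out_b[kept] = b
                    out_u[kept] = self._T @ w
                    kept += 1
        h2 = out_s2u / (out_s2u + sigma2_e)
        logger.info(
            "trait %s: %d retained draws, posterior mean h2 = %.3f",
            trait or "<unnamed>",
            kept,
            float(h2.mean()),
        )
        return PosteriorSamples(
            animal_ids=self.pedigree.ids,
            sex_levels=self.sex_levels,
            sigma2_u=out_s2u[:kept],
            h2=h2[:kept],
            sex_effects=out_b[:kept],
            u=out_u[:kept],
            config=config,
            trait=trait,
        )
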