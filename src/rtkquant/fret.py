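"""Monomer–dimer equilibrium FRET model for membrane receptors.

A receptor population at total surface density ``[T]`` partitions between
monomers M and dimers D according to mass action with a two-dimensional
dissociation constant ``K_diss = [M]^2 / [D]`` (all quantities in the same,
arbitrary, surface-density units).  The fraction of protomers that are
dimeric is

    f_D([T]; K) = ([T] - (K/4)(sqrt(1 + 8[T]/K) - 1)) / [T]

and the measured FRET efficiency in a membrane region with acceptor
fraction ``x_A`` is

    FRET = f_D * x_A * E~

where the intrinsic FRET ``E~`` is the efficiency inside a single
donor–acceptor dimer, a structural constant independent of dimerization
propensity.  Fitting FRET/x_A against [T] therefore yields the two unknowns
(K_diss, E~) of the dimerization curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FretSample",
    "DimerFitResult",
    "dimeric_fraction",
    "predict_fret",
    "fit_dimerization",
    "bootstrap_fit",
]


@dataclass(frozen=True)
class FretSample:
    """One membrane-region measurement.

    Attributes
    ----------
    region_id : str
        Identifier of the membrane region (typically cell + region index).
    total_density : float
        Total receptor surface density [T] = donor + acceptor densities.
    acceptor_fraction : float
        x_A = acceptor / (donor + acceptor), in [0, 1].
    fret : float
        Measured FRET efficiency in [0, 1].
    """

    region_id: str
    total_density: float
    acceptor_fraction: float
    fret: float

    def __post_init__(self) -> None:
        if not self.total_density > 0:
            raise ValueError(f"total_density must be > 0, got {self.total_density}")
        if not 0.0 <= self.acceptor_fraction <= 1.0:
            raise ValueError(
                f"acceptor_fraction must be in [0, 1], got {self.acceptor_fraction}"
            )
        if not 0.0 <= self.fret <= 1.0:
            raise ValueError(f"fret must be in [0, 1], got {self.fret}")


@dataclass
class DimerFitResult:
    """Result of fitting the dimerization curve.

    Confidence intervals are asymptotic (estimate ± 1.96 SE, delta method on
    the internal log/logit parameterization) unless produced by
    :func:`bootstrap_fit`.
    """

    k_diss: float
    e_tilde: float
    k_diss_se: float
    e_tilde_se: float
    k_diss_ci: tuple[float, float]
    e_tilde_ci: tuple[float, float]
    rss: float
    n_samples: int
    converged: bool
    non_identifiable: bool = False
    message: str = ""
    warnings: list[str] = field(default_factory=list)


def dimeric_fraction(total_density, k_diss):
    """Fraction of protomers in dimers at density ``[T]`` and constant ``K``.

    Evaluated in the cancellation-free form

        f_D = 1 - 2 / (1 + sqrt(1 + 8 T / K))

    which is algebraically identical to the textbook expression
    ``(T - (K/4)(sqrt(1+8T/K)-1)) / T`` but numerically stable for
    ``T/K`` spanning arbitrarily many orders of magnitude (the textbook form
    loses all significant digits for ``T << K``).

    Parameters
    ----------
    total_density : float or array_like
        Total receptor surface density [T], > 0.
    k_diss : float or array_like
        Two-dimensional dissociation constant, same units as [T], > 0.

    Returns
    -------
    float or ndarray
        f_D in the open interval (0, 1).
    """
    t = np.asarray(total_density, dtype=float)
    k = np.asarray(k_diss, dtype=float)
    if np.any(t <= 0):
        raise ValueError("total_density must be > 0")
    if np.any(k <= 0):
        raise ValueError("k_diss must be > 0")
    f = 1.0 - 2.0 / (1.0 + np.sqrt(1.0 + 8.0 * t / k))
    if f.ndim == 0:
        return float(f)
    return f


def predict_fret(total_density, acceptor_fraction, k_diss, e_tilde):
    """Forward model: FRET = f_D([T]; K) * x_A * E~."""
    x = np.asarray(acceptor_fraction, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("acceptor_fraction must be in [0, 1]")
    if not 0.0 < e_tilde <= 1.0:
        raise ValueError(f"e_tilde must be in (0, 1], got {e_tilde}")
    out = dimeric_fraction(total_density, k_diss) * x * e_tilde
    return out


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


from scipy.special import expit as _expit  # noqa: E402


def _residuals(theta, t, y, w):
    """Residuals of FRET/x_A against f_D * E~ in the (log K, logit E~) space.

    log K is clamped to +/-300 so optimizer line searches cannot push K to
    exactly 0 or infinity in floating point.
    """
    k = math.exp(min(max(theta[0], -300.0), 300.0))
    e = float(_expit(theta[1]))
    return w * (dimeric_fraction(t, k) * e - y)


def fit_dimerization(
    samples,
    init: tuple[float, float] | None = None,
    weights=None,
) -> DimerFitResult:
    """Fit (K_diss, E~) to dimerization-curve data by nonlinear least squares.

    The objective is sum_i w_i (FRET_i / x_A,i - f_D(T_i; K) * E~)^2, i.e.
    the fit is performed on the acceptor-fraction-normalized efficiency, as
    the equilibrium link equation is written.  Parameters are optimized on
    log scale (K_diss) and logit scale (E~) so positivity and the (0, 1]
    efficiency bound hold without a constrained solver.  When ``init`` is
    absent a multi-start over a log-spaced K grid spanning
    1e-2–1e4 x median(T) guards against local minima.

    Parameters
    ----------
    samples : iterable of FretSample
        Must contain >= 2 samples with x_A > 0 and a nontrivial density
        spread.
    init : (k_diss, e_tilde), optional
        Starting point; skips the multi-start.
    weights : array_like, optional
        Per-sample weights on FRET/x_A (e.g. inverse variances); default
        equal weights.

    Returns
    -------
    DimerFitResult
        With asymptotic standard errors from the curvature at the optimum
        and a ``non_identifiable`` flag raised when the objective profile in
        K is flat (e.g. all data in the pure-dimer plateau).
    """
    samples = [s for s in samples if s.acceptor_fraction > 0]
    if len(samples) < 2:
        raise ValueError(
            "need >= 2 samples with acceptor_fraction > 0 to fit two parameters"
        )
    t = np.array([s.total_density for s in samples])
    y = np.array([s.fret / s.acceptor_fraction for s in samples])
    if weights is None:
        w = np.ones_like(t)
    else:
        w = np.sqrt(np.asarray(weights, dtype=float))
        if w.shape != t.shape:
            raise ValueError("weights must match the number of usable samples")

    warns: list[str] = []
    t_spread = t.max() / t.min()
    if t_spread < 1.05:
        warns.append(
            "density range spans < 5%; K_diss is ill-conditioned on these data"
        )

    med_t = float(np.median(t))
    if init is not None:
        starts = [(math.log(init[0]), _logit(min(max(init[1], 1e-6), 1 - 1e-9)))]
    else:
        k_grid = med_t * np.logspace(-2, 4, 13)
        e0 = min(max(float(np.clip(y.max(), 0.05, 0.95)), 0.05), 0.95)
        starts = [(math.log(k), _logit(e0)) for k in k_grid]

    best = None
    for theta0 in starts:
        sol = least_squares(
            _residuals,
            x0=np.array(theta0),
            args=(t, y, w),
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=500 * 2,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol

    k_hat = math.exp(best.x[0])
    e_hat = float(_expit(best.x[1]))
    rss = float(2.0 * best.cost)
    n = len(samples)

    # Flat-profile check: if dividing K by 10 changes the objective by less
    # than tolerance, the data do not constrain K from below; walk down the
    # grid and report the smallest K in the flat region.
    non_ident = False
    obj_tol = 1e-10 * (1.0 + rss)
    k_probe = k_hat
    while True:
        k_lower = k_probe / 10.0
        r = _residuals(np.array([math.log(k_lower), best.x[1]]), t, y, w)
        if abs(float(r @ r) - rss) <= obj_tol:
            non_ident = True
            k_probe = k_lower
            if k_probe < 1e-12 * med_t:
                break
        else:
            break
    if non_ident:
        k_hat = k_probe
        warns.append(
            "objective is flat in K_diss below the data range; reporting the "
            "smallest K in the flat region"
        )

    # Asymptotic covariance from J^T J at the optimum (internal scale), then
    # delta method: d k/d logk = k, d e/d logit e = e(1-e).
    dof = max(n - 2, 1)
    s2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se_logk = math.sqrt(max(cov[0, 0], 0.0))
        se_logite = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_logk = se_logite = float("inf")
        non_ident = True
    k_se = k_hat * se_logk
    e_se = e_hat * (1 - e_hat) * se_logite
    z = 1.959963984540054
    k_ci = (k_hat * math.exp(-z * se_logk), k_hat * math.exp(z * se_logk))
    e_ci = (
        float(_expit(best.x[1] - z * se_logite)),
        float(_expit(best.x[1] + z * se_logite)),
    )

    return DimerFitResult(
        k_diss=k_hat,
        e_tilde=e_hat,
        k_diss_se=k_se,
        e_tilde_se=e_se,
        k_diss_ci=k_ci,
        e_tilde_ci=e_ci,
        rss=rss,
        n_samples=n,
        converged=bool(best.success),
        non_identifiable=non_ident,
        message=best.message,
        warnings=warns,
    )


def bootstrap_fit(
    samples,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> DimerFitResult:
    """Case-resampling bootstrap confidence intervals for (K_diss, E~).

    Resamples whole regions with replacement, refits each replicate starting
    from the full-data optimum, and reports percentile intervals.
    Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for stable percentile intervals")
    samples = list(samples)
    if len([s for s in samples if s.acceptor_fraction > 0]) < 2:
        raise ValueError("fewer usable samples than parameters")
    full = fit_dimerization(samples)
    rng = np.random.default_rng(seed)
    n = len(samples)
    ks = np.empty(n_boot)
    es = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = [samples[i] for i in idx]
        try:
            r = fit_dimerization(boot, init=(full.k_diss, full.e_tilde))
            ks[b] = r.k_diss
            es[b] = r.e_tilde
        except ValueError:
            ks[b] = np.nan
            es[b] = np.nan
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    k_ci = tuple(np.nanpercentile(ks, [lo, hi]))
    e_ci = tuple(np.nanpercentile(es, [lo, hi]))
    return replace(
        full,
        k_diss_ci=(float(k_ci[0]), float(k_ci[1])),
        e_tilde_ci=(float(e_ci[0]), float(e_ci[1])),
        k_diss_se=float(np.nanstd(ks, ddof=1)),
        e_tilde_se=float(np.nanstd(es, ddof=1)),
        message=f"percentile bootstrap, {n_boot} replicates",
    )


def read_samples_csv(path) -> list[FretSample]:
    """Read region measurements from CSV.

    Expected columns: ``region_id, donor_density, acceptor_density, fret``.
    Total density is donor + acceptor; the acceptor fraction is
    acceptor / (donor + acceptor).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"region_id", "donor_density", "acceptor_density", "fret"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        total = float(row.donor_density) + float(row.acceptor_density)
        out.append(
            FretSample(
                region_id=str(row.region_id),
                total_density=total,
                acceptor_fraction=float(row.acceptor_density) / total,
                fret=float(row.fret),
            )
        )
    return out
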