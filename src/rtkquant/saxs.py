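"""Primary small-angle X-ray scattering analysis.

Covers the standard desk pipeline applied to a reduced, background-
subtracted scattering curve I(q):

- Guinier fitting of the low-q region, ln I = ln I0 - (Rg^2/3) q^2, with the
  conventional validity window q_max * Rg <= 1.3.
- The Debye formula as a forward model from point coordinates,
  I(q) = sum_ij w_i w_j sinc(q r_ij), with an optional distance-histogram
  acceleration for large point sets.
- The pair-distance distribution P(r): directly from coordinates as a
  weighted pairwise-distance histogram, or from a scattering curve by a
  regularized indirect Fourier transform (IFT) with non-negativity and
  endpoint constraints, scanning candidate maximum dimensions D_max and
  scoring each by fit quality, smoothness and support parsimony.
- Consistency statistics between the three Rg routes (coordinates, Guinier,
  second moment of P(r): Rg^2 = \\int r^2 P(r) dr / 2) and curve-to-curve
  P(r) comparisons (Delta D_max, Delta Rg, tail mass, L1 distance).

Point weights default to 1 (shape-only scattering); atomic form factors and
hydration shells are out of scope — they scale absolute intensities but not
the shape-level quantities computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

__all__ = [
    "ScatteringCurve",
    "AtomSet",
    "GuinierResult",
    "PairDistribution",
    "read_scattering",
    "write_scattering",
    "read_pdb",
    "write_pdb",
    "guinier_fit",
    "debye_intensity",
    "pr_from_structure",
    "ift_pr",
    "compare_pr",
    "radius_of_gyration",
]


@dataclass
class ScatteringCurve:
    """A reduced 1-D scattering curve: q (1/Angstrom), I(q), optional sigma."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity lengths differ")
        if np.any(self.q <= 0):
            raise ValueError("q must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")

    @property
    def negative_intensity_mask(self) -> np.ndarray:
        """Points with I <= 0 (noise-dominated high-q tail); flagged, kept."""
        return self.intensity <= 0

    def trimmed(self) -> "ScatteringCurve":
        """Copy without non-positive-intensity points."""
        keep = ~self.negative_intensity_mask
        return ScatteringCurve(
            self.q[keep],
            self.intensity[keep],
            None if self.sigma is None else self.sigma[keep],
        )


@dataclass
class AtomSet:
    """Point model: n x 3 coordinates in Angstrom with scattering weights."""

    coordinates: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be n x 3")
        if self.coordinates.shape[0] < 1:
            raise ValueError("need at least one point")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.weights is None:
            self.weights = np.ones(len(self.coordinates))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (len(self.coordinates),):
                raise ValueError("weights length must match coordinates")

    def __len__(self) -> int:
        return len(self.coordinates)


@dataclass
class GuinierResult:
    rg: float
    i0: float
    q_range_used: tuple[float, float]
    r_squared: float
    qmax_rg: float
    n_points: int


@dataclass
class PairDistribution:
    """P(r) on a grid 0..d_max, unit area, with the moment Rg."""

    r: np.ndarray
    p: np.ndarray
    d_max: float
    rg: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.r.shape != self.p.shape:
            raise ValueError("r and p lengths differ")


def radius_of_gyration(atoms: AtomSet) -> float:
    """Mass-weighted Rg about the centroid, directly from coordinates."""
    w = atoms.weights / atoms.weights.sum()
    center = w @ atoms.coordinates
    d2 = np.sum((atoms.coordinates - center) ** 2, axis=1)
    return float(np.sqrt(w @ d2))


# ---------------------------------------------------------------------------
# I/O


def read_scattering(path) -> ScatteringCurve:
    """Read a 2- or 3-column text scattering file (q, I[, sigma]).

    Whitespace- or comma-separated; lines starting with '#', ';' or '%'
    (and blank lines) are ignored.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s[0] in "#;%":
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(x) for x in parts]
            except ValueError:
                continue  # tolerate stray header text
            if len(vals) >= 2:
                rows.append(vals[:3])
    if not rows:
        raise ValueError(f"no data rows found in {path}")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows])
    sigma = arr[:, 2] if ncol >= 3 else None
    return ScatteringCurve(arr[:, 0], arr[:, 1], sigma)


def write_scattering(curve: ScatteringCurve, path) -> None:
    cols = [curve.q, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(
        path,
        np.column_stack(cols),
        header="q(1/A) I(q)" + (" sigma" if curve.sigma is not None else ""),
        fmt="%.10g",
    )


def read_pdb(path, chain: str | None = None, ca_only: bool = False) -> AtomSet:
    """Read ATOM/HETATM coordinates from a PDB file via gemmi.

    Parameters
    ----------
    chain : optional chain name to select.
    ca_only : keep only C-alpha atoms (coarse backbone model).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    coords = []
    for model in st:
        for ch in model:
            if chain is not None and ch.name != chain:
                continue
            for res in ch:
                for atom in res:
                    if ca_only and atom.name != "CA":
                        continue
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not coords:
        raise ValueError(f"no atoms selected from {path}")
    return AtomSet(np.array(coords))


def write_pdb(atoms: AtomSet, path) -> None:
    """Write a point model as minimal PDB ATOM records (dummy carbons)."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(atoms.coordinates, start=1):
            serial = i % 100000
            resseq = ((i - 1) // 10) % 10000 + 1
            fh.write(
                f"ATOM  {serial:5d}  C   BEA A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Guinier


def guinier_fit(curve: ScatteringCurve, qmax_rg_cutoff: float = 1.3) -> GuinierResult:
    """Fit the Guinier region of a scattering curve.

    Starts from the 5 lowest-q points and extends the window while the
    self-consistency condition q_max * Rg <= cutoff holds for the Rg fitted
    on that window.  Returns Rg = sqrt(-3 * slope) and I0 = exp(intercept)
    of the ln I vs q^2 regression, plus the linearity R^2 of the final
    window.
    """
    c = curve.trimmed()
    if len(c.q) < 5:
        raise ValueError("need >= 5 positive-intensity points for a Guinier fit")
    q2 = c.q**2
    lnI = np.log(c.intensity)

    def fit_window(n):
        A = np.column_stack([q2[:n], np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, lnI[:n], rcond=None)
        return coef  # slope, intercept

    n = 5
    best_n = None
    while n <= len(c.q):
        slope, intercept = fit_window(n)
        if slope >= 0:
            if best_n is None:
                # noise can flip the slope of a tiny initial window; keep
                # growing before declaring the curve non-globular
                n += 1
                continue
            break
        rg = math.sqrt(-3.0 * slope)
        if c.q[n - 1] * rg > qmax_rg_cutoff:
            if best_n is not None:
                break
        else:
            best_n = n
        n += 1
    if best_n is None:
        # even 5 points exceed the cutoff; accept the minimal window
        best_n = 5
        slope, intercept = fit_window(best_n)
        if slope >= 0:
            raise ValueError(
                "positive Guinier slope: no Guinier region "
                "(non-globular or aggregated input)"
            )
    slope, intercept = fit_window(best_n)
    rg = math.sqrt(-3.0 * slope)
    resid = lnI[:best_n] - (slope * q2[:best_n] + intercept)
    ss_tot = float(np.sum((lnI[:best_n] - lnI[:best_n].mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return GuinierResult(
        rg=rg,
        i0=math.exp(intercept),
        q_range_used=(float(c.q[0]), float(c.q[best_n - 1])),
        r_squared=r2,
        qmax_rg=float(c.q[best_n - 1] * rg),
        n_points=best_n,
    )


# ---------------------------------------------------------------------------
# Debye forward model and structure-based P(r)


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (unnormalized convention)."""
    return np.sinc(x / np.pi)


def debye_intensity(
    atoms: AtomSet, q_grid, method: str = "auto", bin_width: float = 0.1
) -> ScatteringCurve:
    """Debye scattering intensity of a point model.

    I(q) = sum_i sum_j w_i w_j sin(q r_ij)/(q r_ij), including the i = j
    terms, so I(0) = (sum w)^2.  ``method`` is "direct" (exact O(n^2) per q),
    "histogram" (pairwise distances binned at ``bin_width`` Angstrom), or
    "auto" (direct for n <= 2000).
    """
    q = np.asarray(q_grid, dtype=float)
    if q.size == 0:
        raise ValueError("empty q grid")
    n = len(atoms)
    w = atoms.weights
    if method == "auto":
        method = "direct" if n <= 2000 else "histogram"
    if n == 1:
        return ScatteringCurve(q, np.full(q.shape, float(w[0] ** 2)))
    self_term = float(w @ w)
    if method == "direct":
        d = pdist(atoms.coordinates)
        iu = np.triu_indices(n, k=1)
        pw = w[iu[0]] * w[iu[1]]
        # I(q) = self + 2 * sum_{i<j} w_i w_j sinc(q d)
        I = self_term + 2.0 * np.array(
            [np.sum(pw * _sinc(qi * d)) for qi in q]
        )
    elif method == "histogram":
        centers, hist = _pair_histogram(atoms, bin_width)
        I = self_term + 2.0 * np.array(
            [np.sum(hist * _sinc(qi * centers)) for qi in q]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return ScatteringCurve(q, I)


def _pair_histogram(atoms: AtomSet, bin_width: float):
    """Weighted histogram of unordered pair distances (i < j)."""
    d = pdist(atoms.coordinates)
    w = atoms.weights
    n = len(atoms)
    iu = np.triu_indices(n, k=1)
    pw = w[iu[0]] * w[iu[1]]
    d_max = float(d.max())
    n_bins = max(int(np.ceil(d_max / bin_width)), 1)
    hist, edges = np.histogram(
        d, bins=n_bins, range=(0.0, n_bins * bin_width), weights=pw
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, hist


def pr_from_structure(atoms: AtomSet, bin_width: float = 1.0) -> PairDistribution:
    """Pair-distance distribution of a point model.

    Histogram of weighted pairwise distances, normalized to unit area
    (rectangle rule), with P(0) = 0 and support ending at the maximum
    pairwise distance.  Rg comes from the second moment,
    Rg^2 = \\int r^2 P(r) dr / 2, which for a distribution computed from
    coordinates equals the mass-weighted coordinate Rg up to binning.
    """
    if len(atoms) < 2:
        raise ValueError("need >= 2 points for a pair distribution")
    centers, hist = _pair_histogram(atoms, bin_width)
    d = pdist(atoms.coordinates)
    d_max = float(d.max())
    # prepend the r=0 boundary and append a zero just past d_max
    r = np.concatenate([[0.0], centers, [centers[-1] + bin_width]])
    p = np.concatenate([[0.0], hist, [0.0]]).astype(float)
    area = np.sum(p) * bin_width
    p /= area
    rg2 = np.sum(r**2 * p) * bin_width / 2.0
    return PairDistribution(r=r, p=p, d_max=d_max, rg=float(np.sqrt(rg2)))


# ---------------------------------------------------------------------------
# Indirect Fourier transform


def _ift_single(curve: ScatteringCurve, d_max: float, alpha: float, n_r: int):
    """Regularized non-negative least-squares inversion at one fixed D_max.

    Solves  min || (A p - I)/sigma ||^2 + alpha ||D2 p||^2,  p >= 0,
    where A maps P(r) on an r grid of ``n_r`` points (endpoints pinned to 0)
    through I(q) = 4 pi \\int P(r) sinc(q r) dr.  Returns (p_full, chi2_red,
    roughness) with p_full including the pinned endpoints.
    """
    q = curve.q
    I = curve.intensity
    if curve.sigma is not None:
        sig = curve.sigma
    else:
        # no experimental errors: weight relatively (1% of I, floored) so the
        # decades-spanning intensity contributes shape information at all q
        sig = np.maximum(1e-2 * np.abs(I), 1e-8 * np.abs(I).max())
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    inner = slice(1, n_r - 1)  # P(0) = P(d_max) = 0 pinned
    A = 4.0 * np.pi * _sinc(np.outer(q, r[inner])) * dr
    Aw = A / sig[:, None]
    Iw = I / sig
    m = n_r - 2
    # second-difference operator on the inner grid (implicit zeros outside)
    D2 = np.zeros((m, m))
    for i in range(m):
        D2[i, i] = -2.0
        if i > 0:
            D2[i, i - 1] = 1.0
        if i < m - 1:
            D2[i, i + 1] = 1.0
    D2 /= dr**2
    scale = np.sqrt(alpha)
    stacked = np.vstack([Aw, scale * D2])
    target = np.concatenate([Iw, np.zeros(m)])
    try:
        p_inner, _ = nnls(stacked, target, maxiter=100 * m)
    except RuntimeError:
        # ill-conditioned at this (d_max, alpha): report an unusable fit
        return r, np.zeros(n_r), float("inf"), float("inf")
    resid = Aw @ p_inner - Iw
    dof = max(len(q) - m, 1)
    chi2_red = float(resid @ resid) / dof
    rough = float(np.sum((D2 @ p_inner) ** 2)) * dr
    p_full = np.concatenate([[0.0], p_inner, [0.0]])
    return r, p_full, chi2_red, rough


def _alpha_scale(curve: ScatteringCurve, d_max: float, n_r: int) -> float:
    """Natural regularization scale: ratio of the squared Frobenius norms of
    the weighted design matrix and the second-difference operator, so a
    dimensionless weight of 1 balances the two terms."""
    q = curve.q
    sig = curve.sigma
    if sig is None:
        sig = np.maximum(1e-2 * np.abs(curve.intensity), 1e-8 * np.abs(curve.intensity).max())
    r = np.linspace(0.0, d_max, n_r)
    dr = r[1] - r[0]
    A = 4.0 * np.pi * _sinc(np.outer(q, r[1:-1])) * dr
    a_norm = float(np.sum((A / sig[:, None]) ** 2))
    d2_norm = 6.0 * (n_r - 2) / dr**4  # ||D2||_F^2 of the tridiagonal stencil
    return a_norm / d2_norm


def _choose_alpha(curve: ScatteringCurve, d_max: float, n_r: int) -> float:
    """L-curve-style heuristic: the largest alpha whose chi^2 stays within
    10% of the least-regularized fit."""
    alphas = np.geomspace(1e-10, 1.0, 11) * _alpha_scale(curve, d_max, n_r)
    chi2s = []
    for a in alphas:
        _, _, c, _ = _ift_single(curve, d_max, a, n_r)
        chi2s.append(c)
    chi2s = np.asarray(chi2s)
    best = np.nanmin(np.where(np.isfinite(chi2s), chi2s, np.nan))
    ok = np.flatnonzero(chi2s <= 1.10 * best + 1e-12)
    return float(alphas[ok[-1]])


def ift_pr(
    curve: ScatteringCurve,
    d_max_candidates,
    alpha: float | None = None,
    n_r: int = 101,
    return_diagnostics: bool = False,
):
    """Indirect Fourier transform: P(r) and D_max from a scattering curve.

    For each candidate D_max the inversion of
    I(q) = 4 pi \\int_0^{D_max} P(r) sinc(q r) dr is solved on a fixed
    ``n_r``-point r grid with a second-derivative smoothness penalty,
    non-negativity, and P(0) = P(D_max) = 0.  Candidates are scored by a
    perceptual criterion combining goodness of fit, curve roughness, and a
    parsimony rule: among candidates whose chi^2 is within 5% of the best,
    the smallest D_max wins (excess support costs nothing in chi^2 but
    spreads oscillatory artifacts).  The smoothness weight is picked per
    candidate by an L-curve heuristic unless ``alpha`` is given.

    Returns the winning :class:`PairDistribution` (and the per-candidate
    diagnostics table if requested).
    """
    cands = sorted(float(d) for d in np.atleast_1d(d_max_candidates))
    if not cands or min(cands) <= 0:
        raise ValueError("d_max candidates must be positive")
    if len(curve.q) < 50:
        raise ValueError("need >= 50 scattering points for a stable inversion")
    diags = []
    for d_max in cands:
        a = alpha if alpha is not None else _choose_alpha(curve, d_max, n_r)
        r, p, chi2_red, rough = _ift_single(curve, d_max, a, n_r)
        diags.append(
            {"d_max": d_max, "alpha": a, "chi2_red": chi2_red, "roughness": rough,
             "r": r, "p": p}
        )
    chi2s = np.array([d["chi2_red"] for d in diags])
    best_chi2 = chi2s.min()
    if not np.isfinite(best_chi2):
        raise ValueError(
            "no candidate D_max admits a finite fit; diagnostics: "
            + ", ".join(f"D={d['d_max']:g}: chi2={d['chi2_red']:.3g}" for d in diags)
        )
    admissible = [d for d, c in zip(diags, chi2s) if c <= 1.05 * best_chi2]
    # among near-equal fits prefer the smallest support, then the smoothest
    admissible.sort(key=lambda d: (d["d_max"], d["roughness"]))
    win = admissible[0]
    r, p = win["r"], win["p"]
    dr = r[1] - r[0]
    area = np.trapezoid(p, r)
    if area <= 0:
        raise ValueError("inversion returned an empty P(r)")
    p = p / area
    rg2 = np.trapezoid(r**2 * p, r) / 2.0
    # effective D_max: last r with appreciable mass (support may end before
    # the candidate boundary)
    nz = np.flatnonzero(p > 1e-4 * p.max())
    d_eff = float(r[nz[-1]]) if nz.size else win["d_max"]
    pr = PairDistribution(r=r, p=p, d_max=d_eff, rg=float(np.sqrt(rg2)))
    if return_diagnostics:
        return pr, [
            {k: d[k] for k in ("d_max", "alpha", "chi2_red", "roughness")}
            for d in diags
        ]
    return pr


# ---------------------------------------------------------------------------
# P(r) comparison


def compare_pr(
    pr_a: PairDistribution, pr_b: PairDistribution, tail_quantile: float = 0.9
) -> dict:
    """Compare two pair-distance distributions (a minus b).

    Both are interpolated onto a common grid zero-padded to the larger
    D_max.  Reports Delta D_max, Delta Rg, the difference in mass beyond the
    ``tail_quantile`` of the *pooled* distribution (a tail-prominence
    measure), and the L1 distance between the normalized curves.  All delta
    fields negate when the arguments are swapped.
    """
    r_max = max(pr_a.r[-1], pr_b.r[-1])
    grid = np.linspace(0.0, r_max, 512)
    pa = np.interp(grid, pr_a.r, pr_a.p, left=0.0, right=0.0)
    pb = np.interp(grid, pr_b.r, pr_b.p, left=0.0, right=0.0)
    pa /= np.trapezoid(pa, grid)
    pb /= np.trapezoid(pb, grid)
    pooled = 0.5 * (pa + pb)
    cum = np.cumsum(pooled)
    cum /= cum[-1]
    r_q = float(grid[np.searchsorted(cum, tail_quantile)])
    tail = grid > r_q
    tail_a = float(np.trapezoid(np.where(tail, pa, 0.0), grid))
    tail_b = float(np.trapezoid(np.where(tail, pb, 0.0), grid))
    return {
        "delta_d_max": pr_a.d_max - pr_b.d_max,
        "delta_rg": pr_a.rg - pr_b.rg,
        "tail_r": r_q,
        "delta_tail_mass": tail_a - tail_b,
        "l1_distance": float(np.trapezoid(np.abs(pa - pb), grid)),
    }
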