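"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator draws from exactly the statistical model the corresponding
analysis assumes, so recovery of the generating parameters is a meaningful
test of the analysis and not of the generator:

- FRET regions: [T] and x_A uniform over stated ranges, efficiencies from
  the monomer–dimer forward model plus additive Gaussian noise clipped to
  [0, 1].
- Membrane images: per pixel, independent Poisson numbers of s-mers, then
  Poisson photon emission at q photons per fluorophore — the compound
  process whose segment statistics the fluctuation-brightness estimator
  inverts.
- Toy structures: bead models (solid sphere, spherical shell, dumbbell,
  two-domain-with-linker) with closed-form Rg and D_max.
- HDX peptides: per-residue exponential exchange, a global back-exchange
  loss applied to all in-solution uptake, Gaussian replicate noise on the
  centroid.
- Kinase tables: long-tailed signal distributions in which the top block
  carries an exact, requested share of the total.

All generators are deterministic given their seed; sub-streams are spawned
per region/pixel-block/peptide so partial regeneration is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rtkquant.fif import Detector, PHOTON_COUNTING, PhotonImage
from rtkquant.fret import FretSample, predict_fret
from rtkquant.hdx import HdxPeptide
from rtkquant.saxs import AtomSet
from rtkquant.screen import KinaseRecord

__all__ = [
    "FretSimConfig",
    "MembraneSimConfig",
    "HdxSimConfig",
    "gen_fret_dataset",
    "gen_membrane_image",
    "gen_toy_structure",
    "gen_hdx_dataset",
    "gen_kinase_table",
]


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ValueError(message)


# ---------------------------------------------------------------------------
# FRET


@dataclass(frozen=True)
class FretSimConfig:
    """Monomer–dimer FRET simulation settings.

    Defaults emulate a typical transient-transfection imaging session: a
    few hundred membrane regions whose total receptor density spans about
    two orders of magnitude around the dissociation constant, acceptor
    fractions near the 2:1 acceptor:donor transfection target, and a few
    percent additive noise on the measured efficiency.
    """

    k_diss: float = 200.0
    e_tilde: float = 0.55
    n_regions: int = 300
    density_range: tuple[float, float] = (20.0, 2000.0)
    acceptor_fraction_range: tuple[float, float] = (0.4, 0.8)
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.k_diss > 0, "k_diss must be > 0")
        _require(0 < self.e_tilde <= 1, "e_tilde must be in (0, 1]")
        _require(self.n_regions >= 1, "n_regions must be >= 1")
        _require(self.density_range[0] > 0, "density_range min must be > 0")
        _require(
            self.density_range[1] >= self.density_range[0],
            "density_range must be (min, max) with max >= min",
        )
        lo, hi = self.acceptor_fraction_range
        _require(0 <= lo <= hi <= 1, "acceptor_fraction_range must lie in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")


def gen_fret_dataset(cfg: FretSimConfig) -> list[FretSample]:
    """Simulate membrane-region FRET measurements.

    Densities are drawn log-uniformly over ``density_range`` (receptor
    expression varies over orders of magnitude across cells), acceptor
    fractions uniformly; the forward model FRET = f_D([T]; K) x_A E~ is
    evaluated exactly and Gaussian noise added, clipped to [0, 1].
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_regions)
    samples = []
    lo, hi = cfg.density_range
    flo, fhi = cfg.acceptor_fraction_range
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        t = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        x_a = float(rng.uniform(flo, fhi))
        f = predict_fret(t, x_a, cfg.k_diss, cfg.e_tilde)
        if cfg.noise_sd > 0:
            f = f + rng.normal(0.0, cfg.noise_sd)
        samples.append(
            FretSample(
                region_id=f"region{i:04d}",
                total_density=t,
                acceptor_fraction=x_a,
                fret=float(np.clip(f, 0.0, 1.0)),
            )
        )
    return samples


def fret_samples_to_frame(samples) -> pd.DataFrame:
    """Tabulate samples with the documented CSV columns."""
    return pd.DataFrame(
        {
            "region_id": [s.region_id for s in samples],
            "donor_density": [
                s.total_density * (1 - s.acceptor_fraction) for s in samples
            ],
            "acceptor_density": [
                s.total_density * s.acceptor_fraction for s in samples
            ],
            "fret": [s.fret for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# Membrane images


@dataclass(frozen=True)
class MembraneSimConfig:
    """Photon-count membrane-image simulation settings.

    ``species`` lists (oligomer size s, mean units per pixel mu_s);
    ``photons_per_fluorophore`` is the expected photon yield q per labelled
    protomer per exposure.  Defaults: a monomeric population at 5 units per
    pixel and q = 3, on a 256 x 256 frame.
    """

    image_shape: tuple[int, int] = (256, 256)
    species: tuple[tuple[int, float], ...] = ((1, 5.0),)
    photons_per_fluorophore: float = 3.0
    detector: Detector = PHOTON_COUNTING
    seed: int = 0

    def __post_init__(self) -> None:
        _require(
            len(self.image_shape) == 2 and min(self.image_shape) >= 1,
            "image_shape must be (rows, cols) >= 1",
        )
        for s, mu in self.species:
            _require(int(s) == s and s >= 1, f"oligomer size must be >= 1, got {s}")
            _require(mu >= 0, f"mean units per pixel must be >= 0, got {mu}")
        _require(
            self.photons_per_fluorophore > 0, "photons_per_fluorophore must be > 0"
        )


def gen_membrane_image(cfg: MembraneSimConfig, mask=None) -> PhotonImage:
    """Simulate one photon-counting (or analog) membrane frame.

    Per pixel and species, the number of s-mers is Poisson(mu_s); total
    photons are Poisson(q * sum_s N_s * s).  The compound process has
    per-pixel mean <I> = q sum mu_s s and variance <I> + q^2 sum mu_s s^2,
    i.e. fluctuation brightness eps = q sum(mu s^2)/sum(mu s).  An analog
    detector adds zero-mean Gaussian read noise of variance sigma_D^2
    (rounded back to integer counts, floored at zero).

    Rows are generated from per-row sub-streams so partial regeneration is
    stable.  All-zero densities yield a valid all-zero image.
    """
    rows, cols = cfg.image_shape
    q = cfg.photons_per_fluorophore
    streams = np.random.SeedSequence(cfg.seed).spawn(rows)
    counts = np.empty((rows, cols), dtype=np.int64)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        fluors = np.zeros(cols)
        for s, mu in cfg.species:
            if mu > 0:
                fluors += s * rng.poisson(mu, size=cols)
        counts[r] = rng.poisson(q * fluors)
        if cfg.detector.kind == "analog" and cfg.detector.sigma_d2 > 0:
            noise = rng.normal(0.0, np.sqrt(cfg.detector.sigma_d2), size=cols)
            counts[r] = np.maximum(np.rint(counts[r] + noise).astype(np.int64), 0)
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    return PhotonImage(counts=counts, mask=mask, detector=cfg.detector)


# ---------------------------------------------------------------------------
# Toy structures


def gen_toy_structure(kind: str, seed: int = 0, **params) -> AtomSet:
    """Bead models with known geometry for scattering fixtures.

    Kinds and parameters (lengths in Angstrom):

    - ``solid_sphere_beads``: uniform beads in a ball; ``radius`` (default
      30), ``n_points`` (default 5000).  Rg -> radius * sqrt(3/5), D_max ->
      2 * radius.
    - ``sphere_shell``: beads on a spherical surface; Rg -> radius.
    - ``dumbbell``: two solid spheres; ``radius`` (15), ``separation``
      between centers (80); D_max -> separation + 2 * radius.
    - ``two_domain_linker``: two solid spheres of ``radius_a``/``radius_b``
      joined by a thin bead string of ``linker_length``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if kind == "solid_sphere_beads":
        radius = params.pop("radius", 30.0)
        n = params.pop("n_points", 5000)
        _require(radius > 0 and n >= 1, "radius and n_points must be positive")
        coords = _ball(rng, n, radius)
    elif kind == "sphere_shell":
        radius = params.pop("radius", 30.0)
        n = params.pop("n_points", 2000)
        _require(radius > 0 and n >= 1, "radius and n_points must be positive")
        v = rng.normal(size=(n, 3))
        coords = radius * v / np.linalg.norm(v, axis=1, keepdims=True)
    elif kind == "dumbbell":
        radius = params.pop("radius", 15.0)
        sep = params.pop("separation", 80.0)
        n = params.pop("n_points", 4000)
        _require(radius > 0 and sep >= 0 and n >= 2, "invalid dumbbell parameters")
        half = n // 2
        a = _ball(rng, half, radius) - [sep / 2, 0, 0]
        b = _ball(rng, n - half, radius) + [sep / 2, 0, 0]
        coords = np.vstack([a, b])
    elif kind == "two_domain_linker":
        ra = params.pop("radius_a", 20.0)
        rb = params.pop("radius_b", 12.0)
        lk = params.pop("linker_length", 30.0)
        n = params.pop("n_points", 4000)
        _require(ra > 0 and rb > 0 and lk >= 0, "invalid two-domain parameters")
        na = int(n * ra**3 / (ra**3 + rb**3))
        nl = max(int(lk), 1)
        xa, xb = -(lk / 2 + ra), lk / 2 + rb
        a = _ball(rng, na, ra) + [xa, 0, 0]
        b = _ball(rng, n - na, rb) + [xb, 0, 0]
        linker = np.column_stack(
            [np.linspace(-lk / 2, lk / 2, nl), np.zeros(nl), np.zeros(nl)]
        )
        coords = np.vstack([a, b, linker])
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    if params:
        raise ValueError(f"unknown parameters for {kind!r}: {sorted(params)}")
    return AtomSet(coords)


def _ball(rng, n: int, radius: float) -> np.ndarray:
    """n points uniform in a ball of given radius (radial inverse CDF)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


# ---------------------------------------------------------------------------
# HDX

# monoisotopic residue masses (Da); peptide mass = sum + water
_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_WATER = 18.010565
# centroid shifts are expressed in deuteron units: 1 Da per incorporated
# deuteron, so a fully exchanged, back-exchange-corrected peptide has
# RFU exactly 1 (the 0.6% H->D mass-defect refinement is a scale factor the
# uptake arithmetic never sees)
_DEUTERIUM_SHIFT = 1.0


@dataclass(frozen=True)
class HdxSimConfig:
    """Exponential-exchange HDX simulation settings.

    ``rates`` gives per-residue exchange rate constants (1/min) indexed in
    parallel with ``sequence``; ``peptides`` are (start, end) spans in
    construct numbering starting at ``residue_offset``.  The time grid
    defaults to {0, 0.5, 1, 2, 5} minutes with triplicate measurements, a
    25% global back-exchange loss and 0.05 Da replicate noise.
    """

    sequence: str
    rates: tuple[float, ...]
    peptides: tuple[tuple[int, int], ...]
    residue_offset: int = 1
    time_points: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 5.0)
    n_replicates: int = 3
    back_exchange: float = 0.25
    replicate_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        _require(len(self.sequence) >= 1, "sequence must be non-empty")
        _require(
            len(self.rates) == len(self.sequence),
            "rates must have one entry per residue",
        )
        _require(all(k >= 0 for k in self.rates), "rates must be >= 0")
        _require(0 <= self.back_exchange < 1, "back_exchange must be in [0, 1)")
        _require(self.replicate_sd >= 0, "replicate_sd must be >= 0")
        _require(self.n_replicates >= 1, "need >= 1 replicate")
        last = self.residue_offset + len(self.sequence) - 1
        for start, end in self.peptides:
            _require(
                self.residue_offset <= start <= end <= last,
                f"peptide span ({start}, {end}) outside sequence",
            )
        bad = set(self.sequence) - set(_RESIDUE_MASS)
        _require(not bad, f"unknown residues: {sorted(bad)}")


def expected_uptake(cfg: HdxSimConfig, span: tuple[int, int], time: float) -> float:
    """Closed-form mean measured uptake (Da) of a peptide at one time.

    Exchange-competent amides are all residues of the span except the two
    N-terminal ones and prolines; each contributes
    (1 - exp(-k t)); the sum is scaled by (1 - back_exchange) and by the
    H -> D mass shift.
    """
    start, end = span
    i0 = start - cfg.residue_offset
    i1 = end - cfg.residue_offset
    total = 0.0
    for j in range(i0, i1 + 1):
        if j - i0 < 2 or cfg.sequence[j] == "P":
            continue
        total += 1.0 - np.exp(-cfg.rates[j] * time)
    return (1.0 - cfg.back_exchange) * _DEUTERIUM_SHIFT * total


def gen_hdx_dataset(cfg: HdxSimConfig) -> list[HdxPeptide]:
    """Simulate centroid masses for every peptide/time/replicate.

    The undeuterated centroid is the monoisotopic peptide mass; deuterated
    centroids add the closed-form expected uptake plus Gaussian replicate
    noise.  Noise is not added at t = 0 (the undeuterated control defines
    the mass scale).
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.peptides))
    peptides = []
    for idx, ((start, end), ss) in enumerate(zip(cfg.peptides, streams)):
        rng = np.random.default_rng(ss)
        i0 = start - cfg.residue_offset
        seq = cfg.sequence[i0 : i0 + (end - start + 1)]
        undeut = sum(_RESIDUE_MASS[a] for a in seq) + _WATER
        centroids = {}
        for t in cfg.time_points:
            mean_mass = undeut + expected_uptake(cfg, (start, end), t)
            if t == 0 or cfg.replicate_sd == 0:
                reps = np.full(cfg.n_replicates, mean_mass)
            else:
                reps = mean_mass + rng.normal(0, cfg.replicate_sd, cfg.n_replicates)
            centroids[float(t)] = tuple(float(x) for x in reps)
        peptides.append(
            HdxPeptide(
                peptide_id=f"pep{idx:03d}_{start}-{end}",
                sequence=seq,
                span=(start, end),
                centroids=centroids,
                undeuterated_centroid=undeut,
            )
        )
    return peptides


def hdx_peptides_to_frame(peptides) -> pd.DataFrame:
    """Tabulate simulated peptides in the state-table CSV dialect."""
    rows = []
    for p in peptides:
        for t, reps in sorted(p.centroids.items()):
            for i, mass in enumerate(reps, start=1):
                rows.append(
                    {
                        "peptide_id": p.peptide_id,
                        "sequence": p.sequence,
                        "start": p.span[0],
                        "end": p.span[1],
                        "time": t,
                        "replicate": i,
                        "centroid_mass": mass,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kinase tables

_FAMILIES = (
    "PKC", "CK1", "NEK", "PAK", "AGC", "CAMK", "STE", "CMGC", "TKL", "CK2",
)


def gen_kinase_table(
    n_kinases: int,
    n_top: int,
    top_share: float,
    seed: int = 0,
    substrate: str = "linker_pS897",
    assay: str = "radio_33P",
) -> list[KinaseRecord]:
    """Long-tailed kinase screen in which the top block holds an exact share.

    A sorted lognormal sample fixes the rank order; an order-preserving
    power transform of the values is then solved (1-D root bracketing) so
    the top ``n_top`` kinases sum to ``top_share`` of the total, followed by
    an exact affine correction of the top block.  Any share strictly
    between n_top/n_kinases (the equal-signal floor) and 1 is reachable for
    every seed; shares at or below the floor are rejected as infeasible for
    a descending ranking.
    """
    from scipy.optimize import brentq

    _require(0 < n_top < n_kinases, "need 0 < n_top < n_kinases")
    _require(0 < top_share < 1, "top_share must be in (0, 1)")
    if top_share <= n_top / n_kinases:
        raise ValueError(
            f"top_share {top_share} infeasible: the top {n_top} of "
            f"{n_kinases} kinases always hold more than {n_top / n_kinases:.3f} "
            "of a descending ranking"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base = np.sort(rng.lognormal(mean=0.0, sigma=1.0, size=n_kinases))[::-1]
    logv = np.log(base) - np.log(base[0])  # <= 0, scale-free shape

    def share_at(gamma: float) -> float:
        w = np.exp(gamma * logv)
        return float(w[:n_top].sum() / w.sum())

    hi = 1.0
    while share_at(hi) < top_share:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"top_share {top_share} infeasible for this shape")
    gamma = brentq(lambda g: share_at(g) - top_share, 1e-9, hi, xtol=1e-13)
    signals = np.exp(gamma * logv)
    # exact affine correction of the top block (factor ~ 1, order-safe)
    s_top, s_tail = signals[:n_top].sum(), signals[n_top:].sum()
    signals[:n_top] *= top_share * s_tail / ((1.0 - top_share) * s_top)
    if signals[n_top - 1] <= signals[n_top]:
        raise ValueError(
            f"top_share {top_share} infeasible for n_top {n_top}: correction "
            "broke the rank order"
        )
    signals *= 3e5 / signals[0]  # CPM-like magnitude; scale is arbitrary
    records = []
    for i, sig in enumerate(signals):
        records.append(
            KinaseRecord(
                kinase=f"KIN{i:03d}",
                family=_FAMILIES[i % len(_FAMILIES)],
                substrate_peptide=substrate,
                signal=float(sig),
                assay=assay,
            )
        )
    return records


def kinase_records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kinase": [r.kinase for r in records],
            "family": [r.family for r in records],
            "substrate": [r.substrate_peptide for r in records],
            "signal": [r.signal for r in records],
            "assay": [r.assay for r in records],
        }
    )
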