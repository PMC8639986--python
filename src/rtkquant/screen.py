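"""Kinase-screen ranking and phosphosite-cluster statistics.

An in vitro screen measures, for each serine/threonine kinase, the signal
(radioassay counts per minute or luminescent relative light units) obtained
with a substrate peptide spanning a phosphosite cluster.  The analytics
here answer the questions such a screen raises:

- which kinases dominate the screen (descending ranking with cumulative
  signal fraction, top-k share queries, counts above a signal cutoff);
- which site a kinase targets, inferred from substrate-peptide variants in
  which individual sites are Ala-substituted or pre-phosphorylated
  ("priming");
- how often phosphopeptides carry multiple sites simultaneously, and how
  site phosphorylation levels correlate across cell lines.

CPM and RLU come from different assays and are never mixed in one ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "KinaseRecord",
    "SubstrateDef",
    "PhosphoPeptideObs",
    "rank_kinases",
    "threshold_count",
    "site_preference",
    "multisite_fraction",
    "site_correlation",
]


@dataclass(frozen=True)
class KinaseRecord:
    """One kinase x substrate-peptide measurement."""

    kinase: str
    family: str
    substrate_peptide: str
    signal: float
    assay: str = "radio_33P"  # or "adp_glo"

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")
        if self.assay not in ("radio_33P", "adp_glo"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class SubstrateDef:
    """Which cluster sites a substrate-peptide variant offers.

    ``available``: residue numbers phosphorylatable in this peptide.
    ``primed``: residues synthesized pre-phosphorylated.
    ``variant_group``: peptides differing only in the last residue share a
    group and are averaged before any comparison.
    """

    name: str
    available: frozenset[int]
    primed: frozenset[int] = frozenset()
    variant_group: str | None = None

    @property
    def group(self) -> str:
        return self.variant_group or self.name


@dataclass(frozen=True)
class PhosphoPeptideObs:
    """One phosphopeptide observation: the set of modified sites seen."""

    sites: frozenset[int]
    count: int = 1

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a phosphopeptide observation must carry >= 1 site")
        if self.count < 1:
            raise ValueError("count must be >= 1")


def _check_single_assay(records) -> None:
    assays = {r.assay for r in records}
    if len(assays) > 1:
        raise ValueError(f"cannot mix assays in one comparison: {sorted(assays)}")


def rank_kinases(records) -> pd.DataFrame:
    """Rank kinases by signal for one substrate peptide.

    Returns a DataFrame sorted by descending signal (ties broken by kinase
    name) with columns ``rank, kinase, family, signal, fraction,
    cumulative_fraction``.  The top-k share is
    ``df["cumulative_fraction"].iloc[k-1]``.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    _check_single_assay(records)
    substrates = {r.substrate_peptide for r in records}
    if len(substrates) > 1:
        raise ValueError(f"ranking needs a single substrate, got {sorted(substrates)}")
    total = sum(r.signal for r in records)
    if total == 0:
        raise ValueError("total signal is zero; ranking undefined")
    ordered = sorted(records, key=lambda r: (-r.signal, r.kinase))
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "kinase": [r.kinase for r in ordered],
            "family": [r.family for r in ordered],
            "signal": [r.signal for r in ordered],
        }
    )
    df["fraction"] = df["signal"] / total
    df["cumulative_fraction"] = df["fraction"].cumsum()
    return df


def top_share(ranked: pd.DataFrame, k: int) -> float:
    """Cumulative signal fraction of the top-k kinases of a ranking."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k must be in [1, {len(ranked)}]")
    return float(ranked["cumulative_fraction"].iloc[k - 1])


def threshold_count(records, cutoff: float) -> int:
    """Number of records with signal strictly greater than ``cutoff``."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return sum(1 for r in records if r.signal > cutoff)


def site_preference(
    records,
    kinase: str,
    substrates: dict[str, SubstrateDef],
    prefer_ratio: float = 3.0,
    require_ratio: float = 10.0,
) -> dict:
    """Infer the site preference of one kinase from substrate variants.

    Replicate peptides in the same ``variant_group`` (differing only in the
    last residue) are arithmetically averaged first.  Substrate groups are
    then compared pairwise; when two groups differ only in the availability
    of a single site, the signal ratio attributes activity to that site:

    - ratio >= ``require_ratio``: "mainly phosphorylates <site>"
    - ratio >= ``prefer_ratio``:  "prefers <site>"
    - otherwise: "indifferent to <site>"

    When the groups differ only in whether a site is pre-phosphorylated and
    the primed variant wins by ``prefer_ratio``, the label is
    "requires priming at <site>" (the acidophilic-kinase pattern).

    Returns a report with the averaged signals, each pairwise comparison,
    and the labels.  Raises if fewer than two substrate groups exist;
    comparisons with no interpretable single-site difference are flagged.
    """
    recs = [r for r in records if r.kinase == kinase]
    if not recs:
        raise ValueError(f"no records for kinase {kinase!r}")
    _check_single_assay(recs)
    missing = {r.substrate_peptide for r in recs} - set(substrates)
    if missing:
        raise ValueError(f"undefined substrates: {sorted(missing)}")

    group_signal: dict[str, list[float]] = {}
    group_def: dict[str, SubstrateDef] = {}
    for r in recs:
        sd = substrates[r.substrate_peptide]
        group_signal.setdefault(sd.group, []).append(r.signal)
        prior = group_def.setdefault(sd.group, sd)
        if (prior.available, prior.primed) != (sd.available, sd.primed):
            raise ValueError(
                f"variant group {sd.group!r} mixes different site definitions"
            )
    means = {g: float(np.mean(v)) for g, v in group_signal.items()}
    if len(means) < 2:
        raise ValueError("need >= 2 substrate groups to infer a preference")

    comparisons = []
    labels = []
    for ga, gb in combinations(sorted(means), 2):
        da, db = group_def[ga], group_def[gb]
        # orient so that a is the higher-signal group
        if means[ga] < means[gb]:
            ga, gb, da, db = gb, ga, db, da
        hi, lo = means[ga], means[gb]
        ratio = hi / lo if lo > 0 else float("inf")
        avail_diff = da.available ^ db.available
        primed_diff = da.primed ^ db.primed
        entry = {
            "higher": ga,
            "lower": gb,
            "ratio": ratio,
            "interpretable": False,
            "label": None,
        }
        if len(avail_diff) == 1 and not primed_diff:
            (site,) = avail_diff
            if site in da.available:  # extra site drives extra signal
                entry["interpretable"] = True
                if ratio >= require_ratio:
                    entry["label"] = f"mainly phosphorylates S/T{site}"
                elif ratio >= prefer_ratio:
                    entry["label"] = f"prefers S/T{site}"
                else:
                    entry["label"] = f"indifferent to S/T{site}"
        elif len(primed_diff) == 1 and not avail_diff:
            (site,) = primed_diff
            if site in da.primed:
                entry["interpretable"] = True
                if ratio >= prefer_ratio:
                    entry["label"] = f"requires priming at S/T{site}"
                else:
                    entry["label"] = f"indifferent to priming at S/T{site}"
        comparisons.append(entry)
        if entry["label"]:
            labels.append(entry["label"])
    if not any(c["interpretable"] for c in comparisons):
        labels = ["no single-site comparison available"]
    return {
        "kinase": kinase,
        "group_signals": means,
        "comparisons": comparisons,
        "labels": labels,
    }


def multisite_fraction(observations) -> dict:
    """Multi-phosphorylation statistics over phosphopeptide observations.

    Returns the (count-weighted) fraction of observations with >= 2
    modified sites, a frequency table of site combinations, and the largest
    number of simultaneous sites observed.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("no observations")
    total = sum(o.count for o in observations)
    multi = sum(o.count for o in observations if len(o.sites) >= 2)
    combos: dict[tuple[int, ...], int] = {}
    for o in observations:
        key = tuple(sorted(o.sites))
        combos[key] = combos.get(key, 0) + o.count
    table = pd.DataFrame(
        {
            "sites": ["+".join(str(s) for s in k) for k in sorted(combos)],
            "n_sites": [len(k) for k in sorted(combos)],
            "count": [combos[k] for k in sorted(combos)],
        }
    ).sort_values(["n_sites", "sites"], ignore_index=True)
    return {
        "fraction_multisite": multi / total,
        "combination_table": table,
        "max_sites": max(len(o.sites) for o in observations),
        "n_observations": total,
    }


def site_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between phosphosites across cell lines.

    ``matrix`` has cell lines as rows and sites as columns.  Requires >= 3
    rows.  Constant columns have undefined correlation; their entries are
    NaN and a ``constant_columns`` attribute lists them.
    """
    if len(matrix) < 3:
        raise ValueError("need >= 3 cell lines for a correlation")
    if not np.all(np.isfinite(matrix.to_numpy(dtype=float))):
        raise ValueError("matrix must be finite")
    constant = [c for c in matrix.columns if matrix[c].nunique() == 1]
    corr = matrix.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
    corr.attrs["constant_columns"] = constant
    return corr
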