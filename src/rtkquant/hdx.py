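"""Centroid-based hydrogen–deuterium-exchange (HDX-MS) uptake arithmetic.

Deuterium uptake of a peptic peptide is the shift of the centroid of its
mass envelope relative to the undeuterated control, averaged over
replicates.  The raw uptake underestimates in-solution exchange because
deuterons are lost during quench and chromatography; a global back-exchange
factor corrects it: corrected = raw / (1 - factor), with ~0.25 typical.
Relative fractional uptake (RFU) divides the corrected uptake by the
number of exchange-competent backbone amides of the peptide — by the
standard convention, peptide length minus 2 (the N-terminal residue
retains no amide deuterium and the second back-exchanges too fast) minus
interior prolines (no backbone NH).  Condition-vs-condition difference
profiles (e.g. phosphomimetic mutant minus wild type) flag peptides whose
|ΔRFU| exceeds a multiple of the pooled replicate SD, and per-residue maps
average the RFU of all covering peptides for structure coloring.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "HdxPeptide",
    "UptakeRecord",
    "UptakeDiff",
    "max_exchangeable",
    "uptake_from_centroids",
    "correct_back_exchange",
    "relative_fractional_uptake",
    "uptake_table",
    "uptake_difference",
    "map_to_residues",
    "read_state_table",
    "NO_COVERAGE",
]

NO_COVERAGE = float("nan")

DEFAULT_TIME_POINTS = (0.0, 0.5, 1.0, 2.0, 5.0)  # minutes


@dataclass
class HdxPeptide:
    """One peptic peptide with centroid masses per (time point, replicate).

    ``centroids`` maps time (min) -> sequence of replicate centroid masses
    (Da).  ``span`` is (start, end), 1-based inclusive, in construct
    numbering.
    """

    peptide_id: str
    sequence: str
    span: tuple[int, int]
    centroids: dict[float, tuple[float, ...]]
    undeuterated_centroid: float

    def __post_init__(self) -> None:
        start, end = self.span
        if end < start:
            raise ValueError(f"span end {end} < start {start}")
        if len(self.sequence) != end - start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.span}"
            )

    @property
    def n_interior_prolines(self) -> int:
        """Prolines past the first two residues (the fast-exchange window)."""
        return self.sequence[2:].count("P")


@dataclass
class UptakeRecord:
    peptide_id: str
    time: float
    uptake_raw: float
    uptake_sd: float
    uptake_corrected: float | None = None
    back_exchange_factor: float | None = None
    rfu: float | None = None
    rfu_sd: float | None = None


@dataclass
class UptakeDiff:
    peptide_id: str
    time: float
    delta_rfu: float
    pooled_sd: float
    significant: bool


def max_exchangeable(peptide: HdxPeptide, convention: str = "minus2") -> int:
    """Number of exchange-competent backbone amides.

    ``minus2`` (default): length - 2 - interior prolines.  ``minus1``:
    length - 1 - prolines past the first residue.
    """
    n = len(peptide.sequence)
    if convention == "minus2":
        m = n - 2 - peptide.n_interior_prolines
    elif convention == "minus1":
        m = n - 1 - peptide.sequence[1:].count("P")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if m <= 0:
        raise ValueError(
            f"peptide {peptide.peptide_id} has no exchange-competent amides"
        )
    return m


def uptake_from_centroids(peptide: HdxPeptide) -> list[UptakeRecord]:
    """Raw uptake per time point: replicate mean of centroid - undeuterated.

    SD is the replicate standard deviation (ddof=1; zero for a single
    replicate).
    """
    if peptide.undeuterated_centroid is None:
        raise ValueError(f"peptide {peptide.peptide_id}: missing undeuterated control")
    records = []
    for time in sorted(peptide.centroids):
        reps = np.asarray(peptide.centroids[time], dtype=float)
        if reps.size == 0:
            raise ValueError(
                f"peptide {peptide.peptide_id}: no replicates at t={time}"
            )
        shifts = reps - peptide.undeuterated_centroid
        sd = float(shifts.std(ddof=1)) if reps.size > 1 else 0.0
        records.append(
            UptakeRecord(
                peptide_id=peptide.peptide_id,
                time=float(time),
                uptake_raw=float(shifts.mean()),
                uptake_sd=sd,
            )
        )
    return records


def correct_back_exchange(record: UptakeRecord, factor: float = 0.25) -> UptakeRecord:
    """Apply the global back-exchange correction: raw / (1 - factor)."""
    if not 0.0 <= factor < 1.0:
        raise ValueError(f"back-exchange factor must be in [0, 1), got {factor}")
    return replace(
        record,
        uptake_corrected=record.uptake_raw / (1.0 - factor),
        back_exchange_factor=factor,
    )


def relative_fractional_uptake(
    record: UptakeRecord, peptide: HdxPeptide, convention: str = "minus2"
) -> UptakeRecord:
    """RFU = corrected uptake / max exchangeable amides (and its SD)."""
    if record.uptake_corrected is None:
        raise ValueError("apply correct_back_exchange before computing RFU")
    m = max_exchangeable(peptide, convention)
    # the SD propagates through the same linear scaling as the mean
    scale = 1.0 / (1.0 - (record.back_exchange_factor or 0.0))
    return replace(
        record,
        rfu=record.uptake_corrected / m,
        rfu_sd=record.uptake_sd * scale / m,
    )


def uptake_table(
    peptides, back_exchange: float = 0.25, convention: str = "minus2"
) -> pd.DataFrame:
    """Full pipeline over a peptide collection -> tidy uptake DataFrame."""
    rows = []
    for pep in peptides:
        for rec in uptake_from_centroids(pep):
            rec = correct_back_exchange(rec, back_exchange)
            rec = relative_fractional_uptake(rec, pep, convention)
            rows.append(
                {
                    "peptide_id": rec.peptide_id,
                    "start": pep.span[0],
                    "end": pep.span[1],
                    "time": rec.time,
                    "uptake_raw": rec.uptake_raw,
                    "uptake_sd": rec.uptake_sd,
                    "uptake_corrected": rec.uptake_corrected,
                    "rfu": rec.rfu,
                    "rfu_sd": rec.rfu_sd,
                }
            )
    return pd.DataFrame(rows)


def uptake_difference(
    records_a, records_b, sd_multiplier: float = 2.0
) -> list[UptakeDiff]:
    """Per-peptide/time RFU difference, condition a minus condition b.

    Only (peptide_id, time) pairs present in both conditions are compared.
    The pooled SD is sqrt(sd_a^2 + sd_b^2) on the RFU scale; a difference is
    flagged significant when |Δ| > sd_multiplier x pooled SD (and the pooled
    SD is nonzero).  Swapping the arguments negates every Δ exactly.
    """

    def index(records):
        out = {}
        for r in records:
            if r.rfu is None:
                raise ValueError("records must carry RFU (run the uptake pipeline)")
            out[(r.peptide_id, r.time)] = r
        return out

    a, b = index(records_a), index(records_b)
    keys = sorted(set(a) & set(b))
    if not keys:
        raise ValueError("no common (peptide, time) coverage between conditions")
    diffs = []
    for key in keys:
        ra, rb = a[key], b[key]
        delta = ra.rfu - rb.rfu
        pooled = float(np.hypot(ra.rfu_sd or 0.0, rb.rfu_sd or 0.0))
        sig = pooled > 0 and abs(delta) > sd_multiplier * pooled
        diffs.append(
            UptakeDiff(
                peptide_id=key[0],
                time=key[1],
                delta_rfu=delta,
                pooled_sd=pooled,
                significant=bool(sig),
            )
        )
    return diffs


def map_to_residues(records, peptides, time: float) -> dict[int, float]:
    """Residue-level RFU map at one time point.

    Each residue covered by at least one peptide gets the unweighted mean
    RFU of the covering peptides; residues outside all spans get the
    no-coverage marker (NaN).  The returned dict spans the union of peptide
    spans.
    """
    peptides = list(peptides)
    if not peptides:
        raise ValueError("need at least one peptide")
    by_id = {p.peptide_id: p for p in peptides}
    rfu_at_t = {
        r.peptide_id: r.rfu
        for r in records
        if r.time == time and r.rfu is not None and r.peptide_id in by_id
    }
    lo = min(p.span[0] for p in peptides)
    hi = max(p.span[1] for p in peptides)
    out: dict[int, float] = {}
    for res in range(lo, hi + 1):
        vals = [
            rfu_at_t[pid]
            for pid, p in by_id.items()
            if pid in rfu_at_t and p.span[0] <= res <= p.span[1]
        ]
        out[res] = float(np.mean(vals)) if vals else NO_COVERAGE
    return out


def read_state_table(path_or_df) -> list[HdxPeptide]:
    """Read a peptide state table into :class:`HdxPeptide` objects.

    Columns: ``peptide_id, sequence, start, end, time, replicate,
    centroid_mass``.  Rows at time 0 are the undeuterated controls; their
    replicate mean becomes the undeuterated centroid.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {
        "peptide_id", "sequence", "start", "end", "time", "replicate",
        "centroid_mass",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    peptides = []
    for pid, grp in df.groupby("peptide_id", sort=True):
        seq = grp["sequence"].iloc[0]
        start = int(grp["start"].iloc[0])
        end = int(grp["end"].iloc[0])
        t0 = grp[grp["time"] == 0.0]
        if t0.empty:
            raise ValueError(f"peptide {pid}: missing undeuterated (t=0) control")
        undeut = float(t0["centroid_mass"].mean())
        centroids = {
            float(t): tuple(sub["centroid_mass"].astype(float))
            for t, sub in grp[grp["time"] > 0].groupby("time")
        }
        centroids[0.0] = tuple(t0["centroid_mass"].astype(float))
        peptides.append(
            HdxPeptide(
                peptide_id=str(pid),
                sequence=str(seq),
                span=(start, end),
                centroids=centroids,
                undeuterated_centroid=undeut,
            )
        )
    return peptides
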