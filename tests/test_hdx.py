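"""Uptake arithmetic, back-exchange correction, differences, residue maps."""

import dataclasses

import numpy as np
import pytest

from rtkquant import hdx
from rtkquant.synthetic import (
    HdxSimConfig,
    expected_uptake,
    gen_hdx_dataset,
    hdx_peptides_to_frame,
)


def make_peptide(sequence="GASPLKTERV", start=1, centroids=None, undeut=1000.0):
    end = start + len(sequence) - 1
    return hdx.HdxPeptide(
        peptide_id=f"p{start}",
        sequence=sequence,
        span=(start, end),
        centroids=centroids or {0.0: (undeut,)},
        undeuterated_centroid=undeut,
    )


class TestUptakeFromCentroids:
    def test_undeuterated_centroids_give_zero_uptake(self):
        pep = make_peptide(
            centroids={0.0: (1000.0,), 1.0: (1000.0, 1000.0), 5.0: (1000.0,)}
        )
        for rec in hdx.uptake_from_centroids(pep):
            assert rec.uptake_raw == 0.0

    def test_replicate_mean_and_sd(self):
        pep = make_peptide(centroids={1.0: (1001.0, 1001.2, 1001.1)})
        (rec,) = hdx.uptake_from_centroids(pep)
        assert rec.uptake_raw == pytest.approx(1.1)
        assert rec.uptake_sd == pytest.approx(0.1, rel=1e-9)

    def test_generator_round_trip_matches_closed_form(self, hdx_config):
        cfg = dataclasses.replace(hdx_config, replicate_sd=0.0)
        for pep in gen_hdx_dataset(cfg):
            for rec in hdx.uptake_from_centroids(pep):
                assert rec.uptake_raw == pytest.approx(
                    expected_uptake(cfg, pep.span, rec.time), abs=1e-9
                )


class TestBackExchange:
    def test_zero_factor_is_identity(self):
        rec = hdx.UptakeRecord("p", 1.0, 1.5, 0.1)
        assert hdx.correct_back_exchange(rec, 0.0).uptake_corrected == 1.5

    def test_quarter_loss_maps_1p5_to_2(self):
        rec = hdx.UptakeRecord("p", 1.0, 1.5, 0.1)
        assert hdx.correct_back_exchange(rec, 0.25).uptake_corrected == pytest.approx(
            2.0
        )

    def test_correction_inverts_exactly(self):
        rec = hdx.UptakeRecord("p", 1.0, 1.234567, 0.1)
        corrected = hdx.correct_back_exchange(rec, 0.37)
        assert corrected.uptake_corrected * (1 - 0.37) == pytest.approx(
            rec.uptake_raw, abs=1e-12
        )

    def test_invalid_factor_rejected(self):
        rec = hdx.UptakeRecord("p", 1.0, 1.5, 0.1)
        with pytest.raises(ValueError):
            hdx.correct_back_exchange(rec, 1.0)


class TestRelativeFractionalUptake:
    def test_ten_residue_one_proline_example(self):
        # 10 residues, 1 interior proline: 10 - 2 - 1 = 7 competent amides
        pep = make_peptide(sequence="GASPLKTERV")
        assert hdx.max_exchangeable(pep) == 7
        rec = hdx.UptakeRecord("p1", 1.0, 3.5 * 0.75, 0.0)
        rec = hdx.correct_back_exchange(rec, 0.25)
        rec = hdx.relative_fractional_uptake(rec, pep)
        assert rec.rfu == pytest.approx(0.5)

    def test_fully_exchanged_corrected_rfu_is_one(self):
        # rates >> 1/t: measured uptake = (1 - BE) x competent amides,
        # correction restores RFU = 1 exactly
        seq = "GASPLKTERV"
        cfg = HdxSimConfig(
            sequence=seq,
            rates=(1e6,) * len(seq),
            peptides=((1, 10),),
            back_exchange=0.25,
            replicate_sd=0.0,
            seed=0,
        )
        (pep,) = gen_hdx_dataset(cfg)
        recs = hdx.uptake_from_centroids(pep)
        t5 = [r for r in recs if r.time == 5.0][0]
        assert t5.uptake_raw == pytest.approx(0.75 * 7)
        rec = hdx.relative_fractional_uptake(
            hdx.correct_back_exchange(t5, 0.25), pep
        )
        assert rec.rfu == pytest.approx(1.0)

    def test_time_zero_rfu_is_zero(self, hdx_config):
        for pep in gen_hdx_dataset(hdx_config):
            recs = hdx.uptake_from_centroids(pep)
            t0 = [r for r in recs if r.time == 0.0][0]
            rec = hdx.relative_fractional_uptake(
                hdx.correct_back_exchange(t0), pep
            )
            assert rec.rfu == 0.0

    def test_all_proline_interior_rejected(self):
        pep = make_peptide(sequence="GAPPP")
        with pytest.raises(ValueError, match="exchange-competent"):
            hdx.max_exchangeable(pep)

    def test_monotone_in_time_without_noise(self, hdx_config):
        cfg = dataclasses.replace(hdx_config, replicate_sd=0.0)
        df = hdx.uptake_table(gen_hdx_dataset(cfg))
        for _, grp in df.sort_values("time").groupby("peptide_id"):
            assert np.all(np.diff(grp["rfu"]) >= -1e-12)


def _rfu_records(cfg):
    out = []
    for pep in gen_hdx_dataset(cfg):
        for rec in hdx.uptake_from_centroids(pep):
            rec = hdx.correct_back_exchange(rec, cfg.back_exchange)
            out.append(hdx.relative_fractional_uptake(rec, pep))
    return out


class TestUptakeDifference:
    def test_self_difference_zero_nothing_significant(self, hdx_config):
        recs = _rfu_records(hdx_config)
        for d in hdx.uptake_difference(recs, recs):
            assert d.delta_rfu == 0.0
            assert not d.significant

    def test_swap_negates_exactly(self, hdx_config):
        a = _rfu_records(hdx_config)
        b = _rfu_records(dataclasses.replace(hdx_config, seed=99))
        ab = hdx.uptake_difference(a, b)
        ba = hdx.uptake_difference(b, a)
        for d1, d2 in zip(ab, ba):
            assert d1.delta_rfu == -d2.delta_rfu
            assert d1.significant == d2.significant

    def test_empty_intersection_rejected(self, hdx_config):
        a = _rfu_records(hdx_config)
        b = [dataclasses.replace(r, peptide_id="other") for r in a]
        with pytest.raises(ValueError, match="no common"):
            hdx.uptake_difference(a, b)

    def test_shifted_block_flagged(self, hdx_config):
        # add +0.2 RFU worth of mass to the first two peptides of the mutant
        wt = _rfu_records(hdx_config)
        mutant_peps = gen_hdx_dataset(dataclasses.replace(hdx_config, seed=55))
        block = {p.peptide_id for p in mutant_peps[:2]}
        shifted = []
        for pep in mutant_peps:
            if pep.peptide_id in block:
                m = hdx.max_exchangeable(pep)
                bump = 0.2 * m * (1 - hdx_config.back_exchange)
                pep = dataclasses.replace(
                    pep,
                    centroids={
                        t: tuple(c + (bump if t > 0 else 0.0) for c in reps)
                        for t, reps in pep.centroids.items()
                    },
                )
            shifted.append(pep)
        mut = []
        for pep in shifted:
            for rec in hdx.uptake_from_centroids(pep):
                rec = hdx.correct_back_exchange(rec, hdx_config.back_exchange)
                mut.append(hdx.relative_fractional_uptake(rec, pep))
        diffs = hdx.uptake_difference(mut, wt)
        in_block = [d for d in diffs if d.peptide_id in block and d.time > 0]
        outside = [d for d in diffs if d.peptide_id not in block and d.time > 0]
        assert all(d.significant for d in in_block)
        assert np.mean([d.significant for d in outside]) < 0.3


class TestMapToResidues:
    def test_single_peptide_propagates_its_rfu(self):
        pep = make_peptide(centroids={0.0: (1000.0,), 1.0: (1003.0,)})
        recs = [
            hdx.relative_fractional_uptake(
                hdx.correct_back_exchange(r, 0.0), pep
            )
            for r in hdx.uptake_from_centroids(pep)
        ]
        rmap = hdx.map_to_residues(recs, [pep], time=1.0)
        expected = 3.0 / 7
        for res in range(1, 11):
            assert rmap[res] == pytest.approx(expected)

    def test_overlap_is_mean_of_covering_peptides(self):
        pep_a = make_peptide(sequence="GASKLKTERV", start=1,
                             centroids={0.0: (1000.0,), 1.0: (1000.0 + 0.2 * 8,)})
        pep_b = make_peptide(sequence="TERVAAGKLM", start=7, undeut=900.0,
                             centroids={0.0: (900.0,), 1.0: (900.0 + 0.4 * 8,)})
        recs = []
        for pep in (pep_a, pep_b):
            for r in hdx.uptake_from_centroids(pep):
                recs.append(
                    hdx.relative_fractional_uptake(
                        hdx.correct_back_exchange(r, 0.0), pep
                    )
                )
        rmap = hdx.map_to_residues(recs, [pep_a, pep_b], time=1.0)
        assert rmap[3] == pytest.approx(0.2)  # only peptide a
        assert rmap[8] == pytest.approx(0.3)  # overlap: mean of 0.2 and 0.4
        assert rmap[12] == pytest.approx(0.4)  # only peptide b

    def test_uncovered_residue_marked(self):
        pep = make_peptide(start=5, centroids={0.0: (1000.0,), 1.0: (1001.0,)})
        other = make_peptide(start=30, centroids={0.0: (1000.0,), 1.0: (1001.0,)})
        recs = []
        for p in (pep, other):
            for r in hdx.uptake_from_centroids(p):
                recs.append(
                    hdx.relative_fractional_uptake(
                        hdx.correct_back_exchange(r, 0.0), p
                    )
                )
        rmap = hdx.map_to_residues(recs, [pep, other], time=1.0)
        assert np.isnan(rmap[20])  # in the gap between the two spans
        assert not np.isnan(rmap[6])


class TestStateTable:
    def test_round_trip_through_csv(self, hdx_config, tmp_path):
        peptides = gen_hdx_dataset(hdx_config)
        path = tmp_path / "state.csv"
        hdx_peptides_to_frame(peptides).to_csv(path, index=False)
        back = hdx.read_state_table(path)
        assert len(back) == len(peptides)
        orig = {p.peptide_id: p for p in peptides}
        for p in back:
            assert p.span == orig[p.peptide_id].span
            assert p.undeuterated_centroid == pytest.approx(
                orig[p.peptide_id].undeuterated_centroid
            )
            for t, reps in p.centroids.items():
                np.testing.assert_allclose(
                    reps, orig[p.peptide_id].centroids[t], rtol=1e-12
                )

    def test_missing_control_rejected(self, hdx_config):
        import pandas as pd

        df = hdx_peptides_to_frame(gen_hdx_dataset(hdx_config))
        df = df[df["time"] > 0]
        with pytest.raises(ValueError, match="undeuterated"):
            hdx.read_state_table(pd.DataFrame(df))
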