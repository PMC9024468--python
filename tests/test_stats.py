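"""Cohort statistics: AU permillage, moving averages, distances, logo, contexts."""

import numpy as np
import pytest

from stwintron import (
    PlantSpec,
    StwintronRecord,
    au_permille,
    exon_context_checks,
    gc_permille,
    group_summary,
    junction_logo,
    make_stwintron,
    moving_average_profile,
    pyrimidine_tracts,
    random_background,
    spacer_distances,
)


def _record(stw, rec_id="s1", group="UO", phase=1, flank5=None, flank3=None, seed=0):
    rng = np.random.default_rng(seed)
    return StwintronRecord(
        id=rec_id,
        group=group,
        sequence=stw.sequence,
        motif_spans=stw.motif_spans,
        phase=phase,
        flank5=flank5 if flank5 is not None else random_background(15, 0.5, rng),
        flank3=flank3 if flank3 is not None else random_background(15, 0.5, rng),
    )


@pytest.fixture(scope="module")
def cohort():
    """12 seeded Model-A records across groups."""
    records = []
    for i in range(12):
        spec = PlantSpec.random("A", seed=900 + i, phase=(i % 3))
        stw = make_stwintron(spec, seed=950 + i)
        group = "sister" if i < 4 else "UO"
        records.append(_record(stw, rec_id=f"s{i}", group=group,
                               phase=i % 3, seed=990 + i))
    return records


class TestAuPermille:
    @pytest.mark.parametrize("seq,expected", [("ATAT", 1000.0), ("ACGT", 500.0),
                                              ("GGCC", 0.0)])
    def test_values(self, seq, expected):
        assert au_permille(seq) == expected

    def test_complements_gc_permille(self, rng):
        seq = random_background(500, 0.37, rng)
        assert au_permille(seq) + gc_permille(seq) == 1000.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            au_permille("")


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        out = moving_average_profile([5.0] * 30, window=9)
        assert np.allclose(out, 5.0)

    def test_window_one_is_identity(self):
        values = [1.0, 4.0, 2.0, 8.0]
        assert np.allclose(moving_average_profile(values, window=1), values)

    def test_impulse_spreads_one_ninth_over_nine_bins(self):
        values = np.zeros(31)
        values[15] = 9.0
        out = moving_average_profile(values, window=9)
        assert np.allclose(out[11:20], 1.0)
        assert np.allclose(out[:11], 0.0) and np.allclose(out[20:], 0.0)

    def test_interior_windows_preserve_mean(self):
        rng = np.random.default_rng(3)
        values = rng.random(101)
        out = moving_average_profile(values, window=9)
        # interior points are full 9-window averages of the input
        assert np.isclose(out[4:-4].mean(), np.convolve(values, np.ones(9) / 9,
                                                        "valid").mean())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average_profile([1.0], window=4)


class TestSpacerDistances:
    def test_distances_equal_constructed_spacers(self):
        spec = PlantSpec.random("A", seed=77)
        spec = PlantSpec(
            model=spec.model, internal_donor=spec.internal_donor,
            external_donor=spec.external_donor, internal_bp=spec.internal_bp,
            external_bp=spec.external_bp, internal_acceptor=spec.internal_acceptor,
            external_acceptor=spec.external_acceptor, spacers=(30, 7, 40, 6),
        )
        stw = make_stwintron(spec, seed=78)
        assert spacer_distances(stw) == {
            "internal_donor_bp": 30, "internal_bp_acc": 7,
            "external_donor_bp": 40, "external_bp_acc": 6,
        }

    def test_minimal_model_a_distances_at_range_minima(self):
        spec = PlantSpec.random("A", seed=79)
        spec = PlantSpec(
            model=spec.model, internal_donor=spec.internal_donor,
            external_donor=spec.external_donor, internal_bp=spec.internal_bp,
            external_bp=spec.external_bp, internal_acceptor=spec.internal_acceptor,
            external_acceptor=spec.external_acceptor, spacers=(25, 4, 25, 4),
        )
        stw = make_stwintron(spec, seed=80)
        assert len(stw.sequence) == 88
        assert list(spacer_distances(stw).values()) == [25, 4, 25, 4]

    def test_scanner_candidates_lie_inside_model_ranges(self, model_a, planted_a):
        from stwintron import scan_sequence

        for cand in scan_sequence(planted_a.sequence, model_a, mode="exhaustive"):
            dists = spacer_distances(cand)
            for value, (lo, hi) in zip(dists.values(), model_a.spacer_ranges()):
                assert lo <= value <= hi


class TestPyrimidineTracts:
    def test_single_tract_found(self):
        assert pyrimidine_tracts("AACTTTTCTCAA", min_len=7) == [(2, 10)]

    def test_purine_only_sequence_empty(self):
        assert pyrimidine_tracts("GAGAGAGAGAAAG") == []

    def test_tract_at_sequence_end_flushed(self):
        assert pyrimidine_tracts("AATTTTCCC", min_len=7) == [(2, 9)]

    def test_straddling_tract_assigned_by_start(self):
        base = PlantSpec.random("A", seed=81)
        spec = PlantSpec(
            model=base.model, internal_donor=base.internal_donor,
            external_donor=base.external_donor, internal_bp=base.internal_bp,
            external_bp="TCTAAC",  # BP starting with pyrimidines
            internal_acceptor=base.internal_acceptor,
            external_acceptor=base.external_acceptor, spacers=base.spacers,
        )
        stw = make_stwintron(spec, seed=82)
        bp_s = dict((n, (s, e)) for n, s, e in stw.motif_spans)["external_bp"][0]
        # force a T run just before the external BP: the tract starts in the
        # donor-to-BP region and straddles into the BP element
        seq = list(stw.sequence)
        for i in range(bp_s - 8, bp_s):
            seq[i] = "T"
        seq = "".join(seq)
        donor_side = pyrimidine_tracts(seq, 7, "donor_to_bp",
                                       motif_spans=stw.motif_spans, intron="external")
        acc_side = pyrimidine_tracts(seq, 7, "bp_to_acceptor",
                                     motif_spans=stw.motif_spans, intron="external")
        assert any(s < bp_s <= e for s, e in donor_side)
        assert not any(s < bp_s <= e for s, e in acc_side)


class TestJunctionLogo:
    def test_two_identical_records_give_two_bits_everywhere(self, cohort):
        logo = junction_logo([cohort[0], cohort[0]])
        occupied = logo.counts.sum(axis=1) > 0
        assert np.allclose(logo.information[occupied.to_numpy()], 2.0)

    def test_column_16_is_invariant_g1(self, cohort):
        logo = junction_logo(cohort)
        assert logo.n_positions == 60
        col = logo.frequencies.iloc[15]  # 1-based column 16
        assert col["G"] == 1.0
        assert logo.information[15] == pytest.approx(2.0)

    def test_frequencies_sum_to_one_and_info_bounded(self, cohort):
        logo = junction_logo(cohort)
        sums = logo.frequencies.sum(axis=1).to_numpy()
        occupied = logo.counts.sum(axis=1).to_numpy() > 0
        assert np.allclose(sums[occupied], 1.0)
        assert (logo.information >= 0).all() and (logo.information <= 2).all()

    def test_random_flank_columns_near_zero_bits(self):
        rng = np.random.default_rng(600)
        records = []
        spec = PlantSpec.random("A", seed=601)
        stw = make_stwintron(spec, seed=602)
        for i in range(300):
            records.append(_record(stw, rec_id=f"r{i}",
                                   flank5=random_background(15, 0.5, rng),
                                   flank3=random_background(15, 0.5, rng)))
        logo = junction_logo(records)
        assert logo.information[:15].mean() < 0.05

    def test_short_flanks_padded_not_counted(self, cohort):
        rec = _record(make_stwintron(PlantSpec.random("A", seed=603), seed=604),
                      flank5="ACG", flank3="")
        logo = junction_logo([rec, cohort[0]])
        assert logo.counts.iloc[0].sum() == 1  # only the full-flank record


class TestExonContexts:
    def test_tallies(self, planted_a):
        recs = [
            _record(planted_a, "a", flank5="A" * 13 + "AG", flank3="GT" + "C" * 13),
            _record(planted_a, "b", flank5="A" * 12 + "TAG", flank3="GTA" + "A" * 12),
            _record(planted_a, "c", flank5="A" * 13 + "CC", flank3="AA" + "A" * 13),
        ]
        tally = exon_context_checks(recs)
        assert tally == {
            "ag_up_and_gt_down": 2, "tag_up": 1, "cag_up": 0,
            "gt_down": 2, "gta_down": 1, "g_down": 2,
        }

    def test_neutral_context_contributes_nothing(self, planted_a):
        rec = _record(planted_a, flank5="A" * 13 + "CC", flank3="AA" + "A" * 13)
        assert all(v == 0 for v in exon_context_checks([rec]).values())


class TestGroupSummary:
    def test_singleton_group_mean_is_the_value(self, cohort):
        summary = group_summary(cohort[:1])
        row = summary.table.loc["sister"]
        assert row["n"] == 1
        assert row["au_mean"] == row["au_min"] == row["au_max"]
        assert row["au_mean"] == pytest.approx(au_permille(cohort[0].sequence))

    def test_phase_proportions_sum_to_one(self, cohort):
        summary = group_summary(cohort)
        for _, row in summary.table.iterrows():
            assert row["phase0"] + row["phase1"] + row["phase2"] == pytest.approx(1.0)

    def test_au_curve_is_nondecreasing_and_half_point_reported(self, cohort):
        summary = group_summary(cohort)
        for gname, curve in summary.au_curves.items():
            assert (np.diff(curve["au_smoothed"]) >= -1e-9).all()
            assert summary.table.loc[gname, "au_min"] - 1e-9 <= summary.au_at_half[gname]
            assert summary.au_at_half[gname] <= summary.table.loc[gname, "au_max"] + 1e-9
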