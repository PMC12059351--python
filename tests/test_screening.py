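"""Dose-response tables, inhibition normalization and window detection."""

import numpy as np
import pandas as pd
import pytest

from ecmbridge import (ScreenDesign, WellRecord, analytic_windows,
                       build_screen_table, efficacy_window, export_heatmap,
                       generate_screen_dataset, inert_compound,
                       quantify_well, remodeling_inhibition, rocki_like,
                       tbri_like)
from ecmbridge.screening import EfficacyWindow, fit_hill


def make_records(compounds=("A", "B"), n_conc=6, n_rep=3,
                 score_fn=None, tox_fn=None):
    """Synthetic well records with CTR/TGFB controls."""
    score_fn = score_fn or (lambda comp, ci: 20.0 + 15.0 * ci)
    tox_fn = tox_fn or (lambda comp, ci: 0.05)
    recs = []
    for ctrl, score in (("CTR", 20.0), ("TGFB", 120.0)):
        for rep in range(1, n_rep + 1):
            recs.append(WellRecord(replicate=rep, remodeling_score=score,
                                   toxicity_fraction=0.02, control=ctrl))
    for comp in compounds:
        for ci in range(1, n_conc + 1):
            for rep in range(1, n_rep + 1):
                recs.append(WellRecord(
                    replicate=rep, remodeling_score=score_fn(comp, ci),
                    toxicity_fraction=tox_fn(comp, ci),
                    compound=comp, conc_index=ci))
    return recs


class TestInhibition:
    @pytest.mark.parametrize("score, expected", [
        (120.0, 0.0),    # equals the TGFB control
        (20.0, 100.0),   # equals the CTR control
        (70.0, 50.0),    # halfway
    ])
    def test_worked_values(self, score, expected):
        assert remodeling_inhibition(score, 20.0, 120.0) == \
            pytest.approx(expected)

    def test_inverted_controls_rejected(self):
        with pytest.raises(ValueError):
            remodeling_inhibition(50.0, 120.0, 20.0)

    def test_affine_invariance(self):
        base = remodeling_inhibition(70.0, 20.0, 120.0)
        shifted = remodeling_inhibition(70.0 + 13.0, 33.0, 133.0)
        assert shifted == pytest.approx(base)


class TestScreenTable:
    def test_record_count_and_aggregates(self):
        table = build_screen_table(make_records())
        assert len(table.records) == 2 * 6 * 3 + 6  # 42 wells
        agg = table.aggregates
        assert (agg["n"] == 3).all()
        assert agg["remodeling_sem"].notna().all()

    def test_missing_control_rejected(self):
        recs = [r for r in make_records() if r.control != "CTR"]
        with pytest.raises(ValueError, match="CTR"):
            build_screen_table(recs)

    def test_duplicate_well_rejected(self):
        recs = make_records()
        with pytest.raises(ValueError, match="duplicate"):
            build_screen_table(recs + [recs[-1]])

    def test_single_replicate_sem_flagged(self):
        recs = make_records(n_rep=1)
        table = build_screen_table(recs)
        assert table.aggregates["remodeling_sem"].isna().all()

    def test_heatmap_long_format_and_clipping(self, tmp_path):
        table = build_screen_table(make_records())
        long = export_heatmap(table, path=str(tmp_path / "hm.png"))
        assert len(long) == 3 * 6 * 2  # 18 rows per compound
        assert long["toxicity_fraction"].between(0, 1).all()
        assert (tmp_path / "hm.png").exists()


class TestEfficacyWindow:
    def test_partition_property(self):
        table = build_screen_table(make_records())
        for w in efficacy_window(table).values():
            union = w.effective_nontoxic | w.effective_toxic | w.ineffective
            assert union == set(range(1, 7))
            assert len(w.effective_nontoxic) + len(w.effective_toxic) + \
                len(w.ineffective) == 6

    def test_disjointness_enforced(self):
        with pytest.raises(ValueError):
            EfficacyWindow("X", {1, 2}, {2, 3}, {4, 5, 6}, 50.0, 0.2)

    def test_zero_potency_all_ineffective(self):
        recs = make_records(compounds=("inert",),
                            score_fn=lambda c, ci: 120.0)
        w = efficacy_window(build_screen_table(recs))["inert"]
        assert w.effective_nontoxic == set()
        assert w.ineffective == set(range(1, 7))

    def test_non_monotone_window_detected(self):
        # effective only at mid concentrations; detector must not assume
        # a monotone dose-response
        scores = {1: 110.0, 2: 40.0, 3: 45.0, 4: 115.0, 5: 118.0, 6: 119.0}
        recs = make_records(compounds=("bell",),
                            score_fn=lambda c, ci: scores[ci])
        w = efficacy_window(build_screen_table(recs))["bell"]
        assert w.effective_nontoxic == {2, 3}

    def test_toxic_doses_separated(self):
        tox = {1: 0.8, 2: 0.7, 3: 0.5, 4: 0.05, 5: 0.05, 6: 0.05}
        scores = {1: 25.0, 2: 25.0, 3: 30.0, 4: 55.0, 5: 110.0, 6: 118.0}
        recs = make_records(compounds=("rock",),
                            score_fn=lambda c, ci: scores[ci],
                            tox_fn=lambda c, ci: tox[ci])
        w = efficacy_window(build_screen_table(recs))["rock"]
        assert w.effective_toxic == {1, 2, 3}
        assert w.effective_nontoxic == {4}
        assert w.ineffective == {5, 6}


class TestAnalyticWindows:
    def test_preset_compounds_produce_expected_patterns(self):
        design = ScreenDesign(compounds=[rocki_like(), tbri_like(),
                                         inert_compound()])
        wins = analytic_windows(design)
        assert wins["ROCKi-like"]["effective_toxic"] == {1, 2, 3}
        assert wins["ROCKi-like"]["effective_nontoxic"] == {4}
        assert wins["TbRi-like"]["effective_nontoxic"] == {2, 3}
        assert 1 in wins["TbRi-like"]["ineffective"]  # non-monotone top dose
        assert wins["inert"]["ineffective"] == set(range(1, 7))

    def test_windows_match_threshold_sweep(self):
        # with a laxer efficacy threshold the window can only grow
        design = ScreenDesign(compounds=[rocki_like()])
        strict = analytic_windows(design, efficacy_threshold_pct=70.0)
        lax = analytic_windows(design, efficacy_threshold_pct=30.0)
        s = strict["ROCKi-like"]
        l = lax["ROCKi-like"]
        assert (s["effective_nontoxic"] | s["effective_toxic"]) <= \
            (l["effective_nontoxic"] | l["effective_toxic"])


class TestHillFit:
    def test_recovers_planted_parameters(self):
        conc = np.array([1.0, 3.0, 9.0, 27.0, 81.0, 243.0])
        resp = 90.0 * conc**2 / (conc**2 + 27.0**2)
        emax, ec50, h = fit_hill(conc, resp)
        assert emax == pytest.approx(90.0, rel=0.05)
        assert ec50 == pytest.approx(27.0, rel=0.05)
        assert h == pytest.approx(2.0, rel=0.1)


class TestEndToEnd:
    def test_quantified_screen_matches_analytic_windows(self):
        """Simulate a one-compound screen, quantify every well with the
        imaging pipeline, and recover the planted efficacy window."""
        design = ScreenDesign(compounds=[rocki_like()], n_replicates=2)
        ds = generate_screen_dataset(design, seed=21)
        assert len(ds.wells) == 1 * 6 * 2 + 4
        table = build_screen_table([quantify_well(w) for w in ds.wells])
        wins = efficacy_window(table)
        oracle = analytic_windows(design)["ROCKi-like"]
        w = wins["ROCKi-like"]
        assert w.effective_nontoxic == oracle["effective_nontoxic"]
        assert w.effective_toxic == oracle["effective_toxic"]
        assert w.ineffective == oracle["ineffective"]
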