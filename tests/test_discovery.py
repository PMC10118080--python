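"""Marker discovery, targeted screening, mixture limits, signal variability."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oilmark.marker_discovery import (
    MIXTURE_SCHEME,
    abundance_variability,
    discover_markers,
    fit_class_model,
    match_candidates_to_library,
    mixture_detection_table,
    screen_sample,
)
from oilmark.synthetic_data import PANEL_SPECIES, TARGET_SPECIES, SimulationDesign
from oilmark.types import Sample, ToleranceWindows


def panel_for(target):
    return [s for s in TARGET_SPECIES if s != target] + PANEL_SPECIES


class TestDiscovery:
    def test_noise_free_recovery_is_exact_per_species(self, noise_free_study, library):
        _, _, matrix, _ = noise_free_study
        model, _ = fit_class_model(matrix, cv_folds=None)
        for target in TARGET_SPECIES:
            cands = discover_markers(matrix, target, panel_for(target), model=model)
            lib_t = [m for m in library if m.oil == target]
            assert len(cands) == len(lib_t)
            matched = match_candidates_to_library(cands, lib_t)
            assert all(v is not None for v in matched.values())

    def test_candidates_are_exclusive_on_rescreen(self, noise_free_study):
        """Exclusivity is absolute: every accepted candidate has zero
        detections across the 64-sample negative panel."""
        samples, _, matrix, _ = noise_free_study
        model, _ = fit_class_model(matrix, cv_folds=None)
        for target in TARGET_SPECIES:
            panel = panel_for(target)
            n_panel = sum(
                1 for s in samples if s.species in panel and s.role in ("oil", "panel")
            )
            assert n_panel == 64
            for c in discover_markers(matrix, target, panel, model=model):
                assert c.panel_hits == 0
                assert c.class_frequency == 1.0

    def test_feature_shared_with_panel_is_excluded(self, noise_free_study):
        _, _, matrix, _ = noise_free_study
        model, _ = fit_class_model(matrix, cv_folds=None)
        # every consensus detected in any pumpkin sample must not be returned
        pumpkin_cols = matrix.class_columns("pumpkin")
        shared = set(np.flatnonzero(matrix.detected()[:, pumpkin_cols].any(axis=1)))
        cands = discover_markers(matrix, "sunflower", panel_for("sunflower"), model=model)
        mz_ref = matrix.consensus["mz_ref"].to_numpy()
        for c in cands:
            i = int(np.argmin(np.abs(mz_ref - c.mz_ref)))
            assert i not in shared

    def test_infinite_vip_threshold_returns_nothing(self, noise_free_study):
        _, _, matrix, _ = noise_free_study
        model, _ = fit_class_model(matrix, cv_folds=None)
        assert (
            discover_markers(
                matrix,
                "sunflower",
                panel_for("sunflower"),
                vip_threshold=np.inf,
                model=model,
            )
            == []
        )

    def test_missing_target_class_rejected(self, noise_free_study):
        _, _, matrix, _ = noise_free_study
        with pytest.raises(ValueError, match="absent"):
            discover_markers(matrix, "soybean", panel_for("sunflower"))

    def test_discovery_screening_consistency_on_fresh_samples(
        self, default_study, library
    ):
        """Markers discovered on one simulated study are recovered by
        targeted screening of freshly simulated pure oils of the same design."""
        from dataclasses import replace

        from oilmark.synthetic_data import simulate_dataset

        _, _, matrix, _ = default_study
        model, _ = fit_class_model(matrix, cv_folds=None)
        fresh, _ = simulate_dataset(replace(SimulationDesign(seed=7), seed=4242))
        for target in TARGET_SPECIES:
            cands = discover_markers(matrix, target, panel_for(target), model=model)
            lib_t = [m for m in library if m.oil == target]
            matched = match_candidates_to_library(cands, lib_t)
            recovered = {n for n, c in matched.items() if c is not None}
            for s in fresh:
                if s.species != target:
                    continue
                hits, _ = screen_sample(s, lib_t)
                assert recovered <= {h.marker.number for h in hits}


class TestScreening:
    def test_pure_sunflower_sample_hits_13_of_13_and_nothing_else(
        self, noise_free_study, library
    ):
        samples, _, _, _ = noise_free_study
        s = next(x for x in samples if x.species == "sunflower" and x.role == "oil")
        hits, summary = screen_sample(s, library)
        by_oil = summary.set_index("oil")
        assert by_oil.loc["sunflower", "n_hits"] == 13
        assert bool(by_oil.loc["sunflower", "complete"])
        assert by_oil.loc[["rapeseed", "sesame", "flax"], "n_hits"].sum() == 0

    def test_exact_feature_gives_zero_ppm_error_hit(self, library):
        s = Sample(
            id="x",
            features=pd.DataFrame(
                {"mz": [413.3429], "rt_min": [24.81], "height": [5000.0]}
            ),
        )
        hits, _ = screen_sample(s, library)
        assert len(hits) == 1
        assert hits[0].marker.number == 20
        assert hits[0].mz_error_ppm == pytest.approx(0.0, abs=1e-9)
        assert hits[0].rt_error_min == pytest.approx(0.0, abs=1e-12)

    def test_empty_sample_has_no_hits(self, library):
        hits, summary = screen_sample(Sample(id="e"), library)
        assert hits == []
        assert summary["n_hits"].sum() == 0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            screen_sample(Sample(id="e"), [])

    def test_fragment_confirmation_counts_and_gates(self, library):
        m20 = next(m for m in library if m.number == 20)
        s = Sample(
            id="x",
            features=pd.DataFrame(
                {"mz": [413.3429], "rt_min": [24.81], "height": [5000.0]}
            ),
        )
        ms2 = {20: list(m20.fragments[:3])}
        hits, _ = screen_sample(s, [m20], ms2_spectra=ms2, min_fragments=3)
        assert len(hits) == 1 and hits[0].fragments_matched == 3
        hits, _ = screen_sample(s, [m20], ms2_spectra=ms2, min_fragments=4)
        assert hits == []

    @given(mult=st.floats(1.0, 6.0), extra_ppm=st.floats(0.0, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_enlarging_windows_never_loses_hits(self, mult, extra_ppm):
        lib = [
            __import__("oilmark").types.MarkerRecord(
                "sesame", 1, 300.0, 10.0, 0.1, (120.0,), 20, True, True
            )
        ]
        s = Sample(
            id="x",
            features=pd.DataFrame(
                {"mz": [300.0008], "rt_min": [10.12], "height": [2000.0]}
            ),
        )
        base_hits, _ = screen_sample(s, lib, rt_tol_multiplier=1.5)
        w = ToleranceWindows(mz_ppm=5.0 + extra_ppm)
        more_hits, _ = screen_sample(s, lib, windows=w, rt_tol_multiplier=1.5 * mult)
        assert len(more_hits) >= len(base_hits)


@pytest.fixture(scope="module")
def table():
    return mixture_detection_table()


class TestMixtureTable:
    def test_reproduces_library_flags_noise_free(self, table, library):
        lib = {m.number: m for m in library}
        for _, r in table.iterrows():
            expected = (
                lib[r["number"]].detect_1pct
                if r["fraction"] == 0.01
                else lib[r["number"]].detect_5pct
            )
            assert bool(r["detected"]) is expected

    def test_per_oil_counts_at_1pct(self, table):
        at1 = table[table["fraction"] == 0.01]
        counts = at1.groupby("oil")["detected"].sum().to_dict()
        assert counts == {"sunflower": 13, "rapeseed": 6, "sesame": 3, "flax": 0}

    def test_all_detected_at_5pct(self, table):
        assert table.loc[table["fraction"] == 0.05, "detected"].all()

    def test_detection_monotone_in_fraction(self, library):
        tab = mixture_detection_table(fractions=(0.005, 0.02, 0.08))
        piv = tab.pivot(index="number", columns="fraction", values="detected")
        for _, row in piv.iterrows():
            assert row.is_monotonic_increasing or row.all() or not row.any()

    def test_scheme_matches_preparation_protocol(self):
        assert MIXTURE_SCHEME == {
            "flax": "sunflower",
            "sesame": "sunflower",
            "rapeseed": "sunflower",
            "sunflower": "rapeseed",
        }


class TestVariability:
    @pytest.mark.parametrize(
        "heights,expected",
        [
            ([100.0, 10.8], 89.2),
            ([5.0, 5.0, 5.0], 0.0),
            ([42.0], 0.0),
        ],
    )
    def test_formula(self, heights, expected):
        assert abundance_variability(heights) == pytest.approx(expected)

    def test_all_absent_is_undefined(self):
        assert abundance_variability([0.0, 0.0]) is None

    def test_default_noise_spread_matches_producer_batch_regime(
        self, default_study, library
    ):
        """Across the 8 samples of a species, marker signal spreads fall in
        the tens-of-percent regime produced by producer+batch variability."""
        samples, _, _, _ = default_study
        spreads = []
        for m in library:
            hs = []
            for s in samples:
                if s.species == m.oil and s.role == "oil":
                    hits, _ = screen_sample(s, [m])
                    if hits:
                        hs.append(hits[0].height)
            v = abundance_variability(hs)
            if v is not None:
                spreads.append(v)
        spreads = np.array(spreads)
        assert len(spreads) == 29
        assert 30.0 < spreads.min() and spreads.max() < 100.0
        assert 40.0 < np.median(spreads) < 95.0
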