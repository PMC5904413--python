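"""Pooled-library estimators: read assignment, enrichment, interference."""

import math

import numpy as np
import pandas as pd
import pytest

from cascadescope import pooled_quant as pq
from cascadescope import synthetic_data as synth
from cascadescope.duplex_model import build_variant_panel, classify_panel
from cascadescope.io import revcomp


@pytest.fixture
def library(spacer):
    return pq.panel_library(build_variant_panel(spacer))


class TestVariantLibrary:
    def test_windows_are_unique_and_present(self, library):
        for vid, window in library.windows.items():
            assert window in library.references[vid]
            for other, ref in library.references.items():
                if other != vid:
                    assert window not in ref and window not in revcomp(ref)

    def test_windows_pairwise_distinct(self, library):
        assert len(set(library.windows.values())) == 13

    def test_unresolvable_library_rejected(self):
        with pytest.raises(ValueError):
            pq.VariantLibrary(references={"a": "ACGTACGTACGT", "b": "ACGTACGTACGT"})


class TestAssignReads:
    def test_full_reference_reads_assign_to_their_variant(self, library):
        for vid, ref in library.references.items():
            table = pq.assign_reads([ref], library)
            assert table.counts.loc[vid].iloc[0] == 1
            assert table.counts.drop(vid).iloc[:, 0].sum() == 0

    def test_reverse_complement_reads_assign(self, library):
        ref = library.references["ix"]
        table = pq.assign_reads([revcomp(ref)], library)
        assert table.counts.loc["ix"].iloc[0] == 1

    def test_chimeric_read_unassigned(self, library):
        chimera = library.references["i"] + library.references["x"]
        table = pq.assign_reads([chimera], library, condition="c")
        assert table.counts["c"].sum() == 0
        assert table.unassigned["c"] == 1

    def test_counts_match_simulation_truth(self, library):
        rng = np.random.default_rng(1)
        truth_counts = {vid: int(rng.integers(5, 30)) for vid in library.references}
        reads = [
            ref
            for vid, ref in library.references.items()
            for _ in range(truth_counts[vid])
        ]
        table = pq.assign_reads(reads, library, condition="r")
        assert table.counts["r"].to_dict() == truth_counts
        assert table.total("r") == sum(truth_counts.values())

    def test_short_read_rejected(self, library):
        with pytest.raises(ValueError):
            pq.assign_reads(["ACGT"], library)


def series(d):
    return pd.Series(d, dtype=float)


class TestChipEnrichment:
    def test_null_enrichment_is_one(self):
        counts = series({"i": 500, "ix": 300, "ii": 200})
        result = pq.chip_enrichment(counts, counts * 7, reference_variant="i")
        assert np.allclose(result["enrichment"], 1.0)

    def test_arithmetic(self):
        chip = series({"i": 100, "v": 900})
        inp = series({"i": 100, "v": 100})
        result = pq.chip_enrichment(chip, inp, reference_variant="i")
        assert result.loc["v", "enrichment"] == pytest.approx(9.0)
        assert result.loc["i", "enrichment"] == 1.0

    def test_scale_invariance_exact(self):
        rng = np.random.default_rng(2)
        chip = series({f"v{i}": c for i, c in enumerate(rng.integers(10, 500, 8))})
        inp = series({f"v{i}": c for i, c in enumerate(rng.integers(10, 500, 8))})
        a = pq.chip_enrichment(chip, inp, reference_variant="v0")
        b = pq.chip_enrichment(chip * 13, inp * 7, reference_variant="v0")
        assert np.array_equal(a["enrichment"].to_numpy(), b["enrichment"].to_numpy())

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pq.chip_enrichment(series({"i": 0, "v": 5}), series({"i": 5, "v": 5}))

    def test_zero_nonreference_gets_pseudocount_and_flag(self):
        chip = series({"i": 100, "xi": 0})
        inp = series({"i": 100, "xi": 100})
        result = pq.chip_enrichment(chip, inp, reference_variant="i")
        assert result.loc["xi", "is_bound"]
        assert 0 < result.loc["xi", "enrichment"] < 0.02

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_recovers_simulated_factors_within_3sd(self, seed):
        """ChIP enrichment factors are recovered from 1e5-read multinomials."""
        variants = [f"v{i}" for i in range(13)]
        abund = {v: 1 / 13 for v in variants}
        effects = {v: e for v, e in zip(variants, [1.0, 0.02, 0.3, 0.1, 0.05,
                                                   0.07, 0.2, 0.5, 1.1, 0.9,
                                                   0.02, 0.02, 0.03])}
        inp = synth.simulate_pool_counts(abund, 1.0, 100_000, seed=seed, condition="input")
        chip = synth.simulate_pool_counts(abund, effects, 100_000, seed=seed + 50,
                                          condition="chip")
        result = pq.chip_enrichment(chip, inp, reference_variant="v0")
        p_eff = np.array(list(effects.values())) / sum(effects.values())
        for i, v in enumerate(variants):
            got = result.loc[v, "enrichment"]
            want = effects[v] / effects["v0"]
            # delta-method SD of log ratio from the four multinomial counts
            sd = math.sqrt(
                1 / (100_000 * p_eff[i]) + 1 / (100_000 * p_eff[0])
                + 1 / (100_000 / 13) + 1 / (100_000 / 13)
            )
            assert abs(math.log(got) - math.log(want)) < 3 * sd


class TestInterferenceEfficiency:
    def test_no_depletion_gives_one(self):
        counts = series({"i": 700, "ii": 700, "x": 700})
        result = pq.interference_efficiency(counts, counts, reference_variant="ii")
        assert np.allclose(result["interference"], 1.0)

    def test_hundredfold_depletion(self):
        no_cas3 = series({"i": 1000, "ii": 1000})
        cas3 = series({"i": 10, "ii": 1000})
        result = pq.interference_efficiency(no_cas3, cas3, reference_variant="ii")
        assert result.loc["i", "interference"] == pytest.approx(100.0)

    def test_zero_cas3_count_flagged_as_bound(self):
        no_cas3 = series({"i": 1000, "ii": 1000})
        cas3 = series({"i": 0, "ii": 1000})
        result = pq.interference_efficiency(no_cas3, cas3, reference_variant="ii")
        assert result.loc["i", "is_bound"]
        assert result.loc["i", "interference"] > 100

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_recovers_simulated_depletion_within_3sd(self, seed):
        variants = [f"v{i}" for i in range(13)]
        abund = {v: 1 / 13 for v in variants}
        depletion = {v: (100.0 if v in ("v0", "v2", "v6", "v7") else 1.0)
                     for v in variants}
        survive = {v: 1 / d for v, d in depletion.items()}
        no_cas3 = synth.simulate_pool_counts(abund, 1.0, 100_000, seed=seed,
                                             condition="no_cas3")
        cas3 = synth.simulate_pool_counts(abund, survive, 100_000, seed=seed + 50,
                                          condition="cas3")
        result = pq.interference_efficiency(no_cas3, cas3, reference_variant="v1")
        p_surv = np.array(list(survive.values())) / sum(survive.values())
        for i, v in enumerate(variants):
            got = result.loc[v, "interference"]
            want = depletion[v] / depletion["v1"]
            sd = math.sqrt(
                1 / (100_000 / 13) * 2
                + 1 / (100_000 * p_surv[i]) + 1 / (100_000 * p_surv[1])
            )
            assert abs(math.log(got) - math.log(want)) < 3 * sd

    def test_end_to_end_classifier_agreement(self, spacer):
        """Variants the classifier calls interference-positive are exactly the
        ones whose pooled depletion estimate exceeds a 3-SD null threshold."""
        rows = classify_panel(spacer)
        positive_truth = {label for label, _, _, call in rows
                          if call.interference == "detectable"}
        variants = [label for label, *_ in rows]
        abund = {v: 1 / 13 for v in variants}
        survive = {v: (0.01 if v in positive_truth else 1.0) for v in variants}
        for seed in (21, 22, 23):
            no_cas3 = synth.simulate_pool_counts(abund, 1.0, 100_000, seed=seed,
                                                 condition="a")
            cas3 = synth.simulate_pool_counts(abund, survive, 100_000, seed=seed + 5,
                                              condition="b")
            result = pq.interference_efficiency(no_cas3, cas3, reference_variant="ii")
            null_sd = math.sqrt(4 * 13 / 100_000)  # log-scale SD for an i_v = 1 variant
            called = {v for v in variants
                      if math.log(result.loc[v, "interference"]) > 3 * null_sd}
            assert called == positive_truth


class TestTransformationEfficiency:
    def test_no_interference_is_one(self):
        r = pq.transformation_efficiency(200, 200, 200, 200)
        assert r.value == 1.0 and not r.below_detection

    def test_halved_counts(self):
        r = pq.transformation_efficiency(100, 200, 200, 200)
        assert r.value == pytest.approx(0.5)

    def test_zero_transformants_reported_against_floor(self):
        r = pq.transformation_efficiency(0, 200, 200, 200)
        assert r.value == 0.0
        assert r.below_detection
        assert r.detection_floor == pytest.approx(3e-5)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pq.transformation_efficiency(10, 0, 200, 200)


class TestAdaptationMetrics:
    def test_positive_fraction(self):
        assert pq.positive_fraction(12, 1000) == pytest.approx(0.012)

    def test_one_expansion_unit(self):
        call = pq.expansion_units(561, 500)
        assert call.units == 1 and call.is_clean  # one 61-bp spacer/repeat unit

    def test_parental_amplicon_is_zero_units(self):
        call = pq.expansion_units(500, 500)
        assert call.units == 0 and call.is_clean

    def test_off_unit_residual_flagged(self):
        call = pq.expansion_units(530, 500)
        assert not call.is_clean

    def test_combined_interface(self):
        out = pq.adaptation_metrics(positives=12, total=1000,
                                    amplicon_lengths=[500, 561, 622],
                                    parental_length=500)
        assert out["positive_fraction"] == pytest.approx(0.012)
        assert [e.units for e in out["expansions"]] == [0, 1, 2]

    def test_invalid_events_rejected(self):
        with pytest.raises(ValueError):
            pq.positive_fraction(5, 0)
        with pytest.raises(ValueError):
            pq.expansion_units(-10, 500)
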